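"""Per-nucleotide Matthews-correlation concordance of peak sets and
cutoff clustering of samples into cell types.

Two peak sets over the same genome induce a binary labeling of every base
(in/out of a peak).  Their agreement is summarised by the confusion counts

    TP  bases in peaks of both samples
    FP  bases in peaks of B only        (with A the reference operand)
    FN  bases in peaks of A only
    TN  bases in peaks of neither

and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

MCC is symmetric in the two samples (swapping them exchanges FP and FN).
Samples whose pairwise MCC exceeds a cutoff are taken to be the same cell
type; clustering is by connected components of the thresholded graph, with
an average-linkage hierarchical alternative.  Singleton clusters are flagged
as outliers.

Counts are held as Python integers (exact) and the MCC is evaluated in
double precision; for genome-scale counts the relative error is < 1e-12.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .intervals import GenomeAssembly, IntervalSet, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MccMatrix",
    "ClusterAssignment",
    "confusion_counts",
    "mcc",
    "mcc_matrix",
    "threshold_clusters",
    "merge_cluster_peaks",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Base-level confusion counts of two peak sets on one assembly."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(
    a: IntervalSet, b: IntervalSet, assembly: GenomeAssembly
) -> ConfusionCounts:
    """TP/FP/FN/TN over every assembly base, with ``a`` as reference.

    TN counts all uncovered assembly bases; gaps are not excluded.
    """
    for s in (a, b):
        for iv in s:
            if iv.chrom not in assembly:
                raise ValidationError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > assembly[iv.chrom]:
                raise ValidationError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {assembly[iv.chrom]}"
                )
    tp = a.intersect_bases(b)
    fn = a.total_bases() - tp
    fp = b.total_bases() - tp
    tn = assembly.total_length - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def mcc(c: ConfusionCounts) -> float | None:
    """Matthews correlation; None (undefined) when a marginal is zero.

    A zero factor in the radicand — e.g. one sample has no peaks at all —
    makes the coefficient 0/0; that propagates as None, never as 0 or an
    exception, so an empty sample cannot silently look 'uncorrelated'.
    """
    d1 = c.tp + c.fp
    d2 = c.tp + c.fn
    d3 = c.tn + c.fp
    d4 = c.tn + c.fn
    if d1 == 0 or d2 == 0 or d3 == 0 or d4 == 0:
        return None
    num = c.tp * c.tn - c.fp * c.fn  # exact integer arithmetic
    denom = math.sqrt(float(d1) * float(d2) * float(d3) * float(d4))
    return float(num) / denom


@dataclass
class MccMatrix:
    """Symmetric sample-by-sample MCC matrix; NaN marks undefined entries."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match sample count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MccMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def mcc_matrix(
    samples: Sequence[IntervalSet], assembly: GenomeAssembly
) -> MccMatrix:
    """All pairwise MCCs of >=2 samples; diagonal 1 for non-empty samples."""
    if len(samples) < 2:
        raise ValidationError("MCC matrix needs at least 2 samples")
    ids = [s.sample_id or f"sample{i}" for i, s in enumerate(samples)]
    if len(set(ids)) != len(ids):
        raise ValidationError("sample ids must be unique")
    n = len(samples)
    vals = np.full((n, n), np.nan)
    totals = [s.total_bases() for s in samples]
    genome = assembly.total_length
    for i in range(n):
        vals[i, i] = 1.0 if 0 < totals[i] < genome else np.nan
        for j in range(i + 1, n):
            m = mcc(confusion_counts(samples[i], samples[j], assembly))
            vals[i, j] = vals[j, i] = np.nan if m is None else m
    return MccMatrix(ids, vals)


@dataclass(frozen=True)
class ClusterAssignment:
    """sample -> cluster id partition with singleton clusters flagged."""

    assignment: Mapping[str, int]
    outliers: frozenset[str]

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sample, cid in self.assignment.items():
            out.setdefault(cid, []).append(sample)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": list(self.assignment),
                "cluster": [self.assignment[s] for s in self.assignment],
                "outlier": [int(s in self.outliers) for s in self.assignment],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def threshold_clusters(
    m: MccMatrix, cutoff: float = 0.55, method: str = "components"
) -> ClusterAssignment:
    """Cluster samples whose pairwise MCC exceeds ``cutoff``.

    ``method='components'`` (default): connected components of the graph with
    an edge wherever MCC > cutoff — deterministic and parameter-free.
    ``method='average'``: average-linkage hierarchical clustering on distance
    1 - MCC, tree cut at 1 - cutoff.

    Undefined (NaN) entries are treated as below the cutoff with a warning,
    so an empty sample becomes a singleton outlier instead of poisoning the
    clustering.  Cluster ids are assigned in order of first member appearance.
    """
    if not (-1 < cutoff < 1):
        raise ValidationError(f"cutoff must be in (-1, 1), got {cutoff}")
    vals = m.values
    n = len(m.sample_ids)
    off_diag = ~np.eye(n, dtype=bool)
    if np.isnan(vals[off_diag]).any():
        log.warning("undefined MCC entries treated as below the cutoff")
    adj = np.zeros((n, n), dtype=bool)
    with np.errstate(invalid="ignore"):
        adj[off_diag] = vals[off_diag] > cutoff

    if method == "components":
        _, labels = connected_components(csr_matrix(adj), directed=False)
    elif method == "average":
        with np.errstate(invalid="ignore"):
            dist = 1.0 - np.where(np.isnan(vals), -1.0, vals)
        np.fill_diagonal(dist, 0.0)
        dist = np.maximum(dist, dist.T)  # enforce exact symmetry for squareform
        z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(z, t=1.0 - cutoff, criterion="distance")
    else:
        raise ValidationError(f"unknown clustering method {method!r}")

    # renumber clusters by first appearance for deterministic ids
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for sample, lab in zip(m.sample_ids, labels):
        cid = remap.setdefault(int(lab), len(remap))
        assignment[sample] = cid
    sizes: dict[int, int] = {}
    for cid in assignment.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    outliers = frozenset(s for s, cid in assignment.items() if sizes[cid] == 1)
    return ClusterAssignment(assignment, outliers)


def merge_cluster_peaks(samples: Sequence[IntervalSet], sample_id: str = "") -> IntervalSet:
    """Merged union of a cluster's member peak sets — one enhancer set per
    cell type."""
    if not samples:
        raise ValidationError("cannot merge an empty cluster")
    intervals = [iv for s in samples for iv in s]
    assembly = next((s.assembly for s in samples if s.assembly is not None), None)
    return IntervalSet(
        intervals,
        sample_id=sample_id or "+".join(s.sample_id for s in samples),
        assembly=assembly,
    ).merge()
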