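"""Shared fixtures and the per-nucleotide boolean-array oracle.

The oracle materialises interval sets as boolean coverage masks over a toy
genome and recomputes every base-level statistic by exhaustive counting —
a deliberately naive, independent reference for the interval algebra.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from enhsnp.intervals import GenomeAssembly, GenomicInterval, IntervalSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# oracle helpers (importable via fixtures)
# ---------------------------------------------------------------------------


def coverage_masks(s: IntervalSet, assembly: GenomeAssembly) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(assembly[c], dtype=bool) for c in assembly.chroms}
    for iv in s:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def oracle_total_bases(s: IntervalSet, assembly: GenomeAssembly) -> int:
    return int(sum(m.sum() for m in coverage_masks(s, assembly).values()))


def oracle_intersect_bases(a: IntervalSet, b: IntervalSet, assembly: GenomeAssembly) -> int:
    ma, mb = coverage_masks(a, assembly), coverage_masks(b, assembly)
    return int(sum((ma[c] & mb[c]).sum() for c in assembly.chroms))


def oracle_confusion(a: IntervalSet, b: IntervalSet, assembly: GenomeAssembly):
    ma, mb = coverage_masks(a, assembly), coverage_masks(b, assembly)
    tp = fp = fn = tn = 0
    for c in assembly.chroms:
        tp += int((ma[c] & mb[c]).sum())
        fn += int((ma[c] & ~mb[c]).sum())
        fp += int((~ma[c] & mb[c]).sum())
        tn += int((~ma[c] & ~mb[c]).sum())
    return tp, fp, fn, tn


def oracle_snp_hits(chrom_pos_pairs, s: IntervalSet, assembly: GenomeAssembly) -> int:
    masks = coverage_masks(s, assembly)
    return sum(1 for c, p in chrom_pos_pairs if c in masks and masks[c][p])


def random_interval_set(
    rng: np.random.Generator,
    assembly: GenomeAssembly,
    n: int,
    max_len: int = 500,
    sample_id: str = "random",
) -> IntervalSet:
    intervals = []
    chroms = assembly.chroms
    for _ in range(n):
        c = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, assembly[c] - 1))
        length = int(rng.integers(1, min(max_len, assembly[c] - start) + 1))
        intervals.append(GenomicInterval(c, start, start + length))
    return IntervalSet(intervals, sample_id=sample_id, assembly=assembly)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def toy_assembly() -> GenomeAssembly:
    """10 kb toy genome on two chromosomes — small enough for the oracle."""
    return GenomeAssembly({"chr1": 6000, "chr2": 4000})


@pytest.fixture
def tiny_assembly() -> GenomeAssembly:
    return GenomeAssembly({"chr1": 100})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def oracle():
    """Bundle of brute-force per-base reference implementations."""

    class Oracle:
        masks = staticmethod(coverage_masks)
        total_bases = staticmethod(oracle_total_bases)
        intersect_bases = staticmethod(oracle_intersect_bases)
        confusion = staticmethod(oracle_confusion)
        snp_hits = staticmethod(oracle_snp_hits)
        random_set = staticmethod(random_interval_set)

    return Oracle
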