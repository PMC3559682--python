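"""Disease-vs-background SNP enrichment statistics.

The central quantity: for a region collection R, the enrichment of a disease
SNP set D over a background set B is

    e = (k_D / n_D) / (k_B / n_B)

with k the number of SNPs inside R and n the set size.  e > 1 means disease
SNPs are over-represented in R.  Significance comes from the uncorrected
Pearson chi-square test on the 2x2 table (in-region / not-in-region x
disease / background), df = 1, two-sided.

On top of that sit the derived analyses: per-chromatin-state enrichment,
cell-type sharing profiles, enrichment stratified by how many other cell
types share an enhancer, TFBS overlap fractions, and LD proxy expansion of a
lead-SNP list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet, SnpRecord, SnpSet, ValidationError, count_snps_in_set

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "SharingProfile",
    "UndefinedEnrichmentError",
    "enrichment_ratio",
    "chi_square_2x2",
    "snp_set_enrichment",
    "state_enrichment",
    "sharing_profiles",
    "stratified_enrichment",
    "tfbs_overlap_fraction",
    "expand_by_ld",
    "enrichment_table",
    "printed_p_value",
]


class UndefinedEnrichmentError(ValueError):
    """Raised when the enrichment ratio has a zero denominator (k_b = 0)."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of disease/background SNPs in/out of a region collection."""

    k_d: int  # disease SNPs in region
    m_d: int  # disease SNPs not in region
    k_b: int  # background SNPs in region
    m_b: int  # background SNPs not in region

    def __post_init__(self):
        for v in (self.k_d, self.m_d, self.k_b, self.m_b):
            if v < 0:
                raise ValidationError("contingency counts must be non-negative")

    @property
    def n_d(self) -> int:
        return self.k_d + self.m_d

    @property
    def n_b(self) -> int:
        return self.k_b + self.m_b

    def as_array(self) -> np.ndarray:
        return np.array([[self.k_d, self.m_d], [self.k_b, self.m_b]], dtype=np.int64)


@dataclass(frozen=True)
class EnrichmentResult:
    """One row of a per-tissue enrichment report.

    ``enrichment`` is None when undefined (k_b = 0); ``chi2``/``p_value`` are
    None when the test was skipped on a degenerate table.  ``degenerate``
    carries the reason, if any.
    """

    region_label: str
    table: ContingencyTable2x2
    enrichment: float | None
    chi2: float | None
    p_value: float | None
    degenerate: str | None = None


def enrichment_ratio(k_d: int, n_d: int, k_b: int, n_b: int) -> float:
    """(k_d/n_d) / (k_b/n_b); raises UndefinedEnrichmentError when k_b = 0.

    k_d = 0 with k_b > 0 is a genuine enrichment of 0, not an error.
    """
    if n_d <= 0 or n_b <= 0:
        raise ValidationError("set sizes must be positive")
    if k_b == 0:
        raise UndefinedEnrichmentError(
            "background count in region is 0; enrichment undefined"
        )
    return (k_d / n_d) / (k_b / n_b)


def chi_square_2x2(t: ContingencyTable2x2) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on the 2x2 table, df=1, two-sided.

    No Yates continuity correction: this is the convention the enrichment
    tables here follow (genome-scale counts make the correction irrelevant
    anyway, and it would shift small-table p-values).
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("chi-square undefined: a table margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def printed_p_value(chi2: float, stat_decimals: int = 2) -> float:
    """p evaluated at the chi-square statistic rounded to ``stat_decimals``.

    Historical enrichment tables were often produced by rounding the
    statistic before looking up p (e.g. sf(0.60) = 0.4386 rather than
    sf(0.599) = 0.4390); this helper reproduces that display convention.
    Full-precision p-values are what the analysis itself carries.
    """
    return float(stats.chi2.sf(round(chi2, stat_decimals), df=1))


def snp_set_enrichment(
    disease: SnpSet,
    background: SnpSet,
    region: IntervalSet,
    label: str = "",
) -> EnrichmentResult:
    """Build the 2x2 table for one region collection and test it.

    Each SNP counts once no matter how many intervals cover it.  Degenerate
    cases (empty region, zero in-region counts on both sides) come back
    flagged rather than raising.
    """
    common = disease.rsids & background.rsids
    if common:
        raise ValidationError(
            f"disease and background sets share {len(common)} rsids "
            "(background must have the disease set subtracted)"
        )
    k_d = count_snps_in_set(disease, region)
    k_b = count_snps_in_set(background, region)
    table = ContingencyTable2x2(k_d, disease.size - k_d, k_b, background.size - k_b)
    return _result_from_table(table, label)


def _result_from_table(table: ContingencyTable2x2, label: str) -> EnrichmentResult:
    if table.k_b == 0:
        if table.k_d == 0:
            log.warning("region %r contains no SNPs of either set; test skipped", label)
            return EnrichmentResult(label, table, 0.0, None, None, "empty-region")
        return EnrichmentResult(label, table, None, None, None, "undefined-ratio")
    e = enrichment_ratio(table.k_d, table.n_d, table.k_b, table.n_b)
    if table.m_d == 0 and table.m_b == 0:
        # region covers every SNP of both sets: both fractions 1, no signal
        return EnrichmentResult(label, table, e, 0.0, 1.0, "saturated")
    chi2, p = chi_square_2x2(table)
    return EnrichmentResult(label, table, e, chi2, p)


def from_counts(
    k_d: int, n_d: int, k_b: int, n_b: int, label: str = ""
) -> EnrichmentResult:
    """EnrichmentResult straight from marginal counts (e.g. a published table)."""
    return _result_from_table(
        ContingencyTable2x2(k_d, n_d - k_d, k_b, n_b - k_b), label
    )


# ---------------------------------------------------------------------------
# chromatin-state enrichment
# ---------------------------------------------------------------------------


def state_enrichment(
    disease: SnpSet,
    background: SnpSet,
    segmentation: IntervalSet,
) -> list[EnrichmentResult]:
    """One enrichment per chromatin-state label of a labeled segmentation.

    Same-label segments may overlap (they merge); different-label segments
    overlapping each other make the per-base state ill-defined and are
    rejected.  A SNP in no segment contributes to every label's not-in-region
    cell.
    """
    by_label: dict[str, list] = {}
    for iv in segmentation:
        if iv.label is None:
            raise ValidationError("segmentation contains an unlabeled interval")
        by_label.setdefault(iv.label, []).append(iv)
    label_sets = {
        lab: IntervalSet(ivs, sample_id=lab, assembly=segmentation.assembly)
        for lab, ivs in by_label.items()
    }
    labels = sorted(label_sets)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if label_sets[a].intersect_bases(label_sets[b]) > 0:
                raise ValidationError(
                    f"states {a!r} and {b!r} overlap; segmentation labels must "
                    "partition their covered bases"
                )
    return [
        snp_set_enrichment(disease, background, label_sets[lab], label=lab)
        for lab in labels
    ]


# ---------------------------------------------------------------------------
# sharing profiles & stratified enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SharingProfile:
    """Which cell types' merged enhancer sets cover one SNP."""

    rsid: str
    membership: tuple[int, ...]  # 0/1 per cell type, in input order
    sharing_count: int


def sharing_profiles(
    snps: SnpSet, merged_sets: Mapping[str, IntervalSet]
) -> tuple[list[SharingProfile], dict[int, int]]:
    """Per-SNP cell-type membership vectors plus the sharing histogram.

    The histogram counts SNPs by how many cell types cover them, restricted
    to SNPs covered at least once (SNPs in no enhancer are left out, as in a
    sharing-matrix figure).
    """
    matrix = _membership_matrix(snps, merged_sets)
    profiles = []
    hist: dict[int, int] = {}
    for r, row in zip(snps, matrix):
        count = int(row.sum())
        profiles.append(SharingProfile(r.rsid, tuple(int(x) for x in row), count))
        if count >= 1:
            hist[count] = hist.get(count, 0) + 1
    return profiles, hist


def _membership_matrix(
    snps: SnpSet, merged_sets: Mapping[str, IntervalSet]
) -> np.ndarray:
    cols = [snps.membership(s) for s in merged_sets.values()]
    if not cols:
        return np.zeros((snps.size, 0), dtype=bool)
    return np.column_stack(cols)


def sharing_matrix_frame(
    snps: SnpSet, merged_sets: Mapping[str, IntervalSet]
) -> pd.DataFrame:
    """SNPs x cell types 0/1 DataFrame (all SNPs, ordered as the input set)."""
    matrix = _membership_matrix(snps, merged_sets).astype(int)
    return pd.DataFrame(
        matrix, index=[r.rsid for r in snps], columns=list(merged_sets)
    )


def stratified_enrichment(
    disease: SnpSet,
    background: SnpSet,
    focal: str,
    merged_sets: Mapping[str, IntervalSet],
    stratum: int,
    mode: str = "exact",
) -> EnrichmentResult:
    """Enrichment restricted to positions in the focal cell type's enhancers
    shared with a given number of additional cell types.

    ``mode='exact'``: exactly ``stratum`` other cell types also cover the SNP;
    ``mode='cumulative'``: at most ``stratum`` others.  Membership is
    evaluated per SNP position via sharing profiles.
    """
    if focal not in merged_sets:
        raise ValidationError(f"unknown focal cell type {focal!r}")
    n_others = len(merged_sets) - 1
    if not (0 <= stratum <= n_others):
        raise ValidationError(f"stratum must be in [0, {n_others}], got {stratum}")
    if mode not in ("exact", "cumulative"):
        raise ValidationError(f"mode must be 'exact' or 'cumulative', got {mode!r}")

    def in_stratum(snps: SnpSet) -> int:
        m = _membership_matrix(snps, merged_sets)
        focal_col = list(merged_sets).index(focal)
        in_focal = m[:, focal_col]
        others = m.sum(axis=1) - in_focal
        if mode == "exact":
            sel = in_focal & (others == stratum)
        else:
            sel = in_focal & (others <= stratum)
        return int(sel.sum())

    k_d = in_stratum(disease)
    k_b = in_stratum(background)
    table = ContingencyTable2x2(k_d, disease.size - k_d, k_b, background.size - k_b)
    label = f"{focal}+{stratum}{'<=' if mode == 'cumulative' else ''}"
    return _result_from_table(table, label)


# ---------------------------------------------------------------------------
# TFBS overlap
# ---------------------------------------------------------------------------


def tfbs_overlap_fraction(
    snps_in_enh: SnpSet, snps_out_enh: SnpSet, tfbs: IntervalSet
) -> tuple[float, float, float]:
    """Fractions of each SNP set overlapping TFBSs, and their ratio.

    The two sets are the disease SNPs inside vs outside enhancers; a ratio
    of ~4 means enhancer-resident SNPs hit binding sites four times as often.
    """
    if snps_in_enh.size == 0 or snps_out_enh.size == 0:
        raise ValidationError("TFBS overlap fractions undefined for an empty SNP set")
    common = snps_in_enh.rsids & snps_out_enh.rsids
    if common:
        raise ValidationError("the two SNP sets must be disjoint")
    f_in = count_snps_in_set(snps_in_enh, tfbs) / snps_in_enh.size
    f_out = count_snps_in_set(snps_out_enh, tfbs) / snps_out_enh.size
    ratio = float("nan") if f_out == 0 else f_in / f_out
    return f_in, f_out, ratio


# ---------------------------------------------------------------------------
# LD expansion
# ---------------------------------------------------------------------------


def expand_by_ld(
    leads: SnpSet,
    ld_table: pd.DataFrame | Iterable[tuple],
    threshold: float,
    coords: Mapping[str, tuple[str, int]] | None = None,
    name: str | None = None,
) -> SnpSet:
    """Union of lead SNPs and their LD proxies at r^2 >= threshold.

    ``ld_table`` rows are (lead_rsid, linked_rsid, r2), optionally with
    chrom/pos columns for the linked SNP; otherwise coordinates come from
    ``coords``.  Linked SNPs without coordinates are dropped with a warning.
    Proxies shared by several leads appear once (first lead wins).
    """
    if not (0 < threshold <= 1):
        raise ValidationError(f"r^2 threshold must be in (0, 1], got {threshold}")
    if not isinstance(ld_table, pd.DataFrame):
        ld_table = pd.DataFrame(
            list(ld_table), columns=["lead_rsid", "linked_rsid", "r2"]
        )
    records: list[SnpRecord] = []
    seen: set[str] = set()
    for r in leads:
        records.append(r)
        seen.add(r.rsid)
    has_coords = {"chrom", "pos"}.issubset(ld_table.columns)
    lead_ids = leads.rsids
    for row in ld_table.itertuples(index=False):
        if row.lead_rsid not in lead_ids or float(row.r2) < threshold:
            continue
        if row.linked_rsid in seen:
            continue
        if has_coords and not pd.isna(row.pos):
            chrom, pos = str(row.chrom), int(row.pos)
        elif coords is not None and row.linked_rsid in coords:
            chrom, pos = coords[row.linked_rsid]
        else:
            log.warning(
                "linked SNP %s has no coordinates; dropped", row.linked_rsid
            )
            continue
        records.append(
            SnpRecord(
                rsid=row.linked_rsid,
                chrom=chrom,
                pos=pos,
                origin="ld_linked",
                lead_rsid=row.lead_rsid,
                r2_to_lead=float(row.r2),
            )
        )
        seen.add(row.linked_rsid)
    return SnpSet(name or f"{leads.name}+ld", records)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def enrichment_table(
    results: Sequence[EnrichmentResult], bonferroni: bool = False
) -> pd.DataFrame:
    """Per-region enrichment DataFrame: label, counts, enrichment, chi2, p.

    ``bonferroni=True`` appends a Bonferroni-adjusted p column (off by
    default; the raw chi-square p is the primary statistic reported).
    """
    rows = []
    for r in results:
        rows.append(
            {
                "region": r.region_label,
                "k_d": r.table.k_d,
                "n_d": r.table.n_d,
                "k_b": r.table.k_b,
                "n_b": r.table.n_b,
                "enrichment": r.enrichment,
                "chi2": r.chi2,
                "p_value": r.p_value,
                "degenerate": r.degenerate or "",
            }
        )
    df = pd.DataFrame(rows)
    if bonferroni and len(df):
        m = df["p_value"].notna().sum()
        df["p_bonferroni"] = (df["p_value"] * m).clip(upper=1.0)
    return df
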