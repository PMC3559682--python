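"""Enrichment statistics: ratio, chi-square, states, sharing, strata, TFBS, LD.

Reference values: the published asthma/enhancer contingency counts (e.g.
430 of 2,510 disease SNPs vs 921,179 of 11,327,391 background SNPs in CD4+
T-cell enhancers gives enrichment 2.11), a hand-evaluated chi-square table,
and brute-force recounts on random fixtures.
"""

import math

import numpy as np
import pandas as pd
import pytest

from enhsnp.enrichment import (
    ContingencyTable2x2,
    UndefinedEnrichmentError,
    chi_square_2x2,
    enrichment_ratio,
    enrichment_table,
    expand_by_ld,
    from_counts,
    printed_p_value,
    sharing_profiles,
    snp_set_enrichment,
    state_enrichment,
    stratified_enrichment,
    tfbs_overlap_fraction,
)
from enhsnp.intervals import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    SnpRecord,
    SnpSet,
    ValidationError,
)
from conftest import random_interval_set

TOY = GenomeAssembly({"chr1": 6000, "chr2": 4000})


def _snps(name, positions, chrom="chr1", prefix="rs"):
    return SnpSet(
        name, [SnpRecord(f"{name}_{prefix}{i}", chrom, p) for i, p in enumerate(positions)]
    )


class TestEnrichmentRatio:
    def test_published_cd4_and_brain_rows(self):
        assert enrichment_ratio(430, 2510, 921179, 11327391) == pytest.approx(2.11, abs=0.005)
        assert enrichment_ratio(202, 2510, 1190305, 11327391) == pytest.approx(0.77, abs=0.005)

    def test_equal_fractions_give_unity(self):
        assert enrichment_ratio(10, 100, 100, 1000) == pytest.approx(1.0)

    def test_zero_background_count_is_undefined_not_infinite(self):
        with pytest.raises(UndefinedEnrichmentError):
            enrichment_ratio(5, 100, 0, 1000)

    def test_zero_disease_count_is_genuine_zero(self):
        assert enrichment_ratio(0, 100, 50, 1000) == 0.0


class TestChiSquare:
    def test_kidney_row_statistic_and_printed_p(self):
        chi2, p = chi_square_2x2(ContingencyTable2x2(177, 2333, 755135, 10572256))
        assert chi2 == pytest.approx(0.599, abs=0.001)
        assert p == pytest.approx(0.439, abs=0.0005)
        # the published table evaluated p at the 2-decimal-rounded statistic
        assert round(printed_p_value(chi2), 4) == 0.4386

    def test_identical_proportions(self):
        chi2, p = chi_square_2x2(ContingencyTable2x2(10, 90, 100, 900))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_evaluated_table(self):
        # expected cells 15/85/15/85 -> sum (O-E)^2/E = 200/51 ~ 3.922
        chi2, p = chi_square_2x2(ContingencyTable2x2(20, 80, 10, 90))
        assert chi2 == pytest.approx(200 / 51, rel=1e-9)
        assert p == pytest.approx(0.0477, abs=0.0001)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            chi_square_2x2(ContingencyTable2x2(0, 0, 10, 90))

    @pytest.mark.parametrize(
        "table",
        [(20, 80, 10, 90), (430, 2080, 921179, 10406212), (3, 7, 40, 50)],
    )
    def test_equals_squared_two_proportion_z(self, table):
        k_d, m_d, k_b, m_b = table
        chi2, _ = chi_square_2x2(ContingencyTable2x2(k_d, m_d, k_b, m_b))
        n_d, n_b = k_d + m_d, k_b + m_b
        p_pool = (k_d + k_b) / (n_d + n_b)
        z = (k_d / n_d - k_b / n_b) / math.sqrt(p_pool * (1 - p_pool) * (1 / n_d + 1 / n_b))
        assert chi2 == pytest.approx(z * z, rel=1e-9)

    def test_swapping_sets_inverts_enrichment_and_preserves_test(self):
        r1 = from_counts(20, 100, 10, 100, "fwd")
        r2 = from_counts(10, 100, 20, 100, "rev")
        assert r2.enrichment == pytest.approx(1 / r1.enrichment)
        assert r2.chi2 == pytest.approx(r1.chi2)
        assert r2.p_value == pytest.approx(r1.p_value)


class TestSnpSetEnrichment:
    def test_whole_genome_region_is_null(self):
        disease = _snps("d", [10, 20, 30])
        background = _snps("b", [15, 25, 35, 45])
        genome = IntervalSet([GenomicInterval("chr1", 0, 6000)], assembly=TOY)
        r = snp_set_enrichment(disease, background, genome, "genome")
        assert r.enrichment == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_empty_region_flagged_not_raised(self):
        r = snp_set_enrichment(_snps("d", [10]), _snps("b", [20]), IntervalSet(), "none")
        assert r.enrichment == 0.0 and r.degenerate == "empty-region"
        assert r.chi2 is None and r.p_value is None

    def test_overlapping_sets_rejected(self):
        d = SnpSet("d", [SnpRecord("rs1", "chr1", 5)])
        b = SnpSet("b", [SnpRecord("rs1", "chr1", 5), SnpRecord("rs2", "chr1", 9)])
        with pytest.raises(ValidationError, match="disjoint|subtracted"):
            snp_set_enrichment(d, b, IntervalSet(), "x")

    def test_each_snp_counted_once(self):
        region = IntervalSet(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)]
        )
        r = snp_set_enrichment(
            _snps("d", [60]), _snps("b", [70, 500]), region, "x"
        )
        assert r.table.k_d == 1 and r.table.k_b == 1

    def test_conservation_over_disjoint_partition(self):
        rng = np.random.default_rng(5)
        disease = _snps("d", rng.integers(0, 6000, 200))
        background = _snps("b", rng.integers(0, 6000, 400))
        parts = [
            IntervalSet([GenomicInterval("chr1", i * 1500, (i + 1) * 1500)], assembly=TOY)
            for i in range(4)
        ]
        total_kd = sum(
            snp_set_enrichment(disease, background, p, f"p{i}").table.k_d
            for i, p in enumerate(parts)
        )
        assert total_kd == disease.size  # chr1 fully tiled


class TestStateEnrichment:
    def test_complementary_two_state_toy(self):
        seg = IntervalSet(
            [GenomicInterval("chr1", 0, 3000, "A"), GenomicInterval("chr1", 3000, 6000, "B")],
            assembly=TOY,
        )
        disease = _snps("d", [100, 200, 300, 400])         # all in A
        background = _snps("b", [500, 1500, 3500, 4500])   # half in each
        results = {r.region_label: r for r in state_enrichment(disease, background, seg)}
        assert results["A"].enrichment > 1
        assert results["B"].enrichment < 1

    def test_single_state_covering_genome_gives_unity(self):
        seg = IntervalSet(
            [GenomicInterval(c, 0, TOY[c], "all") for c in TOY.chroms], assembly=TOY
        )
        (r,) = state_enrichment(_snps("d", [10, 20]), _snps("b", [30, 40]), seg)
        assert r.enrichment == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_uniform_snps_on_uniform_segmentation_near_unity(self):
        rng = np.random.default_rng(11)
        seg = IntervalSet(
            [
                GenomicInterval("chr1", s, s + 600, "A" if i % 2 == 0 else "B")
                for i, s in enumerate(range(0, 6000, 600))
            ],
            assembly=TOY,
        )
        disease = _snps("d", rng.integers(0, 6000, 400))
        background = _snps("b", rng.integers(0, 6000, 2000))
        for r in state_enrichment(disease, background, seg):
            assert r.enrichment == pytest.approx(1.0, abs=0.2)

    def test_conflicting_overlapping_labels_rejected(self):
        seg = IntervalSet(
            [GenomicInterval("chr1", 0, 100, "A"), GenomicInterval("chr1", 50, 150, "B")]
        )
        with pytest.raises(ValidationError, match="overlap"):
            state_enrichment(_snps("d", [10]), _snps("b", [20]), seg)


class TestSharingProfiles:
    def three_sets(self):
        return {
            "c1": IntervalSet([GenomicInterval("chr1", 0, 100)]).merge(),
            "c2": IntervalSet([GenomicInterval("chr1", 200, 300)]).merge(),
            "c3": IntervalSet([GenomicInterval("chr1", 50, 150)]).merge(),
        }

    def test_membership_vector_and_count(self):
        profiles, hist = sharing_profiles(_snps("d", [60]), self.three_sets())
        assert profiles[0].membership == (1, 0, 1)
        assert profiles[0].sharing_count == 2
        assert hist == {2: 1}

    def test_uncovered_snp_excluded_from_histogram(self):
        profiles, hist = sharing_profiles(_snps("d", [60, 5000]), self.three_sets())
        assert profiles[1].sharing_count == 0
        assert hist == {2: 1}

    def test_histogram_matches_brute_force_recount(self, rng):
        sets = {
            f"c{i}": random_interval_set(rng, TOY, 25, sample_id=f"c{i}").merge()
            for i in range(4)
        }
        positions = rng.integers(0, 6000, 120)
        snps = _snps("d", positions)
        _, hist = sharing_profiles(snps, sets)
        expected: dict[int, int] = {}
        for pos in positions:
            n = sum(
                any(iv.chrom == "chr1" and iv.start <= pos < iv.end for iv in s)
                for s in sets.values()
            )
            if n >= 1:
                expected[n] = expected.get(n, 0) + 1
        assert hist == expected


class TestStratifiedEnrichment:
    def fixture_sets(self):
        shared = GenomicInterval("chr1", 0, 1000)
        return {
            "focal": IntervalSet([shared, GenomicInterval("chr1", 2000, 3000)]).merge(),
            "otherA": IntervalSet([shared]).merge(),
            "otherB": IntervalSet([shared]).merge(),
        }

    def test_full_sharing_stratum_reproduces_subset_enrichment(self):
        sets = self.fixture_sets()
        disease = _snps("d", [100, 2100])     # one shared, one focal-only
        background = _snps("b", [200, 300, 2200, 4000])
        r = stratified_enrichment(disease, background, "focal", sets, stratum=2)
        # stratum 2 = positions shared by all three sets = [0,1000)
        assert r.table.k_d == 1 and r.table.k_b == 2

    def test_exact_vs_cumulative_modes(self):
        sets = self.fixture_sets()
        disease = _snps("d", [100, 2100])
        background = _snps("b", [200, 300, 2200, 4000])
        exact0 = stratified_enrichment(disease, background, "focal", sets, 0, mode="exact")
        cum2 = stratified_enrichment(disease, background, "focal", sets, 2, mode="cumulative")
        assert exact0.table.k_d == 1          # only the focal-specific SNP
        assert cum2.table.k_d == 2            # everything in focal enhancers

    def test_empty_stratum_flagged(self):
        sets = self.fixture_sets()
        r = stratified_enrichment(_snps("d", [5000]), _snps("b", [5500]), "focal", sets, 1)
        assert r.degenerate == "empty-region"

    def test_unknown_focal_rejected(self):
        with pytest.raises(ValidationError, match="focal"):
            stratified_enrichment(_snps("d", [1]), _snps("b", [2]), "nope", self.fixture_sets(), 0)


class TestTfbsOverlap:
    def test_fraction_examples(self):
        tfbs = IntervalSet([GenomicInterval("chr1", 0, 50)])
        s_in = _snps("in", [10, 20, 100, 200])   # 2 of 4 in TFBS
        s_out = _snps("out", [25, 300])          # 1 of 2
        f_in, f_out, ratio = tfbs_overlap_fraction(s_in, s_out, tfbs)
        assert f_in == pytest.approx(0.5)
        assert f_out == pytest.approx(0.5)
        assert ratio == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            tfbs_overlap_fraction(SnpSet("a", []), _snps("b", [1]), IntervalSet())


class TestLdExpansion:
    def coords(self):
        return {"rs2": ("chr1", 200), "rs3": ("chr1", 300), "rs4": ("chr1", 400)}

    def test_threshold_filters_proxies(self):
        leads = SnpSet("leads", [SnpRecord("rs1", "chr1", 100, "lead")])
        expanded = expand_by_ld(
            leads, [("rs1", "rs2", 0.9), ("rs1", "rs3", 0.5)], 0.8, coords=self.coords()
        )
        assert expanded.rsids == {"rs1", "rs2"}
        proxy = next(r for r in expanded if r.rsid == "rs2")
        assert proxy.origin == "ld_linked" and proxy.lead_rsid == "rs1"
        assert proxy.r2_to_lead == pytest.approx(0.9)

    def test_empty_table_leaves_leads_unchanged(self):
        leads = SnpSet("leads", [SnpRecord("rs1", "chr1", 100, "lead")])
        assert expand_by_ld(leads, [], 0.8).rsids == {"rs1"}

    def test_shared_proxy_appears_once(self):
        leads = SnpSet(
            "leads",
            [SnpRecord("rs1", "chr1", 100, "lead"), SnpRecord("rs9", "chr1", 900, "lead")],
        )
        expanded = expand_by_ld(
            leads, [("rs1", "rs2", 0.95), ("rs9", "rs2", 0.85)], 0.8, coords=self.coords()
        )
        assert sorted(expanded.rsids) == ["rs1", "rs2", "rs9"]

    def test_proxy_without_coordinates_dropped_with_warning(self, caplog):
        leads = SnpSet("leads", [SnpRecord("rs1", "chr1", 100, "lead")])
        with caplog.at_level("WARNING", logger="enhsnp.enrichment"):
            expanded = expand_by_ld(leads, [("rs1", "rsX", 0.99)], 0.8, coords={})
        assert expanded.rsids == {"rs1"}
        assert any("no coordinates" in m for m in caplog.messages)

    def test_invalid_threshold_rejected(self):
        leads = SnpSet("leads", [SnpRecord("rs1", "chr1", 100, "lead")])
        with pytest.raises(ValidationError):
            expand_by_ld(leads, [], 0.0)


class TestReporting:
    def test_table_layout_and_bonferroni_column(self):
        results = [
            from_counts(20, 100, 10, 100, "a"),
            from_counts(10, 100, 20, 100, "b"),
        ]
        df = enrichment_table(results, bonferroni=True)
        assert list(df.columns[:5]) == ["region", "k_d", "n_d", "k_b", "n_b"]
        assert (df["p_bonferroni"] >= df["p_value"]).all()
        plain = enrichment_table(results)
        assert "p_bonferroni" not in plain.columns
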