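"""Synthetic inputs with planted structure for the enhancer-SNP pipeline.

Generates everything the analysis consumes — assembly, per-sample enhancer
peak sets with planted cell-type clustering, background and disease SNPs
with LD blocks and a planted enrichment fold, TFBSs preferentially placed
inside enhancers, and gene models — plus a ground-truth record, so every
stage is testable end-to-end with no external data.

The generative model, in outline:

* Each cell type has a master peak set = a pool shared by all types plus a
  type-specific pool, placed without overlap on the genome.  A replicate is
  its type's master after independent peak dropout and boundary jitter; the
  defaults put within-type MCC near 0.7 and between-type MCC near 0.2, so a
  0.55 cutoff separates types cleanly.
* Background SNPs are uniform over the genome.  Each disease lead SNP and
  each of its LD proxies independently falls inside the focal cell type's
  (emitted, merged) enhancers with probability f*q, where q is the enhancer
  fraction of the genome and f the planted fold — so the measured enrichment
  estimates f with plain binomial sampling error at the full disease-set
  size.  Proxies are placed within a window around their lead and carry an
  r^2 above the expansion threshold.
* TFBSs: per enhancer, a binding site with probability ``tfbs_inside_prob``;
  per equal-length non-enhancer window, probability ``tfbs_outside_prob``.
  A uniformly-placed SNP then overlaps a TFBS with probability proportional
  to the placement probability of its compartment, so the planted in/out
  ratio is recovered by the overlap-fraction statistic.

Randomness: one seed in the config; each stage draws from its own stream
derived from (seed, crc32(stage name)), so adding a stage never perturbs
earlier outputs and identical configs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genes import GeneModel, write_refflat
from .intervals import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    SnpRecord,
    SnpSet,
    ValidationError,
    write_bed,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_assembly",
    "generate_peak_samples",
    "generate_snps",
    "generate_tfbs",
    "generate_gene_models",
    "generate_all",
    "r_squared",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions.

    The default scale (2 x 1 Mb chromosomes, 4 cell types x 2 replicates,
    2,500 disease / 50,000 background SNPs) keeps a full pipeline run in
    seconds while leaving every statistic comfortably above its sampling
    noise floor.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (1_000_000, 1_000_000)
    n_cell_types: int = 4
    replicates_per_type: int = 2
    n_shared_peaks: int = 80
    n_specific_peaks: int = 170
    peak_length_mean: float = 1000.0
    peak_length_sd: float = 200.0
    min_peak_length: int = 200
    replicate_jitter_bp: int = 100
    dropout: float = 0.15
    n_background_snps: int = 50_000
    n_disease_leads: int = 125
    ld_block_size: int = 20  # SNPs per block, lead included
    ld_block_span: int = 100_000  # bp window around the lead for proxies
    ld_r2_threshold: float = 0.8
    planted_fold: float = 2.0
    focal_cell_type: int = 0
    plant_in: str = "merged"  # or "specific": bias only focal-specific peaks
    tfbs_inside_prob: float = 0.8
    tfbs_outside_prob: float = 0.2
    tfbs_length: int = 200
    n_genes: int = 40

    def __post_init__(self):
        if not self.chrom_lengths:
            raise ValidationError("at least one chromosome is required")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be positive")
        if self.planted_fold <= 0:
            raise ValidationError("planted_fold must be > 0")
        if not (0 <= self.dropout < 1):
            raise ValidationError("dropout must be in [0, 1)")
        for p in (self.tfbs_inside_prob, self.tfbs_outside_prob):
            if not (0 <= p <= 1):
                raise ValidationError("TFBS probabilities must be in [0, 1]")
        if not (0 < self.ld_r2_threshold <= 1):
            raise ValidationError("ld_r2_threshold must be in (0, 1]")
        if self.plant_in not in ("merged", "specific"):
            raise ValidationError("plant_in must be 'merged' or 'specific'")
        total_peak = (
            self.n_shared_peaks + self.n_cell_types * self.n_specific_peaks
        ) * self.peak_length_mean
        if total_peak >= sum(self.chrom_lengths):
            raise ValidationError("total peak bases must stay below genome length")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic files."""

    cluster_of_sample: dict[str, int]
    planted_fold: dict[int, float]
    focal_cell_type: int
    snp_in_focal: dict[str, bool]  # disease rsid -> planted inside focal enhancers
    lead_proxies: dict[str, list[str]]
    relocated_proxies: list[str]  # proxies that needed a widened window
    focal_fraction: float  # q: fraction of the genome in focal enhancers

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "cluster_of_sample": self.cluster_of_sample,
                    "planted_fold": {str(k): v for k, v in self.planted_fold.items()},
                    "focal_cell_type": self.focal_cell_type,
                    "snp_in_focal": self.snp_in_focal,
                    "lead_proxies": self.lead_proxies,
                    "relocated_proxies": self.relocated_proxies,
                    "focal_fraction": self.focal_fraction,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            cluster_of_sample=d["cluster_of_sample"],
            planted_fold={int(k): v for k, v in d["planted_fold"].items()},
            focal_cell_type=d["focal_cell_type"],
            snp_in_focal=d["snp_in_focal"],
            lead_proxies=d["lead_proxies"],
            relocated_proxies=d["relocated_proxies"],
            focal_fraction=d["focal_fraction"],
        )


def _rng(cfg: SimulationConfig, stage: str) -> np.random.Generator:
    """Stage-local RNG stream: stable under addition of other stages."""
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, zlib.crc32(stage.encode())])
    )


def generate_assembly(cfg: SimulationConfig) -> GenomeAssembly:
    """chr1..chrN with the configured lengths (deterministic, no RNG)."""
    return GenomeAssembly(
        {f"chr{i + 1}": int(l) for i, l in enumerate(cfg.chrom_lengths)}
    )


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


def _place_disjoint_peaks(
    rng: np.random.Generator,
    assembly: GenomeAssembly,
    n: int,
    cfg: SimulationConfig,
    occupied: dict[str, list[tuple[int, int]]],
) -> list[GenomicInterval]:
    """Rejection-sample ``n`` peaks that overlap nothing placed so far."""
    import bisect

    chroms = assembly.chroms
    lengths = np.array([assembly[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    out = []
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValidationError(
                "could not place requested peaks without overlap; genome too full"
            )
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        length = max(
            cfg.min_peak_length,
            int(round(rng.normal(cfg.peak_length_mean, cfg.peak_length_sd))),
        )
        limit = assembly[chrom] - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        end = start + length
        occ = occupied.setdefault(chrom, [])
        i = bisect.bisect_right(occ, (start, start))
        if i > 0 and occ[i - 1][1] > start:
            continue
        if i < len(occ) and occ[i][0] < end:
            continue
        occ.insert(i, (start, end))
        out.append(GenomicInterval(chrom, start, end))
    return out


def generate_peak_samples(
    cfg: SimulationConfig, assembly: GenomeAssembly
) -> tuple[list[IntervalSet], SyntheticTruth]:
    """Per-replicate peak sets with planted cell-type cluster structure.

    Sample ids are ``t{type}_r{replicate}``.  Peaks exceeding chromosome
    bounds after jitter are clipped, never wrapped.
    """
    rng = _rng(cfg, "peaks")
    occupied: dict[str, list[tuple[int, int]]] = {}
    shared = _place_disjoint_peaks(rng, assembly, cfg.n_shared_peaks, cfg, occupied)
    specific = [
        _place_disjoint_peaks(rng, assembly, cfg.n_specific_peaks, cfg, occupied)
        for _ in range(cfg.n_cell_types)
    ]
    samples: list[IntervalSet] = []
    cluster_of_sample: dict[str, int] = {}
    for t in range(cfg.n_cell_types):
        master = shared + specific[t]
        for r in range(cfg.replicates_per_type):
            keep = rng.random(len(master)) >= cfg.dropout
            intervals = []
            for iv, k in zip(master, keep):
                if not k:
                    continue
                j = cfg.replicate_jitter_bp
                start = iv.start + int(rng.integers(-j, j + 1)) if j else iv.start
                end = iv.end + int(rng.integers(-j, j + 1)) if j else iv.end
                start = max(0, start)
                end = min(assembly[iv.chrom], end)
                if end <= start:  # jitter collapsed the peak; keep one base
                    start, end = iv.start, iv.start + 1
                intervals.append(GenomicInterval(iv.chrom, start, end))
            sid = f"t{t}_r{r}"
            samples.append(IntervalSet(intervals, sample_id=sid, assembly=assembly))
            cluster_of_sample[sid] = t
    folds = {
        t: (cfg.planted_fold if t == cfg.focal_cell_type else 1.0)
        for t in range(cfg.n_cell_types)
    }
    truth = SyntheticTruth(
        cluster_of_sample=cluster_of_sample,
        planted_fold=folds,
        focal_cell_type=cfg.focal_cell_type,
        snp_in_focal={},
        lead_proxies={},
        relocated_proxies=[],
        focal_fraction=0.0,
    )
    # stash the master pools for downstream planting decisions
    truth._shared_master = IntervalSet(  # type: ignore[attr-defined]
        shared, sample_id="shared_master", assembly=assembly
    ).merge()
    return samples, truth


def _focal_regions(
    cfg: SimulationConfig,
    assembly: GenomeAssembly,
    samples: Sequence[IntervalSet],
    truth: SyntheticTruth,
) -> tuple[IntervalSet, IntervalSet]:
    """(planting region, its complement) as seen by the pipeline.

    The planting region is the merged union of the focal type's emitted
    replicates — exactly what the measurement will call that cell type's
    enhancers — optionally minus the shared master pool when the fold is to
    be planted only in focal-specific peaks.
    """
    focal = [
        s
        for s in samples
        if truth.cluster_of_sample[s.sample_id] == cfg.focal_cell_type
    ]
    merged = IntervalSet(
        [iv for s in focal for iv in s], sample_id="focal_merged", assembly=assembly
    ).merge()
    if cfg.plant_in == "specific":
        shared_master = getattr(truth, "_shared_master", None)
        if shared_master is None:
            raise ValidationError("truth lacks master pools; regenerate peaks first")
        merged = merged.subtract(shared_master)
    return merged, merged.complement()


def _sample_positions_from(
    rng: np.random.Generator, region: IntervalSet, n: int
) -> list[tuple[str, int]]:
    """``n`` positions uniform over the bases covered by ``region``."""
    ivs = region.merge().intervals
    if not ivs:
        raise ValidationError("cannot sample positions from an empty region")
    lengths = np.array([iv.length for iv in ivs], dtype=np.int64)
    cum = np.cumsum(lengths)
    draws = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, draws, side="right")
    offsets = draws - (cum[idx] - lengths[idx])
    return [
        (ivs[i].chrom, int(ivs[i].start + off)) for i, off in zip(idx, offsets)
    ]


def _window_around(
    assembly: GenomeAssembly, chrom: str, pos: int, span: int
) -> IntervalSet:
    start = max(0, pos - span)
    end = min(assembly[chrom], pos + span + 1)
    return IntervalSet([GenomicInterval(chrom, start, end)], assembly=assembly)


def generate_snps(
    cfg: SimulationConfig,
    assembly: GenomeAssembly,
    truth: SyntheticTruth,
    samples: Sequence[IntervalSet],
) -> tuple[SnpSet, SnpSet, pd.DataFrame]:
    """(background, disease, ld_table) with the configured fold planted.

    Every disease SNP — lead or proxy — independently lands inside the
    planting region with probability f*q (q = region fraction of the
    genome), else uniformly outside; proxies are confined to a window of
    ``ld_block_span`` bp around their lead (widened only if the window lacks
    the required compartment, which the truth records).  Background SNPs are
    uniform.  Disease and background rsids are disjoint by construction.
    """
    rng = _rng(cfg, "snps")
    genome = assembly.total_length
    n_disease = cfg.n_disease_leads * cfg.ld_block_size
    if cfg.n_background_snps + n_disease > genome:
        raise ValidationError("requested SNP count exceeds genome positions")

    region_in, region_out = _focal_regions(cfg, assembly, samples, truth)
    q = region_in.total_bases() / genome
    p_in = cfg.planted_fold * q
    if p_in > 1:
        raise ValidationError(
            f"planted_fold {cfg.planted_fold} x region fraction {q:.3f} exceeds 1"
        )

    # background: uniform over the genome
    bg_positions = _sample_positions_from(
        rng,
        IntervalSet(
            [GenomicInterval(c, 0, assembly[c]) for c in assembly.chroms],
            assembly=assembly,
        ),
        cfg.n_background_snps,
    )
    background = SnpSet(
        "background",
        [
            SnpRecord(f"rsb{i:07d}", chrom, pos, origin="background")
            for i, (chrom, pos) in enumerate(bg_positions)
        ],
    )

    # disease: leads + LD blocks
    records: list[SnpRecord] = []
    ld_rows: list[tuple[str, str, float]] = []
    snp_in_focal: dict[str, bool] = {}
    lead_proxies: dict[str, list[str]] = {}
    relocated: list[str] = []
    half_span = cfg.ld_block_span // 2

    def draw_in_region(region: IntervalSet, window: IntervalSet | None):
        if window is None:
            return _sample_positions_from(rng, region, 1)[0], False
        local = window.intersect(region)
        widened = False
        span = half_span
        while local.total_bases() == 0:
            widened = True
            span *= 2
            chrom = window.intervals[0].chrom
            center = (window.intervals[0].start + window.intervals[0].end) // 2
            window = _window_around(assembly, chrom, center, span)
            local = window.intersect(region)
            if span > max(cfg.chrom_lengths):
                local = region
                break
        return _sample_positions_from(rng, local, 1)[0], widened

    for b in range(cfg.n_disease_leads):
        lead_id = f"rsd{b:05d}_lead"
        inside = bool(rng.random() < p_in)
        (chrom, pos), _ = draw_in_region(region_in if inside else region_out, None)
        records.append(SnpRecord(lead_id, chrom, pos, origin="lead"))
        snp_in_focal[lead_id] = inside
        proxies: list[str] = []
        for k in range(cfg.ld_block_size - 1):
            proxy_id = f"rsd{b:05d}_p{k:02d}"
            p_inside = bool(rng.random() < p_in)
            window = _window_around(assembly, chrom, pos, half_span)
            (pc, pp), widened = draw_in_region(
                region_in if p_inside else region_out, window
            )
            r2 = float(rng.uniform(cfg.ld_r2_threshold, 1.0))
            records.append(
                SnpRecord(
                    proxy_id, pc, pp, origin="ld_linked", lead_rsid=lead_id, r2_to_lead=r2
                )
            )
            ld_rows.append((lead_id, proxy_id, r2))
            snp_in_focal[proxy_id] = p_inside
            proxies.append(proxy_id)
            if widened:
                relocated.append(proxy_id)
        lead_proxies[lead_id] = proxies

    disease = SnpSet("disease", records)
    ld_table = pd.DataFrame(ld_rows, columns=["lead_rsid", "linked_rsid", "r2"])
    truth.snp_in_focal = snp_in_focal
    truth.lead_proxies = lead_proxies
    truth.relocated_proxies = relocated
    truth.focal_fraction = q
    return background, disease, ld_table


# ---------------------------------------------------------------------------
# LD algebra helper
# ---------------------------------------------------------------------------


def r_squared(p_ab: float, p_a: float, p_b: float) -> float:
    """Squared LD correlation r^2 = D^2 / (p_a(1-p_a) p_b(1-p_b)),
    D = p_ab - p_a*p_b, for haplotype frequency p_ab and allele frequencies
    p_a, p_b."""
    for p in (p_a, p_b):
        if not (0 < p < 1):
            raise ValidationError("r^2 undefined for a monomorphic allele")
    if p_ab < 0 or p_ab > min(p_a, p_b):
        raise ValidationError("haplotype frequency must satisfy 0 <= p_ab <= min(p_a, p_b)")
    d = p_ab - p_a * p_b
    return (d * d) / (p_a * (1 - p_a) * p_b * (1 - p_b))


# ---------------------------------------------------------------------------
# TFBS
# ---------------------------------------------------------------------------


def generate_tfbs(
    cfg: SimulationConfig,
    assembly: GenomeAssembly,
    samples: Sequence[IntervalSet],
) -> IntervalSet:
    """Short binding-site intervals biased toward enhancers.

    'Enhancers' here means the pooled merged peaks of all samples.  Per
    enhancer: one TFBS with probability ``tfbs_inside_prob``, fully inside
    it.  Per equal-length window of the non-enhancer genome: one TFBS with
    probability ``tfbs_outside_prob`` (partial trailing windows get a
    proportionally reduced probability, keeping the per-base TFBS density in
    each compartment exactly proportional to its placement probability).
    """
    rng = _rng(cfg, "tfbs")
    pooled = IntervalSet(
        [iv for s in samples for iv in s], sample_id="pooled", assembly=assembly
    ).merge()
    t = cfg.tfbs_length
    out: list[GenomicInterval] = []

    def place_in(seg: GenomicInterval, prob: float) -> None:
        if rng.random() >= prob:
            return
        if seg.length <= t:
            out.append(GenomicInterval(seg.chrom, seg.start, seg.end))
        else:
            off = int(rng.integers(0, seg.length - t + 1))
            out.append(GenomicInterval(seg.chrom, seg.start + off, seg.start + off + t))

    mean_len = max(
        1, int(round(np.mean([iv.length for iv in pooled.intervals]) if len(pooled) else t))
    )
    for iv in pooled:
        place_in(iv, cfg.tfbs_inside_prob)
    for gap in pooled.complement():
        full, rem = divmod(gap.length, mean_len)
        for w in range(full):
            place_in(
                GenomicInterval(
                    gap.chrom, gap.start + w * mean_len, gap.start + (w + 1) * mean_len
                ),
                cfg.tfbs_outside_prob,
            )
        if rem > 0:
            place_in(
                GenomicInterval(gap.chrom, gap.end - rem, gap.end),
                cfg.tfbs_outside_prob * rem / mean_len,
            )
    return IntervalSet(out, sample_id="tfbs", assembly=assembly)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def generate_gene_models(
    cfg: SimulationConfig, assembly: GenomeAssembly
) -> list[GeneModel]:
    """Non-overlapping multi-exon transcripts with valid CDS, random strand."""
    rng = _rng(cfg, "genes")
    models: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    import bisect

    chroms = assembly.chroms
    lengths = np.array([assembly[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    attempts = 0
    while len(models) < cfg.n_genes and attempts < 200 * max(cfg.n_genes, 1):
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        n_exons = int(rng.integers(2, 6))
        exon_lens = rng.integers(100, 400, size=n_exons)
        intron_lens = rng.integers(200, 2000, size=n_exons - 1)
        tx_len = int(exon_lens.sum() + intron_lens.sum())
        limit = assembly[chrom] - tx_len
        if limit <= 0:
            continue
        tx_start = int(rng.integers(0, limit))
        tx_end = tx_start + tx_len
        occ = occupied.setdefault(chrom, [])
        i = bisect.bisect_right(occ, (tx_start, tx_start))
        if i > 0 and occ[i - 1][1] > tx_start:
            continue
        if i < len(occ) and occ[i][0] < tx_end:
            continue
        occ.insert(i, (tx_start, tx_end))
        exons = []
        cursor = tx_start
        for k in range(n_exons):
            exons.append((cursor, cursor + int(exon_lens[k])))
            cursor += int(exon_lens[k])
            if k < n_exons - 1:
                cursor += int(intron_lens[k])
        # CDS: from inside the first exon to inside the last exon
        cds_start = exons[0][0] + int(rng.integers(20, exon_lens[0] - 20))
        cds_end = exons[-1][0] + int(rng.integers(20, exon_lens[-1] - 20))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(
            GeneModel(
                tx_id=f"tx{len(models):04d}",
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start,
                cds_end=cds_end,
                exons=tuple(exons),
            )
        )
    return models


# ---------------------------------------------------------------------------
# one-call dataset emission
# ---------------------------------------------------------------------------


def generate_all(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input; returns the file manifest.

    Files: ``chrom.sizes``, ``peaks_<sample>.bed``, ``background.snps``,
    ``disease.snps``, ``ld_table.tsv``, ``tfbs.bed``, ``genes.refflat``,
    ``truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    assembly = generate_assembly(cfg)
    p = outdir / "chrom.sizes"
    assembly.to_file(p)
    manifest["chrom_sizes"] = p

    samples, truth = generate_peak_samples(cfg, assembly)
    for s in samples:
        p = outdir / f"peaks_{s.sample_id}.bed"
        write_bed(s, p)
        manifest[f"peaks_{s.sample_id}"] = p

    background, disease, ld_table = generate_snps(cfg, assembly, truth, samples)
    p = outdir / "background.snps"
    background.to_table(p)
    manifest["background"] = p
    p = outdir / "disease.snps"
    disease.to_table(p)
    manifest["disease"] = p
    p = outdir / "ld_table.tsv"
    ld_table.to_csv(p, sep="\t", index=False)
    manifest["ld_table"] = p

    tfbs = generate_tfbs(cfg, assembly, samples)
    p = outdir / "tfbs.bed"
    write_bed(tfbs, p)
    manifest["tfbs"] = p

    models = generate_gene_models(cfg, assembly)
    p = outdir / "genes.refflat"
    write_refflat(models, p)
    manifest["genes"] = p

    p = outdir / "truth.json"
    truth.to_json(p)
    manifest["truth"] = p

    p = outdir / "config.json"
    with open(p, "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=1, sort_keys=True)
    manifest["config"] = p
    return manifest
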