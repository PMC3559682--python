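"""End-to-end orchestration: annotate -> MCC -> cluster -> merge -> enrich
-> stratify -> TFBS -> report.

Canonical outputs are plain-text TSVs mirroring the familiar report tables
(enrichment per cell type, MCC matrix, cluster assignment, sharing matrix,
stratified enrichment series, TFBS overlap fractions, region distribution),
plus a machine-parseable JSON run report listing every file written, every
warning raised, and the effective configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    enrichment_table,
    sharing_matrix_frame,
    sharing_profiles,
    snp_set_enrichment,
    state_enrichment,
    stratified_enrichment,
    tfbs_overlap_fraction,
)
from .genes import read_refflat, region_distribution
from .intervals import (
    GenomeAssembly,
    IntervalSet,
    SnpSet,
    ValidationError,
    read_bed,
    read_chrom_sizes,
    read_snp_table,
)
from .mcc import mcc_matrix, merge_cluster_peaks, threshold_clusters

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run; defaults are the standard ones
    (MCC cutoff 0.55, LD r^2 threshold 0.8, exact strata, raw chi-square)."""

    chrom_sizes: str
    disease_snps: str
    background_snps: str
    peak_beds: dict[str, str]  # sample id -> BED path
    out_dir: str
    genes: str | None = None
    states_bed: str | None = None
    tfbs_bed: str | None = None
    ld_table: str | None = None
    mcc_cutoff: float = 0.55
    ld_r2_threshold: float = 0.8
    stratification_mode: str = "exact"
    bonferroni: bool = False
    one_based_snps: bool = False
    cluster_method: str = "components"
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunReport:
    """Machine-parseable provenance of one pipeline run."""

    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, **counts) -> None:
        self.stages.append({"stage": name, **counts})

    def add_output(self, key: str, path: Path) -> None:
        if not Path(path).exists():
            raise ValidationError(f"output {path} was not written")
        self.outputs[key] = str(path)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


class _WarningCollector(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record: logging.LogRecord) -> None:
        self.sink.append(record.getMessage())


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run every stage the inputs allow and write the report.

    Optional stages (region annotation, chromatin states, TFBS) run only
    when their inputs are configured.  Degenerate statistics come back as
    flagged rows, never crashes; a missing input fails fast with the stage
    name in the message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(cfg), version=__version__)
    collector = _WarningCollector(report.warnings)
    pkg_logger = logging.getLogger("enhsnp")
    pkg_logger.addHandler(collector)
    try:
        return _run(cfg, out, report)
    finally:
        pkg_logger.removeHandler(collector)


def _require(path: str | None, stage: str) -> str:
    if path is None or not Path(path).exists():
        raise ValidationError(f"stage {stage!r}: required input {path!r} missing")
    return path


def _run(cfg: PipelineConfig, out: Path, report: RunReport) -> RunReport:
    # ---- load ------------------------------------------------------------
    assembly = read_chrom_sizes(_require(cfg.chrom_sizes, "load"))
    disease = read_snp_table(
        _require(cfg.disease_snps, "load"), name="disease", one_based=cfg.one_based_snps
    )
    background = read_snp_table(
        _require(cfg.background_snps, "load"),
        name="background",
        one_based=cfg.one_based_snps,
    )
    background = background.subtract(disease)  # input hygiene: disjoint by rsid
    samples = [
        read_bed(_require(path, "load"), assembly=assembly, sample_id=sid)
        for sid, path in cfg.peak_beds.items()
    ]
    report.add_stage(
        "load",
        n_samples=len(samples),
        n_disease=disease.size,
        n_background=background.size,
    )

    # ---- region annotation ----------------------------------------------
    if cfg.genes:
        models = read_refflat(_require(cfg.genes, "annotate"))
        rows = []
        for name, snps in (("disease", disease), ("background", background)):
            dist = region_distribution(snps, models)
            for cls, count, frac in dist.to_rows():
                rows.append({"set": name, "region_class": cls, "count": count, "fraction": frac})
        p = out / "region_distribution.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        report.add_output("region_distribution", p)
        report.add_stage("annotate", n_gene_models=len(models))

    # ---- MCC + clustering + merge ---------------------------------------
    matrix = mcc_matrix(samples, assembly)
    p = out / "mcc_matrix.tsv"
    matrix.to_tsv(p)
    report.add_output("mcc_matrix", p)

    clusters = threshold_clusters(matrix, cutoff=cfg.mcc_cutoff, method=cfg.cluster_method)
    p = out / "clusters.tsv"
    clusters.to_tsv(p)
    report.add_output("clusters", p)
    report.add_stage(
        "cluster",
        n_clusters=len(clusters.clusters()),
        n_outliers=len(clusters.outliers),
    )

    by_id = {s.sample_id: s for s in samples}
    merged_sets: dict[str, IntervalSet] = {}
    for cid, members in sorted(clusters.clusters().items()):
        name = f"cluster{cid}"
        merged = merge_cluster_peaks([by_id[m] for m in members], sample_id=name)
        merged_sets[name] = merged
        from .intervals import write_bed

        p = out / f"enhancers_{name}.bed"
        write_bed(merged, p)
        report.add_output(f"enhancers_{name}", p)

    # ---- per-cell-type enrichment table ----------------------------------
    results = [
        snp_set_enrichment(disease, background, merged, label=name)
        for name, merged in merged_sets.items()
    ]
    results.sort(key=lambda r: -(r.enrichment if r.enrichment is not None else -1))
    df = enrichment_table(results, bonferroni=cfg.bonferroni)
    p = out / "enrichment_enhancers.tsv"
    df.to_csv(p, sep="\t", index=False)
    report.add_output("enrichment_enhancers", p)
    report.add_stage("enrich", n_regions=len(results))

    # ---- chromatin states ------------------------------------------------
    if cfg.states_bed:
        seg = read_bed(_require(cfg.states_bed, "states"), assembly=assembly)
        state_results = state_enrichment(disease, background, seg)
        p = out / "enrichment_states.tsv"
        enrichment_table(state_results, bonferroni=cfg.bonferroni).to_csv(
            p, sep="\t", index=False
        )
        report.add_output("enrichment_states", p)
        report.add_stage("states", n_states=len(state_results))

    # ---- sharing matrix + histogram --------------------------------------
    frame = sharing_matrix_frame(disease, merged_sets)
    p = out / "sharing_matrix.tsv"
    frame.to_csv(p, sep="\t", index_label="rsid")
    report.add_output("sharing_matrix", p)
    _, hist = sharing_profiles(disease, merged_sets)
    p = out / "sharing_histogram.tsv"
    pd.DataFrame(
        sorted(hist.items()), columns=["n_cell_types", "n_snps"]
    ).to_csv(p, sep="\t", index=False)
    report.add_output("sharing_histogram", p)

    # ---- stratified enrichment (focal = top-enriched cluster) ------------
    focal = results[0].region_label if results else None
    if focal is not None and len(merged_sets) > 1:
        strat_rows = []
        for stratum in range(len(merged_sets)):
            res = stratified_enrichment(
                disease,
                background,
                focal,
                merged_sets,
                stratum,
                mode=cfg.stratification_mode,
            )
            strat_rows.append(res)
        p = out / "enrichment_stratified.tsv"
        df = enrichment_table(strat_rows)
        df.insert(0, "stratum", range(len(strat_rows)))
        df.insert(1, "focal", focal)
        df.to_csv(p, sep="\t", index=False)
        report.add_output("enrichment_stratified", p)
        report.add_stage("stratify", focal=focal, n_strata=len(strat_rows))

    # ---- TFBS overlap ----------------------------------------------------
    if cfg.tfbs_bed:
        tfbs = read_bed(_require(cfg.tfbs_bed, "tfbs"), assembly=assembly)
        pooled = merge_cluster_peaks(list(merged_sets.values()), sample_id="pooled")
        inside_mask = disease.membership(pooled)
        in_set = SnpSet("disease_in_enh", [r for r, m in zip(disease, inside_mask) if m])
        out_set = SnpSet("disease_out_enh", [r for r, m in zip(disease, inside_mask) if not m])
        if in_set.size and out_set.size:
            f_in, f_out, ratio = tfbs_overlap_fraction(in_set, out_set, tfbs)
            p = out / "tfbs_overlap.tsv"
            pd.DataFrame(
                [
                    {
                        "n_in_enhancers": in_set.size,
                        "n_out_enhancers": out_set.size,
                        "fraction_in": f_in,
                        "fraction_out": f_out,
                        "ratio": ratio,
                    }
                ]
            ).to_csv(p, sep="\t", index=False)
            report.add_output("tfbs_overlap", p)
            report.add_stage("tfbs", n_tfbs=len(tfbs))
        else:
            log.warning("TFBS stage skipped: a SNP compartment is empty")

    p = out / "run_report.json"
    report.to_json(p)
    report.outputs["run_report"] = str(p)
    return report
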