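"""Classification of SNPs into genomic context classes from gene models.

Each SNP gets exactly one of five classes — ``cds``, ``utr5``, ``utr3``,
``intron``, ``intergenic`` — the classic breakdown of where disease-associated
variants land relative to transcript structure.  When several transcripts
overlap a position they may disagree (intronic in one isoform, coding in
another); ties resolve by the fixed precedence cds > utr5 > utr3 > intron,
i.e. a coding consequence dominates.  Exonic bases of non-coding transcripts
(CDS-less models) fold into the intron class: the five-class scheme has no
ncRNA-exon bucket and "genic but non-coding" is the closest honest label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import SnpRecord, SnpSet, ValidationError

__all__ = [
    "GeneModel",
    "RegionClass",
    "RegionDistribution",
    "GeneIndex",
    "classify_snp",
    "region_distribution",
    "read_refflat",
    "read_bed12",
]


class RegionClass(str, enum.Enum):
    CDS = "cds"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRON = "intron"
    INTERGENIC = "intergenic"


# lower rank wins when transcripts disagree
_PRECEDENCE: Mapping[RegionClass, int] = {
    RegionClass.CDS: 0,
    RegionClass.UTR5: 1,
    RegionClass.UTR3: 2,
    RegionClass.INTRON: 3,
    RegionClass.INTERGENIC: 4,
}


@dataclass(frozen=True)
class GeneModel:
    """A transcript: exon blocks, CDS bounds and strand, half-open 0-based.

    ``cds_start == cds_end`` marks a non-coding transcript.
    """

    tx_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.tx_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValidationError(f"{self.tx_id}: invalid transcript bounds")
        if not self.exons:
            raise ValidationError(f"{self.tx_id}: transcript has no exons")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValidationError(f"{self.tx_id}: exon ({s},{e}) outside transcript bounds")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.tx_id}: exons unsorted or overlapping")
            prev_end = e
        if self.cds_start != self.cds_end:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise ValidationError(f"{self.tx_id}: CDS outside transcript bounds")
            # CDS must begin and end inside exons (its middle spans introns,
            # which is normal; coding bases are exon ∩ [cds_start, cds_end))
            def _exonic(pos: int) -> bool:
                return any(s <= pos < e for s, e in self.exons)

            if not _exonic(self.cds_start) or not _exonic(self.cds_end - 1):
                raise ValidationError(f"{self.tx_id}: CDS boundary falls outside exons")

    @property
    def is_coding(self) -> bool:
        return self.cds_start != self.cds_end

    def classify(self, pos: int) -> RegionClass | None:
        """Class of ``pos`` under this transcript alone; None if outside it."""
        if not (self.tx_start <= pos < self.tx_end):
            return None
        exonic = any(s <= pos < e for s, e in self.exons)
        if not exonic:
            return RegionClass.INTRON
        if not self.is_coding:
            return RegionClass.INTRON  # ncRNA exon: genic, non-coding
        if self.cds_start <= pos < self.cds_end:
            return RegionClass.CDS
        if pos < self.cds_start:
            return RegionClass.UTR5 if self.strand == "+" else RegionClass.UTR3
        return RegionClass.UTR3 if self.strand == "+" else RegionClass.UTR5


class GeneIndex:
    """Per-chromosome overlap index over transcripts (sorted starts +
    running-max ends, so a backward scan finds every candidate)."""

    def __init__(self, models: Iterable[GeneModel]):
        self.models = list(models)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for m in self.models:
            by_chrom.setdefault(m.chrom, []).append(m)
        for chrom, ms in by_chrom.items():
            ms.sort(key=lambda m: m.tx_start)
            starts = np.asarray([m.tx_start for m in ms], dtype=np.int64)
            cummax_end = np.maximum.accumulate(
                np.asarray([m.tx_end for m in ms], dtype=np.int64)
            )
            self._by_chrom[chrom] = (starts, cummax_end, ms)

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, cummax_end, ms = entry
        hi = int(np.searchsorted(starts, pos, side="right"))
        out = []
        for j in range(hi - 1, -1, -1):
            if cummax_end[j] <= pos:
                break
            m = ms[j]
            if m.tx_start <= pos < m.tx_end:
                out.append(m)
        return out

    def classify(self, chrom: str, pos: int) -> RegionClass:
        best = RegionClass.INTERGENIC
        for m in self.overlapping(chrom, pos):
            c = m.classify(pos)
            if c is not None and _PRECEDENCE[c] < _PRECEDENCE[best]:
                best = c
                if best is RegionClass.CDS:
                    break
        return best


def classify_snp(snp: SnpRecord, models: Iterable[GeneModel] | GeneIndex) -> RegionClass:
    """Single class for one SNP; precedence cds > utr5 > utr3 > intron."""
    index = models if isinstance(models, GeneIndex) else GeneIndex(models)
    return index.classify(snp.chrom, snp.pos)


@dataclass(frozen=True)
class RegionDistribution:
    """Per-class SNP counts and fractions (fractions sum to 1)."""

    counts: Mapping[RegionClass, int]
    n: int

    @property
    def fractions(self) -> dict[RegionClass, float]:
        return {c: k / self.n for c, k in self.counts.items()}

    def to_rows(self) -> list[tuple[str, int, float]]:
        return [(c.value, self.counts[c], self.counts[c] / self.n) for c in RegionClass]


def region_distribution(
    snps: SnpSet, models: Iterable[GeneModel] | GeneIndex
) -> RegionDistribution:
    """Distribution of a SNP set over the five genomic context classes."""
    if snps.size == 0:
        raise ValidationError("region distribution undefined for an empty SNP set")
    index = models if isinstance(models, GeneIndex) else GeneIndex(models)
    counts = {c: 0 for c in RegionClass}
    for r in snps:
        counts[index.classify(r.chrom, r.pos)] += 1
    return RegionDistribution(counts, snps.size)


# ---------------------------------------------------------------------------
# gene-model I/O
# ---------------------------------------------------------------------------


def _parse_block_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x]


def read_refflat(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-style table: geneName, txName, chrom, strand, txStart,
    txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds."""
    models = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 11:
                raise ValidationError(f"line {i}: refFlat needs 11 columns, got {len(f)}")
            exon_starts = _parse_block_list(f[9])
            exon_ends = _parse_block_list(f[10])
            if len(exon_starts) != len(exon_ends) or len(exon_starts) != int(f[8]):
                raise ValidationError(f"line {i}: exon block count mismatch")
            models.append(
                GeneModel(
                    tx_id=f[1],
                    chrom=f[2],
                    strand=f[3],
                    tx_start=int(f[4]),
                    tx_end=int(f[5]),
                    cds_start=int(f[6]),
                    cds_end=int(f[7]),
                    exons=tuple(zip(exon_starts, exon_ends)),
                )
            )
    return models


def write_refflat(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            fh.write(
                f"{m.tx_id}\t{m.tx_id}\t{m.chrom}\t{m.strand}\t{m.tx_start}\t"
                f"{m.tx_end}\t{m.cds_start}\t{m.cds_end}\t{len(m.exons)}\t"
                f"{starts}\t{ends}\n"
            )


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (blockStarts relative to chromStart)."""
    models = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValidationError(f"line {i}: BED12 needs 12 columns, got {len(f)}")
            chrom_start = int(f[1])
            sizes = _parse_block_list(f[10])
            offsets = _parse_block_list(f[11])
            if len(sizes) != len(offsets) or len(sizes) != int(f[9]):
                raise ValidationError(f"line {i}: block count mismatch")
            exons = tuple(
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(offsets, sizes)
            )
            models.append(
                GeneModel(
                    tx_id=f[3],
                    chrom=f[0],
                    strand=f[5],
                    tx_start=chrom_start,
                    tx_end=int(f[2]),
                    cds_start=int(f[6]),
                    cds_end=int(f[7]),
                    exons=exons,
                )
            )
    return models
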