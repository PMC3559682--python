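"""Genomic coordinate model, BED I/O and per-nucleotide interval algebra.

Everything downstream — Matthews-correlation concordance of peak sets,
SNP-in-region counting, chromatin-state overlap — reduces to exact base-level
set operations on half-open intervals.  Coordinates are 0-based half-open
(BED-native) throughout: an interval ``[start, end)`` covers ``end - start``
bases and a SNP at position ``p`` lies inside it iff ``start <= p < end``.

The algebra is implemented on sorted numpy arrays per chromosome, giving
O(n log n) merge and O(n + m) intersection; correctness is pinned to an
exhaustive per-base boolean-array oracle in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "BedParseError",
    "ValidationError",
    "GenomeAssembly",
    "GenomicInterval",
    "IntervalSet",
    "SnpRecord",
    "SnpSet",
    "merge_intervals",
    "total_bases",
    "intersect_bases",
    "count_snps_in_set",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_snp_table",
]


class BedParseError(ValueError):
    """Malformed line in a BED-like file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(ValueError):
    """A record violates a coordinate or consistency invariant."""


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome name -> length (bp) map defining the universe of bases.

    The total length is the denominator behind every per-nucleotide statistic
    (in particular the true-negative count of the MCC confusion table).
    """

    chrom_sizes: Mapping[str, int]

    def __post_init__(self):
        if not self.chrom_sizes:
            raise ValidationError("assembly must contain at least one chromosome")
        for name, length in self.chrom_sizes.items():
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chrom_sizes", dict(self.chrom_sizes))

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.chrom_sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __getitem__(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeAssembly":
        """Read a two-column ``name<TAB>length`` chrom-sizes file."""
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for i, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise BedParseError("expected 'name<TAB>length'", i)
                name = parts[0]
                if name in sizes:
                    raise ValidationError(f"duplicate chromosome {name!r}")
                try:
                    sizes[name] = int(parts[1])
                except ValueError as exc:
                    raise BedParseError(f"non-integer length {parts[1]!r}", i) from exc
        return cls(sizes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chrom_sizes.items():
                fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    return GenomeAssembly.from_file(path)


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic segment; ``label`` holds e.g. a chromatin-state name."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted-by-start intervals; abutting intervals coalesce."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    cummax = np.maximum.accumulate(e)
    is_new = np.empty(s.size, dtype=bool)
    is_new[0] = True
    is_new[1:] = s[1:] > cummax[:-1]  # strict: start == running end coalesces
    run_start = np.flatnonzero(is_new)
    run_end = np.append(run_start[1:], s.size) - 1
    return s[run_start].copy(), cummax[run_end].copy()


class IntervalSet:
    """A sample's collection of intervals (one ChIP-seq peak set, a state map, ...).

    The record list preserves input order and labels; base-level queries go
    through a cached merged per-chromosome array representation, so calling
    code never needs to merge explicitly.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        sample_id: str = "",
        assembly: GenomeAssembly | None = None,
        merged: bool = False,
    ):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.sample_id = sample_id
        self.assembly = assembly
        self.merged_flag = merged
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        if assembly is not None:
            for iv in self.intervals:
                if iv.chrom not in assembly:
                    raise ValidationError(
                        f"interval on unknown chromosome {iv.chrom!r} "
                        f"(sample {sample_id!r})"
                    )
                if iv.end > assembly[iv.chrom]:
                    raise ValidationError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {assembly[iv.chrom]}"
                    )

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __repr__(self) -> str:
        return (
            f"IntervalSet(sample_id={self.sample_id!r}, n={len(self)}, "
            f"merged={self.merged_flag})"
        )

    # -- merged-array backbone ----------------------------------------------

    def _chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Merged, sorted (starts, ends) per chromosome (cached)."""
        if self._arrays is None:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            arrays = {}
            for chrom, pairs in by_chrom.items():
                a = np.asarray(pairs, dtype=np.int64)
                arrays[chrom] = _merge_arrays(a[:, 0], a[:, 1])
            self._arrays = arrays
        return self._arrays

    def merge(self) -> "IntervalSet":
        """Union of the input bases as sorted, pairwise-disjoint intervals.

        Labels are dropped (a merged run may span differently-labeled
        records); idempotent.
        """
        out = []
        for chrom in sorted(self._chrom_arrays()):
            s, e = self._chrom_arrays()[chrom]
            out.extend(GenomicInterval(chrom, int(a), int(b)) for a, b in zip(s, e))
        return IntervalSet(out, sample_id=self.sample_id, assembly=self.assembly, merged=True)

    # -- base-level queries ---------------------------------------------------

    def total_bases(self) -> int:
        return int(
            sum((e - s).sum() for s, e in self._chrom_arrays().values())
        )

    def _check_same_assembly(self, other: "IntervalSet") -> None:
        if (
            self.assembly is not None
            and other.assembly is not None
            and self.assembly.chrom_sizes != other.assembly.chrom_sizes
        ):
            raise ValidationError("interval sets are on different assemblies")

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Interval set covering exactly the bases present in both sets."""
        self._check_same_assembly(other)
        mine, theirs = self._chrom_arrays(), other._chrom_arrays()
        out: list[GenomicInterval] = []
        for chrom in sorted(set(mine) & set(theirs)):
            s1, e1 = mine[chrom]
            s2, e2 = theirs[chrom]
            lo = np.searchsorted(e2, s1, side="right")
            hi = np.searchsorted(s2, e1, side="left")
            for k in range(s1.size):
                a, b = lo[k], hi[k]
                if a >= b:
                    continue
                cs = np.maximum(s2[a:b], s1[k])
                ce = np.minimum(e2[a:b], e1[k])
                out.extend(
                    GenomicInterval(chrom, int(x), int(y)) for x, y in zip(cs, ce)
                )
        return IntervalSet(
            out,
            sample_id=self.sample_id,
            assembly=self.assembly or other.assembly,
            merged=True,
        )

    def intersect_bases(self, other: "IntervalSet") -> int:
        """Number of bases covered by both sets (symmetric)."""
        self._check_same_assembly(other)
        mine, theirs = self._chrom_arrays(), other._chrom_arrays()
        total = 0
        for chrom in set(mine) & set(theirs):
            s1, e1 = mine[chrom]
            s2, e2 = theirs[chrom]
            lo = np.searchsorted(e2, s1, side="right")
            hi = np.searchsorted(s2, e1, side="left")
            for k in range(s1.size):
                a, b = lo[k], hi[k]
                if a >= b:
                    continue
                total += int(
                    (np.minimum(e2[a:b], e1[k]) - np.maximum(s2[a:b], s1[k])).sum()
                )
        return total

    def complement(self) -> "IntervalSet":
        """Bases of the attached assembly not covered by this set."""
        if self.assembly is None:
            raise ValidationError("complement requires an attached assembly")
        out: list[GenomicInterval] = []
        arrays = self._chrom_arrays()
        for chrom in self.assembly.chroms:
            length = self.assembly[chrom]
            if chrom not in arrays:
                out.append(GenomicInterval(chrom, 0, length))
                continue
            s, e = arrays[chrom]
            prev = 0
            for a, b in zip(s, e):
                if a > prev:
                    out.append(GenomicInterval(chrom, int(prev), int(a)))
                prev = int(b)
            if prev < length:
                out.append(GenomicInterval(chrom, prev, length))
        return IntervalSet(out, sample_id=self.sample_id, assembly=self.assembly, merged=True)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases in this set but not in ``other``."""
        if self.assembly is not None:
            return self.intersect(other_complement_on(self.assembly, other))
        # no assembly: complement within this set's own span
        span = {
            chrom: int(e[-1]) for chrom, (s, e) in self._chrom_arrays().items()
        }
        comp = other_complement_on(GenomeAssembly(span), other)
        return self.intersect(comp)

    def contains(self, chroms: Iterable[str], positions: Iterable[int]) -> np.ndarray:
        """Boolean array: does each (chrom, pos) fall inside >=1 interval?"""
        chroms = np.asarray(list(chroms), dtype=object)
        positions = np.asarray(list(positions), dtype=np.int64)
        hit = np.zeros(positions.size, dtype=bool)
        arrays = self._chrom_arrays()
        for chrom in np.unique(chroms):
            if chrom not in arrays:
                continue
            mask = chroms == chrom
            s, e = arrays[chrom]
            pos = positions[mask]
            idx = np.searchsorted(s, pos, side="right") - 1
            ok = idx >= 0
            ok[ok] = pos[ok] < e[idx[ok]]
            hit[mask] = ok
        return hit

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "label": [iv.label for iv in self.intervals],
            }
        )

    @property
    def labels(self) -> set[str]:
        return {iv.label for iv in self.intervals if iv.label is not None}


def other_complement_on(assembly: GenomeAssembly, s: IntervalSet) -> IntervalSet:
    """Complement of ``s`` evaluated over an explicit assembly."""
    clone = IntervalSet(s.intervals, sample_id=s.sample_id, assembly=None)
    clone.assembly = assembly
    return clone.complement()


# -- module-level functional aliases ----------------------------------------


def merge_intervals(s: IntervalSet) -> IntervalSet:
    return s.merge()


def total_bases(s: IntervalSet) -> int:
    return s.total_bases()


def intersect_bases(a: IntervalSet, b: IntervalSet) -> int:
    return a.intersect_bases(b)


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

_ORIGINS = ("lead", "ld_linked", "background")


@dataclass(frozen=True)
class SnpRecord:
    """A point variant.  ``pos`` is 0-based; a SNP is a length-1 interval."""

    rsid: str
    chrom: str
    pos: int
    origin: str = "background"
    lead_rsid: str | None = None
    r2_to_lead: float | None = None

    def __post_init__(self):
        if self.pos < 0:
            raise ValidationError(f"negative position for {self.rsid}")
        if self.origin not in _ORIGINS:
            raise ValidationError(f"unknown origin {self.origin!r} for {self.rsid}")
        if self.origin == "ld_linked" and self.lead_rsid is None:
            raise ValidationError(f"ld_linked SNP {self.rsid} lacks a lead_rsid")


class SnpSet:
    """A named collection of SNPs with unique rsIDs."""

    def __init__(self, name: str, records: Iterable[SnpRecord]):
        self.name = name
        self.records: list[SnpRecord] = list(records)
        seen: set[str] = set()
        for r in self.records:
            if r.rsid in seen:
                raise ValidationError(f"duplicate rsid {r.rsid!r} in set {name!r}")
            seen.add(r.rsid)
        self._chroms = np.asarray([r.chrom for r in self.records], dtype=object)
        self._positions = np.asarray([r.pos for r in self.records], dtype=np.int64)

    @property
    def size(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.records)

    @property
    def rsids(self) -> set[str]:
        return {r.rsid for r in self.records}

    @property
    def chroms(self) -> np.ndarray:
        return self._chroms

    @property
    def positions(self) -> np.ndarray:
        return self._positions

    def subtract(self, other: "SnpSet") -> "SnpSet":
        """Remove ``other``'s rsIDs — how a background set is made disjoint
        from the disease set."""
        drop = other.rsids
        return SnpSet(self.name, [r for r in self.records if r.rsid not in drop])

    def membership(self, s: IntervalSet) -> np.ndarray:
        """Per-SNP boolean: covered by >=1 interval of ``s``.

        SNPs on chromosomes absent from the interval set count as outside
        (a warning is logged when the set has an assembly lacking them).
        """
        if s.assembly is not None:
            missing = {c for c in set(self._chroms.tolist()) if c not in s.assembly}
            if missing:
                log.warning(
                    "SNP chromosomes %s absent from assembly; counted as "
                    "non-overlapping",
                    sorted(missing),
                )
        return s.contains(self._chroms, self._positions)

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                lead = r.lead_rsid or ""
                r2 = "" if r.r2_to_lead is None else f"{r.r2_to_lead:.6g}"
                fh.write(f"{r.rsid}\t{r.chrom}\t{r.pos}\t{r.origin}\t{lead}\t{r2}\n")

    @classmethod
    def from_table(
        cls, path: str | Path, name: str | None = None, one_based: bool = False
    ) -> "SnpSet":
        return read_snp_table(path, name=name, one_based=one_based)


def read_snp_table(
    path: str | Path, name: str | None = None, one_based: bool = False
) -> SnpSet:
    """Read ``rsid<TAB>chrom<TAB>pos[<TAB>origin<TAB>lead_rsid<TAB>r2]``.

    ``one_based=True`` converts VCF-convention positions to the internal
    0-based convention by subtracting 1.
    """
    records = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError("expected >=3 columns (rsid, chrom, pos)", i)
            try:
                pos = int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"non-integer position {parts[2]!r}", i) from exc
            if one_based:
                pos -= 1
            origin = parts[3] if len(parts) > 3 and parts[3] else "background"
            lead = parts[4] if len(parts) > 4 and parts[4] else None
            r2 = float(parts[5]) if len(parts) > 5 and parts[5] else None
            records.append(SnpRecord(parts[0], parts[1], pos, origin, lead, r2))
    return SnpSet(name or Path(path).stem, records)


def count_snps_in_set(snps: SnpSet, s: IntervalSet) -> int:
    """Number of SNPs inside >=1 interval; each SNP counted at most once."""
    if snps.size == 0:
        return 0
    return int(snps.membership(s).sum())


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------


def read_bed(
    path: str | Path,
    assembly: GenomeAssembly | None = None,
    sample_id: str | None = None,
) -> IntervalSet:
    """Parse a 3+ column BED file into an (unmerged) IntervalSet.

    A 4th column, when present, is stored as the interval label.  Validation
    against ``assembly`` (known chromosome, end within bounds) happens at
    construction when one is given.
    """
    intervals = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError("expected >=3 tab-separated columns", i)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"non-integer coordinates {parts[1]!r}/{parts[2]!r}", i) from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"invalid interval {parts[0]}:{start}-{end} (need 0 <= start < end)", i
                )
            label = parts[3] if len(parts) > 3 and parts[3] else None
            intervals.append(GenomicInterval(parts[0], start, end, label))
    return IntervalSet(
        intervals,
        sample_id=sample_id or Path(path).stem,
        assembly=assembly,
        merged=False,
    )


def write_bed(s: IntervalSet, path: str | Path) -> None:
    """Write sorted 3- or 4-column BED; labeled sets keep their 4th column."""
    has_labels = any(iv.label is not None for iv in s.intervals)
    rows = sorted(s.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in rows:
            if has_labels:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
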