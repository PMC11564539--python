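"""Genomic bin annotations: intervals, compartments, GC strata, mappability.

The unit of analysis is a fixed-width (default 100 bp) genomic bin.  Each bin
carries its compartment (autosome, mitochondrion, chrX or chrY), its reference
GC fraction, the GC stratum derived from it, and an inclusion decision with a
reason for exclusion.  Only bins that are fully mappable, free of ambiguous
reference bases and inside the 30-60% GC range enter the copy-number model.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AUTOSOME",
    "MITO",
    "CHRX",
    "CHRY",
    "COMPARTMENTS",
    "DEFAULT_ALIASES",
    "N_GC_STRATA",
    "GC_LO",
    "GC_HI",
    "ExclusionReason",
    "GenomicInterval",
    "BinAnnotation",
    "MappabilityTrack",
    "assign_gc_stratum",
    "compartment_of",
]

AUTOSOME = "autosome"
MITO = "mito"
CHRX = "chrX"
CHRY = "chrY"
COMPARTMENTS = (AUTOSOME, MITO, CHRX, CHRY)

#: GRCh38-style contig aliases; users may pass their own mapping.
DEFAULT_ALIASES: Mapping[str, str] = {
    "chrM": MITO, "chrMT": MITO, "MT": MITO, "M": MITO,
    "chrX": CHRX, "X": CHRX,
    "chrY": CHRY, "Y": CHRY,
}

N_GC_STRATA = 6
GC_LO = 0.30
GC_HI = 0.60
_GC_STEP = 0.05
# achievable GC fractions in 100-bp bins are spaced 0.01 apart, so a 1e-6
# tolerance absorbs float representation error without merging strata
_GC_TOL = 1e-6


class ExclusionReason(str, Enum):
    NONE = "none"
    LOW_MAPPABILITY = "low_mappability"
    GC_OUT_OF_RANGE = "gc_out_of_range"
    AMBIGUOUS_BASES = "ambiguous_bases"


def compartment_of(contig: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map a contig name to its compartment; unknown names are autosomal."""
    aliases = DEFAULT_ALIASES if aliases is None else aliases
    return aliases.get(contig, AUTOSOME)


def assign_gc_stratum(gc_fraction: float) -> int | None:
    """Assign a GC fraction to one of six 5%-wide strata covering [30%, 60%].

    Strata are half-open ``[lo, lo+5%)`` except the last, which is closed at
    60% so the six strata tile the interval with no gap or overlap.  Fractions
    outside [0.30, 0.60] return ``None``.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    pct = gc_fraction * 100.0
    if pct < 30.0 - _GC_TOL * 100 or pct > 60.0 + _GC_TOL * 100:
        return None
    stratum = int((pct - 30.0 + _GC_TOL * 100) // 5.0) + 1
    return min(stratum, N_GC_STRATA)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval (BED convention)."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig name must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BinAnnotation:
    """One genomic bin with its GC stratum and inclusion decision."""

    interval: GenomicInterval
    compartment: str
    gc_fraction: float
    gc_stratum: int | None = None
    included: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    def __post_init__(self) -> None:
        if not isinstance(self.exclusion_reason, ExclusionReason):
            object.__setattr__(
                self, "exclusion_reason", ExclusionReason(self.exclusion_reason)
            )
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.included:
            if self.gc_stratum is None:
                raise ValueError("an included bin must have a GC stratum")
            if self.exclusion_reason is not ExclusionReason.NONE:
                raise ValueError(
                    "an included bin cannot carry an exclusion reason"
                )
        if self.gc_stratum is not None and not 1 <= self.gc_stratum <= N_GC_STRATA:
            raise ValueError(f"gc_stratum out of range: {self.gc_stratum}")

    def excluded(self, reason: ExclusionReason) -> "BinAnnotation":
        return replace(self, included=False, exclusion_reason=reason)


@dataclass
class MappabilityTrack:
    """Per-contig sorted, merged lists of uniquely mappable intervals.

    Built from BED rows of regions with 100% mappability; overlapping or
    adjacent regions are merged on load so that coverage queries are a binary
    search over disjoint intervals.
    """

    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "MappabilityTrack":
        raw: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            raw.setdefault(iv.contig, []).append((iv.start, iv.end))
        merged: dict[str, list[tuple[int, int]]] = {}
        for contig, spans in raw.items():
            spans.sort()
            out: list[tuple[int, int]] = []
            for start, end in spans:
                if out and start <= out[-1][1]:
                    out[-1] = (out[-1][0], max(out[-1][1], end))
                else:
                    out.append((start, end))
            merged[contig] = out
        return cls(regions=merged)

    @classmethod
    def from_bed(cls, path) -> "MappabilityTrack":
        intervals = []
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}: line {lineno}: BED rows need >= 3 columns"
                    )
                try:
                    intervals.append(
                        GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        return cls.from_intervals(intervals)

    def covers(self, interval: GenomicInterval) -> bool:
        """True iff the interval is entirely inside the merged track."""
        spans = self.regions.get(interval.contig)
        if not spans:
            return False
        idx = bisect.bisect_right(spans, (interval.start, float("inf"))) - 1
        if idx < 0:
            return False
        start, end = spans[idx]
        return start <= interval.start and interval.end <= end

    @property
    def contigs(self) -> Sequence[str]:
        return tuple(self.regions)
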