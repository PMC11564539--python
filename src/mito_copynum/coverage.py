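"""Per-bin filtered read counts from alignments or precomputed depth tables.

Reads are filtered on mapping quality and SAM flags, then assigned to the
single bin containing their leftmost aligned reference position.  As an
alternative to alignment I/O, a mosdepth-style per-region mean-depth table
can be ingested; because the downstream copy-number estimate is a ratio,
depth is an acceptable proportional surrogate for read counts.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .bins import COMPARTMENTS, N_GC_STRATA, BinAnnotation

__all__ = [
    "ReadFilterPolicy",
    "CountMatrix",
    "passes_filters",
    "count_reads",
    "ingest_depth_table",
    "aggregate",
    "write_count_table",
    "read_count_table",
]

#: unmapped | secondary | QC fail | duplicate | supplementary
DEFAULT_FLAG_MASK = 0x4 | 0x100 | 0x200 | 0x400 | 0x800  # == 3844
DEFAULT_MIN_MAPQ = 30

READ_START_COUNT = "read_start_count"
MEAN_DEPTH = "mean_depth"


@dataclass(frozen=True)
class ReadFilterPolicy:
    """Alignment-record filter: MAPQ floor plus a SAM-flag exclusion mask."""

    min_mapq: int = DEFAULT_MIN_MAPQ
    excluded_flag_mask: int = DEFAULT_FLAG_MASK

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.excluded_flag_mask < 0:
            raise ValueError("excluded_flag_mask must be >= 0")


def passes_filters(read_record, policy: ReadFilterPolicy | None = None) -> bool:
    """True iff the record clears the MAPQ floor and none of the masked flags.

    With the default policy this rejects unmapped (0x4), secondary (0x100),
    QC-fail (0x200), duplicate (0x400) and supplementary (0x800) records —
    flag mask 3844 — and records with MAPQ below 30.  ``read_record`` is any
    object exposing ``flag`` and ``mapping_quality`` (e.g. a pysam
    AlignedSegment).
    """
    policy = policy or ReadFilterPolicy()
    return (
        read_record.mapping_quality >= policy.min_mapq
        and (read_record.flag & policy.excluded_flag_mask) == 0
    )


@dataclass
class CountMatrix:
    """Per-bin counts for one sample plus their sufficient statistics.

    ``data`` has one row per included bin: contig, start, end, compartment,
    gc_stratum, count.  ``source`` records whether counts are read starts
    (integers) or mean depths (reals); the two must never be mixed because
    they differ by a read-length scale factor.
    """

    data: pd.DataFrame
    sample_id: str = "sample"
    source: str = READ_START_COUNT
    filtered_out: int = 0
    warnings_count: int = 0
    _stats: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.source not in (READ_START_COUNT, MEAN_DEPTH):
            raise ValueError(f"unknown count source {self.source!r}")
        required = {"contig", "start", "end", "compartment", "gc_stratum", "count"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if (self.data["count"] < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def stats(self) -> pd.DataFrame:
        if self._stats is None:
            self._stats = aggregate(self)
        return self._stats

    def scaled(self, factor: float) -> "CountMatrix":
        """Return a copy with every count multiplied by ``factor`` (depth source)."""
        data = self.data.copy()
        data["count"] = data["count"] * factor
        return CountMatrix(data=data, sample_id=self.sample_id, source=MEAN_DEPTH)


def _bin_lookup(bins: Sequence[BinAnnotation]) -> tuple[dict, int]:
    included = [b for b in bins if b.included]
    if not included:
        raise ValueError("no included bins supplied")
    widths = {b.interval.width for b in included}
    if len(widths) != 1:
        raise ValueError(f"bins have mixed widths: {sorted(widths)}")
    lookup = {(b.interval.contig, b.interval.start): b for b in included}
    return lookup, widths.pop()


def count_reads(
    alignment,
    bins: Sequence[BinAnnotation],
    policy: ReadFilterPolicy | None = None,
    sample_id: str | None = None,
    reference_filename: str | None = None,
) -> CountMatrix:
    """Count filtered reads per included bin from an indexed BAM/CRAM.

    Each passing read is assigned to exactly one bin: the bin containing its
    leftmost aligned reference position.  Reads starting in excluded bins (or
    past the last full bin of a contig) are not counted.  The traversal is a
    single pass per contig and is deterministic for a given input.
    """
    policy = policy or ReadFilterPolicy()
    own_handle = False
    if isinstance(alignment, (str, Path)):
        alignment = pysam.AlignmentFile(
            str(alignment), reference_filename=reference_filename
        )
        own_handle = True
    try:
        if not alignment.has_index():
            raise ValueError(f"alignment file {alignment.filename!r} is not indexed")
        lookup, width = _bin_lookup(bins)
        header_contigs = set(alignment.references)
        bin_contigs = {b.interval.contig for b in bins if b.included}
        missing = sorted(bin_contigs - header_contigs)
        if missing:
            raise ValueError(
                f"contigs {missing} in the bin table are absent from the alignment "
                f"header (header has {sorted(header_contigs)})"
            )
        counts: dict[tuple[str, int], int] = {key: 0 for key in lookup}
        rejected = 0
        for contig in sorted(bin_contigs):
            for read in alignment.fetch(contig):
                if not passes_filters(read, policy):
                    rejected += 1
                    continue
                start = read.reference_start
                key = (contig, (start // width) * width)
                if key in counts:
                    counts[key] += 1
    finally:
        if own_handle:
            alignment.close()
    rows = [
        {
            "contig": b.interval.contig,
            "start": b.interval.start,
            "end": b.interval.end,
            "compartment": b.compartment,
            "gc_stratum": b.gc_stratum,
            "count": counts[(b.interval.contig, b.interval.start)],
        }
        for b in bins
        if b.included
    ]
    return CountMatrix(
        data=pd.DataFrame(rows),
        sample_id=sample_id or "sample",
        source=READ_START_COUNT,
        filtered_out=rejected,
    )


def ingest_depth_table(
    path,
    bins: Sequence[BinAnnotation],
    sample_id: str | None = None,
) -> CountMatrix:
    """Ingest a mosdepth-style 4-column regions table as per-bin mean depths.

    Rows are ``contig  start  end  value`` in 0-based half-open coordinates
    and must align exactly to bin boundaries.  Rows for excluded or unknown
    bins are skipped with a warning tally; a missing included bin is fatal.
    """
    lookup, width = _bin_lookup(bins)
    known_bins = {
        (b.interval.contig, b.interval.start, b.interval.end) for b in bins
    }
    opener = gzip.open if str(path).endswith(".gz") else open
    values: dict[tuple[str, int], float] = {}
    skipped = 0
    with opener(path, "rt") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 columns (contig, start, end, depth)"
                )
            contig, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if start % width != 0 or end - start != width:
                raise ValueError(
                    f"{path}: line {lineno}: region {contig}:{start}-{end} is not "
                    f"aligned to the {width}-bp bin grid"
                )
            if (contig, start) in lookup:
                values[(contig, start)] = value
            elif (contig, start, end) in known_bins:
                skipped += 1  # excluded bin
            else:
                skipped += 1  # unknown but grid-aligned bin
    if skipped:
        warnings.warn(f"{skipped} depth rows for excluded or unknown bins ignored")
    missing = [key for key in lookup if key not in values]
    if missing:
        preview = ", ".join(f"{c}:{s}" for c, s in sorted(missing)[:5])
        raise ValueError(
            f"{path}: depth table is missing {len(missing)} included bin(s): {preview}"
        )
    rows = [
        {
            "contig": b.interval.contig,
            "start": b.interval.start,
            "end": b.interval.end,
            "compartment": b.compartment,
            "gc_stratum": b.gc_stratum,
            "count": values[(b.interval.contig, b.interval.start)],
        }
        for b in bins
        if b.included
    ]
    return CountMatrix(
        data=pd.DataFrame(rows),
        sample_id=sample_id or "sample",
        source=MEAN_DEPTH,
        warnings_count=skipped,
    )


def aggregate(counts: CountMatrix) -> pd.DataFrame:
    """Per-compartment, per-stratum sufficient statistics.

    Returns a frame indexed by (compartment, gc_stratum) with columns
    ``n_bins`` (number of included bins) and ``total_count`` (summed counts).
    Every stratum 1..6 is present for every compartment that appears in the
    matrix, with zeros for empty strata, so downstream code never needs to
    distinguish absent from empty.
    """
    if counts.data.empty:
        raise ValueError("empty count matrix")
    present = [c for c in COMPARTMENTS if c in set(counts.data["compartment"])]
    grouped = counts.data.groupby(["compartment", "gc_stratum"])["count"].agg(
        ["size", "sum"]
    )
    index = pd.MultiIndex.from_product(
        [present, range(1, N_GC_STRATA + 1)], names=["compartment", "gc_stratum"]
    )
    stats = pd.DataFrame(index=index, columns=["n_bins", "total_count"], dtype=float)
    stats["n_bins"] = 0.0
    stats["total_count"] = 0.0
    for (comp, stratum), row in grouped.iterrows():
        stats.loc[(comp, stratum), "n_bins"] = float(row["size"])
        stats.loc[(comp, stratum), "total_count"] = float(row["sum"])
    total = float(counts.data["count"].sum())
    if not np.isclose(stats["total_count"].sum(), total):
        raise AssertionError("sufficient statistics do not conserve the total count")
    return stats


def write_count_table(counts: CountMatrix, path, stats_path=None) -> None:
    """Write the per-bin count table (TSV) and optionally a JSON stats sidecar."""
    with open(path, "w") as handle:
        handle.write(f"#sample_id={counts.sample_id}\tsource={counts.source}\n")
        handle.write("#contig\tstart\tend\tcompartment\tgc_stratum\tcount\n")
        for row in counts.data.itertuples(index=False):
            handle.write(
                f"{row.contig}\t{row.start}\t{row.end}\t{row.compartment}\t"
                f"{row.gc_stratum}\t{row.count!r}\n"
            )
    if stats_path is not None:
        stats = counts.stats
        payload = {
            "sample_id": counts.sample_id,
            "source": counts.source,
            "strata": [
                {
                    "compartment": comp,
                    "gc_stratum": int(stratum),
                    "n_bins": stats.loc[(comp, stratum), "n_bins"],
                    "total_count": stats.loc[(comp, stratum), "total_count"],
                }
                for comp, stratum in stats.index
            ],
        }
        Path(stats_path).write_text(json.dumps(payload, indent=2) + "\n")


def read_count_table(path) -> CountMatrix:
    """Read a count table written by :func:`write_count_table`."""
    sample_id, source = "sample", READ_START_COUNT
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#sample_id="):
                    parts = dict(
                        item.split("=", 1) for item in line[1:].split("\t") if "=" in item
                    )
                    sample_id = parts.get("sample_id", sample_id)
                    source = parts.get("source", source)
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns")
            rows.append(
                {
                    "contig": fields[0],
                    "start": int(fields[1]),
                    "end": int(fields[2]),
                    "compartment": fields[3],
                    "gc_stratum": int(fields[4]),
                    "count": float(fields[5]),
                }
            )
    if not rows:
        raise ValueError(f"{path}: no count rows found")
    data = pd.DataFrame(rows)
    if source == READ_START_COUNT:
        data["count"] = data["count"].astype(int)
    return CountMatrix(data=data, sample_id=sample_id, source=source)
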