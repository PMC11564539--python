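"""Reference preparation: tile contigs into bins and decide inclusion.

Turns a reference FASTA plus a mappability BED into the fixed table of
included 100-bp bins with GC-stratum labels that read counting and the
copy-number model consume.  The table is TSV with a BED-compatible first
three columns (0-based half-open coordinates).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

from .bins import (
    BinAnnotation,
    ExclusionReason,
    GenomicInterval,
    MappabilityTrack,
    assign_gc_stratum,
    compartment_of,
)

__all__ = [
    "tile_genome",
    "apply_mappability",
    "prepare_bins",
    "write_bin_table",
    "read_bin_table",
]

_TABLE_COLUMNS = (
    "contig",
    "start",
    "end",
    "compartment",
    "gc_fraction",
    "gc_stratum",
    "included",
    "exclusion_reason",
)


def tile_genome(
    reference,
    contigs: Sequence[str],
    bin_width: int = 100,
    aliases: Mapping[str, str] | None = None,
) -> list[BinAnnotation]:
    """Tile contigs into contiguous fixed-width bins with GC annotations.

    Parameters
    ----------
    reference
        An indexed FASTA handle (`pyfaidx.Fasta` or anything mapping contig
        name to a sliceable sequence with ``len``).
    contigs
        Contig names to tile; a missing contig is a fatal error.
    bin_width
        Bin width in bp; a trailing partial bin is dropped so every bin has
        identical width (the Poisson model assumes equal exposure per bin).

    Bins containing any non-ACGT base are flagged ``ambiguous_bases``; their
    GC fraction is computed over the unambiguous bases only.  Inclusion is
    not decided here — see :func:`apply_mappability`.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    out: list[BinAnnotation] = []
    for contig in contigs:
        try:
            record = reference[contig]
        except KeyError as exc:
            raise KeyError(f"contig {contig!r} not found in reference") from exc
        length = len(record)
        n_bins = length // bin_width
        if n_bins == 0:
            warnings.warn(
                f"contig {contig!r} shorter than bin width ({length} < {bin_width}); skipped"
            )
            continue
        compartment = compartment_of(contig, aliases)
        seq = str(record[: n_bins * bin_width]).upper()
        for i in range(n_bins):
            sub = seq[i * bin_width : (i + 1) * bin_width]
            g = sub.count("G")
            c = sub.count("C")
            a = sub.count("A")
            t = sub.count("T")
            unambiguous = a + c + g + t
            ambiguous = len(sub) - unambiguous
            gc = (g + c) / unambiguous if unambiguous else float("nan")
            out.append(
                BinAnnotation(
                    interval=GenomicInterval(contig, i * bin_width, (i + 1) * bin_width),
                    compartment=compartment,
                    gc_fraction=gc,
                    gc_stratum=assign_gc_stratum(gc) if unambiguous else None,
                    included=False,
                    exclusion_reason=(
                        ExclusionReason.AMBIGUOUS_BASES
                        if ambiguous
                        else ExclusionReason.NONE
                    ),
                )
            )
    return out


def apply_mappability(
    bins: Iterable[BinAnnotation], track: MappabilityTrack
) -> list[BinAnnotation]:
    """Decide inclusion: a bin is kept only when fully covered by the track,
    inside the GC range, and free of ambiguous bases.

    Exclusion reasons are assigned with precedence ambiguous_bases >
    low_mappability > gc_out_of_range, so a bin failing several conditions
    reports the most structural one.
    """
    out: list[BinAnnotation] = []
    missing_contigs: set[str] = set()
    for bin_ in bins:
        if bin_.exclusion_reason is ExclusionReason.AMBIGUOUS_BASES:
            out.append(bin_)
            continue
        if bin_.interval.contig not in track.regions:
            missing_contigs.add(bin_.interval.contig)
            out.append(bin_.excluded(ExclusionReason.LOW_MAPPABILITY))
            continue
        if not track.covers(bin_.interval):
            out.append(bin_.excluded(ExclusionReason.LOW_MAPPABILITY))
            continue
        if bin_.gc_stratum is None:
            out.append(bin_.excluded(ExclusionReason.GC_OUT_OF_RANGE))
            continue
        out.append(
            BinAnnotation(
                interval=bin_.interval,
                compartment=bin_.compartment,
                gc_fraction=bin_.gc_fraction,
                gc_stratum=bin_.gc_stratum,
                included=True,
                exclusion_reason=ExclusionReason.NONE,
            )
        )
    for contig in sorted(missing_contigs):
        warnings.warn(
            f"contig {contig!r} absent from the mappability track; all its bins excluded"
        )
    return out


def prepare_bins(
    reference,
    track: MappabilityTrack,
    contigs: Sequence[str] | None = None,
    bin_width: int = 100,
    aliases: Mapping[str, str] | None = None,
) -> list[BinAnnotation]:
    """Tile the reference and apply mappability/GC/ambiguity filters."""
    if contigs is None:
        contigs = list(reference.keys())
    return apply_mappability(tile_genome(reference, contigs, bin_width, aliases), track)


def write_bin_table(bins: Iterable[BinAnnotation], path) -> None:
    """Write the bin-annotation table: BED-compatible TSV with extra columns."""
    with open(path, "w") as handle:
        handle.write("#" + "\t".join(_TABLE_COLUMNS) + "\n")
        for bin_ in bins:
            iv = bin_.interval
            handle.write(
                "\t".join(
                    (
                        iv.contig,
                        str(iv.start),
                        str(iv.end),
                        bin_.compartment,
                        repr(bin_.gc_fraction),
                        "." if bin_.gc_stratum is None else str(bin_.gc_stratum),
                        "1" if bin_.included else "0",
                        bin_.exclusion_reason.value,
                    )
                )
                + "\n"
            )


def read_bin_table(path) -> list[BinAnnotation]:
    """Read a bin-annotation table, validating each row's invariants.

    The GC stratum recorded in the file must agree with the stratum recomputed
    from the GC fraction; disagreement is a fatal validation error naming the
    line, because it means the table was edited or produced by an
    incompatible stratum convention.
    """
    out: list[BinAnnotation] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_TABLE_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(_TABLE_COLUMNS)} columns, got {len(fields)}"
                )
            try:
                interval = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                gc = float(fields[4])
                stratum = None if fields[5] == "." else int(fields[5])
                included = bool(int(fields[6]))
                reason = ExclusionReason(fields[7])
                bin_ = BinAnnotation(
                    interval=interval,
                    compartment=fields[3],
                    gc_fraction=gc,
                    gc_stratum=stratum,
                    included=included,
                    exclusion_reason=reason,
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if gc == gc and stratum != assign_gc_stratum(gc):  # gc==gc: skip NaN
                raise ValueError(
                    f"{path}: line {lineno}: gc_stratum {stratum} inconsistent with "
                    f"gc_fraction {gc!r} (expected {assign_gc_stratum(gc)})"
                )
            out.append(bin_)
    return out
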