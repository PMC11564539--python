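"""Synthetic data generation for the copy-number model and its plumbing.

Three generators, all deterministic under a fixed seed:

* :func:`simulate_counts` — per-bin counts drawn from the GC-stratified
  Poisson model with known (mu, Np, beta), the module's ground-truth
  workhorse.  Defaults emulate a 30x short-read genome in miniature:
  Np = 15 reads per 100-bp bin per haploid copy, mtDNA copy number 150,
  1e5 autosomal bins and 160 mitochondrial bins spread over the six GC
  strata with mtDNA's characteristic ~44% GC.
* :func:`simulate_reference` — tiny FASTA + mappability BED pairs whose
  per-bin GC content is exact by construction, together with an expected
  bin-annotation table computed by independent string counting (an oracle
  for reference preparation).
* :func:`simulate_alignment_fixture` — minimal sorted, indexed BAM files
  containing exactly the intended passing reads plus contaminant records
  that the default read filter must reject (an oracle for read counting).

What these generators do NOT emulate: overdispersion, GC bias varying
within a stratum, mappability errors, NUMT cross-mapping, paired-end
fragment structure.  Tests passing on this data validate the estimator's
math and plumbing, not robustness to those real-data artifacts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .bins import (
    AUTOSOME,
    CHRX,
    CHRY,
    MITO,
    N_GC_STRATA,
    BinAnnotation,
    ExclusionReason,
    GenomicInterval,
    compartment_of,
)
from .coverage import MEAN_DEPTH, READ_START_COUNT, CountMatrix

__all__ = [
    "SimulationConfig",
    "simulate_counts",
    "simulate_reference",
    "simulate_alignment_fixture",
]

# default bin composition: 1e5 autosomal bins skewed toward mid-GC as in
# real genomes; 160 mt bins centred on mtDNA's ~44% GC
_DEFAULT_AUTO = (25_000, 20_000, 18_000, 15_000, 12_000, 10_000)
_DEFAULT_MT = (10, 25, 50, 45, 20, 10)
_DEFAULT_X = (50, 50, 50, 50, 50, 50)
_DEFAULT_Y = (10, 10, 10, 10, 10, 10)


@dataclass
class SimulationConfig:
    """Ground-truth parameters and bin composition for count simulation.

    ``true_beta`` is renormalised on load so its autosomal-bin-weighted mean
    is exactly 1 (the model's identifiability convention); a notice is
    emitted when renormalisation changes the values.
    """

    seed: int = 0
    n_auto_bins_per_stratum: tuple[int, ...] = _DEFAULT_AUTO
    n_mt_bins_per_stratum: tuple[int, ...] = _DEFAULT_MT
    n_x_bins_per_stratum: tuple[int, ...] = _DEFAULT_X
    n_y_bins_per_stratum: tuple[int, ...] = _DEFAULT_Y
    true_mu_mt: float = 150.0
    true_mu_x: float = 2.0
    true_mu_y: float = 0.0
    true_np: float = 15.0
    true_beta: tuple[float, ...] = (1.0,) * N_GC_STRATA
    count_mode: str = READ_START_COUNT
    read_length: int = 150
    noise: bool = True  #: False emits exact expected values (no Poisson draw)

    def __post_init__(self) -> None:
        for name in (
            "n_auto_bins_per_stratum",
            "n_mt_bins_per_stratum",
            "n_x_bins_per_stratum",
            "n_y_bins_per_stratum",
            "true_beta",
        ):
            value = tuple(getattr(self, name))
            if len(value) != N_GC_STRATA:
                raise ValueError(f"{name} must have {N_GC_STRATA} entries")
            setattr(self, name, value)
        if min(self.true_mu_mt, self.true_mu_x, self.true_mu_y) < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.true_np <= 0:
            raise ValueError("true_np must be positive")
        if self.count_mode not in (READ_START_COUNT, MEAN_DEPTH):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")
        n_auto = np.array(self.n_auto_bins_per_stratum, dtype=float)
        beta = np.array(self.true_beta, dtype=float)
        if (beta <= 0).any():
            raise ValueError("true_beta must be positive")
        weighted = float((n_auto * beta).sum() / n_auto.sum())
        if abs(weighted - 1.0) > 1e-12:
            beta = beta / weighted
            self.true_beta = tuple(beta)

    def truth(self) -> dict:
        """Ground-truth record to serialise alongside generated data."""
        return asdict(self)


def _bin_frame(
    compartment: str, contig: str, n_per_stratum: Sequence[int], offset: int = 0
) -> pd.DataFrame:
    n = np.asarray(n_per_stratum, dtype=int)
    total = int(n.sum())
    starts = offset + 100 * np.arange(total)
    return pd.DataFrame(
        {
            "contig": contig,
            "start": starts,
            "end": starts + 100,
            "compartment": compartment,
            "gc_stratum": np.repeat(np.arange(1, N_GC_STRATA + 1), n),
        }
    )


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, dict]:
    """Draw per-bin counts under the GC-stratified Poisson model.

    Autosomal bins in stratum i draw Poisson(2 * Np * beta_i); target
    compartments draw Poisson(mu * Np * beta_i).  In ``mean_depth`` mode the
    drawn counts are scaled by read_length/100, mimicking per-bin mean depth
    at constant read length.  With ``noise=False`` the expected values are
    emitted exactly (useful for algebraic identities).  Returns the count
    matrix and the ground-truth record.
    """
    rng = np.random.default_rng(config.seed)
    beta = np.array(config.true_beta, dtype=float)
    parts = []
    specs = [
        (AUTOSOME, "chr1", config.n_auto_bins_per_stratum, 2.0),
        (MITO, "chrM", config.n_mt_bins_per_stratum, config.true_mu_mt),
        (CHRX, "chrX", config.n_x_bins_per_stratum, config.true_mu_x),
        (CHRY, "chrY", config.n_y_bins_per_stratum, config.true_mu_y),
    ]
    for compartment, contig, n_per_stratum, mu in specs:
        if sum(n_per_stratum) == 0:
            continue
        frame = _bin_frame(compartment, contig, n_per_stratum)
        rates = mu * config.true_np * beta[frame["gc_stratum"].to_numpy() - 1]
        if config.noise:
            frame["count"] = rng.poisson(rates)
        else:
            frame["count"] = rates
        parts.append(frame)
    data = pd.concat(parts, ignore_index=True)
    source = config.count_mode
    if source == MEAN_DEPTH:
        data["count"] = data["count"] * (config.read_length / 100.0)
    elif not config.noise:
        source = MEAN_DEPTH  # expected values are not integers in general
    matrix = CountMatrix(data=data, sample_id=f"sim-{config.seed}", source=source)
    return matrix, config.truth()


def _gc_count(target: float) -> int:
    k = round(target * 100)
    if abs(k - target * 100) > 1e-6 or not 0 <= k <= 100:
        raise ValueError(
            f"GC target {target} is not achievable in a 100-bp bin "
            "(needs an integer count of G+C in 0..100)"
        )
    return int(k)


def _expected_stratum(k: int) -> int | None:
    """Stratum from the integer G+C count, by integer arithmetic only."""
    if k < 30 or k > 60:
        return None
    return min((k - 30) // 5 + 1, N_GC_STRATA)


def simulate_reference(
    seed: int,
    contig_gc: dict[str, Sequence[float]],
    mappable: dict[str, Sequence[tuple[int, int]]] | None = None,
    trailing_bases: int = 0,
) -> tuple[str, str, list[BinAnnotation]]:
    """Generate a FASTA + mappability BED with exact per-bin GC content.

    ``contig_gc`` maps contig name to the GC fraction of each successive
    100-bp bin; each fraction must be an integer count of G+C out of 100.
    ``mappable`` maps contig name to fully-mappable (start, end) spans; by
    default every contig is fully mappable.  ``trailing_bases`` appends that
    many extra A's to each contig (exercising partial-bin dropping).

    Returns (fasta_text, bed_text, expected_annotations).  The expected
    annotations are computed here by direct string counting and integer
    stratum arithmetic — independently of the reference-preparation code
    they serve as an oracle for.
    """
    rng = np.random.default_rng(seed)
    fasta_lines: list[str] = []
    bed_lines: list[str] = []
    expected: list[BinAnnotation] = []
    for contig, targets in contig_gc.items():
        seq_parts: list[str] = []
        for target in targets:
            k = _gc_count(target)
            bases = np.array(
                list(rng.choice(["G", "C"], size=k))
                + list(rng.choice(["A", "T"], size=100 - k))
            )
            rng.shuffle(bases)
            seq_parts.append("".join(bases))
        seq = "".join(seq_parts) + "A" * trailing_bases
        fasta_lines.append(f">{contig}")
        fasta_lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))

        spans = (
            [(0, len(targets) * 100 + trailing_bases)]
            if mappable is None or contig not in mappable
            else list(mappable[contig])
        )
        for start, end in spans:
            bed_lines.append(f"{contig}\t{start}\t{end}")

        # oracle annotations by string counting
        merged = []
        for start, end in sorted(spans):
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        compartment = compartment_of(contig)
        for i, _ in enumerate(targets):
            sub = seq[i * 100 : (i + 1) * 100]
            k = sub.count("G") + sub.count("C")
            stratum = _expected_stratum(k)
            covered = any(s <= i * 100 and (i + 1) * 100 <= e for s, e in merged)
            if not covered:
                reason = ExclusionReason.LOW_MAPPABILITY
            elif stratum is None:
                reason = ExclusionReason.GC_OUT_OF_RANGE
            else:
                reason = ExclusionReason.NONE
            expected.append(
                BinAnnotation(
                    interval=GenomicInterval(contig, i * 100, (i + 1) * 100),
                    compartment=compartment,
                    gc_fraction=k / 100,
                    gc_stratum=stratum,
                    included=reason is ExclusionReason.NONE,
                    exclusion_reason=reason,
                )
            )
    return "\n".join(fasta_lines) + "\n", "\n".join(bed_lines) + "\n", expected


def simulate_alignment_fixture(
    seed: int,
    bins: Sequence[BinAnnotation],
    intended_counts: dict[tuple[str, int], int],
    contaminants: Sequence[tuple[int, int, str, int]] = (),
    out_path: str | Path = "fixture.bam",
    read_length: int = 50,
) -> Path:
    """Write a minimal sorted, indexed BAM exercising the read filters.

    ``intended_counts`` maps (contig, bin start) to the number of clean
    primary reads to place with leftmost positions inside that bin.
    ``contaminants`` are (flag, mapq, contig, position) records that the
    default filter policy must reject (or that fall in excluded bins).
    Returns the BAM path; a .bai index is written alongside.
    """
    rng = np.random.default_rng(seed)
    contigs: dict[str, int] = {}
    for b in bins:
        iv = b.interval
        contigs[iv.contig] = max(contigs.get(iv.contig, 0), iv.end + 1000)
    for _, _, contig, pos in contaminants:
        contigs[contig] = max(contigs.get(contig, 0), pos + read_length + 1000)
    names = sorted(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": contigs[name]} for name in names],
    }
    records: list[tuple[int, int, int, int, str]] = []  # (tid, pos, flag, mapq, name)
    serial = 0
    for (contig, bin_start), count in intended_counts.items():
        width = next(
            b.interval.width
            for b in bins
            if b.interval.contig == contig and b.interval.start == bin_start
        )
        offsets = rng.integers(0, width, size=count)
        for off in offsets:
            records.append(
                (names.index(contig), int(bin_start + off), 0, 60, f"clean{serial}")
            )
            serial += 1
    for flag, mapq, contig, pos in contaminants:
        records.append((names.index(contig), int(pos), int(flag), int(mapq), f"bad{serial}"))
        serial += 1
    records.sort()

    out_path = Path(out_path)
    with pysam.AlignmentFile(str(out_path), "wb", header=header) as bam:
        for tid, pos, flag, mapq, name in records:
            seg = pysam.AlignedSegment(bam.header)
            seg.query_name = name
            seg.flag = flag
            seg.reference_id = tid
            seg.reference_start = pos
            seg.mapping_quality = mapq
            if not flag & 0x4:
                seg.cigarstring = f"{read_length}M"
            seg.query_sequence = "A" * read_length
            seg.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            bam.write(seg)
    pysam.index(str(out_path))
    return out_path
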