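import numpy as np
import pyfaidx
import pytest

from mito_copynum import (
    MappabilityTrack,
    SimulationConfig,
    simulate_counts,
    simulate_reference,
)
from mito_copynum.reference import prepare_bins

BIASED_BETA = (0.8, 0.9, 1.0, 1.05, 1.1, 1.2)


@pytest.fixture(scope="session")
def biased_sim():
    """One realistic-scale simulated sample with GC bias and known truth."""
    config = SimulationConfig(seed=1234, true_beta=BIASED_BETA)
    matrix, truth = simulate_counts(config)
    return matrix, truth


@pytest.fixture()
def tiny_reference(tmp_path):
    """A small synthetic reference with its oracle annotations on disk."""
    contig_gc = {
        "chr1": [0.32, 0.38, 0.41, 0.47, 0.52, 0.55, 0.28, 0.61],
        "chrM": [0.42, 0.44, 0.46],
        "chrX": [0.38, 0.52],
    }
    fasta_text, bed_text, expected = simulate_reference(
        seed=7, contig_gc=contig_gc, trailing_bases=43
    )
    fasta_path = tmp_path / "ref.fa"
    bed_path = tmp_path / "map.bed"
    fasta_path.write_text(fasta_text)
    bed_path.write_text(bed_text)
    return fasta_path, bed_path, expected


@pytest.fixture()
def tiny_bins(tiny_reference):
    fasta_path, bed_path, _ = tiny_reference
    reference = pyfaidx.Fasta(str(fasta_path))
    return prepare_bins(reference, MappabilityTrack.from_bed(bed_path))


def poisson_loglik_mu(mu, n, S, beta, Np):
    """Plug-in Poisson log-likelihood in mu (up to mu-free terms)."""
    n = np.asarray(n, float)
    S = np.asarray(S, float)
    beta = np.asarray(beta, float)
    mask = n > 0
    if mu <= 0:
        return -np.inf
    return float(
        np.sum(S[mask] * np.log(mu * Np * beta[mask]))
        - np.sum(n[mask] * mu * Np * beta[mask])
    )
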