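"""GC-stratified Poisson copy-number model.

The model assumes read counts in disjoint equal-width bins are independent
Poisson variables whose mean factorises into a per-haploid-copy intensity
``Np``, a GC-stratum bias ``beta_i`` and the compartment copy number:

    autosomal bin in stratum i:   A(B) ~ Poisson(2 * Np * beta_i)
    target bin in stratum i:      M(B) ~ Poisson(mu * Np * beta_i)

with ``mu`` the copies per diploid cell of the target compartment (mtDNA,
chrX or chrY).  ``Np`` and ``beta`` are profiled out on the (vastly more
numerous) autosomal bins; ``mu`` is then the pooled Poisson MLE with those
plugged in:

    Np      = (sum_i S_i / sum_i n_i) / 2           (autosomes)
    beta_i  = (S_i / n_i) / (2 * Np)                (autosomes, per stratum)
    mu_hat  = sum_i S_ci / (Np * sum_i n_ci * beta_i)

where ``n`` are bin counts and ``S`` summed read counts per stratum.  The
split of scale between Np and beta is a normalisation convention (here the
count-weighted mean of beta over autosomal bins is exactly 1, making beta_i
read as relative bias); ``mu_hat`` is invariant to that split and to any
common rescaling of all counts — which is what licenses mean-depth tables
as input.

Uncertainty is plug-in: conditional on (Np, beta), the target total
``sum S`` is Poisson, giving ``se = mu_hat / sqrt(sum S)`` and an exact
(Garwood, chi-square based) 95% interval scaled by the fixed denominator.

The naive ratio estimator ``2 * mt mean / autosomal mean`` — valid only
under uniform coverage — is provided as a baseline for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .bins import AUTOSOME, CHRX, CHRY, MITO, N_GC_STRATA
from .coverage import CountMatrix

__all__ = [
    "CompartmentEstimate",
    "CopyNumberFit",
    "RatioEstimate",
    "PoissonCopyNumber",
    "estimate_Np",
    "estimate_beta",
    "estimate_mu",
    "fit_sample",
    "ratio_estimator",
]

TARGET_COMPARTMENTS = (MITO, CHRX, CHRY)


@dataclass(frozen=True)
class CompartmentEstimate:
    """Copy number of one compartment with plug-in Poisson uncertainty."""

    compartment: str
    mu: float
    se: float
    ci_low: float
    ci_high: float
    n_bins: int
    total_count: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("copy number cannot be negative")
        if not self.ci_low <= self.mu <= self.ci_high:
            raise ValueError("confidence interval must contain the estimate")


@dataclass
class CopyNumberFit:
    """Full fit of one sample: Np, beta, and per-compartment copy numbers."""

    sample_id: str
    Np: float
    beta: np.ndarray  # length 6; NaN for strata with no autosomal bins
    estimates: dict[str, CompartmentEstimate]
    strata_used: dict[str, tuple[int, ...]]
    diagnostics: pd.DataFrame
    source: str

    @property
    def mu_mt(self) -> float | None:
        est = self.estimates.get(MITO)
        return None if est is None else est.mu

    @property
    def mu_x(self) -> float | None:
        est = self.estimates.get(CHRX)
        return None if est is None else est.mu

    @property
    def mu_y(self) -> float | None:
        est = self.estimates.get(CHRY)
        return None if est is None else est.mu


@dataclass(frozen=True)
class RatioEstimate:
    """Baseline uniform-coverage estimator: 2 x target mean / autosomal mean."""

    compartment: str
    mu_naive: float

    def __post_init__(self) -> None:
        if self.mu_naive < 0:
            raise ValueError("copy number cannot be negative")


def _stratum_arrays(stats: pd.DataFrame, compartment: str) -> tuple[np.ndarray, np.ndarray]:
    """(n, S) arrays of length 6 for one compartment; zeros where absent."""
    n = np.zeros(N_GC_STRATA)
    S = np.zeros(N_GC_STRATA)
    if compartment not in stats.index.get_level_values("compartment"):
        raise ValueError(f"no bins for compartment {compartment!r}")
    sub = stats.loc[compartment]
    for stratum, row in sub.iterrows():
        n[int(stratum) - 1] = row["n_bins"]
        S[int(stratum) - 1] = row["total_count"]
    return n, S


def estimate_Np(n: np.ndarray, S: np.ndarray) -> float:
    """Per-bin, per-haploid-copy intensity from autosomal sufficient stats.

    Half the mean autosomal bin count, so that the count-weighted mean of the
    per-stratum bias factors is exactly 1.
    """
    n = np.asarray(n, dtype=float)
    S = np.asarray(S, dtype=float)
    total_bins = n.sum()
    if total_bins <= 0:
        raise ValueError("no autosomal bins: cannot estimate Np")
    total = S.sum()
    if total <= 0:
        raise ValueError("zero autosomal signal: cannot estimate Np")
    return (total / total_bins) / 2.0


def estimate_beta(n: np.ndarray, S: np.ndarray, Np: float) -> np.ndarray:
    """Per-stratum GC-bias MLE: beta_i = (S_i/n_i) / (2 Np); NaN if stratum empty."""
    if Np <= 0:
        raise ValueError("Np must be positive")
    n = np.asarray(n, dtype=float)
    S = np.asarray(S, dtype=float)
    if not (n > 0).any():
        raise ValueError("all autosomal strata are empty")
    beta = np.full(N_GC_STRATA, np.nan)
    mask = n > 0
    beta[mask] = (S[mask] / n[mask]) / (2.0 * Np)
    return beta


def _garwood_interval(k: float, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (chi-square) confidence interval for a Poisson total ``k``."""
    k = float(k)
    low = 0.0 if k == 0 else 0.5 * sps.chi2.ppf(alpha / 2.0, 2.0 * k)
    high = 0.5 * sps.chi2.ppf(1.0 - alpha / 2.0, 2.0 * k + 2.0)
    return low, high


def estimate_mu(
    n_target: np.ndarray,
    S_target: np.ndarray,
    beta: np.ndarray,
    Np: float,
    compartment: str = MITO,
    alpha: float = 0.05,
) -> CompartmentEstimate:
    """Pooled Poisson MLE of the target copy number with beta, Np plugged in.

    Only strata that actually contain target bins enter the denominator; a
    target stratum with bins but no autosomal bins (hence no defined beta) is
    fatal.  A zero target total yields mu = 0 with a degenerate lower bound.
    """
    n_target = np.asarray(n_target, dtype=float)
    S_target = np.asarray(S_target, dtype=float)
    if Np <= 0:
        raise ValueError("Np must be positive")
    occupied = n_target > 0
    if not occupied.any():
        raise ValueError(f"no bins for compartment {compartment!r}")
    undefined = occupied & ~np.isfinite(beta)
    if undefined.any():
        bad = [int(i) + 1 for i in np.flatnonzero(undefined)]
        raise ValueError(
            f"compartment {compartment!r} has bins in strata {bad} where the "
            "GC bias is undefined (no autosomal bins in those strata)"
        )
    denom = Np * float(np.sum(n_target[occupied] * beta[occupied]))
    total = float(S_target.sum())
    mu = total / denom
    se = mu / np.sqrt(total) if total > 0 else 0.0
    lo_k, hi_k = _garwood_interval(total, alpha)
    return CompartmentEstimate(
        compartment=compartment,
        mu=mu,
        se=se,
        ci_low=lo_k / denom,
        ci_high=hi_k / denom,
        n_bins=int(n_target.sum()),
        total_count=total,
    )


def _autosomal_diagnostics(counts: CountMatrix, beta: np.ndarray, Np: float) -> pd.DataFrame:
    """Per-stratum observed vs expected means and bin-level Pearson dispersion."""
    rows = []
    auto = counts.data[counts.data["compartment"] == AUTOSOME]
    for stratum in range(1, N_GC_STRATA + 1):
        sub = auto[auto["gc_stratum"] == stratum]["count"]
        expected = 2.0 * Np * beta[stratum - 1]
        if len(sub) == 0 or not np.isfinite(expected) or expected <= 0:
            dispersion = np.nan
        else:
            dispersion = float(((sub - expected) ** 2 / expected).mean())
        rows.append(
            {
                "gc_stratum": stratum,
                "n_bins": int(len(sub)),
                "observed_mean": float(sub.mean()) if len(sub) else np.nan,
                "expected_mean": expected,
                "pearson_dispersion": dispersion,
            }
        )
    return pd.DataFrame(rows).set_index("gc_stratum")


class PoissonCopyNumber(BaseEstimator):
    """GC-stratified Poisson copy-number estimator (sklearn-style).

    Parameters
    ----------
    compartments : sequence of str
        Target compartments to estimate among {"mito", "chrX", "chrY"};
        compartments absent from the input are silently skipped unless none
        remain.
    alpha : float
        Two-sided miscoverage for the exact Poisson confidence interval
        (default 0.05, i.e. a 95% interval).

    Attributes (after :meth:`fit`)
    ------------------------------
    Np_ : float
        Per-bin, per-haploid-copy read intensity from autosomal bins.
    beta_ : ndarray of shape (6,)
        GC-bias factors, count-weighted mean exactly 1 over autosomal bins;
        NaN for strata with no autosomal bins.
    estimates_ : dict mapping compartment -> CompartmentEstimate
    mu_mt_, mu_x_, mu_y_ : float or None
    diagnostics_ : DataFrame of per-stratum observed/expected autosomal means
        and Pearson dispersion (≈1 under the Poisson assumption).
    fit_result_ : CopyNumberFit
    """

    def __init__(
        self,
        compartments: Sequence[str] = TARGET_COMPARTMENTS,
        alpha: float = 0.05,
    ) -> None:
        self.compartments = compartments
        self.alpha = alpha

    def fit(self, X: CountMatrix | pd.DataFrame, y=None) -> "PoissonCopyNumber":
        """Fit to one sample's counts.

        ``X`` is a :class:`~mito_copynum.coverage.CountMatrix` or a
        sufficient-statistics frame indexed by (compartment, gc_stratum) with
        columns ``n_bins`` and ``total_count``.
        """
        if isinstance(X, CountMatrix):
            stats, counts = X.stats, X
            sample_id, source = X.sample_id, X.source
        else:
            stats, counts = X, None
            sample_id, source = "sample", "sufficient_stats"
        unknown = set(self.compartments) - set(TARGET_COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown target compartments: {sorted(unknown)}")

        n_auto, S_auto = _stratum_arrays(stats, AUTOSOME)
        Np = estimate_Np(n_auto, S_auto)
        beta = estimate_beta(n_auto, S_auto, Np)

        present = set(stats.index.get_level_values("compartment"))
        estimates: dict[str, CompartmentEstimate] = {}
        strata_used: dict[str, tuple[int, ...]] = {}
        for comp in self.compartments:
            if comp not in present:
                continue
            n_c, S_c = _stratum_arrays(stats, comp)
            if not (n_c > 0).any():
                continue
            estimates[comp] = estimate_mu(n_c, S_c, beta, Np, comp, self.alpha)
            strata_used[comp] = tuple(int(i + 1) for i in np.flatnonzero(n_c > 0))
        if not estimates:
            raise ValueError(
                f"none of the target compartments {tuple(self.compartments)} "
                "have bins in the input"
            )

        if counts is not None:
            diagnostics = _autosomal_diagnostics(counts, beta, Np)
        else:
            diagnostics = pd.DataFrame(
                {
                    "n_bins": n_auto.astype(int),
                    "observed_mean": np.where(n_auto > 0, S_auto / np.where(n_auto > 0, n_auto, 1), np.nan),
                    "expected_mean": 2.0 * Np * beta,
                    "pearson_dispersion": np.nan,
                },
                index=pd.RangeIndex(1, N_GC_STRATA + 1, name="gc_stratum"),
            )

        self.Np_ = Np
        self.beta_ = beta
        self.estimates_ = estimates
        self.diagnostics_ = diagnostics
        self.fit_result_ = CopyNumberFit(
            sample_id=sample_id,
            Np=Np,
            beta=beta,
            estimates=estimates,
            strata_used=strata_used,
            diagnostics=diagnostics,
            source=source,
        )
        return self

    @property
    def mu_mt_(self) -> float | None:
        return self.fit_result_.mu_mt

    @property
    def mu_x_(self) -> float | None:
        return self.fit_result_.mu_x

    @property
    def mu_y_(self) -> float | None:
        return self.fit_result_.mu_y


def fit_sample(
    counts: CountMatrix | pd.DataFrame,
    compartments: Sequence[str] = TARGET_COMPARTMENTS,
    alpha: float = 0.05,
) -> CopyNumberFit:
    """Fit the Poisson model to one sample and return the full fit record."""
    return PoissonCopyNumber(compartments=compartments, alpha=alpha).fit(counts).fit_result_


def ratio_estimator(
    counts: CountMatrix | pd.DataFrame, compartment: str = MITO
) -> RatioEstimate:
    """Uniform-coverage baseline: 2 x (target mean bin count) / (autosomal mean).

    Computed over the same included bins the model uses, so any discrepancy
    with the model estimate reflects GC-stratum composition, not bin choice.
    """
    stats = counts.stats if isinstance(counts, CountMatrix) else counts
    n_auto, S_auto = _stratum_arrays(stats, AUTOSOME)
    n_t, S_t = _stratum_arrays(stats, compartment)
    if n_auto.sum() <= 0 or S_auto.sum() <= 0:
        raise ValueError("zero autosomal signal: cannot form the coverage ratio")
    if n_t.sum() <= 0:
        raise ValueError(f"no bins for compartment {compartment!r}")
    auto_mean = S_auto.sum() / n_auto.sum()
    target_mean = S_t.sum() / n_t.sum()
    return RatioEstimate(compartment=compartment, mu_naive=2.0 * target_mean / auto_mean)
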