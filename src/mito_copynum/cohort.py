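"""Cohort utilities: DNA-source clustering and estimator comparison.

Cohorts whose DNA comes from mixed blood preparations show a bimodal copy
number distribution: platelet-abundant sources (whole blood, buffy coat)
carry extra mtDNA without nuclear DNA and sit roughly twofold above
platelet-depleted sources (leukocytes, PBMCs).  A two-component Gaussian
mixture on the log scale separates the two, with component 1 the lower-mean
("platelet-depleted") cluster by convention.

The comparison utilities quantify agreement between two estimators over the
same samples: per-sample percent change (other - reference) / reference and
concordance as the squared Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

__all__ = [
    "MixtureFit",
    "ComparisonReport",
    "LogNormalMixture2",
    "fit_gmm_2",
    "percent_change",
    "concordance",
]

_VAR_COLLAPSE_FACTOR = 1e-12


@dataclass
class MixtureFit:
    """Two-component univariate Gaussian mixture fit on the log scale.

    Component 1 is always the lower-mean component.  ``posterior_1`` is the
    per-sample posterior probability of component 1; hard assignments are
    argmax posteriors with ties going to cluster 1.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    posterior_1: np.ndarray
    assignments: np.ndarray  # 1 or 2 per sample
    log_likelihood: float
    ll_trajectory: np.ndarray = field(repr=False)
    n_iterations: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if self.converged and not (self.variances > 0).all():
            raise ValueError("variances must be positive")
        if ((self.posterior_1 < 0) | (self.posterior_1 > 1)).any():
            raise ValueError("posteriors must lie in [0, 1]")


def _log_gaussian(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def _em_once(
    x: np.ndarray,
    means0: np.ndarray,
    variances0: np.ndarray,
    weights0: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
):
    """One EM run; returns (ll_trajectory, params) or None on variance collapse."""
    means, variances, weights = means0.copy(), variances0.copy(), weights0.copy()
    trajectory: list[float] = []
    resp = None
    for _ in range(max_iter):
        log_comp = np.stack(
            [
                np.log(weights[k]) + _log_gaussian(x, means[k], variances[k])
                for k in range(2)
            ]
        )
        log_norm = np.logaddexp(log_comp[0], log_comp[1])
        ll = float(log_norm.sum())
        trajectory.append(ll)
        resp = np.exp(log_comp - log_norm)  # responsibilities, shape (2, n)
        nk = resp.sum(axis=1)
        weights = nk / len(x)
        means = (resp @ x) / nk
        variances = np.array(
            [(resp[k] @ (x - means[k]) ** 2) / nk[k] for k in range(2)]
        )
        if (variances < var_floor).any():
            return None
        if len(trajectory) >= 2 and abs(trajectory[-1] - trajectory[-2]) < tol:
            return np.array(trajectory), (weights, means, variances), True
    return np.array(trajectory), (weights, means, variances), False


class LogNormalMixture2(BaseEstimator):
    """Two-component Gaussian mixture on log copy number (sklearn-style).

    EM with multiple initialisations: one quantile-based start (component
    means at the 25th and 75th percentiles) plus ``n_starts - 1`` seeded
    random perturbations of it; the run with the best final log-likelihood
    wins.  Starts whose component variance collapses below
    ``1e-12 x data variance`` are discarded.  If every start fails to
    converge the best run is still reported with ``converged_ = False``.

    Parameters
    ----------
    n_starts : int
        Number of EM initialisations (default 10).
    tol : float
        Absolute log-likelihood change declaring convergence (default 1e-8).
    max_iter : int
        EM iteration cap per start (default 500).
    random_state : int
        Seed for the perturbed initialisations; identical seed and data
        reproduce the fit exactly.

    Attributes (after :meth:`fit`)
    ------------------------------
    weights_, means_, variances_ : ndarrays of shape (2,), ordered so that
        component 1 has the lower mean.
    mixture_fit_ : MixtureFit with posteriors, assignments and the EM
        log-likelihood trajectory (non-decreasing by construction of EM).
    """

    def __init__(
        self,
        n_starts: int = 10,
        tol: float = 1e-8,
        max_iter: int = 500,
        random_state: int = 0,
    ) -> None:
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None) -> "LogNormalMixture2":
        """Fit to positive copy-number estimates (log taken internally).

        ``X`` may be a 1-D array of estimates or an (n, 1) column.
        """
        mu = np.asarray(X, dtype=float).reshape(-1)
        if len(mu) < 4:
            raise ValueError("need at least 4 samples to fit a 2-component mixture")
        if (mu <= 0).any():
            raise ValueError("all copy-number estimates must be positive")
        x = np.log(mu)
        data_var = float(np.var(x))
        # absolute floor at squared rounding scale so exactly-constant data
        # (whose "variance" is pure float noise) still registers as collapse
        rounding = 10.0 * np.finfo(float).eps * (1.0 + abs(float(np.mean(x))))
        var_floor = max(_VAR_COLLAPSE_FACTOR * data_var, rounding**2)
        rng = np.random.default_rng(self.random_state)

        q25, q75 = np.quantile(x, [0.25, 0.75])
        spread = max(np.std(x), 1e-6)
        base_means = np.array([q25, q75], dtype=float)
        base_var = np.array([max(data_var, 1e-12)] * 2)
        base_weights = np.array([0.5, 0.5])

        best = None
        for start in range(self.n_starts):
            if start == 0:
                means0 = base_means.copy()
            else:
                means0 = base_means + rng.normal(scale=0.5 * spread, size=2)
            result = _em_once(
                x, means0, base_var, base_weights, self.tol, self.max_iter, var_floor
            )
            if result is None:
                continue
            trajectory, params, converged = result
            if best is None or trajectory[-1] > best[0][-1]:
                best = (trajectory, params, converged)
        if best is None:
            # every start collapsed (e.g. all-identical data): report a
            # degenerate single-point fit, flagged as unconverged
            warnings.warn(
                "all EM starts collapsed; data may be degenerate (e.g. constant)"
            )
            mean = float(np.mean(x))
            fitres = MixtureFit(
                weights=np.array([0.5, 0.5]),
                means=np.array([mean, mean]),
                variances=np.array([0.0, 0.0]),
                posterior_1=np.full(len(x), 1.0),
                assignments=np.ones(len(x), dtype=int),
                log_likelihood=float("nan"),
                ll_trajectory=np.array([]),
                n_iterations=0,
                converged=False,
            )
        else:
            trajectory, (weights, means, variances), converged = best
            if not converged:
                warnings.warn("EM did not converge in any start; best run reported")
            order = np.argsort(means)
            weights, means, variances = weights[order], means[order], variances[order]
            log_comp = np.stack(
                [
                    np.log(weights[k]) + _log_gaussian(x, means[k], variances[k])
                    for k in range(2)
                ]
            )
            log_norm = np.logaddexp(log_comp[0], log_comp[1])
            posterior_1 = np.exp(log_comp[0] - log_norm)
            assignments = np.where(posterior_1 >= 0.5, 1, 2)
            fitres = MixtureFit(
                weights=weights,
                means=means,
                variances=variances,
                posterior_1=posterior_1,
                assignments=assignments,
                log_likelihood=float(log_norm.sum()),
                ll_trajectory=trajectory,
                n_iterations=len(trajectory),
                converged=bool(converged),
            )
        self.weights_ = fitres.weights
        self.means_ = fitres.means
        self.variances_ = fitres.variances
        self.converged_ = fitres.converged
        self.mixture_fit_ = fitres
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Posterior probabilities, columns ordered (component 1, component 2)."""
        mu = np.asarray(X, dtype=float).reshape(-1)
        if (mu <= 0).any():
            raise ValueError("all copy-number estimates must be positive")
        x = np.log(mu)
        log_comp = np.stack(
            [
                np.log(self.weights_[k]) + _log_gaussian(x, self.means_[k], self.variances_[k])
                for k in range(2)
            ]
        )
        log_norm = np.logaddexp(log_comp[0], log_comp[1])
        p1 = np.exp(log_comp[0] - log_norm)
        return np.column_stack([p1, 1.0 - p1])

    def predict(self, X) -> np.ndarray:
        """Hard cluster labels (1 = lower mean, 2 = higher mean); ties to 1."""
        p1 = self.predict_proba(X)[:, 0]
        return np.where(p1 >= 0.5, 1, 2)


def fit_gmm_2(
    mu: np.ndarray | pd.Series,
    seed: int = 0,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit the two-component log-scale mixture and return the fit record."""
    est = LogNormalMixture2(
        n_starts=n_starts, tol=tol, max_iter=max_iter, random_state=seed
    )
    return est.fit(np.asarray(mu, dtype=float)).mixture_fit_


def percent_change(other: float, reference: float) -> float:
    """Relative change of ``other`` against ``reference``: (other-ref)/ref.

    Returned as a fraction (serialise x100 for percent); the reference must
    be positive.
    """
    if reference <= 0:
        raise ValueError("reference estimate must be positive")
    return (other - reference) / reference


@dataclass
class ComparisonReport:
    """Agreement between two estimators over paired samples."""

    per_sample: pd.DataFrame  # sample_id, a, b, percent_change (fraction)
    mean_percent_change: float
    min_percent_change: float
    max_percent_change: float
    r_squared: float

    def __post_init__(self) -> None:
        if np.isfinite(self.r_squared) and not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 must lie in [0, 1]")


def concordance(
    a: np.ndarray | pd.Series,
    b: np.ndarray | pd.Series,
    sample_ids=None,
) -> ComparisonReport:
    """Concordance between estimator ``a`` and reference estimator ``b``.

    R^2 is the squared Pearson correlation; percent change uses ``a`` as the
    other estimate and ``b`` as the reference.  Zero variance in either
    vector makes R^2 undefined (NaN, with a warning).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("estimate vectors must be 1-D and equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired samples")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(a))]
    if np.var(a) == 0 or np.var(b) == 0:
        warnings.warn("zero variance in an estimate vector; R^2 undefined")
        r2 = float("nan")
    else:
        r2 = float(sps.pearsonr(a, b).statistic ** 2)
    valid = b > 0
    pc = np.full(len(a), np.nan)
    pc[valid] = (a[valid] - b[valid]) / b[valid]
    if (~valid).any():
        warnings.warn(f"{int((~valid).sum())} samples with non-positive reference flagged")
    per_sample = pd.DataFrame(
        {"sample_id": sample_ids, "a": a, "b": b, "percent_change": pc}
    )
    finite = pc[np.isfinite(pc)]
    return ComparisonReport(
        per_sample=per_sample,
        mean_percent_change=float(finite.mean()) if len(finite) else float("nan"),
        min_percent_change=float(finite.min()) if len(finite) else float("nan"),
        max_percent_change=float(finite.max()) if len(finite) else float("nan"),
        r_squared=r2,
    )
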