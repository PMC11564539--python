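"""Poisson copy-number model: MLEs, identities, uncertainty, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from sklearn.base import clone

from mito_copynum import (
    PoissonCopyNumber,
    SimulationConfig,
    estimate_Np,
    estimate_beta,
    estimate_mu,
    fit_sample,
    ratio_estimator,
    simulate_counts,
)
from conftest import BIASED_BETA, poisson_loglik_mu


def stats_frame(entries):
    """Sufficient-statistics frame from {(compartment, stratum): (n, S)}."""
    index = pd.MultiIndex.from_tuples(
        list(entries), names=["compartment", "gc_stratum"]
    )
    return pd.DataFrame(
        {"n_bins": [v[0] for v in entries.values()],
         "total_count": [v[1] for v in entries.values()]},
        index=index, dtype=float,
    )


def test_np_is_half_the_mean_autosomal_count():
    assert estimate_Np(np.array([60, 40]), np.array([1800, 1200])) == 15.0


def test_np_scales_with_counts():
    n, S = np.array([10.0, 20.0]), np.array([300.0, 660.0])
    assert estimate_Np(n, 2 * S) == 2 * estimate_Np(n, S)


def test_np_fatal_without_signal():
    with pytest.raises(ValueError, match="autosomal"):
        estimate_Np(np.array([0.0]), np.array([0.0]))
    with pytest.raises(ValueError, match="signal"):
        estimate_Np(np.array([5.0]), np.array([0.0]))


def test_beta_flat_when_stratum_means_equal():
    n = np.array([10, 20, 30, 0, 0, 0], float)
    S = 30.0 * n
    beta = estimate_beta(n, S, Np=15.0)
    assert np.allclose(beta[:3], 1.0)
    assert np.isnan(beta[3:]).all()


def test_beta_linear_in_stratum_means():
    n = np.full(3, 100.0)
    S = np.array([24.0, 30.0, 36.0]) * n
    beta = estimate_beta(
        np.r_[n, np.zeros(3)], np.r_[S, np.zeros(3)], Np=15.0
    )
    assert np.allclose(beta[:3], [0.8, 1.0, 1.2])


def test_beta_weighted_mean_is_exactly_one(biased_sim):
    matrix, _ = biased_sim
    model = PoissonCopyNumber().fit(matrix)
    stats = matrix.stats.loc["autosome"]
    n = stats["n_bins"].to_numpy()
    beta = model.beta_
    assert np.isclose((n * beta).sum() / n.sum(), 1.0, rtol=0, atol=1e-12)


def test_beta_recovery_within_monte_carlo_error():
    """Per-stratum MLE lands within 3 SE of the simulation truth."""
    config = SimulationConfig(
        seed=99,
        n_auto_bins_per_stratum=(10_000,) * 6,
        true_beta=(0.7, 0.82, 0.94, 1.06, 1.18, 1.3),
    )
    matrix, truth = simulate_counts(config)
    model = PoissonCopyNumber().fit(matrix)
    Np = truth["true_np"]
    for i in range(6):
        true_b = truth["true_beta"][i]
        se = np.sqrt(2 * Np * true_b / 10_000) / (2 * Np)
        assert abs(model.beta_[i] - true_b) < 3 * se, i


def test_mu_hand_example_and_likelihood_oracle():
    """Two-strata arithmetic example; cross-checked by grid maximization."""
    stats = stats_frame(
        {
            ("autosome", 1): (10, 240),
            ("autosome", 2): (10, 360),
            ("mito", 1): (5, 600),
            ("mito", 2): (5, 900),
        }
    )
    fit = fit_sample(stats)
    assert np.isclose(fit.mu_mt, 10.0, rtol=0, atol=1e-12)
    n = np.array([5, 5, 0, 0, 0, 0], float)
    S = np.array([600, 900, 0, 0, 0, 0], float)
    res = minimize_scalar(
        lambda mu: -poisson_loglik_mu(mu, n, S, fit.beta, fit.Np),
        bounds=(1e-6, 1e4), method="bounded",
        options={"xatol": 1e-10},
    )
    assert np.isclose(res.x, fit.mu_mt, rtol=1e-6)


def test_mu_zero_counts_gives_zero_with_degenerate_interval():
    stats = stats_frame({("autosome", 3): (100, 3000), ("chrY", 3): (10, 0)})
    fit = fit_sample(stats, compartments=("chrY",))
    est = fit.estimates["chrY"]
    assert est.mu == 0.0 and est.ci_low == 0.0 and est.ci_high > 0.0


def test_mu_fatal_when_target_stratum_lacks_autosomal_bins():
    stats = stats_frame({("autosome", 1): (100, 3000), ("mito", 2): (5, 600)})
    with pytest.raises(ValueError, match=r"\[2\]"):
        fit_sample(stats)


def test_diploid_equivalent_signal_gives_mu_two():
    stats = stats_frame(
        {("autosome", 2): (50, 1500), ("autosome", 3): (50, 1800),
         ("mito", 2): (5, 150), ("mito", 3): (5, 180)}
    )
    assert np.isclose(fit_sample(stats).mu_mt, 2.0, atol=1e-12)


def test_flat_bias_makes_model_equal_naive_ratio():
    """With flat empirical stratum means the ratio identity is exact."""
    config = SimulationConfig(seed=5, noise=False)
    matrix, _ = simulate_counts(config)
    fit = fit_sample(matrix)
    naive = ratio_estimator(matrix).mu_naive
    assert abs(fit.mu_mt - naive) / naive < 1e-12


def test_mu_invariant_to_np_beta_scale_split():
    """mu depends only on the product Np*beta_i, not on how scale is split."""
    stats = stats_frame(
        {("autosome", 1): (100, 2400), ("autosome", 2): (50, 1800),
         ("mito", 1): (8, 900), ("mito", 2): (4, 700)}
    )
    n_auto = np.array([100, 50, 0, 0, 0, 0], float)
    S_auto = np.array([2400, 1800, 0, 0, 0, 0], float)
    fit = fit_sample(stats)
    # literal "total reads / total bins" convention: Np twice ours
    Np_alt = (S_auto.sum() / n_auto.sum())
    beta_alt = estimate_beta(n_auto, S_auto, Np_alt)
    est_alt = estimate_mu(
        np.array([8, 4, 0, 0, 0, 0], float),
        np.array([900, 700, 0, 0, 0, 0], float),
        beta_alt, Np_alt,
    )
    assert np.isclose(est_alt.mu, fit.mu_mt, rtol=0, atol=1e-12)


def test_mu_scale_invariant_under_depth_rescaling(biased_sim):
    matrix, _ = biased_sim
    mu = fit_sample(matrix).mu_mt
    mu_scaled = fit_sample(matrix.scaled(7.3)).mu_mt
    assert abs(mu_scaled - mu) / mu < 1e-12


def test_read_count_and_depth_modes_agree(biased_sim):
    """Constant-read-length depth is counts x L/100: identical mu exactly."""
    matrix, _ = biased_sim
    depth = matrix.scaled(1.5)  # 150-bp reads over 100-bp bins
    assert np.isclose(fit_sample(depth).mu_mt, fit_sample(matrix).mu_mt, rtol=1e-12)


def test_fit_recovers_truth_for_xx_and_xy_karyotypes():
    for seed, mu_x, mu_y in [(21, 2.0, 0.0), (22, 1.0, 1.0)]:
        config = SimulationConfig(
            seed=seed, true_mu_x=mu_x, true_mu_y=mu_y, true_beta=BIASED_BETA
        )
        matrix, _ = simulate_counts(config)
        fit = fit_sample(matrix)
        est_x, est_y = fit.estimates["chrX"], fit.estimates["chrY"]
        assert abs(est_x.mu - mu_x) <= 3 * max(est_x.se, 1e-9)
        if mu_y == 0:
            assert est_y.mu == 0.0
        else:
            assert abs(est_y.mu - mu_y) <= 3 * est_y.se


def test_fit_recovers_mu_mt_with_gc_bias(biased_sim):
    matrix, truth = biased_sim
    fit = fit_sample(matrix)
    est = fit.estimates["mito"]
    assert abs(est.mu - truth["true_mu_mt"]) <= 3 * est.se
    assert est.ci_low <= est.mu <= est.ci_high


def test_gc_bias_direction_of_naive_estimator():
    """mt bins piled into high-bias strata inflate the naive ratio only."""
    config = SimulationConfig(
        seed=77,
        true_beta=BIASED_BETA,
        n_mt_bins_per_stratum=(0, 0, 0, 0, 60, 100),  # beta > 1 strata
    )
    matrix, truth = simulate_counts(config)
    fit = fit_sample(matrix)
    est = fit.estimates["mito"]
    naive = ratio_estimator(matrix).mu_naive
    beta = np.array(truth["true_beta"])
    n_mt = np.array(config.n_mt_bins_per_stratum)
    predicted_inflation = (n_mt * beta).sum() / n_mt.sum()  # > 1 here
    assert predicted_inflation > 1.05
    assert naive > truth["true_mu_mt"] * (1 + (predicted_inflation - 1) / 2)
    assert abs(est.mu - truth["true_mu_mt"]) <= 3 * est.se


def test_small_instance_oracle_equivalence():
    """Closed-form mu equals brute-force likelihood maximization, 100 draws."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        n_strata = rng.integers(1, 7)
        strata = rng.choice(6, size=n_strata, replace=False) + 1
        n_auto = np.zeros(6)
        S_auto = np.zeros(6)
        n_mt = np.zeros(6)
        S_mt = np.zeros(6)
        for s in strata:
            n_auto[s - 1] = rng.integers(1, 30)
            S_auto[s - 1] = rng.poisson(30 * n_auto[s - 1]) + 1
            n_mt[s - 1] = rng.integers(1, 10)
            S_mt[s - 1] = rng.poisson(40 * n_mt[s - 1]) + 1
        assert n_auto.sum() <= 50 * 6
        Np = estimate_Np(n_auto, S_auto)
        beta = estimate_beta(n_auto, S_auto, Np)
        est = estimate_mu(n_mt, S_mt, beta, Np)
        res = minimize_scalar(
            lambda mu: -poisson_loglik_mu(mu, n_mt, S_mt, beta, Np),
            bounds=(1e-9, 1e5), method="bounded",
            options={"xatol": 1e-12},
        )
        assert abs(res.x - est.mu) / est.mu < 1e-6


def test_sklearn_estimator_api(biased_sim):
    matrix, _ = biased_sim
    model = PoissonCopyNumber(compartments=("mito",), alpha=0.1)
    assert model.get_params() == {"compartments": ("mito",), "alpha": 0.1}
    cloned = clone(model)
    cloned.fit(matrix)
    assert cloned.mu_mt_ > 0
    assert not hasattr(model, "fit_result_")  # clone is independent
    with pytest.raises(ValueError, match="unknown target"):
        PoissonCopyNumber(compartments=("plastid",)).fit(matrix)


def test_ratio_estimator_trivial_means():
    stats = stats_frame({("autosome", 3): (100, 1000), ("mito", 3): (4, 3000)})
    assert ratio_estimator(stats).mu_naive == 150.0
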