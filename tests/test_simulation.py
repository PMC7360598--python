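"""Synthetic-study generator: effect allocation, heritability, link
functions, rank deficiency, type-I/power evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mvgwas import (PhenotypeMatrix, SimulationConfig, evaluate_power,
                    evaluate_type1, genomewide_scaling, make_rank_deficient,
                    qq_data)
from mvgwas.simulation import (draw_effects, simulate_study,
                               run_scenario_suite)
from mvgwas.multivariate_test import MultivariateResult, NullCalibration


def _cfg(**kw):
    base = dict(n_samples=400, n_variants=800, chrom_sizes=(400, 400),
                n_causal=10, T=5, t=5, h2=0.2, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


# ------------------------------------------------------------ draw_effects

def test_effect_allocation_distributed_and_sparse(rng):
    cfg = _cfg(t=5)
    causal_idx = np.arange(400)
    B = draw_effects(cfg, causal_idx, rng, 800)
    nz_rows = np.flatnonzero(np.abs(B).sum(axis=1))
    assert nz_rows.size == 10                      # nc variants, shared
    assert np.all((B[nz_rows] != 0).sum(axis=1) == 5)
    assert np.all((B != 0).sum(axis=0) == 10)      # nc per trait

    cfg_sparse = _cfg(n_causal=100, T=5, t=1, n_variants=2000,
                      chrom_sizes=(1000, 1000))
    B2 = draw_effects(cfg_sparse, np.arange(1000), rng, 2000)
    nz2 = np.flatnonzero(np.abs(B2).sum(axis=1))
    assert nz2.size == 500                         # nc*T/t causal variants
    assert np.all((B2[nz2] != 0).sum(axis=1) == 1)
    assert np.all((B2 != 0).sum(axis=0) == 100)    # exactly nc per trait
    assert nz2.max() < 1000                        # confined to causal chrom


def test_effect_values_uncorrelated_under_identity(rng):
    cfg = _cfg(n_causal=4000, T=2, t=2, n_variants=10000,
               chrom_sizes=(5000, 5000))
    B = draw_effects(cfg, np.arange(5000), rng, 10000)
    nz = np.flatnonzero(np.abs(B).sum(axis=1))
    r = np.corrcoef(B[nz, 0], B[nz, 1])[0, 1]
    assert abs(r) < 3 / np.sqrt(nz.size)


def test_effect_values_cauchy_copula(rng):
    rho = 0.8
    cfg = _cfg(n_causal=5000, T=2, t=2, beta_dist="cauchy",
               beta_corr=np.array([[1, rho], [rho, 1]]),
               n_variants=12000, chrom_sizes=(6000, 6000))
    B = draw_effects(cfg, np.arange(6000), rng, 12000)
    nz = np.flatnonzero(np.abs(B).sum(axis=1))
    vals = B[nz]
    # marginals are standard Cauchy -> rank correlation matches the copula
    ks = stats.kstest(vals[:, 0], stats.cauchy.cdf)
    assert ks.pvalue > 0.001
    rho_rank = stats.spearmanr(vals[:, 0], vals[:, 1]).statistic
    expected = 6 / np.pi * np.arcsin(rho / 2)  # Gaussian-copula Spearman
    assert rho_rank == pytest.approx(expected, abs=0.05)


def test_infeasible_allocation_warns(rng):
    cfg = _cfg(n_causal=3, T=5, t=2)  # nc*T/t = 7.5
    with pytest.warns(UserWarning, match="not integer"):
        B = draw_effects(cfg, np.arange(400), rng, 800)
    assert np.flatnonzero(np.abs(B).sum(axis=1)).size == 8


# ------------------------------------------------------- phenotype builder

def test_heritability_exact_when_no_noise(rng):
    study = simulate_study(_cfg(h2=1.0))
    np.testing.assert_allclose(study.realized_h2, 1.0, atol=1e-12)


def test_realized_heritability_concentrates(rng):
    study = simulate_study(_cfg(n_samples=5000, h2=0.2, seed=9))
    np.testing.assert_allclose(study.realized_h2, 0.2, atol=0.02)


def test_exp_link_creates_then_int_removes_skew(rng):
    study = simulate_study(_cfg(link="exp", seed=4))
    from mvgwas import prepare
    assert np.all(stats.skew(study.Y.values, axis=0) > 1.0)
    post = prepare(study.Y)
    assert np.max(np.abs(stats.skew(post.values, axis=0))) < 0.2


def test_noise_traits_carry_no_signal(rng):
    study = simulate_study(_cfg(n_heritable=2))
    assert np.all(study.B[:, 2:] == 0)
    assert np.all(study.realized_h2[2:] == 0)
    assert np.all(study.realized_h2[:2] > 0.1)


# ---------------------------------------------------------- rank deficiency

@pytest.mark.parametrize("T,expected", [(3, 3), (5, 10), (25, 300)])
def test_pairwise_feature_counts(rng, T, expected):
    Y = PhenotypeMatrix(rng.normal(size=(50, T)))
    out = make_rank_deficient(Y)
    assert out.n_traits == expected


def test_pairwise_features_are_rank_deficient(rng):
    Y = PhenotypeMatrix(rng.normal(size=(200, 5)))
    out = make_rank_deficient(Y)
    C = np.cov(out.values.T)
    assert np.linalg.matrix_rank(C, tol=1e-8) <= 5
    with pytest.raises(ValueError):
        make_rank_deficient(PhenotypeMatrix(rng.normal(size=(10, 2))))


# ------------------------------------------------------------- evaluation

def _fake_result(pvals_most, pvals_minp, chrom):
    m = len(pvals_most)
    table = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(m)], "chrom": chrom,
        "pos": np.arange(1, m + 1) * 1000, "a1": "A", "a2": "G",
        "mostest_stat": 0.0, "mostest_p": pvals_most,
        "mostest_log10p": np.log10(np.maximum(pvals_most, 1e-320)),
        "minp_raw": pvals_minp, "minp_corrected_p": pvals_minp,
        "nan_traits": False})
    cal = NullCalibration(np.eye(1), np.ones(1), np.eye(1), 0, np.eye(1),
                          0.5, 2.0, 1.0, 1, m)
    return MultivariateResult(table=table, calibration=cal)


def test_evaluate_type1_uniform_and_inflated(rng):
    m = 40_000
    chrom = np.r_[np.ones(1000, int), np.full(m - 1000, 2, int)]
    uniform = rng.uniform(size=m)
    res = _fake_result(uniform, uniform, chrom)
    tab = evaluate_type1(res, causal_chrom=1, alphas=(0.05, 1e-3))
    assert len(tab) == 4  # two tests x two alphas
    assert tab["within_ci"].all()
    inflated = uniform ** 3  # grossly anti-conservative
    tab2 = evaluate_type1(_fake_result(inflated, inflated, chrom), 1,
                          alphas=(0.05,))
    assert (~tab2["within_ci"]).all()
    assert (tab2["fraction"] > tab2["ci_hi"]).all()


def test_evaluate_power_trivial_cases(rng):
    m = 100
    chrom = np.r_[np.ones(50, int), np.full(50, 2, int)]
    B = np.zeros((m, 3))
    B[5, 0] = B[10, 1] = 1.0
    p_hit = np.ones(m)
    p_hit[[5, 10]] = 1e-10
    tab = evaluate_power(_fake_result(p_hit, p_hit, chrom), B)
    assert (tab["power_exact"] == 1.0).all()
    p_null = np.ones(m)
    tab0 = evaluate_power(_fake_result(p_null, p_null, chrom), B)
    assert (tab0["power_exact"] == 0.0).all()


def test_genomewide_scaling_arithmetic():
    assert genomewide_scaling(0.004, 7_428_630, 102_079) == \
        pytest.approx(0.291, abs=0.0005)
    assert genomewide_scaling(100, 7_428_630, 102_079) == \
        pytest.approx(7277, abs=1)


def test_qq_data_shape(rng):
    df = qq_data(rng.uniform(size=500))
    assert list(df.columns) == ["expected_log10p", "observed_log10p"]
    assert np.all(np.diff(df["expected_log10p"]) <= 0) or \
        np.all(np.diff(df["expected_log10p"]) >= 0)


# ----------------------------------------------------------------- suite

def test_scenario_suite_deterministic_and_complete():
    cfg = dict(n_samples=300, n_variants=600, chrom_sizes=(300, 300),
               n_causal=5, T=3, t=3, h2=0.3)
    r1 = run_scenario_suite([cfg], n_repeats=2, master_seed=42)
    r2 = run_scenario_suite([cfg], n_repeats=2, master_seed=42)
    pd.testing.assert_frame_equal(r1["metrics"], r2["metrics"])
    metrics = r1["metrics"]
    assert set(metrics["test"]) == {"mostest", "minp"}
    assert any(m.startswith("type1") for m in metrics["metric"])
    assert any(m.startswith("power") for m in metrics["metric"])
    assert "scenario0_null" in r1["qq"] and "scenario0_perm" in r1["qq"]


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(T=3, t=5)
    with pytest.raises(ValueError):
        SimulationConfig(h2=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(link="sqrt")


def test_power_monotone_in_heritability():
    """Omnibus power is non-decreasing across an h2 grid."""
    from mvgwas.simulation import run_study
    powers = []
    for h2 in (0.02, 0.1, 0.4):
        study = simulate_study(_cfg(n_samples=1500, h2=h2, seed=11))
        res = run_study(study)
        tab = evaluate_power(res, study.B, alpha=1e-4)
        powers.append(tab.set_index("test").loc["mostest", "power_exact"])
    assert powers[0] <= powers[1] <= powers[2]
    assert powers[2] > powers[0]
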