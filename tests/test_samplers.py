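import numpy as np
import pytest
from scipy import stats

from sagebias import (
    ChainConfig,
    PosteriorDraws,
    PriorSpec,
    TagLibrary,
    autocorrelation,
    run_dmb,
    run_dpb,
    run_md,
    summarize,
)

RUNNERS = {"dpb": run_dpb, "dmb": run_dmb, "md": run_md}


def _library(t, phi):
    return TagLibrary([f"g{i}" for i in range(len(t))], np.asarray(t), np.asarray(phi))


# -- configuration objects -------------------------------------------------


def test_prior_spec_presets_and_validation():
    assert np.all(PriorSpec(alpha="flat").resolve_alpha(4) == 1.0)
    np.testing.assert_allclose(PriorSpec(alpha="tub").resolve_alpha(4), 0.25)
    with pytest.raises(ValueError):
        PriorSpec(alpha="bogus").resolve_alpha(4)
    with pytest.raises(ValueError):
        PriorSpec(alpha=[1.0, -1.0]).resolve_alpha(2)
    with pytest.raises(ValueError):
        PriorSpec(gamma_shape=0.0)
    with pytest.raises(ValueError):
        PriorSpec(mu=-1.0)


def test_chain_config_validation_and_kept_count():
    assert ChainConfig(20_500, 500, 20).n_kept == 1000
    with pytest.raises(ValueError):
        ChainConfig(100, 100, 1)
    with pytest.raises(ValueError):
        ChainConfig(100, 10, 0)


# -- degenerate and conjugate reductions -----------------------------------


@pytest.mark.parametrize("model", ["dpb", "dmb", "md"])
def test_single_gene_simplex_is_degenerate(model):
    lib = _library([12], [0.6])
    draws = RUNNERS[model](lib, PriorSpec(), ChainConfig(300, 50, 5, seed=1))
    np.testing.assert_allclose(draws.m_draws, 1.0)


@pytest.mark.parametrize("model", ["dpb", "dmb", "md"])
def test_perfect_digestion_conjugate_reduction(model):
    """With phi = 1 every model collapses to the conjugate
    Dirichlet-multinomial: kept draws are i.i.d. Dirichlet(t+1) and the
    posterior mean of m_i approaches (t_i+1)/(t_tot+l)."""
    t = np.array([7, 3, 0, 12])
    lib = _library(t, np.ones(4))
    draws = RUNNERS[model](lib, PriorSpec(), ChainConfig(20_500, 500, 20, seed=3))
    expected = (t + 1) / (t.sum() + 4)
    # Dirichlet marginal sd / sqrt(n_kept), 5 sigma
    tol = 5 * np.sqrt(expected * (1 - expected) / (t.sum() + 4 + 1)) / np.sqrt(1000)
    assert np.all(np.abs(draws.m_draws.mean(axis=0) - expected) < tol)


def test_dmb_fixed_lambda_mode_conjugate():
    t = np.array([4, 6])
    lib = _library(t, np.ones(2))
    draws = run_dmb(
        lib, PriorSpec(lambda_mean=5000.0), ChainConfig(10_500, 500, 10, seed=9)
    )
    expected = (t + 1) / (t.sum() + 2)
    assert np.all(np.abs(draws.m_draws.mean(axis=0) - expected) < 0.02)


def test_md_mu_zero_reduces_to_renormalized_dirichlet():
    t = np.array([3, 1, 6])
    lib = _library(t, np.array([0.9, 0.4, 0.7]))
    draws = run_md(lib, PriorSpec(mu=0.0), ChainConfig(20_500, 500, 20, seed=5))
    assert np.all(draws.latent_draws["r"] == 0)
    expected = (t + 1) / (t.sum() + 3)
    assert np.all(np.abs(draws.m_draws.mean(axis=0) - expected) < 0.02)


def test_md_prior_recovery_with_no_data():
    """With an empty library and mu = 0 the MD posterior is the prior."""
    lib = _library([0, 0, 0], [0.9, 0.5, 0.7])
    alpha = np.array([2.0, 1.0, 1.0])
    draws = run_md(lib, PriorSpec(alpha=alpha, mu=0.0), ChainConfig(20_500, 500, 20, seed=2))
    np.testing.assert_allclose(
        draws.m_draws.mean(axis=0), alpha / alpha.sum(), atol=0.03
    )


# -- structural invariants -------------------------------------------------


def test_kept_draws_sum_to_one_and_dpb_g_respects_counts(toy3_library):
    draws = run_dpb(
        toy3_library, PriorSpec(), ChainConfig(2_500, 500, 4, seed=11), store_latents=True
    )
    np.testing.assert_allclose(draws.m_draws.sum(axis=1), 1.0, atol=1e-9)
    g = draws.latent_draws["g"]
    assert np.all(g >= toy3_library.t)  # binomial support: g_i >= t_i
    assert np.all(draws.latent_draws["N"] >= 1)


def test_md_latents_in_range(toy3_library):
    draws = run_md(toy3_library, PriorSpec(), ChainConfig(2_500, 500, 4, seed=11))
    m0 = draws.latent_draws["m0"]
    assert np.all((m0 > 0) & (m0 < 1))
    assert np.all(draws.latent_draws["r"] >= 0)
    np.testing.assert_allclose(draws.m_draws.sum(axis=1), 1.0, atol=1e-9)


@pytest.mark.parametrize("model", ["dpb", "dmb", "md"])
def test_same_seed_reproduces_chain(model, toy3_library):
    cfg = ChainConfig(600, 100, 5, seed=77)
    a = RUNNERS[model](toy3_library, PriorSpec(), cfg)
    b = RUNNERS[model](toy3_library, PriorSpec(), cfg)
    np.testing.assert_array_equal(a.m_draws, b.m_draws)


def test_tub_prior_clamps_underflow_but_stays_positive():
    """A tub prior over many zero-count genes drives gamma draws below the
    float64 range; they are clamped to the smallest positive normal float
    and counted, and every kept draw remains strictly positive."""
    l = 400
    t = np.zeros(l, dtype=int)
    t[:3] = [50, 30, 20]
    lib = _library(t, np.full(l, 0.8))
    draws = run_dpb(lib, PriorSpec(alpha="tub"), ChainConfig(1_500, 500, 10, seed=13))
    assert draws.n_clamped > 0
    assert np.all(draws.m_draws > 0)


# -- summaries -------------------------------------------------------------


def test_summarize_constant_draws_collapse():
    draws = PosteriorDraws(m_draws=np.tile([0.25, 0.75], (50, 1)), gene_ids=["a", "b"])
    s = summarize(draws)
    assert (s["lower"] == s["median"]).all() and (s["median"] == s["upper"]).all()


def test_summarize_orders_bounds_and_validates_level(toy3_library):
    draws = run_dpb(toy3_library, PriorSpec(), ChainConfig(2_500, 500, 4, seed=19))
    s = summarize(draws)
    assert (s["lower"] <= s["median"]).all() and (s["median"] <= s["upper"]).all()
    with pytest.raises(ValueError):
        summarize(draws, level=1.0)


def test_summarize_interval_matches_beta_marginal():
    """For i.i.d. Dirichlet(t+1) draws the per-gene interval endpoints
    converge to the quantiles of the Beta(t_i+1, t_tot+l-t_i-1) marginal."""
    t = np.array([20, 5, 0])
    rng = np.random.default_rng(4)
    draws = PosteriorDraws(m_draws=rng.dirichlet(t + 1.0, size=20_000))
    s = summarize(draws, level=0.95)
    a = t + 1.0
    b = (t + 1.0).sum() - a
    for i in range(3):
        lo, hi = stats.beta.ppf([0.025, 0.975], a[i], b[i])
        assert s["lower"].iloc[i] == pytest.approx(lo, abs=0.01)
        assert s["upper"].iloc[i] == pytest.approx(hi, abs=0.01)


# -- diagnostics -----------------------------------------------------------


def test_autocorrelation_white_noise_and_lag_zero():
    x = np.random.default_rng(0).standard_normal(10_000)
    rho = autocorrelation(x, [0, 10, 20, 40, 80])
    assert rho[0] == pytest.approx(1.0)
    for lag in (10, 20, 40, 80):
        assert abs(rho[lag]) < 3.0 / np.sqrt(10_000)


def test_autocorrelation_ar1_closed_form():
    rng = np.random.default_rng(1)
    n = 100_000
    x = np.empty(n)
    x[0] = 0.0
    eps = rng.standard_normal(n)
    for i in range(1, n):
        x[i] = 0.9 * x[i - 1] + eps[i]
    rho = autocorrelation(x, [10])
    assert rho[10] == pytest.approx(0.9**10, abs=0.03)


def test_autocorrelation_rejects_constant_or_short_chains():
    with pytest.raises(ValueError):
        autocorrelation(np.ones(100), [10])
    with pytest.raises(ValueError):
        autocorrelation(np.arange(5.0), [10])
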