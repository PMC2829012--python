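import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from sagebias import (
    TagLibrary,
    biased_from_true,
    corrected_mle,
    log_posterior,
    md_marginal_mean,
    md_posterior_mode,
    observed_proportions,
)


def _library(t, phi):
    return TagLibrary([f"g{i}" for i in range(len(t))], np.asarray(t), np.asarray(phi))


# -- library validation ----------------------------------------------------


def test_library_rejects_duplicates_negative_counts_and_bad_phi():
    with pytest.raises(ValueError, match="duplicate"):
        TagLibrary(["a", "a"], np.array([1, 2]), np.array([0.5, 0.5]))
    with pytest.raises(ValueError):
        _library([-1, 2], [0.5, 0.5])
    with pytest.raises(ValueError):
        _library([1, 2], [0.0, 0.5])
    with pytest.raises(ValueError):
        _library([1, 2], [1.5, 0.5])


def test_observed_proportions():
    lib = _library([1, 1, 2], [1.0, 1.0, 1.0])
    np.testing.assert_allclose(observed_proportions(lib), [0.25, 0.25, 0.5])
    assert observed_proportions(lib).sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        observed_proportions(_library([0, 0], [0.5, 0.5]))


# -- bias map and corrected MLE -------------------------------------------


def test_bias_map_cancels_for_uniform_phi():
    m = np.array([0.2, 0.3, 0.5])
    np.testing.assert_allclose(biased_from_true(m, np.full(3, 0.7)), m)


def test_bias_map_worked_example():
    theta = biased_from_true(np.array([1 / 3, 2 / 3]), np.array([1.0, 0.5]))
    np.testing.assert_allclose(theta, [0.5, 0.5])
    assert theta.sum() == pytest.approx(1.0)


def test_corrected_mle_uniform_phi_recovers_naive():
    lib = _library([3, 7, 10], [0.8, 0.8, 0.8])
    np.testing.assert_allclose(corrected_mle(lib), lib.t / lib.t_tot)


def test_corrected_mle_worked_example():
    np.testing.assert_allclose(
        corrected_mle(_library([10, 10], [1.0, 0.5])), [1 / 3, 2 / 3]
    )


@given(
    t=st.lists(st.integers(0, 200), min_size=2, max_size=6).filter(lambda v: sum(v) > 0),
    phis=st.lists(st.floats(0.05, 1.0), min_size=6, max_size=6),
    c=st.floats(0.1, 1.0),
)
def test_corrected_mle_estimating_equation_and_scale_invariance(t, phis, c):
    """The corrected MLE pushed through the bias map reproduces the observed
    proportions exactly, and rescaling every phi by a common factor leaves
    the estimate unchanged."""
    phi = np.array(phis[: len(t)])
    lib = _library(t, phi)
    mhat = corrected_mle(lib)
    np.testing.assert_allclose(
        biased_from_true(mhat, phi), observed_proportions(lib), atol=1e-12
    )
    scaled = corrected_mle(_library(t, c * phi))
    np.testing.assert_allclose(scaled, mhat, atol=1e-12)


# -- log posterior ---------------------------------------------------------


def test_log_posterior_flat_prior_maximized_at_corrected_mle():
    """Grid search over the 2-gene simplex: with alpha = 1 the posterior
    mode coincides with the corrected MLE."""
    lib = _library([10, 10], [1.0, 0.5])
    grid = np.linspace(1e-4, 1 - 1e-4, 4001)
    vals = np.array(
        [log_posterior(np.array([x, 1 - x]), lib, np.ones(2)) for x in grid]
    )
    x_best = grid[np.argmax(vals)]
    assert x_best == pytest.approx(corrected_mle(lib)[0], abs=2.5e-4)


def test_log_posterior_decomposes_into_likelihood_plus_prior():
    lib = _library([5, 2, 1], [0.9, 0.5, 0.7])
    m = np.array([0.5, 0.3, 0.2])
    alpha = np.array([1.0, 2.0, 0.5])
    theta = biased_from_true(m, lib.phi)
    loglik = np.sum(lib.t * np.log(theta))
    logprior = np.sum((alpha - 1.0) * np.log(m))
    assert log_posterior(m, lib, alpha) == pytest.approx(loglik + logprior, abs=1e-10)


def test_log_posterior_ordering_matches_direct_product():
    """Unnormalized density ordering agrees with a brute-force product of
    the biased multinomial likelihood and the Dirichlet prior."""
    lib = _library([5, 2, 0], [0.9, 0.5, 0.7])
    alpha = np.full(3, 1.0)
    pts = [np.array([0.5, 0.3, 0.2]), np.array([0.2, 0.5, 0.3])]
    direct = []
    for m in pts:
        theta = biased_from_true(m, lib.phi)
        direct.append(stats.multinomial.pmf(lib.t, lib.t_tot, theta))
    ours = [log_posterior(m, lib, alpha) for m in pts]
    assert (direct[0] > direct[1]) == (ours[0] > ours[1])


def test_log_posterior_boundary_infinities():
    lib = _library([5, 0], [0.9, 0.5])
    # zero coordinate with positive exponent (t_i + alpha_i - 1 > 0): vanishes
    assert log_posterior(np.array([0.0, 1.0]), lib, np.ones(2)) == -np.inf
    # zero exponent (t_i = 0, alpha_i = 1): the boundary point has finite density
    assert np.isfinite(log_posterior(np.array([1.0, 0.0]), lib, np.ones(2)))
    # sub-unit prior weight on a zero-count gene: density diverges at the edge
    assert log_posterior(np.array([1.0, 0.0]), lib, np.array([1.0, 0.5])) == np.inf


# -- MD closed forms -------------------------------------------------------


def test_md_mode_flat_prior_reduction():
    t = np.array([4, 6, 0])
    np.testing.assert_allclose(
        md_posterior_mode(t, np.ones(3), r=5), t / (t.sum() + 5)
    )


def test_md_mode_worked_example():
    np.testing.assert_allclose(
        md_posterior_mode(np.array([3, 1]), np.ones(2), r=4), [3 / 8, 1 / 8]
    )


def test_md_mode_tub_prior_with_zero_count_leaves_parameter_space():
    with pytest.raises(ValueError, match="outside of the parameter space"):
        md_posterior_mode(np.array([3, 0]), np.full(2, 0.5), r=1)


def test_md_marginal_mean_mu_zero():
    t = np.array([3, 1])
    np.testing.assert_allclose(
        md_marginal_mean(t, np.ones(2), mu=0.0), (t + 1) / (t.sum() + 2 + 1)
    )


def test_md_marginal_mean_matches_bruteforce_poisson_sum():
    """Independent oracle: truncate the Poisson mixture at cumulative mass
    1 - 1e-12 and average the conditional Dirichlet means directly."""
    t = np.array([3.0, 1.0])
    alpha = np.ones(2)
    mu = 2.0
    total = (t + alpha).sum()
    acc = np.zeros(2)
    mass = 0.0
    r = 0
    while mass < 1.0 - 1e-12:
        w = stats.poisson.pmf(r, mu)
        acc += w * (t + alpha) / (total + r + 1.0)
        mass += w
        r += 1
    np.testing.assert_allclose(md_marginal_mean(t, alpha, mu), acc, rtol=1e-10)


@pytest.mark.parametrize("i", [0, 1])
def test_md_marginal_mean_decreasing_in_mu(i):
    t = np.array([5, 2])
    vals = [md_marginal_mean(t, np.ones(2), mu)[i] for mu in (0.0, 0.5, 2.0, 10.0)]
    assert np.all(np.diff(vals) < 0)
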