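"""Model-core tests: densities, Gibbs/Metropolis updates, sampler mechanics."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

from svcindex.model import (
    MCMCConfig,
    ModelState,
    PriorSpec,
    mvcar_logpdf_kernel,
    ndi_value,
    poisson_loglik,
    run_mcmc,
    update_alpha,
    update_beta,
    update_omega,
    update_weights,
)
from svcindex.synthetic import LatticeSpec, make_lattice


def path_graph(n):
    return sp.csr_array(
        sp.diags([np.ones(n - 1), np.ones(n - 1)], [1, -1], format="csr").astype(
            np.int8
        )
    )


# --- index values ----------------------------------------------------------


def test_ndi_constant_row_equals_value():
    w = np.full(9, 1.0 / 9)
    q = np.full((3, 9), 5)
    np.testing.assert_allclose(ndi_value(w, q), [5.0, 5.0, 5.0])


def test_ndi_rejects_boundary_weights():
    w = np.zeros(5)
    w[0] = 1.0
    with pytest.raises(ValueError, match="open interval"):
        ndi_value(w, np.full((2, 5), 3))


def test_ndi_two_variable_average():
    eps = 1e-9
    w = np.array([0.5 - eps, 0.5 - eps, eps, eps])
    w = w / w.sum()
    q = np.array([[2, 8, 5, 5]])
    assert ndi_value(w, q)[0] == pytest.approx(5.0, abs=1e-6)


def test_ndi_bounds():
    rng = np.random.default_rng(0)
    w = rng.dirichlet(np.ones(9))
    q = rng.integers(1, 11, size=(50, 9))
    v = ndi_value(w, q)
    assert v.min() >= 1.0 and v.max() <= 10.0


# --- likelihood ------------------------------------------------------------


def test_poisson_loglik_unit_mean_cases():
    one = np.ones((1, 1))
    # P(0 | mean 1) = e^-1 and P(1 | mean 1) = e^-1
    assert poisson_loglik(np.zeros((1, 1)), one, [0.0], np.zeros((1, 1)), [1.0]) == (
        pytest.approx(-1.0)
    )
    assert poisson_loglik(one, one, [0.0], np.zeros((1, 1)), [1.0]) == (
        pytest.approx(-1.0)
    )


def test_poisson_loglik_matches_scipy_pmf():
    rng = np.random.default_rng(1)
    n, K = 7, 2
    y = rng.poisson(3.0, size=(n, K))
    E = rng.uniform(0.5, 4.0, size=(n, K))
    alpha = rng.normal(size=K)
    beta = 0.1 * rng.normal(size=(n, K))
    ndi = rng.uniform(1, 10, size=n)
    mu = E * np.exp(alpha + beta * ndi[:, None])
    expected = stats.poisson.logpmf(y, mu).sum()
    assert poisson_loglik(y, E, alpha, beta, ndi) == pytest.approx(expected, rel=1e-12)


def test_poisson_loglik_requires_positive_expected():
    with pytest.raises(ValueError, match="positive"):
        poisson_loglik(
            np.ones((1, 1)), np.zeros((1, 1)), [0.0], np.zeros((1, 1)), [1.0]
        )


# --- MVCAR kernel ----------------------------------------------------------


def test_mvcar_kernel_constant_field_has_zero_quadratic():
    adj = make_lattice(LatticeSpec(3, 3))
    omega = np.array([[2.0]])
    beta = np.full((9, 1), 3.7)
    n = 9
    expected = 0.5 * (n - 1) * np.log(2.0)
    assert mvcar_logpdf_kernel(beta, omega, adj) == pytest.approx(expected)


def test_mvcar_kernel_shift_invariant():
    adj = make_lattice(LatticeSpec(4, 3))
    rng = np.random.default_rng(2)
    beta = rng.normal(size=(12, 2))
    omega = np.array([[2.0, 0.5], [0.5, 1.0]])
    base = mvcar_logpdf_kernel(beta, omega, adj)
    shifted = mvcar_logpdf_kernel(beta + np.array([5.0, -3.0]), omega, adj)
    assert shifted == pytest.approx(base, rel=1e-12)


def test_mvcar_kernel_path_hand_value():
    # 3-unit path, K=1, omega=2, beta=(0,1,3):
    # quadratic term = -1/2 * 2 * ((0-1)^2 + (1-3)^2) = -5
    adj = path_graph(3)
    beta = np.array([[0.0], [1.0], [3.0]])
    omega = np.array([[2.0]])
    val = mvcar_logpdf_kernel(beta, omega, adj)
    assert val - 0.5 * 2 * np.log(2.0) == pytest.approx(-5.0)


def test_mvcar_kernel_rejects_indefinite_omega():
    adj = path_graph(3)
    with pytest.raises(ValueError, match="positive definite"):
        mvcar_logpdf_kernel(np.zeros((3, 1)), np.array([[-1.0]]), adj)


# --- intercept update ------------------------------------------------------


def test_update_alpha_gamma_law():
    """With beta = 0, y totals 100 and sum(E) = 100, exp(alpha) is a
    Gamma(100, 100) draw: mean 1, sd 0.1."""
    rng = np.random.default_rng(3)
    y = np.full((10, 1), 10.0)
    E = np.full((10, 1), 10.0)
    beta = np.zeros((10, 1))
    ndi = np.full(10, 5.0)
    draws = np.array([update_alpha(y, E, beta, ndi, rng)[0] for _ in range(20_000)])
    t = np.exp(draws)
    assert t.mean() == pytest.approx(1.0, abs=4 * 0.1 / np.sqrt(20_000))
    assert t.std() == pytest.approx(0.1, rel=0.05)


def test_update_alpha_scale_equivariance():
    y = np.full((5, 1), 4.0)
    E = np.full((5, 1), 2.0)
    beta = np.zeros((5, 1))
    ndi = np.ones(5)
    a1 = update_alpha(y, E, beta, ndi, np.random.default_rng(4))
    a2 = update_alpha(y, 2 * E, beta, ndi, np.random.default_rng(4))
    assert a2[0] == pytest.approx(a1[0] - np.log(2.0), rel=1e-12)


def test_update_alpha_matches_metropolis_oracle():
    """Long-run mean of the Gibbs draw agrees with a random-walk Metropolis
    chain targeting the same full conditional."""
    rng = np.random.default_rng(5)
    y = np.array([[3.0], [7.0], [2.0]])
    E = np.array([[1.0], [2.0], [0.5]])
    beta = np.array([[0.1], [-0.2], [0.3]])
    ndi = np.array([2.0, 5.0, 8.0])
    rates = (E * np.exp(beta * ndi[:, None])).sum()
    total = y.sum()

    def logpost(a):  # flat prior on alpha
        return total * a - rates * np.exp(a)

    chain = np.empty(200_000)
    a = 0.0
    lp = logpost(a)
    for i in range(len(chain)):
        prop = a + 0.4 * rng.standard_normal()
        lp_prop = logpost(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            a, lp = prop, lp_prop
        chain[i] = a
    mh_mean = chain[2000:].mean()
    gibbs = np.array(
        [update_alpha(y, E, beta, ndi, rng)[0] for _ in range(20_000)]
    ).mean()
    assert gibbs == pytest.approx(mh_mean, abs=0.02)


def test_update_alpha_rejects_zero_total():
    with pytest.raises(ValueError, match="zero total"):
        update_alpha(
            np.zeros((3, 1)), np.ones((3, 1)), np.zeros((3, 1)),
            np.ones(3), np.random.default_rng(0),
        )


# --- precision update ------------------------------------------------------


def test_update_omega_flat_field_matches_wishart_mean():
    """beta = 0 collapses the posterior to the Wishart prior with inflated
    degrees of freedom: mean (nu + n - 1) R^{-1}."""
    adj = make_lattice(LatticeSpec(4, 4))
    prior = PriorSpec.default(K=2, C=3)
    rng = np.random.default_rng(6)
    beta = np.zeros((16, 2))
    draws = np.stack([update_omega(beta, adj, prior, rng) for _ in range(20_000)])
    expect = (prior.wishart_df + 15) * np.linalg.inv(prior.wishart_scale)
    np.testing.assert_allclose(draws.mean(axis=0), expect, rtol=0.02, atol=0.5)
    for d in draws[:100]:
        np.linalg.cholesky(d)  # always positive definite


def test_update_omega_matches_metropolis_oracle():
    """K=1 on a 4-unit lattice with a fixed field: the conjugate draw's law
    agrees with a Metropolis sampler targeting prior x MVCAR kernel."""
    adj = path_graph(4)
    prior = PriorSpec(
        wishart_scale=np.array([[0.5]]), wishart_df=1.0, dirichlet_alpha=np.ones(2)
    )
    beta = np.array([[0.1], [-0.2], [0.3], [0.0]])
    S = float(
        sum((beta[a, 0] - beta[b, 0]) ** 2 for a, b in [(0, 1), (1, 2), (2, 3)])
    )
    rng = np.random.default_rng(7)
    conj = np.array(
        [update_omega(beta, adj, prior, rng)[0, 0] for _ in range(20_000)]
    )

    def logtarget(om):  # (nu-K-1)/2 log|O| + (n-1)/2 log|O| - tr((R+S)O)/2
        return 0.5 * (1 - 1 - 1 + 3) * np.log(om) - 0.5 * (0.5 + S) * om

    chain = np.empty(200_000)
    om, lp = 1.0, logtarget(1.0)
    for i in range(len(chain)):
        prop = om * np.exp(0.5 * rng.standard_normal())  # log-scale walk
        lp_prop = logtarget(prop) + np.log(prop)  # Jacobian of log transform
        cur = lp + np.log(om)
        if np.log(rng.uniform()) < lp_prop - cur:
            om, lp = prop, logtarget(prop)
        chain[i] = om
    assert conj.mean() == pytest.approx(chain[5000:].mean(), rel=0.03)


# --- weight update ---------------------------------------------------------


def test_update_weights_prior_only_matches_dirichlet_moments():
    """With the likelihood disabled the weight chain targets Dirichlet(a)."""
    alpha_dir = np.array([2.0, 1.0, 0.5])
    prior = PriorSpec(
        wishart_scale=np.eye(1), wishart_df=1.0, dirichlet_alpha=alpha_dir
    )
    state = ModelState(
        alpha=np.zeros(1),
        beta=np.zeros((5, 1)),
        omega=np.eye(1),
        weights=np.full(3, 1.0 / 3),
    )
    y = np.ones((5, 1))
    E = np.ones((5, 1))
    q = np.ones((5, 3))
    rng = np.random.default_rng(8)
    draws = np.empty((60_000, 3))
    for i in range(len(draws)):
        w, _ = update_weights(
            state, y, E, q, prior, rng, 1.2, use_likelihood=False
        )
        state.weights = w
        draws[i] = w
    a0 = alpha_dir.sum()
    mean = alpha_dir / a0
    var = alpha_dir * (a0 - alpha_dir) / (a0**2 * (a0 + 1))
    np.testing.assert_allclose(draws[2000:].mean(axis=0), mean, atol=0.015)
    np.testing.assert_allclose(draws[2000:].var(axis=0), var, rtol=0.12)
    np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)


# --- coefficient field update ----------------------------------------------


def test_update_beta_zero_scale_keeps_state():
    adj = make_lattice(LatticeSpec(3, 3))
    rng = np.random.default_rng(9)
    state = ModelState(
        alpha=np.zeros(2),
        beta=rng.normal(size=(9, 2)),
        omega=np.eye(2),
        weights=np.full(4, 0.25),
    )
    y = np.ones((9, 2))
    E = np.ones((9, 2))
    ndi = np.full(9, 5.0)
    new, n_acc = update_beta(state, y, E, ndi, adj, rng, proposal_scale=0.0)
    np.testing.assert_array_equal(new, state.beta)


# --- the sampler -----------------------------------------------------------


def _quick_fit(seed=0, **kw):
    import svcindex as s
    from svcindex.prep import compute_expected_counts

    ds, design, _ = s.simulate_dataset(
        s.SimulationConfig(lattice=LatticeSpec(4, 4), seed=17)
    )
    expected = compute_expected_counts(ds.counts, ds.populations)
    kw.setdefault("burn_in", 200)
    kw.setdefault("retained", 100)
    kw.setdefault("n_chains", 2)
    return run_mcmc(ds, design, expected, config=MCMCConfig(seed=seed, **kw))


def test_run_mcmc_deterministic_under_seed():
    s1 = _quick_fit(seed=21)
    s2 = _quick_fit(seed=21)
    np.testing.assert_array_equal(s1.beta, s2.beta)
    np.testing.assert_array_equal(s1.weights, s2.weights)
    np.testing.assert_array_equal(s1.omega, s2.omega)


def test_run_mcmc_thinning_bookkeeping():
    samples = _quick_fit(seed=22, burn_in=50, retained=10, thin=2)
    assert samples.n_draws == 10
    assert samples.alpha.shape == (2, 10, 3)


def test_run_mcmc_stored_state_invariants():
    samples = _quick_fit(seed=23)
    w = samples.pooled("weights")
    np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)
    assert np.all((w > 0) & (w < 1))
    for om in samples.pooled("omega")[::25]:
        np.linalg.cholesky(om)
    assert np.isfinite(samples.pooled("beta")).all()


def test_theta_draws_recompute_exactly():
    samples = _quick_fit(seed=24)
    theta = samples.theta_draws()
    ndi = samples.ndi_draws()
    a = samples.pooled("alpha")
    b = samples.pooled("beta")
    recomputed = np.exp(a[:, None, :] + b * ndi[:, :, None])
    np.testing.assert_array_equal(theta, recomputed)


def test_posterior_concentrates_with_count_scale():
    """Scaling counts upward tightens the weight posterior (total credible
    width shrinks along a 3-point ladder).  Concentration saturates rather
    than vanishing: the likelihood is invariant under rescaling (w, beta)
    jointly, so in the large-count limit the weights stay identified only
    through the CAR smoothness prior on the rescaled coefficient field."""
    import svcindex as s
    from svcindex.prep import compute_expected_counts

    spreads = []
    for rate in (5e-4, 5e-3, 5e-2):
        ds, design, _ = s.simulate_dataset(
            s.SimulationConfig(
                lattice=LatticeSpec(6, 6), K=2, C=3,
                true_weights=(0.5, 0.3, 0.2),
                true_omega=s.synthetic.default_true_omega(2),
                mean_slope=(0.15, 0.15),
                base_rates=(rate, rate),
                seed=31,
            )
        )
        expected = compute_expected_counts(ds.counts, ds.populations)
        samples = run_mcmc(
            ds, design, expected,
            config=MCMCConfig(burn_in=1500, retained=1500, n_chains=2, seed=31),
        )
        w = samples.pooled("weights")
        width = np.quantile(w, 0.975, axis=0) - np.quantile(w, 0.025, axis=0)
        spreads.append(width.sum())
    assert spreads[0] > spreads[1] > spreads[2]


def test_flat_field_limit_with_large_precision():
    """As the generating precision grows, the posterior coefficient fields
    flatten: the per-column spread of posterior medians shrinks monotonically."""
    import svcindex as s
    from svcindex.prep import compute_expected_counts

    spreads = []
    for scale in (1.0, 10.0, 100.0):
        ds, design, _ = s.simulate_dataset(
            s.SimulationConfig(
                lattice=LatticeSpec(6, 6), K=2, C=3,
                true_weights=(0.5, 0.3, 0.2),
                true_omega=scale * s.synthetic.default_true_omega(2),
                mean_slope=(0.15, 0.15),
                base_rates=(0.005, 0.005),
                seed=32,
            )
        )
        expected = compute_expected_counts(ds.counts, ds.populations)
        samples = run_mcmc(
            ds, design, expected,
            config=MCMCConfig(burn_in=800, retained=800, n_chains=1, seed=32),
        )
        med = np.median(samples.pooled("beta"), axis=0)  # (n, K)
        spreads.append(med.std(axis=0).mean())
    assert spreads[0] > spreads[1] > spreads[2]


def test_config_validation():
    with pytest.raises(ValueError, match="mode"):
        MCMCConfig(mode="wild").validate()
    with pytest.raises(ValueError, match="retained"):
        MCMCConfig(retained=0).validate()
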