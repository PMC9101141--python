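"""Shared fixtures: the expensive MCMC runs are session-scoped so the
recovery fit and the tiny-instance oracle comparison are computed once."""

import numpy as np
import pytest
import scipy.sparse as sp

import svcindex as s
from svcindex.model import MCMCConfig, PriorSpec, run_mcmc
from svcindex.prep import (
    ArealDataset,
    DecileDesign,
    ExpectedCounts,
    compute_expected_counts,
)


@pytest.fixture(scope="session")
def recovery_run():
    """Parameter-recovery fit at the reference study conditions:
    20 x 20 rook lattice, K=3 outcomes, C=9 covariates, the estimated-weight
    profile as truth, two chains of 5,000 burn-in + 5,000 retained."""
    report, samples, truth = s.recovery_experiment(
        sim_config=s.SimulationConfig(seed=1),
        mcmc_config=MCMCConfig.test_scale(seed=1),
    )
    return report, samples, truth


def make_tiny_path_instance():
    """A 4-unit path-graph instance (K=1, C=2) small enough for dense
    numerical integration: fixed precision omega=25 so the coefficient field
    is strongly regularized, expected counts of 60, Poisson data generated
    once from a fixed seed."""
    rng = np.random.default_rng(123)
    q = np.array([[1, 3], [4, 4], [7, 6], [10, 8]], dtype=float)
    E = np.full(4, 60.0)
    beta_true = np.array([0.12, 0.15, 0.10, 0.17])
    ndi_true = 0.6 * q[:, 0] + 0.4 * q[:, 1]
    mu = E * np.exp(-0.5 + beta_true * ndi_true)
    y = rng.poisson(mu)
    omega = 25.0

    adj = sp.csr_array(
        sp.diags([np.ones(3), np.ones(3)], [1, -1], format="csr").astype(np.int8)
    )
    dataset = ArealDataset(
        unit_ids=np.array(list("abcd")),
        populations=np.full(4, 100),
        counts=y[:, None],
        covariates=np.zeros((4, 2)),
        adjacency=adj,
        orientation=["direct", "direct"],
    )
    design = DecileDesign(
        deciles=q.astype(int),
        cutpoints=np.zeros((2, 9)),
        orientation=["direct", "direct"],
    )
    expected = ExpectedCounts(rates=np.array([0.2]), expected=E[:, None])
    # wishart_df * inv(wishart_scale) = omega, so the (unsampled) precision
    # stays fixed at 25 throughout the run
    prior = PriorSpec(
        wishart_scale=np.array([[1.0 / omega]]),
        wishart_df=1.0,
        dirichlet_alpha=np.ones(2),
    )
    return {
        "dataset": dataset,
        "design": design,
        "expected": expected,
        "prior": prior,
        "q": q,
        "E": E,
        "y": y.astype(float),
        "omega": omega,
    }


@pytest.fixture(scope="session")
def tiny_path_instance():
    return make_tiny_path_instance()


@pytest.fixture(scope="session")
def tiny_instance_fit(tiny_path_instance):
    """Long two-chain fit of the tiny instance (the quadrature benchmark)."""
    inst = tiny_path_instance
    samples = run_mcmc(
        inst["dataset"],
        inst["design"],
        inst["expected"],
        inst["prior"],
        MCMCConfig(
            burn_in=5_000,
            retained=40_000,
            n_chains=2,
            seed=12,
            sample_omega=False,
        ),
    )
    return samples


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 4 x 4 lattice dataset for prior-only sampler runs."""
    ds, design, truth = s.simulate_dataset(
        s.SimulationConfig(lattice=s.LatticeSpec(4, 4), seed=0)
    )
    expected = compute_expected_counts(ds.counts, ds.populations)
    return ds, design, expected, truth


@pytest.fixture(scope="session")
def prior_weight_samples(small_dataset):
    """Prior-only run: likelihood disabled, only the weight block sampled,
    so the retained weight draws target Dirichlet(1, ..., 1) with C=9."""
    ds, design, expected, _ = small_dataset
    return run_mcmc(
        ds,
        design,
        expected,
        config=MCMCConfig(
            burn_in=2_000,
            retained=20_000,
            n_chains=2,
            seed=3,
            use_likelihood=False,
            sample_beta=False,
            sample_omega=False,
        ),
    )
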