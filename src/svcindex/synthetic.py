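"""Synthetic areal datasets with known ground truth.

Generates data with exactly the structure the spatially varying coefficient
index model assumes: a connected planar lattice of areal units, correlated
right-skewed sociodemographic covariates (one inverse-oriented, playing the
role of per capita income), Dirichlet index weights, an intrinsic
multivariate CAR (MVCAR) field of unit-by-outcome coefficients coupled
across outcomes by a K x K precision, and Poisson counts around
population-proportional expected values.  Every downstream stage can
therefore be tested against a recorded truth without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

from . import gal
from .graphs import validate_adjacency
from .prep import ArealDataset, DecileDesign, build_decile_design

__all__ = [
    "LatticeSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "make_lattice",
    "simulate_covariates",
    "simulate_mvcar_field",
    "simulate_counts",
    "simulate_dataset",
    "write_bundle",
    "default_true_omega",
    "DEFAULT_TRUE_WEIGHTS",
]

# Estimated importance profile of the nine deprivation-index components
# (percent renters down to income), reused as a realistic generating truth.
DEFAULT_TRUE_WEIGHTS = (0.26, 0.18, 0.16, 0.14, 0.12, 0.04, 0.04, 0.03, 0.03)


def default_true_omega(
    K: int = 3, sd: float = 0.3, rho12: float = 0.9, rho13: float = 0.0
) -> np.ndarray:
    """Default MVCAR precision: inverse of a covariance with strong correlation
    between outcomes 1-2 and none between 1-3 (and 2-3).

    The implied conditional correlations of the coefficient fields are exactly
    the correlations of Sigma = Omega^{-1} supplied here.  The conditional sd
    of 0.3 per neighbor difference yields a marginal field spread of roughly
    0.25-0.3 on a 20 x 20 lattice, i.e. unit-level relative risks exp(beta)
    ranging up to about 2 around the mean slope -- the operating point where
    spatially varying index effects are scientifically interesting.
    """
    corr = np.eye(K)
    if K >= 2:
        corr[0, 1] = corr[1, 0] = rho12
    if K >= 3:
        corr[0, 2] = corr[2, 0] = rho13
    sigma = (sd**2) * corr
    return np.linalg.inv(sigma)


@dataclass(frozen=True)
class LatticeSpec:
    """Regular grid of areal units with rook or queen contiguity."""

    nrows: int
    ncols: int
    connectivity: str = "rook"

    def __post_init__(self):
        if self.nrows < 2 or self.ncols < 2:
            raise ValueError("lattice needs nrows, ncols >= 2")
        if self.connectivity not in ("rook", "queen"):
            raise ValueError("connectivity must be 'rook' or 'queen'")

    @property
    def n(self) -> int:
        return self.nrows * self.ncols


@dataclass
class SimulationConfig:
    """Full generative recipe for one synthetic dataset.

    Defaults describe the reference operating point used throughout the test
    suite: a 20 x 20 rook lattice, K=3 outcome types, C=9 covariates, the
    estimated-weight profile as truth, a mean index effect of 0.15 per decile
    unit on the log relative risk, and per-capita base rates giving on the
    order of ten events per unit.
    """

    lattice: LatticeSpec = field(default_factory=lambda: LatticeSpec(20, 20))
    K: int = 3
    C: int = 9
    true_weights: tuple | str = DEFAULT_TRUE_WEIGHTS
    dirichlet_alpha: tuple | None = None  # used when true_weights == "draw"
    true_omega: np.ndarray | None = None  # default: default_true_omega(K)
    intercepts: tuple | None = None  # alpha_k; default zeros
    mean_slope: tuple | None = None  # b_k; default 0.15 each
    population_range: tuple[int, int] = (500, 3000)
    covariate_correlation: float = 0.5
    base_rates: tuple | None = None  # r_k; default 0.0015 each
    seed: int = 0

    def resolved(self) -> "SimulationConfig":
        """Fill derived defaults and validate invariants."""
        cfg = SimulationConfig(**self.__dict__)
        if cfg.true_omega is None:
            cfg.true_omega = default_true_omega(cfg.K)
        cfg.true_omega = np.asarray(cfg.true_omega, dtype=float)
        _check_spd(cfg.true_omega, "true_omega")
        if cfg.intercepts is None:
            cfg.intercepts = (0.0,) * cfg.K
        if cfg.mean_slope is None:
            cfg.mean_slope = (0.15,) * cfg.K
        if cfg.base_rates is None:
            cfg.base_rates = (0.0015,) * cfg.K
        if np.any(np.asarray(cfg.base_rates) <= 0):
            raise ValueError("base_rates must be positive")
        if cfg.dirichlet_alpha is None:
            cfg.dirichlet_alpha = (1.0,) * cfg.C
        if isinstance(cfg.true_weights, str):
            if cfg.true_weights != "draw":
                raise ValueError("true_weights must be a simplex vector or 'draw'")
        else:
            w = np.asarray(cfg.true_weights, dtype=float)
            if len(w) != cfg.C:
                raise ValueError("true_weights length must equal C")
            if abs(w.sum() - 1.0) > 1e-12:
                raise ValueError("true_weights must sum to 1 within 1e-12")
        if not 0 <= cfg.covariate_correlation < 1:
            raise ValueError("covariate_correlation must lie in [0, 1)")
        return cfg


@dataclass
class SyntheticTruth:
    """Generating parameters recorded for recovery testing."""

    w_true: np.ndarray  # (C,) simplex
    alpha_true: np.ndarray  # (K,)
    beta_true: np.ndarray  # (n, K), includes the mean slope
    omega_true: np.ndarray  # (K, K) precision
    ndi_true: np.ndarray  # (n,) = deciles @ w_true

    @property
    def sigma_true(self) -> np.ndarray:
        """Implied coefficient covariance Sigma = Omega^{-1}."""
        return np.linalg.inv(self.omega_true)


def _check_spd(m: np.ndarray, name: str) -> None:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        raise ValueError(f"{name} must be positive definite") from None


def make_lattice(spec: LatticeSpec) -> sp.csr_array:
    """Binary contiguity of a regular grid, row-major unit order.

    Rook neighbors share an edge; queen contiguity adds the diagonals.
    """
    g = nx.grid_2d_graph(spec.nrows, spec.ncols)
    if spec.connectivity == "queen":
        for r in range(spec.nrows - 1):
            for c in range(spec.ncols):
                if c + 1 < spec.ncols:
                    g.add_edge((r, c), (r + 1, c + 1))
                if c - 1 >= 0:
                    g.add_edge((r, c), (r + 1, c - 1))
    order = [(r, c) for r in range(spec.nrows) for c in range(spec.ncols)]
    adj = sp.csr_array(nx.to_scipy_sparse_array(g, nodelist=order, dtype=np.int8))
    return validate_adjacency(adj, require_connected=True)


def simulate_covariates(
    n: int, C: int, correlation: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Right-skewed correlated covariates mimicking areal sociodemographics.

    Columns are exponentiated equicorrelated Gaussians (lognormal marginals:
    nonnegative, right-skewed like percentage and segregation-ratio
    variables). The last column is flagged 'inverse' to play the role of an
    advantage measure (per capita income). Only ranks survive decile scoring,
    so the marginal family is immaterial downstream.
    """
    if not 0 <= correlation < 1:
        raise ValueError("correlation must lie in [0, 1)")
    z_common = rng.standard_normal((n, 1))
    z_indep = rng.standard_normal((n, C))
    latent = np.sqrt(correlation) * z_common + np.sqrt(1 - correlation) * z_indep
    x = np.exp(latent)
    orientation = ["direct"] * (C - 1) + ["inverse"]
    return x, orientation


def simulate_mvcar_field(
    adjacency: sp.sparray,
    omega: np.ndarray,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw an n x K field from the intrinsic MVCAR prior, sum-to-zero.

    The intrinsic density exp(-1/2 sum_{i~j} (b_i-b_j)' Omega (b_i-b_j)) is
    improper (flat along per-component constants); the draw is made proper by
    conditioning each component on a sum-to-zero constraint. Sampling is in
    the spectral basis of the graph Laplacian L: for each eigenpair
    (lambda_m > 0, u_m), the K-vector coordinate is N(0, Omega^{-1}/lambda_m),
    so the field covariance is L^+ (x) Omega^{-1}.

    ``size=None`` returns one (n, K) field; an integer returns (size, n, K)
    independent replicates sharing one spectral factorization.
    """
    adjacency = validate_adjacency(adjacency, require_connected=True)
    omega = np.asarray(omega, dtype=float)
    if omega.ndim == 0:
        omega = omega.reshape(1, 1)
    _check_spd(omega, "omega")
    K = omega.shape[0]
    deg = np.asarray(adjacency.sum(axis=1)).ravel().astype(float)
    lap = (sp.diags(deg) - adjacency.astype(float)).toarray()
    evals, evecs = np.linalg.eigh(lap)
    pos = evals > evals[-1] * 1e-10  # connected graph: exactly one zero eigenvalue
    chol_sigma = np.linalg.cholesky(np.linalg.inv(omega))
    reps = 1 if size is None else int(size)
    z = rng.standard_normal((reps, int(pos.sum()), K)) @ chol_sigma.T
    z /= np.sqrt(evals[pos])[None, :, None]
    field = np.einsum("nm,rmk->rnk", evecs[:, pos], z)
    field -= field.mean(axis=1, keepdims=True)  # exact sum-to-zero
    return field[0] if size is None else field


def simulate_counts(
    truth: SyntheticTruth,
    populations: np.ndarray,
    base_rates: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson counts y_ik ~ Poisson(exp(alpha_k + beta_ik * NDI_i) r_k p_i)."""
    populations = np.asarray(populations, dtype=float)
    base_rates = np.asarray(base_rates, dtype=float)
    log_theta = truth.alpha_true[None, :] + truth.beta_true * truth.ndi_true[:, None]
    mean = np.exp(log_theta) * populations[:, None] * base_rates[None, :]
    if not np.all(np.isfinite(mean)) or np.any(mean <= 0):
        raise ValueError("Poisson means must be finite and positive")
    if np.any(mean > 1e12):
        raise ValueError(
            "Poisson mean exceeds 1e12; use smaller effect sizes or base rates"
        )
    return rng.poisson(mean).astype(np.int64)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ArealDataset, DecileDesign, SyntheticTruth]:
    """Run the full generative recipe; bit-reproducible under the config seed."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    adjacency = make_lattice(cfg.lattice)
    n = cfg.lattice.n

    populations = rng.integers(
        cfg.population_range[0], cfg.population_range[1] + 1, size=n
    )
    covariates, orientation = simulate_covariates(
        n, cfg.C, cfg.covariate_correlation, rng
    )

    if isinstance(cfg.true_weights, str):  # "draw"
        w = rng.dirichlet(np.asarray(cfg.dirichlet_alpha, dtype=float))
    else:
        w = np.asarray(cfg.true_weights, dtype=float)

    dataset = ArealDataset(
        unit_ids=np.array([f"u{i:05d}" for i in range(n)]),
        populations=populations,
        counts=np.zeros((n, cfg.K), dtype=np.int64),
        covariates=covariates,
        adjacency=adjacency,
        orientation=orientation,
    )
    design = build_decile_design(dataset)
    ndi = design.deciles @ w

    delta = simulate_mvcar_field(adjacency, cfg.true_omega, rng)
    beta = np.asarray(cfg.mean_slope, dtype=float)[None, :] + delta
    truth = SyntheticTruth(
        w_true=w,
        alpha_true=np.asarray(cfg.intercepts, dtype=float),
        beta_true=beta,
        omega_true=cfg.true_omega,
        ndi_true=ndi,
    )
    dataset.counts = simulate_counts(truth, populations, cfg.base_rates, rng)
    return dataset.validate(), design, truth


def write_bundle(
    out_dir: str | Path, dataset: ArealDataset, truth: SyntheticTruth | None = None
) -> None:
    """Write the standard dataset bundle: units.csv, adjacency.gal, truth.json."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = {"id": dataset.unit_ids, "population": dataset.populations}
    for k in range(dataset.K):
        cols[f"y_{k + 1}"] = dataset.counts[:, k]
    for j in range(dataset.C):
        cols[f"x_{j + 1}"] = dataset.covariates[:, j]
    pd.DataFrame(cols).to_csv(out / "units.csv", index=False)
    gal.write_gal(out / "adjacency.gal", list(dataset.unit_ids), dataset.adjacency)
    import yaml

    with open(out / "orientation.yaml", "w") as fh:
        yaml.safe_dump(
            {f"x_{j + 1}": flag for j, flag in enumerate(dataset.orientation)}, fh
        )
    if truth is not None:
        payload = {
            "w_true": truth.w_true.tolist(),
            "alpha_true": truth.alpha_true.tolist(),
            "beta_true": truth.beta_true.tolist(),
            "omega_true": truth.omega_true.tolist(),
            "ndi_true": truth.ndi_true.tolist(),
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(payload, fh)
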