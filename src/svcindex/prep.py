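"""Deterministic preprocessing for areal count data.

Turns a raw areal unit table (populations, outcome counts, sociodemographic
covariates) plus a contiguity structure into the quantities the index model
consumes: oriented covariates, decile scores q_ij in {1,...,10}, and
population-proportional expected counts E_ik = r_k * p_i with r_k the overall
per-capita rate of the k-th outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import gal
from .graphs import is_connected, validate_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "ArealDataset",
    "DecileDesign",
    "ExpectedCounts",
    "load_dataset",
    "orient_variable",
    "compute_deciles",
    "build_decile_design",
    "compute_expected_counts",
]


@dataclass
class ArealDataset:
    """A validated areal dataset: units, counts, covariates, adjacency.

    Attributes
    ----------
    unit_ids : (n,) array of str — areal unit identifiers.
    populations : (n,) array of positive ints.
    counts : (n, K) array of nonnegative ints — outcome counts y_ik.
    covariates : (n, C) array of floats — raw sociodemographic values x_ij.
    adjacency : (n, n) sparse symmetric binary contiguity.
    orientation : length-C list of 'direct' | 'inverse' — how each covariate
        relates to disadvantage ('inverse' for advantage measures such as
        per capita income, folded by max(x) - x).
    covariate_names : length-C list of str.
    n_dropped : units removed at load time (zero population / missing values).
    """

    unit_ids: np.ndarray
    populations: np.ndarray
    counts: np.ndarray
    covariates: np.ndarray
    adjacency: sp.csr_array
    orientation: list[str]
    covariate_names: list[str] = field(default_factory=list)
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    @property
    def K(self) -> int:
        return self.counts.shape[1]

    @property
    def C(self) -> int:
        return self.covariates.shape[1]

    def validate(self) -> "ArealDataset":
        if self.n < 10:
            raise ValueError(f"need at least 10 units, got {self.n}")
        if np.any(self.populations <= 0):
            raise ValueError("all retained units must have positive population")
        if np.any(self.counts < 0):
            raise ValueError("outcome counts must be nonnegative")
        if not (np.isfinite(self.covariates).all()):
            raise ValueError("covariates contain missing or nonfinite values")
        bad = set(self.orientation) - {"direct", "inverse"}
        if bad:
            raise ValueError(f"unknown orientation flags: {bad}")
        if len(self.orientation) != self.C:
            raise ValueError("orientation must have one flag per covariate")
        validate_adjacency(self.adjacency, require_connected=True)
        if self.adjacency.shape[0] != self.n:
            raise ValueError("adjacency order does not match number of units")
        return self


@dataclass
class DecileDesign:
    """Decile scores of the oriented covariates.

    ``deciles`` is n x C with entries in {1,...,10}; ``cutpoints`` holds the
    nine empirical decile thresholds per variable (computed on the oriented
    values); ``orientation`` records the flags that were applied.
    """

    deciles: np.ndarray
    cutpoints: np.ndarray  # (C, 9)
    orientation: list[str]
    covariate_names: list[str] = field(default_factory=list)


@dataclass
class ExpectedCounts:
    """Expected counts E_ik = r_k * p_i and the overall rates r_k."""

    rates: np.ndarray  # (K,)
    expected: np.ndarray  # (n, K)


def orient_variable(x: np.ndarray, flag: str) -> np.ndarray:
    """Orient a covariate so larger values mean more disadvantage.

    'direct' returns x unchanged; 'inverse' folds it as max(x) - x, the
    convention used for advantage measures like per capita income.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariate contains nonfinite values")
    if flag == "direct":
        return x.copy()
    if flag == "inverse":
        return x.max() - x
    raise ValueError(f"unknown orientation flag {flag!r}")


def compute_deciles(x_oriented: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decile-score one oriented covariate.

    Cutpoints are the empirical quantiles at 0.1, ..., 0.9 using the
    median-unbiased definition; unit i gets the smallest decile d with
    x_i <= cutpoint_d (decile 10 above all cutpoints). Tied values share a
    decile. A constant column collapses to decile 1 with a warning.

    Returns (q, cutpoints) with q integer in {1..10} and cutpoints shape (9,).
    """
    x = np.asarray(x_oriented, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations to form deciles")
    if np.ptp(x) == 0:
        warnings.warn(
            "constant covariate column: all units assigned decile 1", stacklevel=2
        )
        cut = np.full(9, x[0])
        return np.ones(x.size, dtype=np.int64), cut
    cut = np.quantile(x, np.arange(1, 10) / 10.0, method="median_unbiased")
    q = np.searchsorted(cut, x, side="left") + 1
    return q.astype(np.int64), cut


def build_decile_design(dataset: ArealDataset) -> DecileDesign:
    """Orient every covariate and decile-score it on the analysis set."""
    n, C = dataset.covariates.shape
    q = np.empty((n, C), dtype=np.int64)
    cuts = np.empty((C, 9))
    for j in range(C):
        oriented = orient_variable(dataset.covariates[:, j], dataset.orientation[j])
        q[:, j], cuts[j] = compute_deciles(oriented)
    return DecileDesign(
        deciles=q,
        cutpoints=cuts,
        orientation=list(dataset.orientation),
        covariate_names=list(dataset.covariate_names),
    )


def compute_expected_counts(y: np.ndarray, populations: np.ndarray) -> ExpectedCounts:
    """Expected counts under proportional allocation of each outcome's total.

    r_k = sum_i y_ik / sum_i p_i and E_ik = r_k * p_i, so the expected counts
    reproduce each outcome's observed total exactly.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 1 and y.size > 1:
        y = y.T
    p = np.asarray(populations, dtype=float)
    if np.any(p <= 0):
        raise ValueError("populations must be positive")
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    totals = y.sum(axis=0)
    if np.any(totals == 0):
        k = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(
            f"outcome column {k} has zero total count; its rate is undefined"
        )
    rates = totals / p.sum()
    expected = np.outer(p, rates)
    return ExpectedCounts(rates=rates, expected=expected)


def load_dataset(
    units_path,
    adjacency_path,
    orientation: dict[str, str] | list[str] | None = None,
) -> ArealDataset:
    """Load a unit table (CSV) and a GAL adjacency into a validated dataset.

    The unit table needs columns ``id``, ``population``, outcome columns
    ``y_1..y_K`` and covariate columns ``x_1..x_C`` (or any columns prefixed
    ``y_``/``x_``). Units with zero population or missing covariates/counts
    are dropped, mirroring standard areal-analysis practice; the drop count
    is logged and recorded on the returned dataset.

    ``orientation`` maps covariate column name to 'direct'/'inverse' (or is a
    list in column order). Unmentioned columns default to 'direct'.
    """
    units = pd.read_csv(units_path, dtype={"id": str})
    gal_ids, adj = gal.read_gal(adjacency_path)
    if set(units["id"]) != set(gal_ids):
        raise ValueError("unit ids in the table and the GAL file do not match as sets")

    # align table to GAL order before any dropping
    units = units.set_index("id").loc[gal_ids].reset_index()

    y_cols = sorted(
        (c for c in units.columns if c.startswith("y_")), key=lambda c: int(c[2:])
    )
    x_cols = sorted(
        (c for c in units.columns if c.startswith("x_")), key=lambda c: int(c[2:])
    )
    if not y_cols or not x_cols:
        raise ValueError("unit table must contain y_* outcome and x_* covariate columns")

    keep = (units["population"].fillna(0) > 0) & units[x_cols + y_cols].notna().all(
        axis=1
    )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d units (zero population or missing values); %d retained",
            n_dropped,
            int(keep.sum()),
        )
    retained = units.loc[keep]
    idx = np.flatnonzero(keep.to_numpy())
    adj = sp.csr_array(sp.csr_matrix(adj)[np.ix_(idx, idx)])
    if not is_connected(adj):
        raise ValueError("adjacency graph is disconnected after dropping invalid units")

    if orientation is None:
        orientation_list = ["direct"] * len(x_cols)
    elif isinstance(orientation, dict):
        orientation_list = [orientation.get(c, "direct") for c in x_cols]
    else:
        orientation_list = list(orientation)

    ds = ArealDataset(
        unit_ids=retained["id"].to_numpy(dtype=str),
        populations=retained["population"].to_numpy(dtype=np.int64),
        counts=retained[y_cols].to_numpy(dtype=np.int64),
        covariates=retained[x_cols].to_numpy(dtype=float),
        adjacency=adj,
        orientation=orientation_list,
        covariate_names=x_cols,
        n_dropped=n_dropped,
    )
    return ds.validate()
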