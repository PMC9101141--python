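"""Convergence assessment and posterior summarization.

Covers the reporting side of the spatially varying coefficient index model:
Gelman-Rubin potential scale reduction for monitored scalars, unit-level
relative-risk summaries with 95% credible-interval significance flags,
conditional correlations between outcome types from Sigma = Omega^{-1},
index-weight and NDI summaries, and Welch t-test comparisons between units
with and without significantly elevated index effects.

All credible intervals are equal-tailed empirical quantiles of the pooled
chains (linear interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import PosteriorSamples
from .prep import DecileDesign

__all__ = [
    "GelmanRubinResult",
    "gelman_rubin",
    "monitored_scalars",
    "convergence_table",
    "summarize_effects",
    "conditional_correlations",
    "summarize_weights",
    "summarize_ndi",
    "welch_tests",
]


@dataclass
class GelmanRubinResult:
    """Potential scale reduction for one monitored scalar."""

    rhat: float
    within: float
    between: float
    converged: bool


def gelman_rubin(chains: np.ndarray, threshold: float = 1.2) -> GelmanRubinResult:
    """Classical Gelman-Rubin potential scale reduction factor.

    ``chains`` is (m, T) with m >= 2 chains of T >= 4 draws each.
    W = mean of the m within-chain variances, B = T * variance of the chain
    means, Vhat = (T-1)/T * W + B/T, Rhat = sqrt(Vhat / W).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 4:
        raise ValueError("need an (m >= 2) x (T >= 4) array of draws")
    m, T = chains.shape
    within = chains.var(axis=1, ddof=1).mean()
    if within == 0:
        raise ValueError("degenerate chain: zero within-chain variance")
    between = T * chains.mean(axis=1).var(ddof=1)
    vhat = (T - 1) / T * within + between / T
    rhat = float(np.sqrt(vhat / within))
    return GelmanRubinResult(
        rhat=rhat, within=float(within), between=float(between),
        converged=bool(rhat < threshold),
    )


def monitored_scalars(
    samples: PosteriorSamples, n_beta: int = 100, seed: int = 0
) -> dict[str, np.ndarray]:
    """Assemble the monitored scalar traces: alpha_k, w_j, Omega entries, and
    a seeded random subsample of up to ``n_beta`` coefficient entries
    (monitoring every unit-by-outcome coefficient would be wasteful).

    Returns a mapping name -> (m, T) array.
    """
    out: dict[str, np.ndarray] = {}
    K = samples.alpha.shape[-1]
    C = samples.weights.shape[-1]
    for k in range(K):
        out[f"alpha[{k + 1}]"] = samples.alpha[:, :, k]
    for j in range(C):
        out[f"w[{j + 1}]"] = samples.weights[:, :, j]
    for k in range(K):
        for l in range(k, K):
            out[f"omega[{k + 1},{l + 1}]"] = samples.omega[:, :, k, l]
    n = samples.beta.shape[2]
    rng = np.random.default_rng(seed)
    total = n * K
    take = min(n_beta, total)
    flat_idx = rng.choice(total, size=take, replace=False)
    for fi in np.sort(flat_idx):
        i, k = divmod(int(fi), K)
        out[f"beta[{i + 1},{k + 1}]"] = samples.beta[:, :, i, k]
    return out


def convergence_table(
    samples: PosteriorSamples,
    threshold: float = 1.2,
    n_beta: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Gelman-Rubin diagnostics for all monitored scalars, one row each."""
    rows = []
    for name, traces in monitored_scalars(samples, n_beta=n_beta, seed=seed).items():
        r = gelman_rubin(traces, threshold=threshold)
        rows.append(
            {
                "parameter": name,
                "rhat": r.rhat,
                "within": r.within,
                "between": r.between,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)


def summarize_effects(samples: PosteriorSamples) -> pd.DataFrame:
    """Unit-level relative risks exp(beta_ik) with 95% CrI significance flags.

    A unit has a significantly elevated index effect for outcome k when the
    2.5% pooled-chain quantile of exp(beta_ik) exceeds 1 (equivalently, the
    lower credible bound of beta_ik exceeds 0).
    """
    beta = samples.pooled("beta")  # (D, n, K)
    if beta.shape[0] < 100:
        raise ValueError("need at least 100 pooled draws for stable quantiles")
    lo, med, hi = np.quantile(beta, [0.025, 0.5, 0.975], axis=0)
    rows = []
    n, K = med.shape
    for k in range(K):
        for i in range(n):
            rows.append(
                {
                    "unit": i,
                    "outcome": k + 1,
                    "rr_median": np.exp(med[i, k]),
                    "rr_lower": np.exp(lo[i, k]),
                    "rr_upper": np.exp(hi[i, k]),
                    "significant": bool(np.exp(lo[i, k]) > 1.0),
                }
            )
    return pd.DataFrame(rows)


def conditional_correlations(omega_draws: np.ndarray) -> pd.DataFrame:
    """Conditional correlations between outcome types' coefficient fields.

    Each precision draw is inverted to Sigma = Omega^{-1} and converted to
    rho_kl = Sigma_kl / sqrt(Sigma_kk Sigma_ll); per pair the posterior
    median and equal-tailed 95% CrI are reported.
    """
    omega_draws = np.asarray(omega_draws, dtype=float)
    if omega_draws.ndim == 2:
        omega_draws = omega_draws[None]
    sigma = np.linalg.inv(omega_draws)
    sd = np.sqrt(np.diagonal(sigma, axis1=1, axis2=2))
    if not np.isfinite(sd).all() or np.any(sd <= 0):
        raise ValueError("numerically singular covariance draw")
    rho = sigma / (sd[:, :, None] * sd[:, None, :])
    K = rho.shape[-1]
    rows = []
    for k in range(K):
        for l in range(k + 1, K):
            draws = rho[:, k, l]
            lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
            rows.append(
                {
                    "pair": f"{k + 1}-{l + 1}",
                    "median": med,
                    "lower": lo,
                    "upper": hi,
                }
            )
    return pd.DataFrame(rows)


def summarize_weights(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-variable posterior median and 95% CrI of the index weights.

    Medians are reported raw (componentwise medians of simplex draws need not
    sum exactly to one). The table is ranked by median weight.
    """
    w = samples.pooled("weights")
    lo, med, hi = np.quantile(w, [0.025, 0.5, 0.975], axis=0)
    df = pd.DataFrame(
        {
            "variable": np.arange(1, w.shape[1] + 1),
            "median": med,
            "lower": lo,
            "upper": hi,
        }
    )
    df["rank"] = df["median"].rank(ascending=False, method="first").astype(int)
    return df.sort_values("rank").reset_index(drop=True)


def summarize_ndi(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-unit posterior median of the disadvantage index NDI_i = sum_j w_j q_ij."""
    ndi = samples.ndi_draws()  # (D, n)
    lo, med, hi = np.quantile(ndi, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {"unit": np.arange(ndi.shape[1]), "ndi_median": med, "lower": lo, "upper": hi}
    )


def welch_two_sample(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Welch-Satterthwaite df, and two-sided p-value."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(x1, x2, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_tests(
    effects: pd.DataFrame,
    design: DecileDesign,
    ndi_medians: np.ndarray,
) -> pd.DataFrame:
    """Compare NDI and decile-variable distributions across significance groups.

    For each outcome type, units are split by the significant flag of their
    index effect; the posterior-median NDI and each decile column are compared
    between the groups with Welch's t-test (raw two-sided p-values, no
    multiplicity correction). Outcomes where either group has fewer than two
    units are skipped with a notice row.
    """
    ndi_medians = np.asarray(ndi_medians, dtype=float)
    variables = {"NDI": ndi_medians}
    for j in range(design.deciles.shape[1]):
        name = (
            design.covariate_names[j]
            if design.covariate_names
            else f"q_{j + 1}"
        )
        variables[name] = design.deciles[:, j].astype(float)

    rows = []
    for k, grp in effects.groupby("outcome"):
        sig_units = grp.loc[grp["significant"], "unit"].to_numpy()
        non_units = grp.loc[~grp["significant"], "unit"].to_numpy()
        if len(sig_units) < 2 or len(non_units) < 2:
            rows.append(
                {
                    "outcome": k,
                    "variable": None,
                    "skipped": True,
                    "note": f"group sizes {len(sig_units)}/{len(non_units)} too small",
                }
            )
            continue
        for name, values in variables.items():
            t, df, p = welch_two_sample(values[sig_units], values[non_units])
            rows.append(
                {
                    "outcome": k,
                    "variable": name,
                    "mean_significant": values[sig_units].mean(),
                    "mean_nonsignificant": values[non_units].mean(),
                    "t": t,
                    "df": df,
                    "p": p,
                    "skipped": False,
                }
            )
    return pd.DataFrame(rows)
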