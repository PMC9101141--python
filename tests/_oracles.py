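"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (textbook
formulas, dense quadrature, brute-force enumeration) and shares no code with
the package, so agreement between the two is evidence of correctness rather
than tautology.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, psi


def gelman_rubin_brute(chains):
    """Potential scale reduction coded directly from the textbook formula."""
    chains = np.asarray(chains, dtype=float)
    m, T = chains.shape
    means = [c.mean() for c in chains]
    variances = [c.var(ddof=1) for c in chains]
    W = sum(variances) / m
    grand = sum(means) / m
    B = T * sum((mu - grand) ** 2 for mu in means) / (m - 1)
    Vhat = (T - 1) / T * W + B / T
    return np.sqrt(Vhat / W), W, B


def welch_brute(x1, x2):
    """Welch t, Welch-Satterthwaite df and two-sided p from the formulas."""
    from scipy.stats import t as t_dist

    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x1.mean() - x2.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, df, p


def laplacian_pseudoinverse(adjacency):
    """Moore-Penrose pseudoinverse of the graph Laplacian (dense spectral)."""
    A = np.asarray(adjacency.todense(), dtype=float)
    lap = np.diag(A.sum(axis=1)) - A
    evals, evecs = np.linalg.eigh(lap)
    pos = evals > evals[-1] * 1e-10
    return (evecs[:, pos] / evals[pos]) @ evecs[:, pos].T


def path_instance_posterior_means(q, E, y, omega, nw=80, nu=61, nsd=8.0):
    """Dense-quadrature posterior means for the 4-unit path instance.

    Model: y_i ~ Poisson(E_i exp(alpha + beta_i ndi_i)), ndi = w1 q1 +
    (1-w1) q2, intrinsic CAR kernel on beta with fixed scalar precision
    omega, flat prior on alpha, Dirichlet(1,1) (uniform) prior on w1.

    The intercept is integrated analytically (flat prior on alpha means
    t = e^alpha has a Gamma full conditional).  The beta integral is done in
    eta = beta * ndi coordinates, where the uniform-shift direction -- exactly
    flat under the likelihood and only weakly curved by the CAR kernel -- is
    Gaussian and is marginalized in closed form; the remaining three contrast
    coordinates are likelihood-dominated and integrated on an adaptive grid
    centered at their conditional mode.  w1 is handled by an outer midpoint
    rule.

    Returns dict with posterior means of w1, beta (4,), alpha.
    """
    q = np.asarray(q, dtype=float)
    E = np.asarray(E, dtype=float)
    y = np.asarray(y, dtype=float)
    n = 4
    S = y.sum()
    logE = np.log(E)
    lap = np.array(
        [[1.0, -1, 0, 0], [-1, 2, -1, 0], [0, -1, 2, -1], [0, 0, -1, 1]]
    )
    a = np.ones(n) / np.sqrt(n)
    basis, _, _ = np.linalg.svd(np.eye(n) - np.outer(a, a))
    V = basis[:, : n - 1]  # orthonormal complement of the shift direction

    wgrid = (np.arange(nw) + 0.5) / nw
    logZ = np.empty(nw)
    Ebeta_w = np.empty((nw, n))
    Elogsum_w = np.empty(nw)
    u0 = np.zeros(n - 1)
    for iw, w1 in enumerate(wgrid):
        ndi = w1 * q[:, 0] + (1 - w1) * q[:, 1]
        D = np.diag(1.0 / ndi)
        M = omega * D @ lap @ D  # kernel precision in eta coordinates
        Mcc = a @ M @ a
        Mcu = a @ M @ V
        Mcond = V.T @ M @ V - np.outer(Mcu, Mcu) / Mcc
        yV = y @ V

        def neg(u):
            eta_u = V @ u
            return -(
                yV @ u
                - S * np.log(np.exp(logE + eta_u).sum())
                - 0.5 * u @ Mcond @ u
            )

        res = minimize(neg, u0, method="BFGS")
        umap = res.x
        u0 = umap
        h = 1e-4
        H = np.empty((n - 1, n - 1))
        f0 = -neg(umap)
        for i in range(n - 1):
            for j in range(i, n - 1):
                ei = np.zeros(n - 1)
                ei[i] = h
                ej = np.zeros(n - 1)
                ej[j] = h
                H[i, j] = H[j, i] = (
                    -neg(umap + ei + ej) + neg(umap + ei) + neg(umap + ej) - f0
                ) / h**2
        sd = np.sqrt(np.diag(np.linalg.inv(-H)))
        grids = [
            np.linspace(umap[i] - nsd * sd[i], umap[i] + nsd * sd[i], nu)
            for i in range(n - 1)
        ]
        logvol = sum(np.log(g[1] - g[0]) for g in grids)
        mesh = np.meshgrid(*grids, indexing="ij")
        upts = np.stack(mesh, axis=-1)  # (nu, nu, nu, 3)
        eta_u = upts @ V.T  # (nu, nu, nu, 4)
        lik = upts @ yV - S * np.log(np.exp(logE + eta_u).sum(axis=-1))
        quad = np.einsum("...i,ij,...j->...", upts, Mcond, upts)
        lp = lik - 0.5 * quad
        peak = lp.max()
        pw = np.exp(lp - peak)
        tot = pw.sum()
        logZ[iw] = (
            peak
            + np.log(tot)
            + logvol
            + 0.5 * np.log(2 * np.pi / Mcc)
            - np.log(ndi).sum()  # Jacobian of beta -> eta
        )
        cbar = -(upts @ Mcu) / Mcc  # conditional mean of the shift coordinate
        eta_mean = (pw[..., None] * (cbar[..., None] * a + eta_u)).sum(
            axis=tuple(range(n - 1))
        ) / tot
        Ebeta_w[iw] = eta_mean / ndi
        Elogsum_w[iw] = (
            pw
            * (cbar / np.sqrt(n) + np.log(np.exp(logE + eta_u).sum(axis=-1)))
        ).sum() / tot

    wts = np.exp(logZ - logsumexp(logZ))
    wts /= wts.sum()
    return {
        "w1": float(wts @ wgrid),
        "beta": wts @ Ebeta_w,
        "alpha": float(psi(S) - wts @ Elogsum_w),
    }
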