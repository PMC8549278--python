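"""Brute-force MCMC oracle targeting the exact joint posterior.

The sampler alternates

  * conjugate Gibbs updates of every variance component: with a Gaussian
    block of rank r and quadratic form q at unit variance, the inverse-Gamma
    full conditional is IG(a + r/2, b + q/2);
  * a preconditioned Metropolis-adjusted Langevin (MALA) update of the whole
    latent field, with the inverse Hessian of the Laplace approximation as a
    fixed mass matrix and a step size adapted to ~57% acceptance during
    burn-in only (all adaptation is frozen afterwards, so the post-burn-in
    chain has the correct stationary distribution).

Sum-to-zero constraints hold by construction: the latent field is the
reduced-eigenbasis coordinate vector of :mod:`geociaf.model`, which excludes
the constant directions, so no re-centring step is needed.

With no observations the latent block is drawn exactly from its conditional
prior, which makes prior-recovery checks exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import ModelDesign

__all__ = ["mcmc_oracle", "draw_variance", "ess", "split_rhat"]


def draw_variance(rng: np.random.Generator, a: float, b: float,
                  rank: int, quadform: float) -> float:
    """One draw from the IG(a + rank/2, b + quadform/2) full conditional."""
    shape = a + 0.5 * rank
    scale = b + 0.5 * quadform
    return float(scale / rng.gamma(shape))


def ess(x: np.ndarray) -> float:
    """Effective sample size by Geyer's initial positive sequence."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf /= acf[0]
    # sum consecutive pairs until a pair goes non-positive
    tau = 1.0
    for k in range(1, n // 2, 2):
        pair = acf[k] + acf[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(n / tau)


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor of one chain."""
    x = np.asarray(x, dtype=float)
    n = len(x) // 2
    halves = np.stack([x[:n], x[n:2 * n]])
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + between / (n * within)))


def _grad(design: ModelDesign, theta: np.ndarray, pdiag: np.ndarray):
    eta = design.A @ theta
    p = expit(eta)
    g = design.A.T @ (design.weights * (design.y - p)) - pdiag * theta
    lp = float(np.sum(design.weights *
                      (design.y * eta - np.logaddexp(0.0, eta)))
               - 0.5 * np.sum(pdiag * theta**2))
    return g, lp


def mcmc_oracle(
    design: ModelDesign,
    iterations: int = 200_000,
    burn_in: int = 20_000,
    seed: int = 0,
    thin: int | None = None,
    latent_steps: int = 1,
    max_stored: int = 20_000,
) -> dict:
    """Run the Gibbs/MALA sampler and return post-burn-in draws.

    Returns a dict with ``theta`` (S x dim), ``variances`` (DataFrame, one
    column per variance component) and ``diagnostics`` (acceptance rate,
    minimum ESS, maximum split-Rhat over fixed effects and variances).
    """
    if not (iterations > burn_in >= 0):
        raise ValueError("need iterations > burn_in >= 0")
    rng = np.random.default_rng(seed)
    names = design.variance_names
    variances = {nm: 0.1 for nm in names}
    dim = design.dim
    zero_data = design.n == 0

    pen_blocks = [b for b in design.blocks if b.var_name is not None]

    def pdiag_of(vs):
        p = np.zeros(dim)
        for b in pen_blocks:
            p[b.sl] = b.prior_eigvals / vs[b.var_name]
        return p

    # fixed preconditioner from the Laplace approximation at initial variances
    if not zero_data:
        from .inference import _newton_mode

        theta, cf, _, _ = _newton_mode(design, pdiag_of(variances))
        L_H = np.tril(cf[0])                       # H = L L'
        # M = H^{-1}; draw M^{1/2} z by solving L' u = z
        step = 0.9
    else:
        theta = np.zeros(dim)
        L_H = None
        step = 1.0

    if thin is None:
        thin = max(1, (iterations - burn_in) // max_stored)
    kept = (iterations - burn_in) // thin
    theta_store = np.empty((kept, dim))
    var_store = np.empty((kept, len(names)))
    k = 0
    accepts = 0
    proposals = 0

    def mala_step(theta, g, lp, step):
        # proposal theta' = theta + (s^2/2) M g + s M^{1/2} z
        Mg = _chol_solve(L_H, g)
        mean_fwd = theta + 0.5 * step**2 * Mg
        z = rng.standard_normal(dim)
        delta = _upper_solve(L_H, z)               # M^{1/2} z
        prop = mean_fwd + step * delta
        g2, lp2 = _grad(design, prop, pdiag)
        mean_rev = prop + 0.5 * step**2 * _chol_solve(L_H, g2)
        # log q densities under metric M^{-1} = H
        d_fwd = prop - mean_fwd
        d_rev = theta - mean_rev
        q_fwd = -0.5 / step**2 * d_fwd @ _apply_H(L_H, d_fwd)
        q_rev = -0.5 / step**2 * d_rev @ _apply_H(L_H, d_rev)
        log_alpha = (lp2 + q_rev) - (lp + q_fwd)
        if np.log(rng.uniform()) < log_alpha:
            return prop, g2, lp2, True, min(1.0, np.exp(min(log_alpha, 0.0)))
        return theta, g, lp, False, min(1.0, np.exp(min(log_alpha, 0.0)))

    pdiag = pdiag_of(variances)
    if not zero_data:
        g, lp = _grad(design, theta, pdiag)

    for it in range(iterations):
        # --- variances | latent: conjugate IG
        for j, b in enumerate(pen_blocks):
            lam = b.prior_eigvals
            gamma = theta[b.sl]
            quad = float(np.sum(lam * gamma**2))
            a, bb = design.spec.hyper(b.var_name)
            variances[b.var_name] = draw_variance(rng, a, bb, b.rank, quad)
        pdiag = pdiag_of(variances)

        # --- latent | variances
        if zero_data:
            for b in pen_blocks:
                lam = b.prior_eigvals
                pos = lam > 0
                gamma = np.zeros(b.size)
                gamma[pos] = rng.standard_normal(pos.sum()) * np.sqrt(
                    variances[b.var_name] / lam[pos])
                theta[b.sl] = gamma
        else:
            g, lp = _grad(design, theta, pdiag)  # pdiag changed
            for _ in range(latent_steps):
                theta, g, lp, acc, aprob = mala_step(theta, g, lp, step)
                proposals += 1
                accepts += acc
                if it < burn_in:  # Robbins-Monro adaptation, burn-in only
                    step *= np.exp(min(0.05, 2.0 / np.sqrt(1 + it))
                                   * (aprob - 0.574))

        if it >= burn_in and (it - burn_in) % thin == 0 and k < kept:
            theta_store[k] = theta
            var_store[k] = [variances[nm] for nm in names]
            k += 1

    theta_store = theta_store[:k]
    var_store = var_store[:k]
    var_df = pd.DataFrame(var_store, columns=names)

    fixed_sl = design.block("fixed").sl
    track = [theta_store[:, j] for j in range(fixed_sl.start, fixed_sl.stop)]
    track += [var_store[:, j] for j in range(var_store.shape[1])]
    ess_min = min((ess(t) for t in track), default=float(k))
    rhat_max = max((split_rhat(t) for t in track), default=1.0)
    diag = {
        "iterations": iterations, "burn_in": burn_in, "thin": thin,
        "acceptance": accepts / max(proposals, 1), "step": step,
        "ess_min": ess_min, "rhat_max": rhat_max,
    }
    return {"theta": theta_store, "variances": var_df, "diagnostics": diag}


def _chol_solve(L, x):
    """(L L')^{-1} x given lower-triangular L."""
    from scipy.linalg import solve_triangular

    u = solve_triangular(L, x, lower=True)
    return solve_triangular(L.T, u, lower=False)


def _upper_solve(L, z):
    """L'^{-1} z: a draw with covariance (L L')^{-1}."""
    from scipy.linalg import solve_triangular

    return solve_triangular(L.T, z, lower=False)


def _apply_H(L, x):
    """(L L') x."""
    return L @ (L.T @ x)
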