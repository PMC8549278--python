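"""Posterior inference for the geo-additive logit model.

The routine engine is a Laplace / empirical-Bayes approximation in the spirit
of INLA: for fixed variance components the latent field (fixed effects,
smooth coordinates, spatial coordinates) is Gaussian-approximated at its
posterior mode; the variances are estimated by maximising the
Laplace-approximate marginal posterior over a log-variance grid by coordinate
descent, and their posterior summaries come from normalised weights on
per-variance conditional grids.  The full nested-INLA machinery is
deliberately not replicated; the engine is validated against a long-run MCMC
oracle (see :mod:`geociaf.mcmc`).

Latent summaries are reported at the empirical-Bayes variance estimate, which
ignores hyperparameter uncertainty in the latent field; the recovery and
oracle-agreement checks quantify what that costs at the problem sizes used.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, ndtr

from .model import (
    ModelDesign,
    ModelSpec,
    ParameterState,
    build_design,
    invgamma_logpdf,
)

__all__ = [
    "FitResult",
    "fit",
    "screen_univariable",
    "posterior_or_table",
]

_Z975 = 1.959963984540054


@dataclass
class FitResult:
    """Posterior summaries (and optional draws) of one model fit."""

    engine: str
    spec: ModelSpec
    summaries: dict                  # section -> DataFrame (mean/sd/q2.5/q97.5)
    fitted_probs: np.ndarray
    variances: dict                  # var name -> point estimate used
    theta_mean: np.ndarray
    theta_cov: np.ndarray | None
    design: ModelDesign
    draws: dict | None = None        # 'theta' (S x dim), 'variances' DataFrame
    flags: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.flags.get("converged", True)

    def state(self) -> ParameterState:
        return ParameterState.from_coords(self.design, self.theta_mean,
                                          self.variances)

    def sample_latent(self, size: int, seed: int) -> np.ndarray:
        """Posterior draws of the latent field (size x dim)."""
        rng = np.random.default_rng(seed)
        if self.draws is not None and "theta" in self.draws:
            stored = self.draws["theta"]
            idx = rng.integers(0, stored.shape[0], size=size)
            return stored[idx]
        L = np.linalg.cholesky(self.theta_cov)
        z = rng.standard_normal((size, self.theta_mean.size))
        return self.theta_mean + z @ L.T

    def sample_eta(self, size: int, seed: int) -> np.ndarray:
        return self.sample_latent(size, seed) @ self.design.A.T

    def to_json_dict(self) -> dict:
        out = {"engine": self.engine, "flags": self.flags, "meta": self.meta,
               "variances": self.variances, "summaries": {}}
        for k, df in self.summaries.items():
            out["summaries"][k] = df.to_dict(orient="list")
        return out


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------

def _prior_precision_diag(design: ModelDesign, variances: dict) -> np.ndarray:
    p = np.zeros(design.dim)
    for b in design.blocks:
        if b.var_name is None:
            continue
        p[b.sl] = b.prior_eigvals / variances[b.var_name]
    return p


def _penalized_objective(design, theta, eta, pdiag):
    ll = np.sum(design.weights * (design.y * eta - np.logaddexp(0.0, eta)))
    return float(ll - 0.5 * np.sum(pdiag * theta**2))


def _newton_mode(design: ModelDesign, pdiag: np.ndarray,
                 theta0: np.ndarray | None = None,
                 max_iter: int = 60, tol: float = 1e-9):
    """Penalised IRLS/Newton for the conditional posterior mode.

    Returns (theta_hat, cho_factor of H, objective, converged).
    """
    A, y, w = design.A, design.y, design.weights
    n, dim = A.shape
    theta = np.zeros(dim) if theta0 is None else theta0.copy()
    eta = A @ theta
    obj = _penalized_objective(design, theta, eta, pdiag)
    jitter = 1e-10
    cf = None
    converged = False
    for _ in range(max_iter):
        p = expit(eta)
        g = A.T @ (w * (y - p)) - pdiag * theta
        d = w * p * (1.0 - p)
        H = (A * d[:, None]).T @ A
        H[np.diag_indices_from(H)] += pdiag + jitter
        try:
            cf = cho_factor(H, lower=True)
        except np.linalg.LinAlgError:
            jitter *= 100
            continue
        step = cho_solve(cf, g)
        # backtracking line search on the penalised objective
        t = 1.0
        for _ls in range(30):
            theta_new = theta + t * step
            eta_new = A @ theta_new
            obj_new = _penalized_objective(design, theta_new, eta_new, pdiag)
            if obj_new >= obj - 1e-12:
                break
            t *= 0.5
        gain = obj_new - obj
        theta, eta, obj = theta_new, eta_new, obj_new
        if np.max(np.abs(g)) < tol * (1.0 + abs(obj)) or gain < 1e-10 * (1 + abs(obj)):
            converged = True
            break
    return theta, cf, obj, converged


def _laplace_log_evidence(design: ModelDesign, variances: dict,
                          theta0=None, return_factor: bool = False):
    """Laplace approximation to log p(y, variances) up to a constant.

    Includes the rank-aware intrinsic-prior normalisers, the IG hyperpriors
    and the log-variance Jacobian (the grid lives on the log scale).
    """
    pdiag = _prior_precision_diag(design, variances)
    theta, cf, obj, conv = _newton_mode(design, pdiag, theta0)
    logdetH = 2.0 * np.sum(np.log(np.diag(cf[0])))
    out = obj - 0.5 * logdetH
    for b in design.blocks:
        if b.var_name is None:
            continue
        lam = b.prior_eigvals[b.prior_eigvals > 0]
        v = variances[b.var_name]
        out += 0.5 * np.sum(np.log(lam)) - 0.5 * len(lam) * np.log(2 * np.pi * v)
    for name in design.variance_names:
        a, bb = design.spec.hyper(name)
        v = variances[name]
        out += invgamma_logpdf(v, a, bb) + np.log(v)
    if return_factor:
        return float(out), theta, cf
    return float(out), theta


def _grid_summary(grid: np.ndarray, logw: np.ndarray) -> dict:
    w = np.exp(logw - logw.max())
    w /= w.sum()
    mean = float(np.sum(w * grid))
    sd = float(np.sqrt(np.sum(w * (grid - mean) ** 2)))
    cdf = np.cumsum(w)
    q = np.interp([0.025, 0.5, 0.975], cdf, grid)
    return {"mean": mean, "sd": sd, "q2.5": float(q[0]),
            "median": float(q[1]), "q97.5": float(q[2])}


def _fit_laplace(design: ModelDesign, seed: int,
                 grid_size: int = 11, grid_range=(2e-4, 5.0),
                 refine_size: int = 21, passes: int = 2,
                 zoom: float = 4.0) -> FitResult:
    t0 = time.perf_counter()
    names = design.variance_names
    variances = {nm: 0.1 for nm in names}
    theta = None
    n_evals = 0

    def sweep(grids):
        nonlocal theta, n_evals
        for nm in names:
            best_val, best_v = -np.inf, variances[nm]
            for v in grids[nm]:
                trial = dict(variances, **{nm: float(v)})
                val, th = _laplace_log_evidence(design, trial, theta)
                n_evals += 1
                if val > best_val:
                    best_val, best_v, theta = val, float(v), th
            variances[nm] = best_v

    # coarse global pass, then zoomed coordinate-descent passes
    coarse = np.geomspace(grid_range[0], grid_range[1], grid_size)
    sweep({nm: coarse for nm in names})
    for _ in range(passes):
        sweep({nm: np.geomspace(variances[nm] / zoom, variances[nm] * zoom, 7)
               for nm in names})

    # Conditional grids around the optimum give the variance posterior
    # summaries, and every evaluated point joins a Gaussian-mixture
    # approximation of the latent posterior, so the latent summaries carry
    # hyperparameter uncertainty instead of conditioning on one estimate.
    var_rows = []
    mix_logw, mix_mean, mix_cov = [], [], []
    dim_eye = np.eye(design.dim)
    for nm in names:
        vg = np.geomspace(variances[nm] / 25, variances[nm] * 25, refine_size)
        logw = np.empty(refine_size)
        for i, v in enumerate(vg):
            trial = dict(variances, **{nm: float(v)})
            logw[i], th_g, cf_g = _laplace_log_evidence(
                design, trial, theta, return_factor=True)
            n_evals += 1
            mix_logw.append(logw[i])
            mix_mean.append(th_g)
            mix_cov.append(cho_solve(cf_g, dim_eye))
        s = _grid_summary(vg, logw)
        # condition the point estimate on the conditional posterior mode
        variances[nm] = float(vg[np.argmax(logw)])
        var_rows.append({"name": nm, **{k: s[k] for k in
                                        ("mean", "sd", "q2.5", "q97.5")}})

    pdiag = _prior_precision_diag(design, variances)
    theta, cf, obj, conv = _newton_mode(design, pdiag, theta)
    if mix_logw:
        w = np.exp(np.array(mix_logw) - max(mix_logw))
        w /= w.sum()
        means = np.array(mix_mean)
        theta = w @ means
        cov = np.einsum("g,gij->ij", w, np.array(mix_cov))
        cov += np.einsum("g,gi,gj->ij", w, means, means)
        cov -= np.outer(theta, theta)
    else:  # no variance components (pure fixed-effect model)
        cov = cho_solve(cf, np.eye(design.dim))
    flags = {"converged": bool(conv)}
    fixed_sl = design.block("fixed").sl
    if np.max(np.abs(theta[fixed_sl])) > 15:
        warnings.warn("possible separation: a fixed effect exceeds 15 on the "
                      "logit scale; intervals may be unreliable", stacklevel=2)
        flags["separation"] = True

    summaries = _gaussian_summaries(design, theta, cov)
    summaries["variances"] = pd.DataFrame(var_rows)
    eta = design.A @ theta
    return FitResult(
        engine="approx", spec=design.spec, summaries=summaries,
        fitted_probs=np.clip(expit(eta), 1e-12, 1 - 1e-12),
        variances=variances, theta_mean=theta, theta_cov=cov, design=design,
        flags=flags,
        meta={"seed": seed, "n_grid_evaluations": n_evals,
              "runtime_s": time.perf_counter() - t0},
    )


def _summary_frame(labels, mean, sd, extra=None) -> pd.DataFrame:
    df = pd.DataFrame({
        "term": labels, "mean": mean, "sd": sd,
        "q2.5": mean - _Z975 * sd, "q97.5": mean + _Z975 * sd,
    })
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


def _gaussian_summaries(design: ModelDesign, theta, cov) -> dict:
    out = {}
    b0 = design.block("fixed")
    sd = np.sqrt(np.diag(cov))
    out["fixed"] = _summary_frame(design.fixed_names, theta[b0.sl], sd[b0.sl])
    for b in design.blocks:
        if b.kind == "smooth":
            covn = b.name.split(":", 1)[1]
            mids = design.smooth_meta[covn]["midpoints"]
            f = b.basis @ theta[b.sl]
            fsd = np.sqrt(np.einsum("ij,jk,ik->i", b.basis,
                                    cov[b.sl, b.sl], b.basis))
            out[b.name] = pd.DataFrame({
                "midpoint": mids, "mean": f, "sd": fsd,
                "q2.5": f - _Z975 * fsd, "q97.5": f + _Z975 * fsd,
            })
        elif b.kind == "icar":
            f = b.basis @ theta[b.sl]
            fsd = np.sqrt(np.einsum("ij,jk,ik->i", b.basis,
                                    cov[b.sl, b.sl], b.basis))
            out["f_str"] = _summary_frame(np.arange(len(f)), f, fsd,
                                          {"p_positive": 1.0 - ndtr(-f / np.maximum(fsd, 1e-12))})
        elif b.kind == "iid":
            f = theta[b.sl]
            fsd = sd[b.sl]
            out[b.name] = _summary_frame(np.arange(len(f)), f, fsd,
                                         {"p_positive": 1.0 - ndtr(-f / np.maximum(fsd, 1e-12))})
    return out


def _summaries_from_draws(design: ModelDesign, theta_draws: np.ndarray,
                          var_draws: pd.DataFrame) -> dict:
    out = {}

    def frame(labels, mat, extra_ppos=False):
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1)
        lo, hi = np.percentile(mat, [2.5, 97.5], axis=0)
        df = pd.DataFrame({"term": labels, "mean": mean, "sd": sd,
                           "q2.5": lo, "q97.5": hi})
        if extra_ppos:
            df["p_positive"] = (mat > 0).mean(axis=0)
        return df

    b0 = design.block("fixed")
    out["fixed"] = frame(design.fixed_names, theta_draws[:, b0.sl])
    for b in design.blocks:
        if b.kind == "smooth":
            covn = b.name.split(":", 1)[1]
            mids = design.smooth_meta[covn]["midpoints"]
            f = theta_draws[:, b.sl] @ b.basis.T
            df = frame(mids, f)
            df = df.rename(columns={"term": "midpoint"})
            out[b.name] = df
        elif b.kind == "icar":
            f = theta_draws[:, b.sl] @ b.basis.T
            out["f_str"] = frame(np.arange(f.shape[1]), f, extra_ppos=True)
        elif b.kind == "iid":
            out[b.name] = frame(np.arange(b.size), theta_draws[:, b.sl],
                                extra_ppos=True)
    rows = []
    for nm in var_draws.columns:
        v = var_draws[nm].to_numpy()
        lo, hi = np.percentile(v, [2.5, 97.5])
        rows.append({"name": nm, "mean": v.mean(), "sd": v.std(ddof=1),
                     "q2.5": lo, "q97.5": hi})
    out["variances"] = pd.DataFrame(rows)
    return out


def fit(design: ModelDesign, engine: str = "approx", seed: int = 0,
        **engine_options) -> FitResult:
    """Fit the model and return posterior summaries.

    ``engine='approx'`` runs the Laplace / empirical-Bayes engine;
    ``engine='mcmc'`` runs the MCMC oracle (slower, used for validation).
    Both are deterministic given the seed.
    """
    if engine == "approx":
        return _fit_laplace(design, seed=seed, **engine_options)
    if engine == "mcmc":
        from .mcmc import mcmc_oracle

        opts = dict(iterations=60_000, burn_in=10_000)
        opts.update(engine_options)
        draws = mcmc_oracle(design, seed=seed, **opts)
        theta_draws = draws["theta"]
        var_draws = draws["variances"]
        summaries = _summaries_from_draws(design, theta_draws, var_draws)
        theta_mean = theta_draws.mean(axis=0)
        eta = design.A @ theta_mean
        return FitResult(
            engine="mcmc", spec=design.spec, summaries=summaries,
            fitted_probs=np.clip(expit(eta), 1e-12, 1 - 1e-12),
            variances={nm: float(var_draws[nm].mean()) for nm in var_draws},
            theta_mean=theta_mean, theta_cov=None, design=design,
            draws={"theta": theta_draws, "variances": var_draws},
            flags={"converged": bool(draws["diagnostics"]["rhat_max"] < 1.05)},
            meta={"seed": seed, **draws["diagnostics"]},
        )
    raise ValueError(f"unknown engine {engine!r}")


# ---------------------------------------------------------------------------
# Univariable screening
# ---------------------------------------------------------------------------

def _weighted_logit_wald(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted logit MLE with a pseudo-likelihood sandwich covariance.

    Survey weights act as likelihood multipliers; the sandwich meat uses the
    squared weighted scores, which keeps Wald tests calibrated under mean-one
    random weights (a plain information-based Wald would be anticonservative
    by a factor of E[w^2]/E[w]).
    """
    beta = np.zeros(X.shape[1])
    for _ in range(50):
        eta = X @ beta
        p = expit(eta)
        g = X.T @ (w * (y - p))
        d = w * p * (1 - p)
        H = (X * d[:, None]).T @ X
        H[np.diag_indices_from(H)] += 1e-10
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(X @ beta)
    d = w * p * (1 - p)
    bread = np.linalg.inv((X * d[:, None]).T @ X + 1e-10 * np.eye(X.shape[1]))
    score = X * (w * (y - p))[:, None]
    meat = score.T @ score
    V = bread @ meat @ bread
    se = np.sqrt(np.diag(V))
    z = beta / np.maximum(se, 1e-300)
    pvals = 2.0 * ndtr(-np.abs(z))
    return beta, se, pvals


def screen_univariable(
    children: pd.DataFrame,
    candidates: Sequence[str],
    alpha: float = 0.10,
    outcome: str = "ciaf",
    weight: str | None = "weight",
    full: bool = False,
):
    """Single-covariate weighted-logit screen at significance level alpha.

    A candidate is retained when any of its non-reference levels (or its
    slope, for a continuous covariate) is significant at ``alpha`` — the
    usual univariable pre-selection step before the multivariable model.
    Returns the included names (and a detail table with ``full=True``).
    """
    y = children[outcome].to_numpy(dtype=float)
    w = (children[weight].to_numpy(dtype=float)
         if weight and weight in children.columns else np.ones(len(children)))
    included, rows = [], []
    for cand in candidates:
        col = children[cand]
        is_cat = isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object
        if is_cat:
            cat = col.astype("category")
            if len(cat.cat.categories) < 2:
                warnings.warn(f"candidate {cand!r} has a single observed level; "
                              "excluded", stacklevel=2)
                rows.append({"candidate": cand, "min_p": np.nan,
                             "included": False})
                continue
            dummies = pd.get_dummies(cat, drop_first=True).to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(children)), dummies])
        else:
            x = col.to_numpy(dtype=float)
            if np.ptp(x) == 0:
                warnings.warn(f"candidate {cand!r} is constant; excluded",
                              stacklevel=2)
                rows.append({"candidate": cand, "min_p": np.nan,
                             "included": False})
                continue
            X = np.column_stack([np.ones(len(children)), x - x.mean()])
        _, _, pvals = _weighted_logit_wald(X, y, w)
        min_p = float(np.min(pvals[1:]))
        keep = min_p < alpha
        if keep:
            included.append(cand)
        rows.append({"candidate": cand, "min_p": min_p, "included": keep})
    if full:
        return included, pd.DataFrame(rows)
    return included


def posterior_or_table(fit_result: FitResult) -> pd.DataFrame:
    """Odds-ratio table: OR = exp(posterior mean), CrI = exp(2.5/97.5%).

    Reference levels are shown with OR 1.00 and no interval.
    """
    fx = fit_result.summaries["fixed"]
    rows = []
    refs = {term: ref for term, ref in fit_result.spec.fixed_terms}
    seen_terms = []
    for _, r in fx.iterrows():
        name = r["term"]
        if name == "intercept" or name.endswith("(linear)"):
            term, level = name, ""
        else:
            term, level = name.split(":", 1)
        if term in refs and term not in seen_terms:
            rows.append({"term": term, "level": refs[term], "OR": 1.0,
                         "q2.5": np.nan, "q97.5": np.nan, "reference": True})
            seen_terms.append(term)
        rows.append({"term": term, "level": level,
                     "OR": float(np.exp(r["mean"])),
                     "q2.5": float(np.exp(r["q2.5"])),
                     "q97.5": float(np.exp(r["q97.5"])),
                     "reference": False})
    return pd.DataFrame(rows)
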