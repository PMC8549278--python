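"""Design assembly and the joint log-density of the geo-additive logit model.

Three nested model classes share one linear predictor

    eta_i = beta0 + W_i beta + sum_l f_l(x_il) + f_str[zone_i] + f_unstr[zone_i]

with a survey-weighted Bernoulli-logit likelihood

    loglik = sum_i w_i * [ y_i eta_i - log(1 + exp(eta_i)) ].

GLMM keeps only the fixed part (plus an exchangeable zone effect), GAMM adds
the nonlinear terms, GGAMM adds the spatial pair.  Nonlinear effects are
piecewise-constant over covariate bins with a second-order random-walk (RW2)
prior on the bin effects; the structured spatial effect carries an intrinsic
CAR prior over the zone graph; the unstructured zone effect is exchangeable
normal.  All variance components get inverse-Gamma IG(a, b) hyperpriors,
a = b = 0.001 by default.

Identifiability: each smooth and the structured field are constrained to sum
to zero (per graph component for the field).  Internally every penalised
block is parametrised in the eigenbasis of its structure matrix with the
constant directions removed, so the constraints hold by construction and the
prior precision of the coordinates is diagonal.  The linear direction of each
RW2 nullspace is retained inside the smooth (flat prior), so fitted curves
carry their own trends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import gammaln

from .graphs import AdjacencyGraph, PrecisionMatrix, icar_precision, rw2_precision

__all__ = [
    "ModelSpec",
    "ModelDesign",
    "ParameterState",
    "bin_covariate",
    "build_design",
    "log_likelihood",
    "log_prior",
    "DEFAULT_HYPERPRIOR",
]

DEFAULT_HYPERPRIOR = (0.001, 0.001)

MODEL_CLASSES = ("GLMM", "GAMM", "GGAMM")


@dataclass
class ModelSpec:
    """Which terms the model contains and which hyperpriors the variances get."""

    model_class: str = "GGAMM"
    outcome: str = "ciaf"
    weight: str | None = "weight"
    fixed_terms: list = field(default_factory=list)       # (name, reference_level)
    linear_terms: list = field(default_factory=list)      # continuous, linear effect
    smooth_terms: list = field(default_factory=list)      # (covariate, n_bins)
    spatial: bool = True
    zone_random: bool = True
    separate_unstructured: bool = False  # keep U and f_unstr apart (weakly identified)
    hyperprior: dict = field(default_factory=dict)        # var name -> (a, b)

    def __post_init__(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"model_class must be one of {MODEL_CLASSES}")
        if self.model_class == "GLMM" and (self.smooth_terms or self.spatial):
            raise ValueError("a GLMM has no smooth or spatial terms")
        if self.model_class == "GAMM" and self.spatial:
            raise ValueError("a GAMM has no spatial term")
        if self.model_class == "GGAMM" and not self.spatial:
            raise ValueError("a GGAMM requires the spatial term")

    def hyper(self, var_name: str) -> tuple[float, float]:
        return tuple(self.hyperprior.get(var_name, DEFAULT_HYPERPRIOR))

    # -- convenience constructors -------------------------------------------
    @classmethod
    def glmm(cls, fixed_terms, linear_terms=(), **kw) -> "ModelSpec":
        return cls(model_class="GLMM", fixed_terms=list(fixed_terms),
                   linear_terms=list(linear_terms), smooth_terms=[],
                   spatial=False, **kw)

    @classmethod
    def gamm(cls, fixed_terms, smooth_terms, **kw) -> "ModelSpec":
        return cls(model_class="GAMM", fixed_terms=list(fixed_terms),
                   smooth_terms=list(smooth_terms), spatial=False, **kw)

    @classmethod
    def ggamm(cls, fixed_terms, smooth_terms, **kw) -> "ModelSpec":
        return cls(model_class="GGAMM", fixed_terms=list(fixed_terms),
                   smooth_terms=list(smooth_terms), spatial=True, **kw)

    @classmethod
    def from_yaml(cls, path_or_text: str) -> "ModelSpec":
        try:
            with open(path_or_text) as fh:
                raw = yaml.safe_load(fh)
        except (OSError, ValueError):
            raw = yaml.safe_load(path_or_text)
        kw = dict(raw)
        kw["fixed_terms"] = [tuple(t) for t in kw.get("fixed_terms", [])]
        kw["smooth_terms"] = [tuple(t) for t in kw.get("smooth_terms", [])]
        if "hyperprior" in kw:
            kw["hyperprior"] = {k: tuple(v) for k, v in kw["hyperprior"].items()}
        return cls(**kw)


def bin_covariate(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Map a continuous covariate to equally spaced bins.

    Integer-valued covariates with at most 60 distinct values get one bin per
    observed value (e.g. child age in months).  The top bin is right-closed so
    the maximum maps into the last bin.

    Returns (bin index per observation, bin midpoints).
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("covariate contains non-finite values")
    if n_bins < 3:
        raise ValueError("need at least 3 bins for an RW2 smooth")
    distinct = np.unique(v)
    if distinct.size < 2:
        raise ValueError("constant covariate: no smooth possible")
    if np.allclose(distinct, np.round(distinct)) and distinct.size <= 60:
        idx = np.searchsorted(distinct, v)
        return idx, distinct
    lo, hi = v.min(), v.max()
    width = (hi - lo) / n_bins
    idx = np.clip(((v - lo) / width).astype(int), 0, n_bins - 1)
    midpoints = lo + width * (np.arange(n_bins) + 0.5)
    return idx, midpoints


@dataclass
class LatentBlock:
    """One block of latent coordinates and its diagonal prior structure.

    ``basis`` maps coordinates to the natural-scale effect (bin effects, zone
    effects); ``prior_eigvals`` are the structure-matrix eigenvalues per
    coordinate (0 = flat direction, None = wholly flat fixed-effect block);
    the prior precision of the coordinates is diag(prior_eigvals) / variance.
    """

    name: str
    kind: str                   # 'fixed' | 'smooth' | 'icar' | 'iid'
    sl: slice
    var_name: str | None
    prior_eigvals: np.ndarray | None
    basis: np.ndarray | None    # natural_dim x block_dim

    @property
    def size(self) -> int:
        return self.sl.stop - self.sl.start

    @property
    def rank(self) -> int:
        if self.prior_eigvals is None:
            return 0
        return int(np.sum(self.prior_eigvals > 0))


@dataclass
class ModelDesign:
    """Analysis-ready design: latent-to-eta map plus all structure metadata."""

    A: np.ndarray               # n x dim latent design
    y: np.ndarray
    weights: np.ndarray
    blocks: list
    spec: ModelSpec
    fixed_names: list
    smooth_meta: dict           # covariate -> dict(idx, midpoints, K)
    zone_index: np.ndarray | None
    cluster_index: np.ndarray | None
    graph: AdjacencyGraph | None
    icar_struct: PrecisionMatrix | None

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def dim(self) -> int:
        return self.A.shape[1]

    @property
    def variance_names(self) -> list:
        return [b.var_name for b in self.blocks if b.var_name is not None]

    def block(self, name: str) -> LatentBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def eta(self, theta: np.ndarray) -> np.ndarray:
        return self.A @ theta


def _sumzero_basis(m: int) -> np.ndarray:
    """Orthonormal basis (m x m-1) of the complement of the constant vector."""
    q, _ = np.linalg.qr(np.eye(m) - np.full((m, m), 1.0 / m))
    # keep m-1 columns orthogonal to 1
    cols = [q[:, j] for j in range(m) if abs(q[:, j] @ np.ones(m)) < 1e-8]
    B = np.column_stack(cols[: m - 1])
    return B


def build_design(
    children: pd.DataFrame,
    spec: ModelSpec,
    graph: AdjacencyGraph | None = None,
    zone_col: str = "zone",
    cluster_col: str = "cluster",
) -> ModelDesign:
    """Assemble the latent design for a child table under a model spec."""
    n = len(children)
    y = children[spec.outcome].to_numpy(dtype=float)
    if spec.weight and spec.weight in children.columns:
        w = children[spec.weight].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("survey weights must be positive")
    else:
        w = np.ones(n)

    cols: list[np.ndarray] = [np.ones((n, 1))]
    fixed_names = ["intercept"]
    for term, ref in spec.fixed_terms:
        cat = children[term]
        if not isinstance(cat.dtype, pd.CategoricalDtype):
            # CSV round-trips turn string levels into numbers; compare as str
            cat = cat.astype(str).astype("category")
        levels = list(cat.cat.categories)
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not observed in {term!r}")
        codes = cat.cat.codes.to_numpy()
        for j, lev in enumerate(levels):
            if lev == ref:
                continue
            cols.append((codes == j).astype(float)[:, None])
            fixed_names.append(f"{term}:{lev}")
    for term in spec.linear_terms:
        x = children[term].to_numpy(dtype=float)
        cols.append((x - x.mean())[:, None])
        fixed_names.append(f"{term}(linear)")

    blocks: list[LatentBlock] = []
    pos = 0
    W = np.hstack(cols)
    blocks.append(LatentBlock("fixed", "fixed", slice(0, W.shape[1]),
                              None, None, None))
    pos = W.shape[1]
    parts = [W]

    smooth_meta: dict = {}
    for cov, n_bins in spec.smooth_terms:
        idx, mids = bin_covariate(children[cov].to_numpy(), n_bins)
        m = len(mids)
        K = rw2_precision(m)
        B = _sumzero_basis(m)
        M = B.T @ K.matrix.toarray() @ B
        lam, U = np.linalg.eigh(M)
        lam = np.where(lam > 1e-8 * max(lam.max(), 1.0), lam, 0.0)
        C = B @ U                                     # m x (m-1), sum-zero columns
        parts.append(C[idx, :])
        blocks.append(LatentBlock(f"smooth:{cov}", "smooth",
                                  slice(pos, pos + m - 1),
                                  f"tau2_{cov}", lam, C))
        pos += m - 1
        smooth_meta[cov] = {"idx": idx, "midpoints": mids, "K": K}

    zone_index = None
    icar_struct = None
    if spec.spatial or spec.zone_random:
        if graph is None:
            raise ValueError("spatial/zone terms need an adjacency graph")
        zone_index = children[zone_col].to_numpy(dtype=int)
        if zone_index.min() < 0 or zone_index.max() >= graph.n_zones:
            raise ValueError("zone index outside graph")

    if spec.spatial:
        icar_struct = icar_precision(graph)
        lam_s, V = icar_struct.positive_eigenpairs()
        parts.append(V[zone_index, :])
        blocks.append(LatentBlock("f_str", "icar",
                                  slice(pos, pos + len(lam_s)),
                                  "var_str", lam_s, V))
        pos += len(lam_s)

    if spec.zone_random or (spec.spatial and spec.separate_unstructured):
        nz = graph.n_zones
        Z = np.zeros((n, nz))
        Z[np.arange(n), zone_index] = 1.0
        parts.append(Z)
        blocks.append(LatentBlock("f_unstr", "iid", slice(pos, pos + nz),
                                  "var_unstr", np.ones(nz), np.eye(nz)))
        pos += nz
        if spec.spatial and spec.separate_unstructured and spec.zone_random:
            warnings.warn(
                "separate unstructured spatial and zone effects are "
                "indistinguishable at zone level; their variances are only "
                "jointly identified", stacklevel=2)
            parts.append(Z.copy())
            blocks.append(LatentBlock("zone_u", "iid", slice(pos, pos + nz),
                                      "var_u", np.ones(nz), np.eye(nz)))
            pos += nz

    A = np.hstack(parts)
    cluster_index = (children[cluster_col].to_numpy(dtype=int)
                     if cluster_col in children.columns else None)
    return ModelDesign(A=A, y=y, weights=w, blocks=blocks, spec=spec,
                       fixed_names=fixed_names, smooth_meta=smooth_meta,
                       zone_index=zone_index, cluster_index=cluster_index,
                       graph=graph, icar_struct=icar_struct)


@dataclass
class ParameterState:
    """Natural-scale parameter values: what the priors and reports refer to."""

    fixed: np.ndarray                       # intercept first, order of fixed_names
    smooths: dict = field(default_factory=dict)    # covariate -> bin-effect vector
    f_str: np.ndarray | None = None
    f_unstr: np.ndarray | None = None
    variances: dict = field(default_factory=dict)  # var name -> value

    @classmethod
    def from_coords(cls, design: ModelDesign, theta: np.ndarray,
                    variances: dict | None = None) -> "ParameterState":
        st = cls(fixed=theta[design.block("fixed").sl].copy(),
                 variances=dict(variances or {}))
        for b in design.blocks:
            if b.kind == "smooth":
                st.smooths[b.name.split(":", 1)[1]] = b.basis @ theta[b.sl]
            elif b.kind == "icar":
                st.f_str = b.basis @ theta[b.sl]
            elif b.kind == "iid" and b.name == "f_unstr":
                st.f_unstr = theta[b.sl].copy()
        return st

    def to_coords(self, design: ModelDesign) -> np.ndarray:
        theta = np.zeros(design.dim)
        theta[design.block("fixed").sl] = self.fixed
        for b in design.blocks:
            if b.kind == "smooth":
                f = self.smooths[b.name.split(":", 1)[1]]
                theta[b.sl] = b.basis.T @ f
            elif b.kind == "icar" and self.f_str is not None:
                theta[b.sl] = b.basis.T @ self.f_str
            elif b.kind == "iid" and b.name == "f_unstr" and self.f_unstr is not None:
                theta[b.sl] = self.f_unstr
        return theta


def _eta_from_state(design: ModelDesign, state: ParameterState) -> np.ndarray:
    eta = design.A[:, design.block("fixed").sl] @ state.fixed
    for cov, meta in design.smooth_meta.items():
        if cov in state.smooths:
            eta = eta + state.smooths[cov][meta["idx"]]
    if state.f_str is not None and design.zone_index is not None:
        eta = eta + state.f_str[design.zone_index]
    if state.f_unstr is not None and design.zone_index is not None:
        eta = eta + state.f_unstr[design.zone_index]
    return eta


def log_likelihood(design: ModelDesign, state: ParameterState) -> float:
    """Survey-weighted Bernoulli-logit log-likelihood; stable for |eta| ~ 700."""
    eta = _eta_from_state(design, state)
    if eta.shape != design.y.shape:
        raise ValueError("state dimensions do not match design")
    return float(np.sum(design.weights *
                        (design.y * eta - np.logaddexp(0.0, eta))))


def intrinsic_gaussian_logpdf(f: np.ndarray, struct: PrecisionMatrix,
                              variance: float) -> float:
    """Log-density of an intrinsic Gaussian with structure matrix K/variance.

    Defined on the span of K's positive eigenvectors; uses the rank-aware
    normaliser (product of nonzero eigenvalues), which is what lets the
    variance be learned.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    lam, V = struct.positive_eigenpairs()
    quad = float(f @ struct.matrix @ f)
    return float(0.5 * np.sum(np.log(lam / (2.0 * np.pi * variance)))
                 - 0.5 * quad / variance)


def invgamma_logpdf(x: float, a: float, b: float) -> float:
    if x <= 0:
        raise ValueError("inverse-Gamma support is positive")
    return float(a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(x) - b / x)


def log_prior(state: ParameterState, design: ModelDesign) -> float:
    """Joint log-prior: flat for fixed effects, RW2/ICAR/iid for the latent
    blocks, IG(a, b) for every variance component."""
    spec = design.spec
    total = 0.0  # flat prior on fixed effects contributes 0
    for cov, meta in design.smooth_meta.items():
        v = state.variances.get(f"tau2_{cov}")
        if v is None or v <= 0:
            raise ValueError(f"positive tau2_{cov} required")
        total += intrinsic_gaussian_logpdf(state.smooths[cov], meta["K"], v)
        total += invgamma_logpdf(v, *spec.hyper(f"tau2_{cov}"))
    if spec.spatial:
        v = state.variances.get("var_str")
        if v is None or v <= 0:
            raise ValueError("positive var_str required")
        total += intrinsic_gaussian_logpdf(state.f_str, design.icar_struct, v)
        total += invgamma_logpdf(v, *spec.hyper("var_str"))
    if state.f_unstr is not None:
        v = state.variances.get("var_unstr")
        if v is None or v <= 0:
            raise ValueError("positive var_unstr required")
        total += float(np.sum(-0.5 * state.f_unstr**2 / v
                              - 0.5 * np.log(2.0 * np.pi * v)))
        total += invgamma_logpdf(v, *spec.hyper("var_unstr"))
    return total
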