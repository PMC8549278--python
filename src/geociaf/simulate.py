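"""Synthetic studies with the statistical structure the geo-additive model assumes.

The generator emulates a national household survey of under-five children:
zones on a rectangular lattice with rook (shared-edge) adjacency, a
zero-centred intrinsic CAR spatial field plus exchangeable zone effects,
categorical fixed effects on the logit scale, nonlinear effects of child age
(steep rise then plateau) and maternal BMI (u-shaped), Gamma survey weights
with mean one, and trivariate anthropometric z-scores whose "any z < -2"
event reproduces each child's CIAF probability.

Ground-truth spatial variances default to pi^2_str = 0.22 and
pi^2_unstr = 0.055, a structured-to-unstructured ratio of four, which is the
regime the model-recovery checks in this package assume.

Everything is seeded: identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.special import expit

from .graphs import AdjacencyGraph, build_adjacency, icar_precision

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "make_zone_lattice",
    "lattice_polygons",
    "simulate_spatial_effects",
    "simulate_children",
    "simulate_anthropometry",
    "simulate_study",
]


def _age_effect(age_months: np.ndarray) -> np.ndarray:
    """Failure risk rises steeply over the first two years, then plateaus."""
    return 1.2 * (1.0 - np.exp(-np.asarray(age_months, dtype=float) / 15.0))

def _bmi_effect(bmi: np.ndarray) -> np.ndarray:
    """U-shape: children of very thin and obese mothers are at higher risk."""
    return 0.010 * (np.asarray(bmi, dtype=float) - 25.0) ** 2


DEFAULT_FIXED = {
    "intercept": 0.55,   # sets baseline CIAF prevalence near 45%
    "sex:female": -0.20,
    "residence:urban": -0.35,
    "wealth:poorer": -0.15,
    "wealth:middle": -0.30,
    "wealth:richer": -0.45,
    "wealth:richest": -0.70,
    "year:2005": -0.20,
    "year:2011": -0.45,
    "year:2016": -0.70,
}

CATEGORICAL_LEVELS = {
    "sex": (("male", "female"), (0.51, 0.49)),
    "residence": (("rural", "urban"), (0.75, 0.25)),
    "wealth": (("poorest", "poorer", "middle", "richer", "richest"),
               (0.2, 0.2, 0.2, 0.2, 0.2)),
    "year": (("2000", "2005", "2011", "2016"), (0.25, 0.25, 0.25, 0.25)),
}

CONTINUOUS_RANGES = {
    "age_months": (0, 59),     # integer months
    "maternal_bmi": (16.0, 34.0),
    "aridity": (0.0, 300.0),   # annual precipitation ratio index
}


@dataclass
class SimulationConfig:
    """Ground-truth configuration of one synthetic study."""

    lattice_rows: int = 4
    lattice_cols: int = 5
    n_children: int = 2000
    clusters_per_zone: int = 5
    fixed_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_FIXED))
    smooth_functions: dict = field(
        default_factory=lambda: {"age_months": _age_effect, "maternal_bmi": _bmi_effect}
    )
    var_structured: float = 0.22
    var_unstructured: float = 0.055
    weight_dispersion: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_rows * self.lattice_cols < 2:
            raise ValueError("lattice must have at least 2 zones")
        if self.n_children < self.lattice_rows * self.lattice_cols:
            raise ValueError("need at least one child per zone")
        for name, v in [("var_structured", self.var_structured),
                        ("var_unstructured", self.var_unstructured),
                        ("weight_dispersion", self.weight_dispersion)]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_zones(self) -> int:
        return self.lattice_rows * self.lattice_cols


@dataclass
class TruthRecord:
    """Everything the generator knew: the target of recovery checks."""

    config: SimulationConfig
    f_str: np.ndarray
    f_unstr: np.ndarray
    eta: np.ndarray
    prob: np.ndarray
    smooth_values: dict  # per smooth term, centred per-child true values

    def to_json(self, path=None) -> str | None:
        cfg = dataclasses.asdict(self.config)
        cfg.pop("smooth_functions")
        payload = {
            "config": cfg,
            "f_str": self.f_str.tolist(),
            "f_unstr": self.f_unstr.tolist(),
            "eta": self.eta.tolist(),
            "prob": self.prob.tolist(),
            "smooth_values": {k: v.tolist() for k, v in self.smooth_values.items()},
        }
        text = json.dumps(payload)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def make_zone_lattice(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-adjacency lattice of rows x cols zones, ids in row-major order."""
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be positive")
    edges = []
    for r in range(rows):
        for c in range(cols):
            z = r * cols + c
            if c + 1 < cols:
                edges.append((z, z + 1))
            if r + 1 < rows:
                edges.append((z, z + cols))
    return build_adjacency(edges, n_zones=rows * cols)


def lattice_polygons(rows: int, cols: int) -> dict:
    """Unit-square GeoJSON FeatureCollection matching make_zone_lattice ids."""
    feats = []
    for r in range(rows):
        for c in range(cols):
            ring = [[c, r], [c + 1, r], [c + 1, r + 1], [c, r + 1], [c, r]]
            feats.append({
                "type": "Feature",
                "properties": {"zone_id": r * cols + c},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            })
    return {"type": "FeatureCollection", "features": feats}


def simulate_spatial_effects(
    graph: AdjacencyGraph,
    var_str: float,
    var_unstr: float,
    seed: int,
    size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the structured (intrinsic CAR) and unstructured zone effects.

    The structured field is sampled exactly in the eigenbasis of Q with the
    zero-eigenvalue (per-component constant) directions removed, so each draw
    sums to zero within every connected component.  ``size`` asks for that
    many replicate draws (arrays of shape (size, n_zones)).
    """
    if var_str < 0 or var_unstr < 0:
        raise ValueError("variances must be non-negative")
    rng = np.random.default_rng(seed)
    n = graph.n_zones
    shape = (n,) if size is None else (size, n)

    if var_str == 0 or graph.n_edges == 0:
        f_str = np.zeros(shape)
    else:
        Q = icar_precision(graph)
        lam, vecs = Q.positive_eigenpairs()
        k = len(lam)
        cshape = (k,) if size is None else (size, k)
        coords = rng.standard_normal(cshape) * np.sqrt(var_str / lam)
        f_str = coords @ vecs.T
    f_unstr = rng.standard_normal(shape) * np.sqrt(var_unstr)
    return f_str, f_unstr


def simulate_children(
    config: SimulationConfig,
    graph: AdjacencyGraph,
    f_str: np.ndarray | None = None,
    f_unstr: np.ndarray | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate the child table: covariates, zone/cluster ids, outcome, weight.

    ``f_str`` / ``f_unstr`` override the drawn spatial fields (planted-signal
    experiments); by default both are drawn from their priors.
    """
    if graph.n_zones != config.n_zones:
        raise ValueError("graph size does not match config lattice")
    rng = np.random.default_rng(config.seed)
    n = config.n_children

    f_str_draw, f_unstr_draw = simulate_spatial_effects(
        graph, config.var_structured, config.var_unstructured,
        seed=int(rng.integers(2**31)),
    )
    f_str = f_str_draw if f_str is None else np.asarray(f_str, dtype=float)
    f_unstr = f_unstr_draw if f_unstr is None else np.asarray(f_unstr, dtype=float)

    zone = rng.integers(0, config.n_zones, size=n)
    cluster = zone * config.clusters_per_zone + rng.integers(
        0, config.clusters_per_zone, size=n
    )

    table = pd.DataFrame({"zone": zone, "cluster": cluster})
    eta = np.full(n, config.fixed_coefficients.get("intercept", 0.0))

    for cov, (levels, probs) in CATEGORICAL_LEVELS.items():
        draw = rng.choice(len(levels), size=n, p=probs)
        table[cov] = pd.Categorical.from_codes(draw, categories=list(levels))
        for j, lev in enumerate(levels[1:], start=1):
            beta = config.fixed_coefficients.get(f"{cov}:{lev}", 0.0)
            eta += beta * (draw == j)

    lo, hi = CONTINUOUS_RANGES["age_months"]
    table["age_months"] = rng.integers(lo, hi + 1, size=n)
    for cov in ("maternal_bmi", "aridity"):
        lo, hi = CONTINUOUS_RANGES[cov]
        table[cov] = rng.uniform(lo, hi, size=n)

    smooth_values = {}
    for cov, fn in config.smooth_functions.items():
        raw = np.asarray(fn(table[cov].to_numpy()), dtype=float)
        centred = raw - raw.mean()  # identifiable part; intercept soaks the mean
        smooth_values[cov] = centred
        eta += centred

    eta += f_str[zone] + f_unstr[zone]
    prob = expit(eta)
    table["ciaf"] = rng.binomial(1, prob)

    if config.weight_dispersion == 0:
        table["weight"] = 1.0
    else:
        shape_k = 1.0 / config.weight_dispersion
        table["weight"] = rng.gamma(shape=shape_k, scale=1.0 / shape_k, size=n)

    truth = TruthRecord(
        config=config, f_str=f_str, f_unstr=f_unstr, eta=eta, prob=prob,
        smooth_values=smooth_values,
    )
    return table, truth


# correlation of (HAZ, WAZ, WHZ): underweight correlates with both stunting
# and wasting; stunting and wasting are only weakly related
_Z_CORR = np.array([
    [1.00, 0.65, 0.15],
    [0.65, 1.00, 0.65],
    [0.15, 0.65, 1.00],
])


def _shift_for_probability() -> PchipInterpolator:
    """Monotone map p(any z < -2) -> common mean shift mu, by root bracketing.

    For mean vector mu*1 and correlation _Z_CORR, the no-failure probability
    is the Gaussian orthant P(all z >= -2) = Phi_R(2 + mu, 2 + mu, 2 + mu).
    """
    mvn = stats.multivariate_normal(mean=np.zeros(3), cov=_Z_CORR)

    def fail_prob(mu: float) -> float:
        # P(all >= -2 | mean mu) = P(all <= 2 + mu) for a centred symmetric normal
        return 1.0 - float(mvn.cdf(np.repeat(2.0 + mu, 3)))

    mus = np.linspace(8.0, -8.0, 161)        # fail prob increases as mu falls
    ps = np.array([fail_prob(m) for m in mus])
    ps = np.maximum.accumulate(ps)           # clean quadrature noise
    keep = np.concatenate([[True], np.diff(ps) > 1e-14])
    return PchipInterpolator(ps[keep], mus[keep])


_SHIFT_INTERP: PchipInterpolator | None = None


def _prob_to_shift(p: np.ndarray) -> np.ndarray:
    global _SHIFT_INTERP
    if _SHIFT_INTERP is None:
        _SHIFT_INTERP = _shift_for_probability()
    lo, hi = _SHIFT_INTERP.x[0], _SHIFT_INTERP.x[-1]
    return np.asarray(_SHIFT_INTERP(np.clip(p, lo, hi)), dtype=float)


def simulate_anthropometry(
    children: pd.DataFrame,
    truth: TruthRecord,
    seed: int,
    max_rounds: int = 500,
) -> pd.DataFrame:
    """Attach (haz, waz, whz) z-scores consistent with the binary outcomes.

    The mean shift of the trivariate normal is calibrated so the marginal
    probability of any z-score below -2 equals each child's CIAF probability;
    draws are then rejection-sampled to agree with the child's simulated
    binary outcome, so the classifier reproduces the outcome exactly while
    the z-score marginals stay calibrated.
    """
    if truth is None or truth.prob is None:
        raise ValueError("truth record with outcome probabilities is required")
    n = len(children)
    if len(truth.prob) != n:
        raise ValueError("truth does not match the child table")
    rng = np.random.default_rng(seed)
    mu = _prob_to_shift(truth.prob)
    L = np.linalg.cholesky(_Z_CORR)
    y = children["ciaf"].to_numpy()

    z = np.empty((n, 3))
    todo = np.arange(n)
    for _ in range(max_rounds):
        if todo.size == 0:
            break
        draw = rng.standard_normal((todo.size, 3)) @ L.T + mu[todo, None]
        z[todo] = draw
        failed = (draw < -2).any(axis=1).astype(int)
        todo = todo[failed != y[todo]]
    if todo.size:
        # vanishing-probability stragglers: nudge across the boundary
        for i in todo:
            if y[i] == 1:
                j = int(np.argmin(z[i]))
                z[i, j] = -2.0 - abs(z[i, j] + 2.0) - 1e-6
            else:
                z[i] = np.maximum(z[i], -1.999)

    out = children.copy()
    out["haz"], out["waz"], out["whz"] = z[:, 0], z[:, 1], z[:, 2]
    return out


def simulate_study(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, AdjacencyGraph, TruthRecord]:
    """Lattice + children + anthropometry in one seeded call."""
    graph = make_zone_lattice(config.lattice_rows, config.lattice_cols)
    children, truth = simulate_children(config, graph)
    children = simulate_anthropometry(
        children, truth, seed=np.random.default_rng(config.seed + 1).integers(2**31)
    )
    return children, graph, truth
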