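"""Design assembly, likelihood and prior of the geo-additive logit model."""

import numpy as np
import pytest

import geociaf as g
from geociaf.model import (ParameterState, intrinsic_gaussian_logpdf,
                           invgamma_logpdf)
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_bin_integer_covariate_identity():
    values = np.arange(60)
    idx, mids = g.bin_covariate(values, n_bins=10)
    np.testing.assert_array_equal(idx, values)
    np.testing.assert_array_equal(mids, values)


def test_bin_uniform_covariate():
    values = np.array([0.05, 0.95, 0.0, 1.0])
    idx, mids = g.bin_covariate(values, n_bins=10)
    assert idx.tolist() == [0, 9, 0, 9]     # max maps into the last bin
    assert len(mids) == 10
    np.testing.assert_allclose(mids[0], 0.05)
    assert np.all(np.diff(mids) > 0)


def test_bin_rejects_bad_input():
    with pytest.raises(ValueError):
        g.bin_covariate(np.ones(10), n_bins=5)       # constant
    with pytest.raises(ValueError):
        g.bin_covariate(np.arange(10.0), n_bins=2)   # too few bins
    with pytest.raises(ValueError):
        g.bin_covariate(np.array([0.0, np.nan]), n_bins=5)


# ---------------------------------------------------------------------------
# spec validation
# ---------------------------------------------------------------------------

def test_model_class_constraints():
    with pytest.raises(ValueError):
        g.ModelSpec(model_class="GLMM", smooth_terms=[("age_months", 10)],
                    spatial=False)
    with pytest.raises(ValueError):
        g.ModelSpec(model_class="GAMM", spatial=True)
    with pytest.raises(ValueError):
        g.ModelSpec(model_class="GGAMM", spatial=False)


def test_spec_yaml_roundtrip():
    text = """
model_class: GGAMM
outcome: ciaf
fixed_terms: [[sex, male], [wealth, poorest]]
smooth_terms: [[age_months, 60]]
spatial: true
zone_random: true
hyperprior: {var_str: [0.5, 0.0005]}
"""
    spec = g.ModelSpec.from_yaml(text)
    assert spec.fixed_terms == [("sex", "male"), ("wealth", "poorest")]
    assert spec.hyper("var_str") == (0.5, 0.0005)
    assert spec.hyper("var_unstr") == (0.001, 0.001)   # default


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_design(small_study_module=None):
    cfg = g.SimulationConfig(n_children=50, seed=21)
    children, graph, _ = g.simulate_study(cfg)
    spec = g.ModelSpec.ggamm(fixed_terms=[("sex", "male")],
                             smooth_terms=[("maternal_bmi", 6)])
    return g.build_design(children, spec, graph)


def zero_state(design):
    st = ParameterState(fixed=np.zeros(len(design.fixed_names)))
    for cov, meta in design.smooth_meta.items():
        st.smooths[cov] = np.zeros(len(meta["midpoints"]))
    if design.spec.spatial:
        st.f_str = np.zeros(design.graph.n_zones)
    st.f_unstr = np.zeros(design.graph.n_zones)
    st.variances = {nm: 1.0 for nm in design.variance_names}
    return st


def test_loglik_all_zero_parameters(tiny_design):
    """eta = 0 means p = 1/2 for everyone: loglik = -sum(w) log 2."""
    st = zero_state(tiny_design)
    expected = -np.sum(tiny_design.weights) * np.log(2.0)
    assert g.log_likelihood(tiny_design, st) == pytest.approx(expected)


def test_loglik_single_observation_hand_value():
    import pandas as pd
    children = pd.DataFrame({"ciaf": [1], "weight": [2.0]})
    spec = g.ModelSpec(model_class="GLMM", spatial=False, zone_random=False)
    design = g.build_design(children, spec)
    st = ParameterState(fixed=np.array([np.log(3.0)]))  # p = 0.75
    assert g.log_likelihood(design, st) == pytest.approx(2 * np.log(0.75))


def test_loglik_saturation_stable(tiny_design):
    st = zero_state(tiny_design)
    st.fixed[0] = 700.0
    val = g.log_likelihood(tiny_design, st)
    assert np.isfinite(val)
    st.fixed[0] = -700.0
    assert np.isfinite(g.log_likelihood(tiny_design, st))


def test_loglik_dimension_mismatch(tiny_design):
    st = zero_state(tiny_design)
    st.smooths["maternal_bmi"] = np.zeros(3)   # wrong bin count
    with pytest.raises((ValueError, IndexError)):
        g.log_likelihood(tiny_design, st)


# ---------------------------------------------------------------------------
# prior
# ---------------------------------------------------------------------------

def test_invgamma_hand_value():
    a = b = 0.001
    expected = a * np.log(b) - gammaln(a) - (a + 1) * np.log(1.0) - b
    assert invgamma_logpdf(1.0, a, b) == pytest.approx(expected)
    with pytest.raises(ValueError):
        invgamma_logpdf(-1.0, a, b)


def test_rw2_prior_linear_sequence_only_normalizer():
    """A linear bin sequence has zero RW2 penalty: density = normaliser."""
    K = g.rw2_precision(8)
    lin = np.linspace(-2, 2, 8)
    assert intrinsic_gaussian_logpdf(lin, K, 1.3) == pytest.approx(
        intrinsic_gaussian_logpdf(np.zeros(8), K, 1.3))


def test_intrinsic_density_matches_eigen_oracle():
    """Rank-aware ICAR density equals the product of eigen-direction normals."""
    rng = np.random.default_rng(3)
    graph = g.make_zone_lattice(2, 3)
    Q = g.icar_precision(graph)
    lam, V = Q.positive_eigenpairs()
    var = 0.7
    coords = rng.standard_normal(len(lam))
    f = V @ coords
    oracle = np.sum(-0.5 * np.log(2 * np.pi * var / lam)
                    - 0.5 * lam * coords**2 / var)
    assert intrinsic_gaussian_logpdf(f, Q, var) == pytest.approx(oracle)
    # doubling the variance changes the density as the eigen-oracle says
    d1 = intrinsic_gaussian_logpdf(f, Q, 2 * var)
    oracle2 = np.sum(-0.5 * np.log(4 * np.pi * var / lam)
                     - 0.25 * lam * coords**2 / var)
    assert d1 == pytest.approx(oracle2)


def test_log_prior_requires_positive_variances(tiny_design):
    st = zero_state(tiny_design)
    st.variances["var_str"] = 0.0
    with pytest.raises(ValueError):
        g.log_prior(st, tiny_design)


def test_nesting_ggamm_reduces_to_glmm():
    """With smooths and spatial terms zeroed, the GGAMM likelihood equals the
    GLMM likelihood on the shared fixed effects."""
    cfg = g.SimulationConfig(n_children=300, seed=22)
    children, graph, _ = g.simulate_study(cfg)
    fixed = [("sex", "male"), ("wealth", "poorest")]
    d_glmm = g.build_design(
        children, g.ModelSpec(model_class="GLMM", fixed_terms=fixed,
                              spatial=False, zone_random=True), graph)
    d_ggamm = g.build_design(
        children, g.ModelSpec.ggamm(fixed, [("maternal_bmi", 8)]), graph)

    beta = np.array([0.2, -0.4, 0.1, 0.0, 0.3, -0.2])  # intercept + 5 levels
    st_glmm = zero_state(d_glmm)
    st_glmm.fixed = beta
    st_ggamm = zero_state(d_ggamm)
    st_ggamm.fixed = beta
    assert g.log_likelihood(d_ggamm, st_ggamm) == pytest.approx(
        g.log_likelihood(d_glmm, st_glmm))


def test_joint_density_concave_in_latent(tiny_design):
    """Directional second differences of loglik + prior quad are <= 0."""
    rng = np.random.default_rng(4)
    design = tiny_design
    variances = {nm: 0.5 for nm in design.variance_names}

    def joint(theta):
        st = ParameterState.from_coords(design, theta, variances)
        return g.log_likelihood(design, st) + g.log_prior(st, design)

    for _ in range(10):
        theta = rng.standard_normal(design.dim) * 0.5
        direction = rng.standard_normal(design.dim)
        h = 1e-3
        second = joint(theta + h * direction) - 2 * joint(theta) + \
            joint(theta - h * direction)
        assert second <= 1e-6


def test_state_coordinate_roundtrip(tiny_design):
    rng = np.random.default_rng(6)
    theta = rng.standard_normal(tiny_design.dim)
    st = ParameterState.from_coords(tiny_design, theta, {"var_str": 1.0})
    # smooth vectors satisfy the sum-to-zero constraint by construction
    for f in st.smooths.values():
        assert abs(f.sum()) < 1e-8
    assert abs(st.f_str.sum()) < 1e-8
    back = st.to_coords(tiny_design)
    np.testing.assert_allclose(back, theta, atol=1e-10)
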