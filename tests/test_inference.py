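"""Laplace engine, MCMC oracle internals, screening and OR tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import geociaf as g
from geociaf.inference import FitResult, _weighted_logit_wald
from geociaf.mcmc import draw_variance, ess, split_rhat


# ---------------------------------------------------------------------------
# Laplace engine basics
# ---------------------------------------------------------------------------

def test_intercept_only_symmetric_data():
    """1000 obs, 500 successes, flat prior: beta0 within +-0.07 of 0."""
    children = pd.DataFrame({"ciaf": np.repeat([0, 1], 500)})
    spec = g.ModelSpec(model_class="GLMM", spatial=False, zone_random=False,
                       weight=None)
    fr = g.fit(g.build_design(children, spec), seed=0)
    assert abs(fr.summaries["fixed"]["mean"].iloc[0]) < 0.07
    assert np.all((fr.fitted_probs > 0) & (fr.fitted_probs < 1))


def test_single_binary_covariate_recovers_or_two():
    """Generating odds ratio 2: exp(posterior mean) within 10%."""
    cfg = g.SimulationConfig(
        n_children=20_000, seed=30,
        fixed_coefficients={"intercept": -0.5, "sex:female": np.log(2.0)},
        smooth_functions={}, var_structured=0.0, var_unstructured=0.0,
        weight_dispersion=0.0)
    children, _ = g.simulate_children(
        cfg, g.make_zone_lattice(cfg.lattice_rows, cfg.lattice_cols))
    spec = g.ModelSpec(model_class="GLMM", fixed_terms=[("sex", "male")],
                       spatial=False, zone_random=False, weight=None)
    fr = g.fit(g.build_design(children, spec), seed=1)
    beta = fr.summaries["fixed"].set_index("term").loc["sex:female", "mean"]
    assert np.exp(beta) == pytest.approx(2.0, rel=0.10)


def test_fit_deterministic_given_seed(small_study, default_spec):
    _, children, graph, _ = small_study
    design = g.build_design(children, default_spec, graph)
    f1 = g.fit(design, seed=5)
    f2 = g.fit(design, seed=5)
    np.testing.assert_array_equal(f1.theta_mean, f2.theta_mean)
    pd.testing.assert_frame_equal(f1.summaries["variances"],
                                  f2.summaries["variances"])


def test_separation_warns_but_returns():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 2, size=200)
    children = pd.DataFrame({"ciaf": x, "group": np.where(x == 1, "b", "a")})
    spec = g.ModelSpec(model_class="GLMM", fixed_terms=[("group", "a")],
                       spatial=False, zone_random=False, weight=None)
    with pytest.warns(UserWarning, match="separation"):
        fr = g.fit(g.build_design(children, spec), seed=0)
    assert fr.flags.get("separation") is True


def test_quantile_ordering_and_fit_sections(small_fit):
    for name, df in small_fit.summaries.items():
        assert (df["q2.5"] <= df["q97.5"]).all(), name
    assert {"fixed", "smooth:age_months", "smooth:maternal_bmi", "f_str",
            "f_unstr", "variances"} <= set(small_fit.summaries)


# ---------------------------------------------------------------------------
# MCMC oracle internals
# ---------------------------------------------------------------------------

def test_variance_gibbs_matches_conjugate_posterior():
    """KS test of IG(a + rank/2, b + quad/2) draws at alpha = 0.01."""
    rng = np.random.default_rng(7)
    a, b, rank, quad = 2.0, 1.5, 10, 4.0
    draws = np.array([draw_variance(rng, a, b, rank, quad)
                      for _ in range(5000)])
    target = stats.invgamma(a + rank / 2, scale=b + quad / 2)
    assert stats.kstest(draws, target.cdf).pvalue > 0.01


def test_zero_data_posterior_equals_prior():
    """With no observations the smooth-variance draws reproduce IG(a, b)."""
    cfg = g.SimulationConfig(n_children=100, seed=31)
    children, graph, _ = g.simulate_study(cfg)
    a, b = 3.0, 2.0      # finite mean b/(a-1)=1 and variance 1
    spec = g.ModelSpec(model_class="GAMM", smooth_terms=[("maternal_bmi", 8)],
                       spatial=False, zone_random=False,
                       hyperprior={"tau2_maternal_bmi": (a, b)})
    design = g.build_design(children, spec, graph)
    design.A = design.A[:0]
    design.y = design.y[:0]
    design.weights = design.weights[:0]
    out = g.mcmc_oracle(design, iterations=30_000, burn_in=2_000, seed=8)
    v = out["variances"]["tau2_maternal_bmi"].to_numpy()
    assert v.mean() == pytest.approx(b / (a - 1), rel=0.10)
    assert np.median(v) == pytest.approx(
        stats.invgamma(a, scale=b).median(), rel=0.10)


def test_mcmc_chain_agreement_between_seeds():
    """Two seeds on the same data: fixed-effect means within 3 combined MCSE."""
    cfg = g.SimulationConfig(
        lattice_rows=1, lattice_cols=4, n_children=150, seed=32,
        fixed_coefficients={"intercept": 0.3, "sex:female": -0.5},
        smooth_functions={})
    children, graph, _ = g.simulate_study(cfg)
    spec = g.ModelSpec.ggamm(fixed_terms=[("sex", "male")], smooth_terms=[])
    design = g.build_design(children, spec, graph)
    runs = [g.mcmc_oracle(design, iterations=30_000, burn_in=5_000, seed=s)
            for s in (1, 2)]
    sl = design.block("fixed").sl
    for j in range(sl.start, sl.stop):
        chains = [r["theta"][:, j] for r in runs]
        means = [c.mean() for c in chains]
        mcse = [c.std(ddof=1) / np.sqrt(max(ess(c), 1.0)) for c in chains]
        combined = np.sqrt(mcse[0] ** 2 + mcse[1] ** 2)
        assert abs(means[0] - means[1]) < 3 * combined


def test_mcmc_argument_validation(small_study, default_spec):
    _, children, graph, _ = small_study
    design = g.build_design(children, default_spec, graph)
    with pytest.raises(ValueError):
        g.mcmc_oracle(design, iterations=100, burn_in=100, seed=0)


def test_ess_and_rhat_sanity():
    rng = np.random.default_rng(9)
    iid = rng.standard_normal(4000)
    assert ess(iid) > 2000
    assert split_rhat(iid) < 1.02
    trending = np.linspace(0, 5, 4000) + rng.standard_normal(4000) * 0.1
    assert split_rhat(trending) > 1.5


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def test_weighted_logit_matches_expanded_data_mle():
    """Integer frequency weights: coefficients agree with an expanded fit."""
    rng = np.random.default_rng(10)
    n = 400
    x = rng.integers(0, 2, n).astype(float)
    y = rng.binomial(1, expit(-0.3 + 0.8 * x))
    w = rng.integers(1, 4, n).astype(float)
    X = np.column_stack([np.ones(n), x])
    beta, _, _ = _weighted_logit_wald(X, y, w)
    # oracle: replicate each row w times, unweighted MLE
    reps = np.repeat(np.arange(n), w.astype(int))
    from scipy.optimize import minimize

    def nll(b):
        eta = X[reps] @ b
        return -np.sum(y[reps] * eta - np.logaddexp(0, eta))

    oracle = minimize(nll, np.zeros(2), method="BFGS").x
    np.testing.assert_allclose(beta, oracle, atol=1e-4)


def test_screening_power_and_contract():
    cfg = g.SimulationConfig(n_children=5000, seed=33)
    children, _ = g.simulate_children(
        cfg, g.make_zone_lattice(cfg.lattice_rows, cfg.lattice_cols))
    included, table = g.screen_univariable(
        children, ["wealth", "sex", "aridity"], full=True)
    assert "wealth" in included          # strong generating gradient
    assert set(table["candidate"]) == {"wealth", "sex", "aridity"}

    assert g.screen_univariable(children, []) == []

    children["onelevel"] = "only"
    with pytest.warns(UserWarning, match="single observed level"):
        inc = g.screen_univariable(children, ["onelevel"])
    assert inc == []


# ---------------------------------------------------------------------------
# OR table
# ---------------------------------------------------------------------------

def _fake_fit(term_names, means, sds, fixed_terms):
    fx = pd.DataFrame({"term": term_names, "mean": means, "sd": sds})
    fx["q2.5"] = fx["mean"] - 1.96 * fx["sd"]
    fx["q97.5"] = fx["mean"] + 1.96 * fx["sd"]
    spec = g.ModelSpec(model_class="GLMM", fixed_terms=fixed_terms,
                       spatial=False, zone_random=False)
    return FitResult(engine="approx", spec=spec, summaries={"fixed": fx},
                     fitted_probs=np.array([0.5]), variances={},
                     theta_mean=np.asarray(means), theta_cov=None, design=None)


def test_or_table_identity_and_reference():
    fr = _fake_fit(["intercept", "sex:female"], [0.1, 0.0], [0.1, 0.05],
                   [("sex", "male")])
    tab = g.posterior_or_table(fr)
    ref = tab[tab["reference"]]
    assert list(ref["level"]) == ["male"] and float(ref["OR"].iloc[0]) == 1.0
    female = tab[(tab["term"] == "sex") & (tab["level"] == "female")]
    assert float(female["OR"].iloc[0]) == pytest.approx(1.0)


def test_or_table_from_constructed_draws():
    """beta draws around log 2: OR CrI brackets 2 and excludes 1."""
    rng = np.random.default_rng(11)
    draws = np.log(2.0) + 0.05 * rng.standard_normal(4000)
    mean, sd = draws.mean(), draws.std(ddof=1)
    fr = _fake_fit(["intercept", "sex:female"], [0.0, mean], [0.1, sd],
                   [("sex", "male")])
    tab = g.posterior_or_table(fr).set_index("level")
    assert tab.loc["female", "q2.5"] < 2.0 < tab.loc["female", "q97.5"]
    assert tab.loc["female", "q2.5"] > 1.0
    assert tab.loc["female", "OR"] == pytest.approx(np.exp(mean))


# ---------------------------------------------------------------------------
# spatial field recovery (structured-to-unstructured ratio 4)
# ---------------------------------------------------------------------------

def test_structured_field_recovery_large_study():
    """Posterior mean of f_str correlates >= 0.7 with the generating field
    when var_str/var_unstr = 4 on a 10x10 lattice with n = 10,000."""
    cfg = g.SimulationConfig(
        lattice_rows=10, lattice_cols=10, n_children=10_000, seed=34,
        fixed_coefficients={"intercept": 0.2, "sex:female": -0.2},
        smooth_functions={}, var_structured=0.4, var_unstructured=0.1)
    children, graph, truth = g.simulate_study(cfg)
    spec = g.ModelSpec.ggamm(fixed_terms=[("sex", "male")], smooth_terms=[])
    design = g.build_design(children, spec, graph)
    fr = g.fit(design, seed=3, grid_size=9, refine_size=9, passes=1)
    est = fr.summaries["f_str"]["mean"].to_numpy()
    corr = np.corrcoef(est, truth.f_str)[0, 1]
    assert corr >= 0.7
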