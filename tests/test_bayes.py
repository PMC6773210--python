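"""Bayesian model family: likelihood modes, samplers, and summaries.

Independent oracles: numerical quadrature for the censored likelihood, a
dense 2-D grid for the intercept-only posterior, order statistics for
interval endpoints, and explicit hand arithmetic for Bayesian R².
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from looktimes import (
    GeneratorConfig,
    ModelSpec,
    bayes_r2,
    log_likelihood,
    posterior_predictive_cells,
    sample_posterior,
    simulate_experiment,
    summarize,
    within_subject_difference,
)
from looktimes.bayes import PosteriorFit, default_priors
from looktimes.design import (
    ContrastScheme,
    ContrastTerm,
    build_contrast_scheme,
    build_design_matrix,
    cell_code_row,
)

from conftest import make_trials


INTERCEPT_SCHEME = ContrastScheme(
    scope="single_experiment",
    terms=(ContrastTerm("(Intercept)", "intercept"),),
    bases={},
)


def _toy_trials(seed=5, n_subj=5, mu=3.6, sigma=0.45):
    """Small trial table with a few ceiling-censored rows."""
    rng = np.random.default_rng(seed)
    t = np.exp(mu + sigma * rng.standard_normal(2 * n_subj))
    cens = t >= 60.0
    t = np.minimum(t, 60.0)
    entries = []
    for i in range(n_subj):
        entries.append((f"s{i}", "congruent", "one_change_first",
                        {"one_change": t[2 * i], "two_change": t[2 * i + 1]}))
    return make_trials(entries)


def test_integrated_equals_none_without_censoring():
    trials = _toy_trials(seed=1)
    trials = trials[~trials["censored"]]
    # rebuild as full subjects only
    keep = trials.groupby("subject_id")["trial_type"].transform("count") == 2
    trials = trials[keep]
    params = {"beta": np.array([3.5]), "sigma_obs": 0.5}
    ll_none = log_likelihood(
        params, trials,
        ModelSpec(censoring="none", scheme=INTERCEPT_SCHEME, random_intercepts=False))
    ll_int = log_likelihood(
        params, trials,
        ModelSpec(censoring="integrated", scheme=INTERCEPT_SCHEME,
                  random_intercepts=False))
    assert ll_int == pytest.approx(ll_none, rel=1e-12)


def test_censored_row_at_its_mean_contributes_log_half():
    # one censored row with linear predictor exactly at the limit: the
    # upper-tail probability is 1/2 regardless of sigma
    trials = make_trials([("s0", "congruent", "one_change_first",
                           {"one_change": 30.0, "two_change": 60.0})])
    for sigma in (0.2, 0.7):
        spec = ModelSpec(censoring="integrated", scheme=INTERCEPT_SCHEME,
                         random_intercepts=False)
        params = {"beta": np.array([math.log(60.0)]), "sigma_obs": sigma}
        ll = log_likelihood(params, trials, spec)
        uncens = (stats.norm.logpdf(math.log(30.0), math.log(60.0), sigma)
                  - math.log(30.0))
        assert ll - uncens == pytest.approx(math.log(0.5), abs=1e-12)


def test_integrated_matches_quadrature_of_latent_density():
    trials = _toy_trials(seed=5)
    assert trials["censored"].sum() >= 2
    spec = ModelSpec(censoring="integrated", scheme=INTERCEPT_SCHEME,
                     random_intercepts=False)
    beta, sigma = np.array([3.55]), 0.5
    ll_int = log_likelihood({"beta": beta, "sigma_obs": sigma}, trials, spec)
    # oracle: uncensored Gaussian terms plus quadrature of the latent-mode
    # density over each censored coordinate above the limit
    z = np.log(trials["looking_s"].to_numpy())
    cens = trials["censored"].to_numpy()
    ll_oracle = float(
        (stats.norm.logpdf(z[~cens], beta[0], sigma) - z[~cens]).sum()
    )
    for _ in range(cens.sum()):
        val, err = integrate.quad(
            lambda v: stats.norm.pdf(v, beta[0], sigma),
            math.log(60.0), beta[0] + 12 * sigma)
        ll_oracle += math.log(val)
    assert ll_int == pytest.approx(ll_oracle, rel=1e-6)


def test_lognormal_rejects_nonpositive_times():
    trials = _toy_trials(seed=1)
    trials.loc[trials.index[0], "looking_s"] = -1.0
    with pytest.raises(ValueError, match="positive"):
        log_likelihood({"beta": np.array([3.5]), "sigma_obs": 0.5}, trials,
                       ModelSpec(censoring="none", scheme=INTERCEPT_SCHEME,
                                 random_intercepts=False))


def test_latent_values_must_respect_support():
    trials = _toy_trials(seed=5)
    m = int(trials["censored"].sum())
    spec = ModelSpec(censoring="latent", scheme=INTERCEPT_SCHEME,
                     random_intercepts=False)
    with pytest.raises(ValueError, match="above the limit"):
        log_likelihood({"beta": np.array([3.5]), "sigma_obs": 0.5,
                        "latent": np.full(m, 1.0)}, trials, spec)


def test_intercept_only_posterior_matches_grid_quadrature_oracle():
    trials = _toy_trials(seed=5, n_subj=7)
    spec = ModelSpec(censoring="latent", scheme=INTERCEPT_SCHEME,
                     random_intercepts=False)
    fit = sample_posterior(spec, trials, n_chains=4, n_draws=2000,
                           n_warmup=500, seed=2)
    # dense grid over (intercept, log sigma) with the same priors
    z = np.log(trials["looking_s"].to_numpy())
    cens = trials["censored"].to_numpy()
    B = math.log(60.0)
    b_grid = np.linspace(2.0, 5.5, 401)
    ls_grid = np.linspace(-3.0, 1.5, 401)
    Bg, Lg = np.meshgrid(b_grid, ls_grid, indexing="ij")
    sg = np.exp(Lg)
    ll = np.zeros_like(Bg)
    for i in range(len(z)):
        if cens[i]:
            ll += stats.norm.logsf(B, Bg, sg)
        else:
            ll += stats.norm.logpdf(z[i], Bg, sg)
    pr = default_priors("lognormal")
    lp = (ll - 0.5 * ((Bg - pr.intercept_loc) / pr.intercept_scale) ** 2
          - 0.5 * sg**2 / pr.sigma_obs_scale**2 + Lg)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    e_b, e_s = float((w * Bg).sum()), float((w * sg).sum())
    assert fit.flat("beta").mean() == pytest.approx(e_b, abs=0.02)
    assert fit.flat("sigma_obs").mean() == pytest.approx(e_s, abs=0.02)


def _dummy_fit(beta_draws, sigma_draws, X, spec=None, u_draws=None,
               sigma_u_draws=None, cells=None, term_names=None):
    draws = {"beta": beta_draws, "sigma_obs": sigma_draws}
    if u_draws is not None:
        draws["u"] = u_draws
        draws["sigma_subject"] = sigma_u_draws
    p = beta_draws.shape[-1]
    return PosteriorFit(
        spec=spec or ModelSpec(censoring="none", scheme=INTERCEPT_SCHEME,
                               random_intercepts=False),
        draws=draws,
        term_names=term_names or tuple(f"b{j}" for j in range(p)),
        subject_ids=np.array([]),
        censored_rows=np.array([], dtype=int),
        cells=cells or [],
        X=X,
        subj_idx=np.zeros(X.shape[0], dtype=int),
        design=None,
        diagnostics=pd.DataFrame(),
        convergence_warnings=[],
        seed=0,
        n_chains=beta_draws.shape[0],
    )


def test_summarize_symmetric_draws_and_quantile_oracle():
    beta = np.array([-1.0, 0.0, 1.0]).reshape(1, 3, 1)
    fit = _dummy_fit(beta, np.ones((1, 3)), np.ones((2, 1)))
    summ = summarize(fit, levels=(90, 95))
    row = summ.table.iloc[0]
    assert row["median"] == 0.0
    assert not row["credible_90"] and not row["credible_95"]
    # endpoints equal order-statistics interpolation on the raw draw array
    rng = np.random.default_rng(0)
    draws = rng.normal(size=(2, 500, 1))
    fit2 = _dummy_fit(draws, np.ones((2, 500)), np.ones((2, 1)))
    summ2 = summarize(fit2, levels=(95,))
    flat = np.sort(draws.reshape(-1))
    n = flat.size

    def quantile_os(q):
        h = (n - 1) * q
        lo = int(math.floor(h))
        return flat[lo] + (h - lo) * (flat[min(lo + 1, n - 1)] - flat[lo])

    assert summ2.table["lower_95"].iloc[0] == pytest.approx(quantile_os(0.025))
    assert summ2.table["upper_95"].iloc[0] == pytest.approx(quantile_os(0.975))


def test_summary_has_thirteen_terms_for_single_scheme(study_trials):
    spec = ModelSpec(likelihood="lognormal", censoring="latent")
    fit = sample_posterior(spec, study_trials, n_chains=2, n_draws=300,
                           n_warmup=200, seed=3, check_convergence=False)
    summ = summarize(fit)
    assert len(summ.table) == 13
    assert list(summ.table.index) == list(
        build_contrast_scheme("single_experiment").term_names)
    # latent censored draws respect the support constraint
    if "latent" in fit.draws:
        assert (fit.flat("latent") >= math.log(60.0) - 1e-12).all()


def test_bayes_r2_single_draw_hand_computed():
    X = np.column_stack([np.ones(5), np.array([-2.0, -1.0, 0.0, 1.0, 2.0])])
    beta = np.array([[[1.0, 0.5]]])           # one chain, one draw
    sigma = np.array([[2.0]])
    fit = _dummy_fit(beta, sigma, X)
    # linear predictor: 1 + 0.5*x -> values (0, .5, 1, 1.5, 2), var = 0.5
    r2 = bayes_r2(fit)
    assert r2.shape == (1,)
    assert r2[0] == pytest.approx(0.5 / (0.5 + 4.0))


def test_bayes_r2_noiseless_limit():
    cfg = GeneratorConfig(sigma_obs=1e-3, sigma_subject=0.0, coder_sd_s=0.0,
                          n_per_cell=2, seed=5)
    trials = simulate_experiment(cfg)
    spec = ModelSpec(censoring="none")
    fit = sample_posterior(spec, trials, n_chains=2, n_draws=400, n_warmup=300,
                           seed=6, check_convergence=False)
    assert np.median(bayes_r2(fit)) >= 0.99


def test_bayes_r2_null_data_near_zero():
    cfg = GeneratorConfig(beta={"(Intercept)": math.log(30.0)},
                          sigma_subject=0.0, coder_sd_s=0.0, n_per_cell=16,
                          seed=7)
    trials = simulate_experiment(cfg)
    spec = ModelSpec(censoring="none", scheme=INTERCEPT_SCHEME,
                     random_intercepts=False)
    fit = sample_posterior(spec, trials, n_chains=2, n_draws=400, n_warmup=300,
                           seed=8, check_convergence=False)
    assert np.median(bayes_r2(fit)) <= 0.05


@pytest.fixture(scope="module")
def small_fit(study_trials):
    spec = ModelSpec(likelihood="lognormal", censoring="latent")
    return sample_posterior(spec, study_trials, n_chains=2, n_draws=500,
                            n_warmup=300, seed=9, check_convergence=False)


def test_predictive_respects_censor_limit(small_fit):
    pred = posterior_predictive_cells(small_fit, seed=0)
    assert (pred["upper_95"] <= 60.0 + 1e-9).all()
    assert len(pred) == 12


def test_predictive_median_tracks_intercept_for_intercept_only_model():
    cfg = GeneratorConfig(beta={"(Intercept)": math.log(25.0)},
                          sigma_subject=0.2, sigma_obs=0.3, coder_sd_s=0.0,
                          n_per_cell=16, seed=10)
    trials = simulate_experiment(cfg)
    spec = ModelSpec(censoring="none", scheme=INTERCEPT_SCHEME)
    fit = sample_posterior(spec, trials, n_chains=2, n_draws=600, n_warmup=300,
                           seed=11, check_convergence=False)
    pred = posterior_predictive_cells(fit, seed=1)
    med_intercept = float(np.median(fit.flat("beta")[:, 0]))
    np.testing.assert_allclose(pred["median"], math.exp(med_intercept), rtol=0.06)


def test_within_subject_difference_structure_and_two_routes(small_fit):
    diffs = within_subject_difference(small_fit)
    keys = sorted(diffs)
    assert keys == sorted(
        ("brightness", c, f)
        for c in ("congruent", "incongruent", "shape_change")
        for f in ("one_change_first", "two_change_first"))
    # independent route: contrast of cell-mean draws built from code rows
    beta = small_fit.flat("beta")
    scheme = small_fit.design.scheme
    for (exp, cond, ft), d in diffs.items():
        r2 = cell_code_row(scheme, condition=cond, trial_type="two_change",
                           first_test=ft, experiment=exp)
        r1 = cell_code_row(scheme, condition=cond, trial_type="one_change",
                           first_test=ft, experiment=exp)
        np.testing.assert_allclose(d["log"], beta @ (r2 - r1), atol=1e-12)


def test_zero_trial_type_coefficients_center_differences_at_zero():
    p = 13
    scheme = build_contrast_scheme("single_experiment")
    rng = np.random.default_rng(1)
    beta = np.zeros((1, 200, p))
    beta[:, :, 0] = 3.4 + 0.05 * rng.standard_normal(200)   # intercept only
    cells = [("brightness", c, f, t)
             for c in ("congruent", "incongruent", "shape_change")
             for f in ("one_change_first", "two_change_first")
             for t in ("one_change", "two_change")]
    fit = _dummy_fit(beta, np.full((1, 200), 0.4), np.ones((2, p)),
                     spec=ModelSpec(censoring="none", scheme=scheme),
                     cells=cells, term_names=scheme.term_names)
    fit.design = type("D", (), {"scheme": scheme})()
    diffs = within_subject_difference(fit)
    for d in diffs.values():
        np.testing.assert_allclose(d["log"], 0.0, atol=1e-12)
        np.testing.assert_allclose(d["seconds"], 0.0, atol=1e-9)


def test_sampler_deterministic_given_seed(study_trials):
    spec = ModelSpec(likelihood="lognormal", censoring="latent")
    f1 = sample_posterior(spec, study_trials, n_chains=2, n_draws=100,
                          n_warmup=100, seed=42, check_convergence=False)
    f2 = sample_posterior(spec, study_trials, n_chains=2, n_draws=100,
                          n_warmup=100, seed=42, check_convergence=False)
    np.testing.assert_array_equal(f1.draws["beta"], f2.draws["beta"])


def test_censored_and_uncensored_fits_converge_as_limit_grows(study_trials):
    # with no rows at the ceiling, the latent-censoring model reduces to the
    # uncensored one on the same data
    uncensored = study_trials.copy()
    uncensored["censored"] = False
    spec_cens = ModelSpec(likelihood="lognormal", censoring="latent")
    spec_none = ModelSpec(likelihood="lognormal", censoring="none")
    f1 = sample_posterior(spec_cens, uncensored, n_chains=2, n_draws=500,
                          n_warmup=300, seed=13, check_convergence=False)
    f2 = sample_posterior(spec_none, uncensored, n_chains=2, n_draws=500,
                          n_warmup=300, seed=13, check_convergence=False)
    gap = np.abs(np.median(f1.flat("beta"), axis=0)
                 - np.median(f2.flat("beta"), axis=0))
    assert gap.max() < 0.05
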