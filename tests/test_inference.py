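import copy

import numpy as np
import pytest
from scipy import stats

from spathaz.core_data import AdjacencyGraph, SurvivalDataset
from spathaz.gmrf_priors import PriorConfig
from spathaz.hazard_models import ModelSpec
from spathaz.inference import (
    MCMCControl,
    compute_dic,
    compute_waic,
    effective_sample_size,
    exceedance_probability,
    run_mcmc,
    split_rhat,
    summarize_fit,
)
from spathaz.synthetic_data import SimulationConfig, simulate_dataset


def _binary_covariate_dataset(n=2000, beta0=-6.2, beta1=0.7, seed=0):
    """Exponential survival with one binary covariate and uniform censoring."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    lam = np.exp(beta0 + beta1 * x)
    t = rng.exponential(1.0, n) / lam
    c = rng.uniform(0, 60, n)
    y, d = np.minimum(t, c), (t <= c).astype(int)
    g = AdjacencyGraph.from_edges(["A", "B"], [("A", "B")])
    ds = SurvivalDataset(
        time=y,
        event=d,
        region_idx=np.zeros(n, dtype=int),
        graph=g,
        X=np.column_stack([np.ones(n), x.astype(float)]),
        x_names=["intercept", "x"],
        horizon=60.0,
    )
    return ds, (beta0, beta1)


@pytest.fixture(scope="module")
def small_fit():
    """One short lognormal fit reused by the summary-level tests."""
    ds, truth = simulate_dataset(SimulationConfig(n_children=600, seed=2))
    model = ModelSpec("lognormal")
    ctrl = MCMCControl(n_iter=1500, burn_in=0.4, thin=3, chains=2, seed=5)
    samples = run_mcmc(ds, model, PriorConfig(), ctrl)
    return ds, truth, model, samples


# --------------------------------------------------------------------------
# sampler
# --------------------------------------------------------------------------


def test_exponential_posterior_matches_closed_form_mle():
    """No random effects: the posterior mean of each log-rate coefficient
    sits within 3 posterior sd of the censored-exponential MLE
    (group deaths over group exposure)."""
    ds, (b0, b1) = _binary_covariate_dataset()
    x = ds.X[:, 1]
    mle0 = np.log(ds.event[x == 0].sum() / ds.time[x == 0].sum())
    mle1 = np.log(ds.event[x == 1].sum() / ds.time[x == 1].sum()) - mle0
    model = ModelSpec("exponential", include_nonlinear=False, include_spatial=False)
    ctrl = MCMCControl(n_iter=4000, burn_in=0.5, thin=2, chains=2, seed=3)
    samples = run_mcmc(ds, model, PriorConfig(), ctrl)
    flat = samples.flat("beta")
    for j, mle in enumerate([mle0, mle1]):
        mean, sd = flat[:, j].mean(), flat[:, j].std()
        assert abs(mean - mle) < 3 * sd


def test_identical_seed_identical_draws():
    ds, _ = simulate_dataset(SimulationConfig(n_children=300, seed=8))
    model = ModelSpec("lognormal")
    ctrl = MCMCControl(n_iter=600, burn_in=0.5, thin=2, chains=2, seed=11)
    s1 = run_mcmc(ds, model, PriorConfig(), ctrl)
    s2 = run_mcmc(ds, model, PriorConfig(), ctrl)
    for k in s1.draws:
        assert np.array_equal(s1.draws[k], s2.draws[k]), k


def test_kept_draws_respect_constraints(small_fit):
    """Sum-to-zero holds for every kept spatial and nonlinear draw."""
    _, _, _, samples = small_fit
    assert np.abs(samples.flat("theta").sum(axis=1)).max() < 1e-8
    assert np.abs(samples.flat("psi").sum(axis=1)).max() < 1e-8
    assert np.all(samples.flat("tau") > 0)


def test_acceptance_rates_reported():
    ds, _ = simulate_dataset(SimulationConfig(n_children=300, family="weibull", seed=1))
    model = ModelSpec("weibull")
    ctrl = MCMCControl(n_iter=2000, burn_in=0.5, thin=5, chains=1, seed=2)
    samples = run_mcmc(ds, model, PriorConfig(), ctrl)
    for name in ("beta", "psi", "theta", "alpha"):
        assert 0.05 < samples.acceptance_rates[name] < 0.7, name


# --------------------------------------------------------------------------
# DIC / WAIC
# --------------------------------------------------------------------------


def test_dic_degenerate_posterior(small_fit):
    ds, _, model, samples = small_fit
    frozen = copy.deepcopy(samples)
    for k in frozen.draws:
        chains, kept, dim = frozen.draws[k].shape
        frozen.draws[k] = np.tile(frozen.draws[k][:1, :1, :], (chains, kept, 1))
    state = {
        k: (frozen.flat(k)[0] if frozen.draws[k].shape[-1] > 1 else float(frozen.flat(k)[0, 0]))
        for k in frozen.draws
    }
    state["beta"] = np.atleast_1d(state["beta"])
    from spathaz.inference import _Sampler

    ll = float(_Sampler(ds, model, PriorConfig(), MCMCControl(n_iter=2)).pointwise(state).sum())
    frozen.loglik = np.full_like(frozen.loglik, ll)
    dic, p_d = compute_dic(frozen, ds, model)
    assert p_d == pytest.approx(0.0, abs=1e-6)
    assert dic == pytest.approx(-2 * ll, abs=1e-6)


def test_dic_ignores_parameter_outside_likelihood(small_fit):
    ds, _, model, samples = small_fit
    dic, _ = compute_dic(samples, ds, model)
    augmented = copy.deepcopy(samples)
    augmented.draws["unused"] = np.ones_like(augmented.draws["tau"])
    dic2, _ = compute_dic(augmented, ds, model)
    assert dic2 == pytest.approx(dic, abs=1e-9)


def test_dic_effective_parameters_near_model_size():
    """Intercept-only exponential fit: p_D close to the single free parameter."""
    ds, _ = _binary_covariate_dataset(n=1500, beta1=0.0, seed=4)
    ds_int = SurvivalDataset(
        time=ds.time,
        event=ds.event,
        region_idx=ds.region_idx,
        graph=ds.graph,
        X=ds.X[:, :1],
        x_names=["intercept"],
        horizon=60.0,
    )
    model = ModelSpec("exponential", include_nonlinear=False, include_spatial=False)
    ctrl = MCMCControl(n_iter=4000, burn_in=0.5, thin=2, chains=2, seed=9)
    samples = run_mcmc(ds_int, model, PriorConfig(), ctrl)
    _, p_d = compute_dic(samples, ds_int, model)
    assert 0.3 < p_d < 3.0


def test_waic_degenerate_and_permutation_invariance():
    rng = np.random.default_rng(0)
    pw = np.tile(rng.uniform(-3, -1, 50), (200, 1))
    waic, p = compute_waic(pw)
    assert p == pytest.approx(0.0, abs=1e-12)
    assert waic == pytest.approx(-2 * pw[0].sum(), abs=1e-9)
    pw2 = rng.normal(-2, 0.1, size=(200, 50))
    w_a, _ = compute_waic(pw2)
    w_b, _ = compute_waic(pw2[rng.permutation(200)])
    assert w_a == pytest.approx(w_b, abs=1e-9)


def test_waic_warns_on_unstable_terms():
    rng = np.random.default_rng(1)
    pw = rng.normal(-2, 2.0, size=(100, 10))  # per-child variance ~4 > 0.4
    with pytest.warns(UserWarning, match="unstable"):
        compute_waic(pw)


# --------------------------------------------------------------------------
# exceedance probabilities
# --------------------------------------------------------------------------


def test_exceedance_trivial_cases():
    draws = -np.abs(np.random.default_rng(0).normal(1, 0.1, (10_000, 3)))
    assert np.allclose(exceedance_probability(draws), 1.0)
    sym = np.random.default_rng(1).normal(0, 1, (10_000, 1))
    p = exceedance_probability(sym)[0]
    assert abs(p - 0.5) < 3 * np.sqrt(0.25 / 10_000)


def test_exceedance_normal_oracle():
    rng = np.random.default_rng(7)
    draws = rng.normal(0.3, 1.0, (10_000, 1))
    p = exceedance_probability(draws)[0]
    target = stats.norm.cdf(-0.3)
    mc_se = np.sqrt(target * (1 - target) / 10_000)
    assert abs(p - target) <= 1.5 * mc_se


def test_exceedance_resamples_small_draws():
    draws = np.random.default_rng(2).normal(0, 1, (500, 2))
    with pytest.warns(UserWarning, match="resampling"):
        p = exceedance_probability(draws, rng=3)
    assert p.shape == (2,)


def test_exceedance_rejects_empty():
    with pytest.raises(ValueError):
        exceedance_probability(np.empty((0, 3)))


# --------------------------------------------------------------------------
# summaries and diagnostics
# --------------------------------------------------------------------------


def test_summary_quantiles_match_sorting_oracle(small_fit):
    ds, _, model, samples = small_fit
    res = summarize_fit(samples, ds, model)
    flat = samples.flat("beta")[:, 0]
    srt = np.sort(flat)

    def q(p):
        return np.quantile(srt, p)

    row = res.fixed_effects.iloc[0]
    assert row["q2.5"] == pytest.approx(q(0.025), abs=1e-9)
    assert row["q97.5"] == pytest.approx(q(0.975), abs=1e-9)
    assert row["mean"] == pytest.approx(flat.mean(), abs=1e-9)
    assert np.all(res.fixed_effects["q2.5"] <= res.fixed_effects["mean"])
    assert np.all(res.fixed_effects["mean"] <= res.fixed_effects["q97.5"])


def test_significance_flag_is_zero_exclusion(small_fit):
    ds, _, model, samples = small_fit
    res = summarize_fit(samples, ds, model)
    for _, row in res.fixed_effects.iterrows():
        assert row["significant"] == (row["q2.5"] > 0 or row["q97.5"] < 0)


def test_nonlinear_reported_on_age_scale(small_fit):
    ds, _, model, samples = small_fit
    res = summarize_fit(samples, ds, model)
    ages = res.nonlinear["maternal_age"].astype(int).to_numpy()
    assert ages[0] == 15 and ages[-1] == 49 and len(ages) == 35


def test_exceedance_table_covers_all_regions(small_fit):
    ds, _, model, samples = small_fit
    res = summarize_fit(samples, ds, model)
    assert len(res.exceedance) == ds.n_regions
    assert set(res.exceedance["region"]) == set(ds.graph.labels)
    assert res.exceedance["prob_theta_lt_0"].between(0, 1).all()
    assert "higher mortality risk" in res.direction_note


def test_split_rhat_behaviour():
    rng = np.random.default_rng(0)
    same = rng.normal(0, 1, (2, 2000))
    assert split_rhat(same) < 1.05
    shifted = np.stack([rng.normal(0, 1, 2000), rng.normal(3, 1, 2000)])
    assert split_rhat(shifted) > 1.5


def test_effective_sample_size_iid_vs_correlated():
    rng = np.random.default_rng(3)
    iid = rng.normal(size=(2, 1500))
    assert effective_sample_size(iid) > 1500
    walk = np.cumsum(rng.normal(size=(2, 1500)), axis=1)
    assert effective_sample_size(walk) < 300


def test_rhat_cross_checked_with_arviz(small_fit):
    """Our split-R-hat agrees with the reference implementation."""
    az = pytest.importorskip("arviz")
    _, _, _, samples = small_fit
    trace = samples.draws["beta"][:, :, 0]
    ours = split_rhat(trace)
    theirs = float(np.ravel(az.rhat(az.convert_to_dataset(trace[:, :, None]))["x"].values)[0])
    assert ours == pytest.approx(theirs, abs=0.05)


def test_exceedance_sharpens_with_sample_size():
    """For a region with a strongly adverse spatial effect, the posterior
    exceedance probability pi(theta < 0 | y) approaches 1 as the cohort
    grows (nondecreasing over n in {500, 2000, 8000})."""
    probs = []
    for n in (500, 2000, 8000):
        ds, truth = simulate_dataset(
            SimulationConfig(n_children=n, tau_theta_true=0.25, seed=31)
        )
        worst = int(np.argmin(truth["theta"]))
        assert truth["theta"][worst] < -1.0  # genuinely elevated-risk region
        ctrl = MCMCControl(n_iter=1500, burn_in=0.4, thin=2, chains=1, seed=3)
        s = run_mcmc(ds, ModelSpec("lognormal"), PriorConfig(), ctrl)
        probs.append(exceedance_probability(s.flat("theta"), rng=0)[worst])
    assert probs[0] <= probs[1] + 0.05 and probs[1] <= probs[2] + 0.05
    assert probs[-1] > 0.9


def test_prior_sampling_mode_runs():
    """likelihood_scale=0 turns the sampler into a prior sampler; the
    fixed-effect block then reproduces its N(0, 100 I) prior moments."""
    ds, _ = simulate_dataset(SimulationConfig(n_children=50, seed=0))
    model = ModelSpec("lognormal", include_nonlinear=False, include_spatial=False)
    ctrl = MCMCControl(
        n_iter=6000, burn_in=0.3, thin=2, chains=2, seed=1, likelihood_scale=0.0,
        store_pointwise=False,
    )
    samples = run_mcmc(ds, model, PriorConfig(), ctrl)
    flat = samples.flat("beta")
    ess = max(effective_sample_size(samples.draws["beta"][:, :, 0]), 10)
    se_mean = 10.0 / np.sqrt(ess)
    assert abs(flat[:, 0].mean()) < 3 * se_mean
    assert abs(flat[:, 0].var() - 100.0) < 3 * 100.0 * np.sqrt(2.0 / ess)
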