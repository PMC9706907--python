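import numpy as np
import pytest
from scipy import integrate, stats

from spathaz.core_data import AdjacencyGraph, SurvivalDataset
from spathaz.hazard_models import (
    BaselineSpec,
    FamilyParams,
    ModelSpec,
    censored_loglik,
    cox_baseline,
    family_hazard,
    family_log_density,
    family_log_survival,
    link_forward,
    link_inverse,
    pointwise_censored_loglik,
)


# --------------------------------------------------------------------------
# densities, survivals, hazards
# --------------------------------------------------------------------------


def test_exponential_values():
    fp = FamilyParams("exponential", lam=1.0)
    assert family_log_density(fp, np.array([1.0]))[0] == pytest.approx(-1.0)
    fp2 = FamilyParams("exponential", lam=2.0)
    assert family_log_survival(fp2, np.array([3.0]))[0] == pytest.approx(-6.0)
    h = family_hazard(fp2, np.array([0.5, 5.0, 50.0]))
    assert np.allclose(h, 2.0)  # constant in y


def test_gamma_shape_one_reduces_to_exponential():
    y = np.linspace(0.1, 50, 23)
    mu = 2.5
    gam = FamilyParams("gamma", mu=mu, s_phi=1.0)
    exp_ = FamilyParams("exponential", lam=1 / mu)
    assert np.allclose(family_log_density(gam, y), family_log_density(exp_, y), atol=1e-12)
    assert np.allclose(family_log_survival(gam, y), family_log_survival(exp_, y), atol=1e-10)


def test_weibull_shape_one_reduces_to_exponential():
    y = np.linspace(0.1, 50, 23)
    wb = FamilyParams("weibull", lam=0.3, alpha=1.0)
    exp_ = FamilyParams("exponential", lam=0.3)
    assert np.allclose(family_log_density(wb, y), family_log_density(exp_, y), atol=1e-12)


def test_weibull_hazard_value():
    fp = FamilyParams("weibull", lam=1.0, alpha=2.0)
    assert family_hazard(fp, np.array([3.0]))[0] == pytest.approx(6.0)


def test_lognormal_matches_scipy():
    """Independent parameterization check: log y ~ N(mu, 1/tau) equals
    scipy's lognorm(s=1/sqrt(tau), scale=exp(mu))."""
    mu, tau = 1.3, 0.7
    fp = FamilyParams("lognormal", mu=mu, tau=tau)
    dist = stats.lognorm(s=1 / np.sqrt(tau), scale=np.exp(mu))
    y = np.array([0.2, 1.0, 5.0, 40.0])
    assert np.allclose(family_log_density(fp, y), dist.logpdf(y), atol=1e-10)
    assert np.allclose(family_log_survival(fp, y), dist.logsf(y), atol=1e-10)


@pytest.mark.parametrize(
    "fp",
    [
        FamilyParams("gamma", mu=2.0, s_phi=3.0),
        FamilyParams("gamma", mu=10.0, s_phi=0.5),
        FamilyParams("lognormal", mu=0.0, tau=1.0),
        FamilyParams("lognormal", mu=3.0, tau=0.2),
    ],
)
def test_log_survival_against_quadrature(fp):
    """Gamma and lognormal log-survival agree with adaptive quadrature of
    the printed density to 1e-8."""
    for y in (0.5, 1.0, 2.0, 8.0, 30.0):
        ref, _ = integrate.quad(
            lambda x: np.exp(family_log_density(fp, np.array([x]))[0]),
            y,
            np.inf,
            limit=200,
            epsabs=1e-300,  # the tail integral itself can be ~1e-17
            epsrel=1e-12,
        )
        assert family_log_survival(fp, np.array([y]))[0] == pytest.approx(
            np.log(ref), abs=1e-8
        )


@pytest.mark.parametrize(
    "fp",
    [
        FamilyParams("exponential", lam=0.7),
        FamilyParams("gamma", mu=2.0, s_phi=3.0),
        FamilyParams("weibull", lam=0.4, alpha=1.7),
        FamilyParams("lognormal", mu=0.5, tau=0.8),
    ],
)
def test_survival_equals_density_over_hazard(fp):
    """S = f / h identity, to 1e-10 where all three are defined."""
    y = np.linspace(0.2, 20, 40)
    s = np.exp(family_log_survival(fp, y))
    ratio = np.exp(family_log_density(fp, y)) / family_hazard(fp, y)
    assert np.allclose(s, ratio, atol=1e-10)


@pytest.mark.parametrize(
    "fp",
    [
        FamilyParams("exponential", lam=0.7),
        FamilyParams("gamma", mu=2.0, s_phi=3.0),
        FamilyParams("weibull", lam=0.4, alpha=1.7),
        FamilyParams("lognormal", mu=0.5, tau=0.8),
    ],
)
def test_hazard_is_derivative_of_cum_hazard(fp):
    """d/dy[-log S(y)] = h(y) by central differences on a grid."""
    y = np.linspace(0.5, 15, 30)
    h_eps = 1e-5
    num = -(
        family_log_survival(fp, y + h_eps) - family_log_survival(fp, y - h_eps)
    ) / (2 * h_eps)
    assert np.allclose(num, family_hazard(fp, y), atol=1e-6, rtol=1e-5)


def test_lognormal_hazard_nonmonotone():
    """Lognormal hazard rises then falls (mu=0, tau=1), cross-checked
    against quadrature-based f/S."""
    fp = FamilyParams("lognormal", mu=0.0, tau=1.0)
    y = np.linspace(0.05, 30, 300)
    h = family_hazard(fp, y)
    d = np.diff(h)
    assert d[0] > 0 and d[-1] < 0  # one sign change: up then down
    peak = np.argmax(h)
    y0 = y[peak]
    s_ref, _ = integrate.quad(
        lambda x: np.exp(family_log_density(fp, np.array([x]))[0]), y0, np.inf
    )
    assert h[peak] == pytest.approx(
        np.exp(family_log_density(fp, np.array([y0]))[0]) / s_ref, rel=1e-6
    )


def test_deep_tail_stays_finite():
    fp = FamilyParams("gamma", mu=0.5, s_phi=2.0)
    ls = family_log_survival(fp, np.array([500.0, 5000.0]))
    assert np.all(np.isfinite(ls)) and np.all(ls < -100)


def test_link_round_trip():
    for fam, val in [("exponential", 0.37), ("gamma", 5.2), ("weibull", 1.1),
                     ("lognormal", -2.0), ("cox", 0.8)]:
        assert link_inverse(fam, link_forward(fam, np.array(val))) == pytest.approx(val)


def test_lognormal_survival_increases_with_eta():
    """Identity-link location contract: larger eta means larger S(y) at
    every y (higher effect = lower hazard)."""
    y = np.linspace(0.2, 59, 25)
    s_lo = family_log_survival(FamilyParams("lognormal", mu=0.5, tau=0.3), y)
    s_hi = family_log_survival(FamilyParams("lognormal", mu=1.5, tau=0.3), y)
    assert np.all(s_hi > s_lo)


# --------------------------------------------------------------------------
# cox baseline
# --------------------------------------------------------------------------


def test_cox_baseline_hand_integral():
    base = BaselineSpec(np.array([0.0, 1.0, 2.0]), np.log([1.0, 2.0]))
    h0, H0 = cox_baseline(np.array([1.5]), base)
    assert h0[0] == pytest.approx(2.0)
    assert H0[0] == pytest.approx(1.0 * 1.0 + 0.5 * 2.0)


def test_cox_single_interval_is_exponential():
    base = BaselineSpec(np.array([0.0, 60.0]), np.array([np.log(0.1)]))
    fp = FamilyParams("cox", mu=0.3, baseline=base)
    exp_ = FamilyParams("exponential", lam=0.1 * np.exp(0.3))
    y = np.linspace(0.5, 59, 17)
    assert np.allclose(family_log_survival(fp, y), family_log_survival(exp_, y), atol=1e-12)
    assert np.allclose(family_log_density(fp, y), family_log_density(exp_, y), atol=1e-12)


def test_cox_cum_baseline_continuous_increasing():
    base = BaselineSpec(np.array([0.0, 5.0, 20.0, 60.0]), np.log([0.2, 0.05, 0.01]))
    t = np.linspace(0.01, 60, 500)
    _, H0 = cox_baseline(t, base)
    assert np.all(np.diff(H0) > 0)
    for bp in (5.0, 20.0):  # continuity at the breakpoints
        _, lo = cox_baseline(np.array([bp - 1e-9]), base)
        _, hi = cox_baseline(np.array([bp + 1e-9]), base)
        assert hi[0] - lo[0] < 1e-6


def test_cox_time_outside_grid_errors():
    base = BaselineSpec(np.array([0.0, 10.0]), np.array([0.0]))
    with pytest.raises(ValueError, match="outside"):
        cox_baseline(np.array([11.0]), base)


def test_baseline_from_event_times():
    rng = np.random.default_rng(0)
    times = rng.uniform(0.5, 59, 300)
    events = rng.integers(0, 2, 300)
    base = BaselineSpec.from_event_times(times, events, n_intervals=10)
    assert base.breakpoints[0] == 0.0
    assert base.breakpoints[-1] >= 59.0


# --------------------------------------------------------------------------
# censored log-likelihood
# --------------------------------------------------------------------------


def _tiny_dataset(times, events):
    g = AdjacencyGraph.from_edges(["A", "B"], [("A", "B")])
    n = len(times)
    return SurvivalDataset(
        time=np.asarray(times, dtype=float),
        event=np.asarray(events, dtype=int),
        region_idx=np.zeros(n, dtype=int),
        graph=g,
        X=np.ones((n, 1)),
        x_names=["intercept"],
    )


def test_exponential_loglik_closed_forms():
    times = [1.0, 2.0, 5.0]
    ds = _tiny_dataset(times, [1, 1, 1])
    model = ModelSpec("exponential", include_nonlinear=False, include_spatial=False)
    beta = np.array([0.4])
    lam = np.exp(0.4)
    ll = censored_loglik(ds, model, {"beta": beta})
    assert ll == pytest.approx(sum(np.log(lam) - lam * t for t in times), abs=1e-12)
    ds0 = _tiny_dataset(times, [0, 0, 0])
    ll0 = censored_loglik(ds0, model, {"beta": beta})
    assert ll0 == pytest.approx(-lam * sum(times), abs=1e-12)


def test_lognormal_loglik_term_by_term():
    """Six mixed records match an independent per-record scalar evaluation."""
    times = [0.5, 1.0, 3.0, 10.0, 25.0, 59.0]
    events = [1, 0, 1, 0, 1, 0]
    ds = _tiny_dataset(times, events)
    model = ModelSpec("lognormal", include_nonlinear=False, include_spatial=False)
    mu, tau = 2.0, 0.5
    ll = censored_loglik(ds, model, {"beta": np.array([mu]), "tau": tau})
    dist = stats.lognorm(s=1 / np.sqrt(tau), scale=np.exp(mu))
    expected = sum(
        dist.logpdf(t) if d else dist.logsf(t) for t, d in zip(times, events)
    )
    assert ll == pytest.approx(expected, abs=1e-12)


def test_loglik_reports_offending_child():
    ds = _tiny_dataset([1.0, 2.0], [1, 1])
    model = ModelSpec("weibull", include_nonlinear=False, include_spatial=False)
    with pytest.raises(ValueError):
        censored_loglik(ds, model, {"beta": np.array([0.0]), "alpha": -1.0})


def test_pointwise_vectorization_matches_scalar():
    y = np.array([0.7, 2.0, 31.0])
    delta = np.array([1.0, 0.0, 1.0])
    eta = np.array([-3.0, -2.5, -4.0])
    out = pointwise_censored_loglik("weibull", y, delta, eta, {"alpha": 0.8})
    for i in range(3):
        fp = FamilyParams("weibull", lam=np.exp(eta[i]), alpha=0.8)
        ref = (
            family_log_density(fp, y[i : i + 1])[0]
            if delta[i]
            else family_log_survival(fp, y[i : i + 1])[0]
        )
        assert out[i] == pytest.approx(ref, abs=1e-12)


def test_model_spec_json_roundtrip(tmp_path):
    base = BaselineSpec(np.array([0.0, 10.0, 60.0]))
    m = ModelSpec("cox", include_nonlinear=False, baseline=base, gamma_s=2.0)
    p = tmp_path / "m.json"
    m.to_json(p)
    m2 = ModelSpec.from_json(p)
    assert m2.family == "cox" and m2.gamma_s == 2.0
    assert np.array_equal(m2.baseline.breakpoints, base.breakpoints)
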