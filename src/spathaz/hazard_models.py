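"""Censored parametric hazard families and the structured additive predictor.

Five competing models for the time-to-death Y (months):

=============  =============================================  ==============
family         parameterized density                          link
=============  =============================================  ==============
exponential    lambda exp(-lambda y)                          eta = log lambda
gamma          Gamma(shape = s*phi, rate = s*phi / mu)        eta = log mu
weibull        alpha y^(alpha-1) lambda exp(-lambda y^alpha)  eta = log lambda
lognormal      log y ~ Normal(mu, 1/tau)                      eta = mu
cox            h(y) = h0(y) exp(mu), piecewise-constant h0    eta = mu
=============  =============================================  ==============

The censored log-likelihood sums, over children,

    delta_ij log f(y_ij) + (1 - delta_ij) log S(y_ij),

with y_ij = min(t_ij, C_ij) the observed time and delta_ij the death
indicator. All computation is on the log scale with complementary special
functions in the tails (the survival never collapses to -inf before y
leaves the representable tail).

The linear predictor is eta_ij = x' beta + z' psi + w' theta; each family
maps eta to its location parameter through the link above. The gamma
multiplier s is fixed at 1 by default (so the shape equals phi) and is
configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import special, stats

from .core_data import DEFAULT_HORIZON, SurvivalDataset

FAMILIES = ("exponential", "gamma", "weibull", "lognormal", "cox")

#: link function per family: eta = g(location parameter)
LINKS = {
    "exponential": "log",
    "gamma": "log",
    "weibull": "log",
    "lognormal": "identity",
    "cox": "identity",
}


def link_forward(family: str, param: np.ndarray) -> np.ndarray:
    """eta = g(param): log for exponential/gamma/weibull, identity otherwise."""
    return np.log(param) if LINKS[family] == "log" else np.asarray(param)


def link_inverse(family: str, eta: np.ndarray) -> np.ndarray:
    """param = g^{-1}(eta)."""
    return np.exp(eta) if LINKS[family] == "log" else np.asarray(eta)


# ---------------------------------------------------------------------------
# piecewise-constant Cox baseline
# ---------------------------------------------------------------------------


@dataclass
class BaselineSpec:
    """Piecewise-constant baseline hazard h0(t) = exp(c_k) on (t_{k-1}, t_k].

    ``breakpoints`` is the full grid 0 = t_0 < t_1 < ... < t_K covering the
    study horizon; ``log_levels`` holds the K free log-hazard levels c_k.
    """

    breakpoints: np.ndarray
    log_levels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        if self.breakpoints.ndim != 1 or self.breakpoints.size < 2:
            raise ValueError("need at least one interval (two breakpoints)")
        if self.breakpoints[0] != 0.0:
            raise ValueError("grid must start at 0")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if self.log_levels is not None:
            self.log_levels = np.asarray(self.log_levels, dtype=float)
            if self.log_levels.size != self.n_intervals:
                raise ValueError("log_levels must have one entry per interval")

    @property
    def n_intervals(self) -> int:
        return self.breakpoints.size - 1

    def interval_index(self, t: np.ndarray) -> np.ndarray:
        """0-based index k with t in (t_k, t_{k+1}] (t = 0 maps to 0)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.breakpoints[-1]):
            raise ValueError("time outside the baseline grid")
        idx = np.searchsorted(self.breakpoints, t, side="left") - 1
        return np.clip(idx, 0, self.n_intervals - 1)

    @classmethod
    def from_event_times(
        cls,
        times: np.ndarray,
        events: np.ndarray,
        n_intervals: int = 10,
        horizon: float = DEFAULT_HORIZON,
    ) -> "BaselineSpec":
        """Decile-style grid: interior breakpoints at quantiles of observed
        event times, end extended to the horizon."""
        ev = np.asarray(times, dtype=float)[np.asarray(events) == 1]
        if ev.size == 0:
            raise ValueError("no observed events to place a baseline grid on")
        qs = np.quantile(ev, np.linspace(0, 1, n_intervals + 1)[1:-1])
        pts = np.concatenate(([0.0], np.unique(qs), [max(horizon, ev.max())]))
        return cls(breakpoints=pts)


def cox_baseline(
    t: np.ndarray, baseline: BaselineSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (h0(t), H0(t)) for a piecewise-constant baseline.

    H0 accumulates exp(c_k) * interval length over complete intervals plus
    the partial last interval; it is continuous and strictly increasing
    whenever all c_k are finite.
    """
    if baseline.log_levels is None:
        raise ValueError("baseline has no log levels set")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    k = baseline.interval_index(t)
    levels = np.exp(baseline.log_levels)
    widths = np.diff(baseline.breakpoints)
    cum = np.concatenate(([0.0], np.cumsum(levels * widths)))
    h0 = levels[k]
    H0 = cum[k] + levels[k] * (t - baseline.breakpoints[k])
    return h0, H0


# ---------------------------------------------------------------------------
# family parameters
# ---------------------------------------------------------------------------


@dataclass
class FamilyParams:
    """Scalar parameters of one hazard family (location via the link).

    Only the fields the family uses are read: ``lam`` (exponential,
    weibull rate), ``mu`` (gamma mean, lognormal log-scale, cox
    log-relative-hazard), ``s_phi`` (gamma shape product s*phi),
    ``alpha`` (weibull shape), ``tau`` (lognormal precision),
    ``baseline`` (cox).
    """

    family: str
    lam: float | None = None
    mu: float | None = None
    s_phi: float | None = None
    alpha: float | None = None
    tau: float | None = None
    baseline: BaselineSpec | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        for name in ("lam", "s_phi", "alpha", "tau"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def eta(self) -> float:
        """The linear-predictor value implied by the location parameter."""
        loc = {"exponential": self.lam, "gamma": self.mu, "weibull": self.lam,
               "lognormal": self.mu, "cox": self.mu}[self.family]
        if loc is None:
            raise ValueError(f"{self.family} location parameter is unset")
        return float(link_forward(self.family, np.asarray(loc)))


def _gamma_shape_rate(fp: FamilyParams) -> tuple[float, float]:
    if fp.s_phi is None or fp.mu is None:
        raise ValueError("gamma family needs s_phi and mu")
    return fp.s_phi, fp.s_phi / fp.mu


def family_log_density(fp: FamilyParams, y: np.ndarray) -> np.ndarray:
    """log f(y) for the family's printed density."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be positive")
    if fp.family == "exponential":
        return np.log(fp.lam) - fp.lam * y
    if fp.family == "gamma":
        a, rate = _gamma_shape_rate(fp)
        return a * np.log(rate) - special.gammaln(a) + (a - 1) * np.log(y) - rate * y
    if fp.family == "weibull":
        return np.log(fp.alpha) + (fp.alpha - 1) * np.log(y) + np.log(fp.lam) - fp.lam * y**fp.alpha
    if fp.family == "lognormal":
        z = np.sqrt(fp.tau) * (np.log(y) - fp.mu)
        return -np.log(y) + 0.5 * np.log(fp.tau) - 0.5 * np.log(2 * np.pi) - 0.5 * z**2
    # cox: f = h * S
    h0, H0 = cox_baseline(y, fp.baseline)
    return np.log(h0) + fp.mu - H0 * np.exp(fp.mu)


def _log_gammaincc(a: float, x: np.ndarray) -> np.ndarray:
    """log of the regularized upper incomplete gamma Q(a, x), with a
    leading-order asymptotic continuation where Q underflows."""
    q = special.gammaincc(a, x)
    out = np.full_like(x, -np.inf, dtype=float)
    pos = q > 0
    out[pos] = np.log(q[pos])
    deep = ~pos & (x > 0)
    if np.any(deep):  # Q(a,x) ~ x^(a-1) e^(-x) / Gamma(a) for x >> a
        xd = x[deep]
        out[deep] = (a - 1) * np.log(xd) - xd - special.gammaln(a) + np.log1p((a - 1) / xd)
    return out


def family_log_survival(fp: FamilyParams, y: np.ndarray) -> np.ndarray:
    """log S(y) = log integral_y^inf f, computed with complementary
    special functions so the deep tail stays finite."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be positive")
    if fp.family == "exponential":
        return -fp.lam * y
    if fp.family == "gamma":
        a, rate = _gamma_shape_rate(fp)
        return _log_gammaincc(a, rate * y)
    if fp.family == "weibull":
        return -fp.lam * y**fp.alpha
    if fp.family == "lognormal":
        z = np.sqrt(fp.tau) * (np.log(y) - fp.mu)
        return stats.norm.logsf(z)
    _, H0 = cox_baseline(y, fp.baseline)
    return -H0 * np.exp(fp.mu)


def family_hazard(fp: FamilyParams, y: np.ndarray) -> np.ndarray:
    """Hazard h(y) = f(y) / S(y), in the family's printed closed form."""
    y = np.asarray(y, dtype=float)
    if fp.family == "exponential":
        return np.full_like(y, fp.lam, dtype=float)
    if fp.family == "weibull":
        return fp.alpha * y ** (fp.alpha - 1) * fp.lam
    if fp.family == "cox":
        h0, _ = cox_baseline(y, fp.baseline)
        return h0 * np.exp(fp.mu)
    # gamma, lognormal: printed ratio f / (1 - F), evaluated stably
    return np.exp(family_log_density(fp, y) - family_log_survival(fp, y))


# ---------------------------------------------------------------------------
# model specification and vectorized likelihood
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """One competing model: hazard family plus predictor structure.

    ``include_nonlinear`` adds the RW2 maternal-age effect psi;
    ``include_spatial`` the ICAR region effect theta. ``gamma_s`` is the
    fixed multiplier s in the gamma shape s*phi. ``baseline`` is required
    for the cox family.
    """

    family: str
    include_nonlinear: bool = True
    include_spatial: bool = True
    gamma_s: float = 1.0
    baseline: BaselineSpec | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.gamma_s <= 0:
            raise ValueError("gamma_s must be positive")

    @property
    def link(self) -> str:
        return LINKS[self.family]

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "family": self.family,
            "link": self.link,
            "include_nonlinear": self.include_nonlinear,
            "include_spatial": self.include_spatial,
            "gamma_s": self.gamma_s,
            "baseline_breakpoints": (
                self.baseline.breakpoints.tolist() if self.baseline else None
            ),
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ModelSpec":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        baseline = (
            BaselineSpec(np.asarray(d["baseline_breakpoints"]))
            if d.get("baseline_breakpoints")
            else None
        )
        return cls(
            family=d["family"],
            include_nonlinear=d["include_nonlinear"],
            include_spatial=d["include_spatial"],
            gamma_s=d.get("gamma_s", 1.0),
            baseline=baseline,
        )


def linear_predictor(
    dataset: SurvivalDataset,
    beta: np.ndarray,
    psi: np.ndarray | None = None,
    theta: np.ndarray | None = None,
) -> np.ndarray:
    """eta_ij = x' beta + z' psi + w' theta, using the index representation
    of the incidence designs (exactly one bin and one region per child)."""
    eta = dataset.X @ np.asarray(beta, dtype=float) if len(beta) else np.zeros(dataset.n)
    if psi is not None:
        if dataset.age_bin is None:
            raise ValueError("dataset has no maternal-age bins for psi")
        eta = eta + np.asarray(psi)[dataset.age_bin]
    if theta is not None:
        eta = eta + np.asarray(theta)[dataset.region_idx]
    return eta


def pointwise_censored_loglik(
    family: str,
    y: np.ndarray,
    delta: np.ndarray,
    eta: np.ndarray,
    aux: Mapping[str, object] | None = None,
) -> np.ndarray:
    """Per-child censored log-likelihood terms
    delta * log f(y | eta) + (1 - delta) * log S(y | eta),
    vectorized over children with a shared auxiliary parameter set.

    ``aux`` supplies the non-location parameters: ``alpha`` (weibull),
    ``s_phi`` (gamma), ``tau`` (lognormal), ``baseline`` (cox).
    """
    aux = aux or {}
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if family == "exponential":
        lam = np.exp(eta)
        logf = eta - lam * y
        logS = -lam * y
    elif family == "weibull":
        alpha = float(aux["alpha"])
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        lam = np.exp(eta)
        ya = y**alpha
        logf = np.log(alpha) + (alpha - 1) * np.log(y) + eta - lam * ya
        logS = -lam * ya
    elif family == "gamma":
        a = float(aux["s_phi"])
        if a <= 0:
            raise ValueError("s_phi must be positive")
        mu = np.exp(eta)
        rate = a / mu
        x = rate * y
        logf = a * np.log(rate) - special.gammaln(a) + (a - 1) * np.log(y) - x
        logS = _log_gammaincc(a, x)
    elif family == "lognormal":
        tau = float(aux["tau"])
        if tau <= 0:
            raise ValueError("tau must be positive")
        z = np.sqrt(tau) * (np.log(y) - eta)
        logf = -np.log(y) + 0.5 * np.log(tau) - 0.5 * np.log(2 * np.pi) - 0.5 * z**2
        logS = stats.norm.logsf(z)
    elif family == "cox":
        baseline: BaselineSpec = aux["baseline"]  # type: ignore[assignment]
        h0, H0 = cox_baseline(y, baseline)
        logS = -H0 * np.exp(eta)
        logf = np.log(h0) + eta + logS
    else:
        raise ValueError(f"unknown family {family!r}")
    return delta * logf + (1.0 - delta) * logS


def censored_loglik(
    dataset: SurvivalDataset,
    model: ModelSpec,
    params: Mapping[str, object],
) -> float:
    """Total censored log-likelihood for a model at one parameter setting.

    ``params`` holds ``beta`` and, per the model structure, ``psi``,
    ``theta``, and the family's auxiliary parameters (``alpha``, ``phi``,
    ``tau``, ``log_levels`` for the cox baseline).
    """
    beta = np.asarray(params.get("beta", np.zeros(dataset.X.shape[1])), dtype=float)
    psi = params.get("psi") if model.include_nonlinear else None
    theta = params.get("theta") if model.include_spatial else None
    eta = linear_predictor(dataset, beta, psi, theta)
    aux: dict[str, object] = {}
    if model.family == "weibull":
        aux["alpha"] = params["alpha"]
    elif model.family == "gamma":
        aux["s_phi"] = model.gamma_s * float(params["phi"])
    elif model.family == "lognormal":
        aux["tau"] = params["tau"]
    elif model.family == "cox":
        if model.baseline is None:
            raise ValueError("cox model needs a baseline grid")
        aux["baseline"] = BaselineSpec(
            breakpoints=model.baseline.breakpoints,
            log_levels=np.asarray(params["log_levels"], dtype=float),
        )
    terms = pointwise_censored_loglik(model.family, dataset.time, dataset.event, eta, aux)
    if not np.all(np.isfinite(terms)):
        bad = int(np.flatnonzero(~np.isfinite(terms))[0])
        raise FloatingPointError(
            f"non-finite log-likelihood term at child index {bad} "
            f"(time={dataset.time[bad]}, event={dataset.event[bad]})"
        )
    return float(terms.sum())
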