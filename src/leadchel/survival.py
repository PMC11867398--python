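"""Parametric survival fitting, extrapolation, and transition probabilities.

Seven candidate families (exponential, Weibull, Gompertz, gamma, lognormal,
log-logistic, generalized gamma) are fitted to right-censored data by maximum
likelihood, compared by AIC/BIC, extrapolated on an annual grid, and converted
to per-cycle transition probabilities via

    tp_i = 1 - S(i) / S(i-1),   i = 1, 2, ... horizon (years).

Parameterizations (chosen for interoperability with the usual reporting of
fitted survival parameters):

* exponential: ``rate``
* weibull: ``shape``, ``scale`` (S(t) = exp(-(t/scale)^shape))
* gompertz: ``shape`` (may be negative), ``rate``; h(t) = rate * exp(shape*t)
* gamma: ``shape``, ``rate``
* lognormal: ``meanlog``, ``sdlog``
* loglogistic: ``shape``, ``scale`` (S(t) = 1/(1+(t/scale)^shape))
* generalized_gamma: ``mu``, ``sigma``, ``Q`` (Prentice form; Q -> 0 is the
  lognormal, Q = 1 the Weibull, sigma = Q the gamma)

Confidence intervals come from the observed information matrix on the
optimizer's transformed scale (log for positivity-constrained parameters),
then mapped back, so e.g. a rate CI is ``exp(log_rate +/- 1.96 se)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

FAMILIES = (
    "exponential", "weibull", "gompertz", "gamma",
    "lognormal", "loglogistic", "generalized_gamma",
)

# transform: "log" params are optimized as logs (positivity), "id" free.
_PARAM_INFO: dict[str, list[tuple[str, str]]] = {
    "exponential": [("rate", "log")],
    "weibull": [("shape", "log"), ("scale", "log")],
    "gompertz": [("shape", "id"), ("rate", "log")],
    "gamma": [("shape", "log"), ("rate", "log")],
    "lognormal": [("meanlog", "id"), ("sdlog", "log")],
    "loglogistic": [("shape", "log"), ("scale", "log")],
    "generalized_gamma": [("mu", "id"), ("sigma", "log"), ("Q", "id")],
}

_TINY = 1e-300
_GG_Q_EPS = 1e-6


def param_names(family: str) -> list[str]:
    return [name for name, _ in _PARAM_INFO[family]]


# ---------------------------------------------------------------------------
# log-density and log-survival per family (vectorized over t)
# ---------------------------------------------------------------------------

def _gg_logpdf(t, mu, sigma, q):
    if abs(q) < _GG_Q_EPS:
        return stats.norm.logpdf((np.log(t) - mu) / sigma) - np.log(sigma * t)
    w = (np.log(t) - mu) / sigma
    qi2 = q ** -2
    return (np.log(abs(q)) - np.log(sigma * t) + qi2 * np.log(qi2)
            + qi2 * (q * w - np.exp(q * w)) - special.gammaln(qi2))


def _gg_logsf(t, mu, sigma, q):
    if abs(q) < _GG_Q_EPS:
        return stats.norm.logsf((np.log(t) - mu) / sigma)
    w = (np.log(t) - mu) / sigma
    qi2 = q ** -2
    u = qi2 * np.exp(q * w)
    if q > 0:
        p = special.gammaincc(qi2, u)  # upper regularized
    else:
        p = special.gammainc(qi2, u)
    return np.log(np.maximum(p, _TINY))


def logpdf(family: str, t, params: np.ndarray):
    t = np.asarray(t, dtype=float)
    p = params
    if family == "exponential":
        return np.log(p[0]) - p[0] * t
    if family == "weibull":
        k, lam = p
        z = t / lam
        return np.log(k / lam) + (k - 1) * np.log(z) - z ** k
    if family == "gompertz":
        a, b = p
        if abs(a) < 1e-12:
            return np.log(b) - b * t
        return np.log(b) + a * t - (b / a) * (np.exp(a * t) - 1.0)
    if family == "gamma":
        return stats.gamma.logpdf(t, p[0], scale=1.0 / p[1])
    if family == "lognormal":
        return stats.lognorm.logpdf(t, p[1], scale=np.exp(p[0]))
    if family == "loglogistic":
        return stats.fisk.logpdf(t, p[0], scale=p[1])
    if family == "generalized_gamma":
        return _gg_logpdf(t, *p)
    raise ValueError(f"unknown family {family!r}")


def logsf(family: str, t, params: np.ndarray):
    t = np.asarray(t, dtype=float)
    p = params
    if family == "exponential":
        return -p[0] * t
    if family == "weibull":
        return -((t / p[1]) ** p[0])
    if family == "gompertz":
        a, b = p
        if abs(a) < 1e-12:
            return -b * t
        return -(b / a) * (np.exp(a * t) - 1.0)
    if family == "gamma":
        return stats.gamma.logsf(t, p[0], scale=1.0 / p[1])
    if family == "lognormal":
        return stats.lognorm.logsf(t, p[1], scale=np.exp(p[0]))
    if family == "loglogistic":
        return stats.fisk.logsf(t, p[0], scale=p[1])
    if family == "generalized_gamma":
        return _gg_logsf(t, *p)
    raise ValueError(f"unknown family {family!r}")


def survival_function(family: str, t, params) -> np.ndarray:
    """S(t) with S(0) = 1; closed form per family."""
    t = np.asarray(t, dtype=float)
    params = np.asarray(params, dtype=float)
    out = np.ones_like(t)
    pos = t > 0
    if pos.any():
        out[pos] = np.exp(logsf(family, t[pos], params))
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class ParametricFit:
    """One fitted time-to-event distribution."""

    endpoint: str
    group: str
    family: str
    params: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    loglik: float = np.nan
    aic: float = np.nan
    bic: float = np.nan
    n: int = 0
    n_events: int = 0
    converged: bool = False
    message: str = ""

    @property
    def param_vector(self) -> np.ndarray:
        return np.array([self.params[k] for k in param_names(self.family)])


def _initial_guess(family: str, times, events) -> np.ndarray:
    """Moment-based starting values on the transformed scale."""
    times = np.maximum(times, 1e-8)
    total_time = times.sum()
    n_events = max(events.sum(), 1)
    rate0 = n_events / total_time
    ev_times = times[events] if events.any() else times
    mlog = float(np.mean(np.log(ev_times)))
    slog = float(np.std(np.log(ev_times))) or 1.0
    raw = {
        "exponential": [rate0],
        "weibull": [1.0, 1.0 / rate0],
        "gompertz": [0.01, rate0],
        "gamma": [1.0, rate0],
        "lognormal": [mlog, slog],
        "loglogistic": [1.0, np.exp(mlog)],
        "generalized_gamma": [mlog, slog, 0.5],
    }[family]
    x0 = []
    for value, (_, tr) in zip(raw, _PARAM_INFO[family]):
        x0.append(np.log(value) if tr == "log" else value)
    return np.array(x0, dtype=float)


def _from_transformed(family: str, x: np.ndarray) -> np.ndarray:
    vals = []
    for xi, (_, tr) in zip(x, _PARAM_INFO[family]):
        vals.append(np.exp(xi) if tr == "log" else xi)
    return np.array(vals)


def _nll(family: str, x: np.ndarray, times, events) -> float:
    params = _from_transformed(family, x)
    with np.errstate(all="ignore"):
        ll = 0.0
        if events.any():
            lp = logpdf(family, times[events], params)
            if not np.all(np.isfinite(lp)):
                return 1e12
            ll += lp.sum()
        cens = ~events
        if cens.any():
            ls = logsf(family, times[cens], params)
            if not np.all(np.isfinite(ls)):
                return 1e12
            ll += ls.sum()
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian."""
    k = len(x)
    H = np.empty((k, k))
    hs = eps * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * hs[i] * hs[j])
    return H


def fit_parametric(times, events, family: str,
                   endpoint: str = "GF", group: str = "all") -> ParametricFit:
    """Maximum-likelihood fit of one family to right-censored data.

    ``times`` are non-negative follow-up times; ``events`` boolean (True =
    event observed, False = censored).  Raises ``ValueError`` when fewer than
    two events are available.  Non-convergence returns a flagged fit
    (``converged=False``) with a diagnostic message rather than raising.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    if events.sum() < 2:
        raise ValueError("at least two events are required for estimation")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")

    x0 = _initial_guess(family, times, events)
    obj = lambda x: _nll(family, x, times, events)

    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    # polish with a gradient method from the simplex optimum
    res2 = optimize.minimize(obj, res.x, method="BFGS",
                             options={"maxiter": 500, "gtol": 1e-8})
    best = res2 if res2.fun <= res.fun else res

    x_hat = best.x
    params = _from_transformed(family, x_hat)
    loglik = -best.fun
    k = len(x_hat)
    n = len(times)
    names = param_names(family)

    fit = ParametricFit(
        endpoint=endpoint, group=group, family=family,
        params=dict(zip(names, params.tolist())),
        loglik=float(loglik),
        aic=float(2 * k - 2 * loglik),
        bic=float(k * np.log(n) - 2 * loglik),
        n=n, n_events=int(events.sum()),
        converged=bool(best.fun < 1e11),
        message="" if best.fun < 1e11 else "likelihood evaluation failed",
    )
    if not fit.converged:
        return fit

    # observed-information CIs on the transformed scale
    try:
        H = _hessian(obj, x_hat)
        cov = np.linalg.inv(H)
        var = np.diag(cov)
        if (var <= 0).any():
            raise np.linalg.LinAlgError("non-positive variance")
        se_t = np.sqrt(var)
        for i, (name, tr) in enumerate(_PARAM_INFO[family]):
            lo_t, hi_t = x_hat[i] - 1.96 * se_t[i], x_hat[i] + 1.96 * se_t[i]
            if tr == "log":
                fit.se[name] = float(params[i] * se_t[i])  # delta method
                fit.ci[name] = (float(np.exp(lo_t)), float(np.exp(hi_t)))
            else:
                fit.se[name] = float(se_t[i])
                fit.ci[name] = (float(lo_t), float(hi_t))
    except np.linalg.LinAlgError as exc:
        fit.message = f"information matrix not invertible: {exc}"
    return fit


def fit_all_families(times, events, endpoint: str = "GF",
                     group: str = "all",
                     families=FAMILIES) -> list[ParametricFit]:
    """Fit every candidate family; failures become flagged fits."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_parametric(times, events, fam, endpoint, group))
        except ValueError as exc:
            fits.append(ParametricFit(endpoint=endpoint, group=group, family=fam,
                                      params={}, converged=False, message=str(exc)))
    return fits


def select_model(fits: list[ParametricFit],
                 override: str | None = None) -> tuple[list[ParametricFit], ParametricFit]:
    """Rank converged fits by AIC and pick the best (or the override family).

    The override mirrors expert-informed model choice: when given, the named
    family is selected regardless of its AIC rank (it must have converged).
    """
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to select from")
    ranked = sorted(ok, key=lambda f: f.aic)
    if override is not None:
        matches = [f for f in ok if f.family == override]
        if not matches:
            raise ValueError(f"override family {override!r} has no converged fit")
        return ranked, matches[0]
    return ranked, ranked[0]


# ---------------------------------------------------------------------------
# Extrapolation and transition probabilities
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    times: np.ndarray      # integer years 0..horizon
    survival: np.ndarray   # S_i, S_0 = 1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.survival[0] != 1.0:
            raise ValueError("S(0) must equal 1")
        if (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival curve must be non-increasing")
        if ((self.survival < -1e-12) | (self.survival > 1 + 1e-12)).any():
            raise ValueError("survival values must lie in [0, 1]")


def extrapolate_survival(fit: ParametricFit, horizon: int) -> SurvivalCurve:
    """Evaluate the fitted family's closed-form S at integer years 0..horizon."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not fit.params:
        raise ValueError("fit carries no parameters")
    t = np.arange(horizon + 1, dtype=float)
    s = survival_function(fit.family, t, fit.param_vector)
    return SurvivalCurve(times=t, survival=s)


def survival_to_tp(curve: SurvivalCurve) -> np.ndarray:
    """Per-cycle transition probabilities tp_i = 1 - S_i/S_{i-1}.

    When S_{i-1} has underflowed to zero the conditional probability is
    undefined; the state is exhausted, so tp is set to 1 with a warning.
    """
    s = curve.survival
    tp = np.empty(len(s) - 1)
    underflow = False
    for i in range(1, len(s)):
        if s[i - 1] <= _TINY:
            tp[i - 1] = 1.0
            underflow = True
        else:
            tp[i - 1] = 1.0 - s[i] / s[i - 1]
    if underflow:
        warnings.warn("survival underflowed to 0 before the horizon; "
                      "tail transition probabilities set to 1", RuntimeWarning)
    return np.clip(tp, 0.0, 1.0)


def tp_to_survival(tp: np.ndarray) -> np.ndarray:
    """Inverse of :func:`survival_to_tp`: S_i = prod_{j<=i}(1 - tp_j)."""
    return np.concatenate([[1.0], np.cumprod(1.0 - np.asarray(tp, dtype=float))])


def tp_series(family: str, params: dict[str, float], horizon: int) -> np.ndarray:
    """Convenience: closed-form S on the annual grid -> tp series."""
    vec = np.array([params[k] for k in param_names(family)])
    t = np.arange(horizon + 1, dtype=float)
    s = survival_function(family, t, vec)
    return survival_to_tp(SurvivalCurve(times=t, survival=s))
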