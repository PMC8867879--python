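"""Relative-survival flexible parametric model: fitting, prediction, loss in
life expectancy, and external age standardisation.

The model parameterises the log cumulative excess hazard as a restricted
cubic spline of log time (baseline df 3 by default) with a linear effect of
age at diagnosis and, optionally, a time-dependent age effect formed by
multiplying age with a second restricted cubic spline of log time (df 3).
Writing ``eta(t, a) = s0(ln t) + alpha a + a s1(ln t)``, the cumulative
excess hazard is ``Lambda = exp(eta)`` and the excess hazard
``lambda = Lambda * (d eta / d ln t) / t``.  The likelihood uses only the
expected mortality rate at each subject's exit time (the expected-survival
term is constant and dropped):

    l = sum_i [ d_i log(h*_i + lambda(t_i)) - Lambda(t_i) ].

Loss in life expectancy extrapolates the fitted relative survival against
the life table:  ``LLE = int_0^tmax S*(t) dt - int_0^tmax S*(t) R(t) dt``,
with ``tmax`` ending at the 100-year age cap by default, and the proportion
of life lost divides by the cancer-free expectation.  Marginal estimates
average individual predictions, optionally reweighted to the International
Cancer Survival Standard (ICSS) age distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import roots_legendre

from .lifetables import LifeTable
from .splines import RestrictedCubicSpline, event_centile_knots

__all__ = [
    "SplineBasis",
    "FPMFit",
    "ICSSWeights",
    "rcs_eval",
    "fit_relative_survival_fpm",
    "predict_R",
    "compute_lle",
    "compute_pll",
    "standardize",
]

#: ICSS reference age distribution for breast cancer survival comparisons.
ICSS_GROUPS = ((-np.inf, 45.0), (45.0, 55.0), (55.0, 65.0), (65.0, 75.0), (75.0, np.inf))
ICSS_PROPORTIONS = (0.07, 0.12, 0.23, 0.29, 0.29)

SplineBasis = RestrictedCubicSpline  # domain alias

_MIN_FOLLOW_UP = 1.0 / 365.25  # zero survival times floored at one day


def rcs_eval(basis: RestrictedCubicSpline, x):
    """Evaluate a restricted cubic spline basis at log time ``x``."""
    return basis.basis(x)


# ---------------------------------------------------------------------------
# Fitted model object


@dataclass
class FPMFit:
    """Fitted relative-survival flexible parametric model.

    ``gamma`` holds the intercept followed by the baseline spline
    coefficients; ``alpha`` is the linear age effect; ``delta`` the
    coefficients of the age x spline-of-log-time interaction (empty when no
    time-dependent effect was requested).  Knots are stored on log time.
    """

    knots: np.ndarray
    gamma: np.ndarray
    alpha: float
    tvc_knots: np.ndarray | None = None
    delta: np.ndarray | None = None
    age_center: float = 0.0  # tvc interaction uses (age - age_center)
    loglik: float = np.nan
    grad_norm: float = np.nan
    converged: bool = False
    n: int = 0
    n_events: int = 0

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self._base = RestrictedCubicSpline(self.knots)
        if self.tvc_knots is not None and self.delta is not None and len(self.delta):
            self.tvc_knots = np.asarray(self.tvc_knots, dtype=float)
            self.delta = np.asarray(self.delta, dtype=float)
            self._tvc = RestrictedCubicSpline(self.tvc_knots)
        else:
            self._tvc = None
            self.delta = None

    # -- predictions ----------------------------------------------------

    def linear_predictor(self, t, age):
        """log cumulative excess hazard eta(t, age)."""
        t = np.asarray(t, dtype=float)
        age = np.asarray(age, dtype=float)
        with np.errstate(divide="ignore"):
            x = np.log(t)
        eta = self.gamma[0] + self._base.basis(x) @ self.gamma[1:] + self.alpha * age
        if self._tvc is not None:
            eta = eta + (age - self.age_center) * (self._tvc.basis(x) @ self.delta)
        return eta

    def cumulative_excess_hazard(self, t, age):
        return np.exp(self.linear_predictor(t, age))

    def excess_hazard(self, t, age):
        t = np.asarray(t, dtype=float)
        age = np.asarray(age, dtype=float)
        x = np.log(t)
        slope = self._base.derivative(x) @ self.gamma[1:]
        if self._tvc is not None:
            slope = slope + (age - self.age_center) * (self._tvc.derivative(x) @ self.delta)
        return self.cumulative_excess_hazard(t, age) * slope / t

    # -- serialisation ---------------------------------------------------

    def to_text(self, path) -> None:
        """Write the parameters to a plain-text (JSON) file for exact reload."""
        payload = {
            "knots": self.knots.tolist(),
            "gamma": self.gamma.tolist(),
            "alpha": float(self.alpha),
            "tvc_knots": None if self._tvc is None else self.tvc_knots.tolist(),
            "delta": None if self.delta is None else self.delta.tolist(),
            "age_center": float(self.age_center),
            "loglik": None if np.isnan(self.loglik) else float(self.loglik),
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_text(cls, path) -> "FPMFit":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            knots=np.asarray(p["knots"]),
            gamma=np.asarray(p["gamma"]),
            alpha=p["alpha"],
            tvc_knots=None if p["tvc_knots"] is None else np.asarray(p["tvc_knots"]),
            delta=None if p["delta"] is None else np.asarray(p["delta"]),
            age_center=p.get("age_center", 0.0),
            loglik=np.nan if p.get("loglik") is None else p["loglik"],
            n=p.get("n", 0),
            n_events=p.get("n_events", 0),
            converged=p.get("converged", False),
        )


def predict_R(fit: FPMFit, age, t):
    """Predicted relative survival R(t | age); tends to 1 as t -> 0+."""
    t_arr = np.asarray(t, dtype=float)
    out = np.where(
        t_arr <= 0, 1.0, np.exp(-np.exp(fit.linear_predictor(np.maximum(t_arr, 1e-300), age)))
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Maximum likelihood fitting


class _Design:
    """Pre-computed design matrices for the excess-hazard likelihood."""

    def __init__(self, time, event, age, expected_rate, knots, tvc_knots, age_center):
        self.t = time
        self.d = event.astype(float)
        self.hstar = expected_rate
        base = RestrictedCubicSpline(knots)
        x = np.log(time)
        agec = (age - age_center)[:, None]
        B = np.column_stack([np.ones_like(x), base.basis(x)])
        Bp = np.column_stack([np.zeros_like(x), base.derivative(x)])
        if tvc_knots is not None:
            tvc = RestrictedCubicSpline(tvc_knots)
            C = tvc.basis(x)
            Cp = tvc.derivative(x)
            self.X = np.column_stack([B, agec, agec * C])
            self.Xp = np.column_stack([Bp, np.zeros_like(agec), agec * Cp])
        else:
            self.X = np.column_stack([B, agec])
            self.Xp = np.column_stack([Bp, np.zeros_like(agec)])
        self.n_base = B.shape[1]
        # column scaling for optimizer conditioning; theta_raw = theta_scaled / scale
        self.scale = np.maximum(
            np.max(np.abs(self.X), axis=0), np.max(np.abs(self.Xp), axis=0)
        )
        self.scale = np.maximum(self.scale, 1e-8)
        self.X = self.X / self.scale
        self.Xp = self.Xp / self.scale


_SLOPE_EPS = 1e-8
_PENALTY = 1e6


def _negloglik_and_grad(theta, dm: _Design):
    eta = dm.X @ theta
    etap = dm.Xp @ theta
    lam_ok = etap > _SLOPE_EPS
    etap_c = np.maximum(etap, _SLOPE_EPS)
    Lam = np.exp(np.clip(eta, -700, 700))
    lam = Lam * etap_c / dm.t
    denom = dm.hstar + lam
    ll = np.sum(dm.d * np.log(denom) - Lam)
    # quadratic penalty keeps the slope of the log cumulative hazard positive
    viol = np.maximum(_SLOPE_EPS - etap, 0.0)
    ll -= _PENALTY * np.sum(viol**2)

    w_event = dm.d / denom
    # d lam / d theta = lam * X + (Lam/t) * Xp   (Xp term frozen where clamped)
    g = (w_event * lam - Lam) @ dm.X
    g += ((w_event * Lam / dm.t) * lam_ok) @ dm.Xp
    g += (2.0 * _PENALTY * viol) @ dm.Xp
    return -ll, -g


def fit_relative_survival_fpm(
    time,
    event,
    age,
    expected_rate,
    df_baseline: int = 3,
    df_tvc: int = 3,
    knots=None,
    tvc_knots=None,
) -> FPMFit:
    """Fit the relative-survival FPM by maximum likelihood.

    Parameters
    ----------
    time, event:
        Follow-up in years and death indicator (administratively censored
        data); zero times are floored at one day.
    age:
        Age at diagnosis in years (linear covariate).
    expected_rate:
        Expected mortality rate h* at each subject's exit (attained
        age/year lookup from the life table); pass zeros for an all-cause
        (no-background) fit.
    df_baseline, df_tvc:
        Degrees of freedom of the baseline spline and of the time-dependent
        age effect (``df_tvc=0`` disables it).
    knots, tvc_knots:
        Optional explicit knots on log time; by default both are placed at
        centiles of the log event times.
    """
    time = np.maximum(np.asarray(time, dtype=float), _MIN_FOLLOW_UP)
    event = np.asarray(event, dtype=bool)
    age = np.asarray(age, dtype=float)
    expected_rate = np.asarray(expected_rate, dtype=float)
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError("need at least two events to fit")

    log_event_times = np.log(time[event])
    if knots is None:
        knots = event_centile_knots(log_event_times, df_baseline)
    knots = np.asarray(knots, dtype=float)
    if df_tvc > 0 and tvc_knots is None:
        tvc_knots = event_centile_knots(log_event_times, df_tvc)
    if df_tvc == 0:
        tvc_knots = None
    age_center = float(np.mean(age))

    # Weibull-equivalent starting fit (df-1), then seed the full model.
    def _fit(theta0, dm):
        res = optimize.minimize(
            _negloglik_and_grad,
            theta0,
            args=(dm,),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-7, "maxiter": 500},
        )
        if not res.success:  # polish / retry from the current point
            res = optimize.minimize(
                _negloglik_and_grad, res.x, args=(dm,), jac=True,
                method="BFGS", options={"gtol": 1e-5, "maxiter": 500},
            )
        return res

    wknots = np.array([knots[0], knots[-1]])
    dm1 = _Design(time, event, age, expected_rate, wknots, None, age_center)
    rate0 = max(n_events / np.sum(time), 1e-10)
    res1 = _fit(np.array([np.log(rate0), 1.0, 0.0]) * dm1.scale, dm1)

    if df_baseline == 1 and df_tvc == 0:
        res, dm = res1, dm1
        knots_used = wknots
    else:
        dm = _Design(time, event, age, expected_rate, knots, tvc_knots, age_center)
        k = dm.X.shape[1]
        raw1 = res1.x / dm1.scale
        theta0 = np.zeros(k)
        theta0[0] = raw1[0]
        theta0[1] = raw1[1]
        theta0[dm.n_base] = raw1[2]
        res = _fit(theta0 * dm.scale, dm)
        knots_used = knots

    theta = res.x / dm.scale  # raw coefficients (centred-age parameterisation)
    nb = dm.n_base
    g = theta[:nb].copy()
    a = float(theta[nb])
    g[0] -= a * age_center  # un-center the linear age term (always exact)
    delta_final = None
    center_final = 0.0
    k_total = theta.size
    uncenter = np.eye(k_total)
    uncenter[0, nb] = -age_center
    if tvc_knots is not None:
        d = theta[nb + 1 :].copy()
        if np.array_equal(np.asarray(tvc_knots, float), knots_used):
            # tvc basis columns coincide with the baseline's: fold the
            # centering offset into gamma so the interaction uses raw age
            g[1 : 1 + d.size] -= age_center * d
            for j in range(d.size):
                uncenter[1 + j, nb + 1 + j] = -age_center
        else:
            center_final = age_center
        delta_final = d

    fval, grad = _negloglik_and_grad(res.x, dm)
    fit = FPMFit(
        knots=knots_used,
        gamma=g,
        alpha=a,
        tvc_knots=None if tvc_knots is None else np.asarray(tvc_knots, dtype=float),
        delta=delta_final,
        age_center=center_final,
        loglik=-fval,
        grad_norm=float(np.linalg.norm(grad)),
        converged=bool(res.success or np.linalg.norm(grad) < 1e-3),
        n=time.size,
        n_events=n_events,
    )
    if not fit.converged:
        raise RuntimeError(
            f"FPM fit did not converge (gradient norm {fit.grad_norm:.3g})"
        )
    fit._theta_scaled = res.x
    fit._design = dm
    fit._uncenter = uncenter
    return fit


def fit_covariance(fit: FPMFit) -> np.ndarray:
    """Observed-information covariance of the reported parameter vector
    (gamma..., alpha[, delta...]), by central finite differences of the
    analytic gradient."""
    theta = fit._theta_scaled
    dm = fit._design
    k = theta.size
    H = np.zeros((k, k))
    h = 1e-5 * np.maximum(np.abs(theta), 1.0)
    for j in range(k):
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        _, gp = _negloglik_and_grad(tp, dm)
        _, gm = _negloglik_and_grad(tm, dm)
        H[:, j] = (gp - gm) / (2 * h[j])
    H = 0.5 * (H + H.T)
    cov_scaled = np.linalg.inv(H)
    D = np.diag(dm.scale)  # theta_raw = theta_scaled / scale
    cov_raw = cov_scaled * np.outer(1.0 / dm.scale, 1.0 / dm.scale)
    T = fit._uncenter
    return T @ cov_raw @ T.T


# ---------------------------------------------------------------------------
# Life expectancy measures


def _panel_nodes(t_max: float, nodes: int, first_break: float | None = None):
    """Gauss–Legendre nodes/weights on yearly panels covering [0, t_max].

    ``first_break`` optionally offsets the panel grid (used to align panels
    with attained-age year boundaries, where the expected hazard steps).
    """
    xs, ws = roots_legendre(nodes)
    if first_break is not None and 0.0 < first_break < min(1.0, t_max):
        edges = np.concatenate([[0.0], np.arange(first_break, t_max, 1.0)])
    else:
        edges = np.arange(0.0, t_max, 1.0)
    lo = edges
    hi = np.minimum(np.append(edges[1:], np.inf), t_max)
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    pts = (mid[:, None] + half[:, None] * xs[None, :]).ravel()
    wts = (half[:, None] * ws[None, :]).ravel()
    return pts, wts


def _age_break(age_dx: float) -> float | None:
    frac = np.ceil(age_dx) - age_dx
    return float(frac) if frac > 0 else None


def expected_life_years(table: LifeTable, age_dx: float, year_dx: float,
                        t_max: float, nodes: int = 8) -> float:
    """Cancer-free remaining life expectancy: int_0^tmax S*(t) dt."""
    pts, wts = _panel_nodes(t_max, nodes, _age_break(age_dx))
    from .lifetables import expected_survival

    s_star = expected_survival(table, age_dx, year_dx, pts)
    return float(np.sum(wts * s_star))


def compute_lle(fit: FPMFit, table: LifeTable, age_dx: float, year_dx: float,
                t_max: float | None = None, nodes: int = 8) -> float:
    """Loss in life expectancy in years for one individual.

    ``LLE = int_0^tmax S*(t) dt - int_0^tmax S*(t) R(t | age) dt`` by
    composite Gauss–Legendre quadrature on yearly panels; ``t_max`` defaults
    to ``age_cap - age_dx`` so the extrapolation ends at the age cap.
    """
    if t_max is None:
        t_max = table.age_cap - age_dx
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if age_dx + t_max > table.age_cap:
        raise ValueError("t_max extends beyond the age cap")
    pts, wts = _panel_nodes(t_max, nodes, _age_break(age_dx))
    from .lifetables import expected_survival

    s_star = expected_survival(table, age_dx, year_dx, pts)
    r = predict_R(fit, age_dx, pts)
    return float(np.sum(wts * s_star) - np.sum(wts * s_star * r))


def compute_pll(lle: float, table: LifeTable, age_dx: float, year_dx: float,
                t_max: float | None = None, nodes: int = 8) -> float:
    """Proportion of life lost: LLE over the cancer-free life expectancy."""
    if t_max is None:
        t_max = table.age_cap - age_dx
    denom = expected_life_years(table, age_dx, year_dx, t_max, nodes=nodes)
    if denom <= 0:
        raise ValueError("zero cancer-free life expectancy")
    return float(lle) / denom


# ---------------------------------------------------------------------------
# Standardisation


@dataclass
class ICSSWeights:
    """External reference age distribution (defaults to the ICSS proportions
    7/12/23/29/29% for ages <=44, 45-54, 55-64, 65-74, >=75)."""

    groups: tuple = ICSS_GROUPS
    proportions: tuple = ICSS_PROPORTIONS

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("reference proportions must sum to 1")
        if len(self.groups) != p.size:
            raise ValueError("one proportion per age group required")

    def group_index(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        idx = np.full(ages.shape, -1, dtype=int)
        for g, (lo, hi) in enumerate(self.groups):
            idx[(ages >= lo) & (ages < hi)] = g
        if np.any(idx < 0):
            raise ValueError("ages outside every reference age group")
        return idx

    def individual_weights(self, ages) -> np.ndarray:
        """w_i = w^s_{g(i)} / a_{g(i)} with a the sample age-group shares."""
        idx = self.group_index(ages)
        n = idx.size
        props = np.asarray(self.proportions, dtype=float)
        counts = np.bincount(idx, minlength=props.size)
        empty = (counts == 0) & (props > 0)
        if np.any(empty):
            raise ValueError(
                "empty sample age group with positive reference weight "
                f"(groups {np.flatnonzero(empty).tolist()})"
            )
        a = counts / n
        with np.errstate(divide="ignore"):
            w_group = np.where(counts > 0, props / np.where(a > 0, a, 1.0), 0.0)
        return w_group[idx]


def standardize(values, ages=None, weights: ICSSWeights | None = None) -> float:
    """Marginal (standardised) estimate from per-individual predictions.

    With ``weights=None`` this is the plain average of the individual
    predictions; with an :class:`ICSSWeights` it is the externally
    age-standardised mean ``(1/N) sum_i w_i v_i`` with ``w_i = w^s_i / a_i``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty cohort")
    if weights is None:
        return float(np.mean(values))
    if ages is None:
        raise ValueError("external standardisation requires ages")
    w = weights.individual_weights(ages)
    return float(np.mean(w * values))
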