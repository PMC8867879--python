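"""Latent natural history of breast cancer: onset, growth, symptomatic
detection.

The generator follows the Swedish continuous tumour-growth model family:
tumour onset occurs at most once per woman according to age-specific yearly
probabilities; from a starting diameter ``d0`` the tumour volume grows
exponentially with an individual inverse growth rate tau (the volume
e-folding time, drawn from a gamma distribution); symptomatic detection is
the first event of an inhomogeneous Poisson process whose intensity is
proportional to current tumour volume (rate ``eta`` per mm^3 per year).
Everything here is independent of screening and of death: it is the latent
record that all screening scenarios are layered on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NaturalHistoryParams",
    "LatentHistory",
    "LatentPopulation",
    "default_onset_probabilities",
    "simulate_onset",
    "tumour_diameter",
    "simulate_symptomatic_age",
    "simulate_population",
]


def default_onset_probabilities(age_cap: int = 100) -> np.ndarray:
    """Stand-in age-specific yearly probabilities of tumour onset.

    A smooth logistic ramp: negligible risk before age 20, rising through
    the 30s to a plateau of 0.0020/year from middle age on.  Calibrated only
    qualitatively, so that without screening the median age at symptomatic
    diagnosis is close to 62 and the bulk of tumours present below 32.5 mm.
    """
    ages = np.arange(age_cap)
    p = 0.0020 / (1.0 + np.exp(-(ages - 32.0) / 6.0))
    p[ages < 20] = 0.0
    return p


@dataclass
class NaturalHistoryParams:
    """Parameters of the latent disease process.

    ``onset_prob[a]`` is the probability of tumour onset during age year
    ``a`` given no earlier onset; ``d0`` the diameter at onset (mm);
    ``tau_shape``/``tau_scale`` the gamma distribution of the inverse volume
    growth rate tau (years); ``eta`` the symptomatic-detection intensity per
    mm^3 of tumour per year.
    """

    onset_prob: np.ndarray = field(default_factory=default_onset_probabilities)
    d0: float = 0.5
    tau_shape: float = 2.0
    tau_scale: float = 0.5
    eta: float = 2.6e-4
    cohort_size: int = 10_000
    birth_years: tuple[int, int] = (1870, 1965)

    def __post_init__(self):
        self.onset_prob = np.asarray(self.onset_prob, dtype=float)
        if np.any(self.onset_prob < 0) or np.any(self.onset_prob > 1):
            raise ValueError("onset probabilities must lie in [0, 1]")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.tau_shape <= 0 or self.tau_scale <= 0:
            raise ValueError("gamma parameters of tau must be positive")
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")


@dataclass
class LatentHistory:
    """One woman's counterfactual disease record (screening-independent)."""

    id: int
    birth_year: int
    onset_age: float  # nan if no onset
    tau: float  # nan if no onset
    symptomatic_age: float  # nan if never symptomatic before the age cap

    def diameter_at(self, age: float, d0: float = 0.5) -> float:
        return float(tumour_diameter(d0, self.tau, self.onset_age, age))


@dataclass
class LatentPopulation:
    """Vectorised container of latent histories (one row per woman)."""

    ids: np.ndarray
    birth_year: np.ndarray
    onset_age: np.ndarray
    tau: np.ndarray
    symptomatic_age: np.ndarray
    d0: float = 0.5

    @property
    def n(self) -> int:
        return self.ids.size

    def history(self, i: int) -> LatentHistory:
        return LatentHistory(
            id=int(self.ids[i]),
            birth_year=int(self.birth_year[i]),
            onset_age=float(self.onset_age[i]),
            tau=float(self.tau[i]),
            symptomatic_age=float(self.symptomatic_age[i]),
        )


def simulate_onset(params: NaturalHistoryParams, n: int, rng: np.random.Generator,
                   age_cap: int = 100) -> np.ndarray:
    """Ages at tumour onset for ``n`` women (nan where onset never occurs).

    Equivalent to scanning integer ages in order and taking the first
    Bernoulli success (sampled via the inverse CDF of the first-success
    distribution); the onset is placed uniformly within the winning year.
    At most one onset per woman.
    """
    p = params.onset_prob[:age_cap]
    surv = np.cumprod(1.0 - p)
    pmf = p.copy()
    pmf[1:] = p[1:] * surv[:-1]
    cdf = np.cumsum(pmf)
    u = rng.uniform(size=n)
    idx = np.searchsorted(cdf, u, side="right")
    onset = np.full(n, np.nan)
    hit = idx < p.size
    onset[hit] = idx[hit] + rng.uniform(size=int(hit.sum()))
    return onset


def tumour_diameter(d0: float, tau, onset_age, age):
    """Tumour diameter (mm) at a given age under exponential volume growth.

    Volume V(t) = V0 exp(t / tau) with t the time since onset, so the
    diameter of the spherical tumour is ``d0 * exp(t / (3 tau))``.
    """
    t = np.asarray(age, dtype=float) - np.asarray(onset_age, dtype=float)
    if np.any(t < -1e-12):
        raise ValueError("age before tumour onset")
    t = np.maximum(t, 0.0)
    out = d0 * np.exp(t / (3.0 * np.asarray(tau, dtype=float)))
    return out if out.ndim else float(out)


def simulate_symptomatic_age(onset_age, tau, params: NaturalHistoryParams,
                             rng: np.random.Generator,
                             age_cap: int = 100) -> np.ndarray:
    """Latent age at symptomatic detection (nan if beyond the age cap).

    Detection is the first event of a Poisson process with intensity
    ``eta * V(age)``.  With exponential volume the waiting time t since
    onset solves ``eta * V0 * tau * (exp(t/tau) - 1) = E`` for a standard
    exponential deviate E, i.e. ``t = tau * log1p(E / (eta * V0 * tau))``.
    """
    onset_age = np.asarray(onset_age, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if params.eta < 0:
        raise ValueError("eta must be non-negative")
    e = rng.exponential(size=onset_age.shape)
    if params.eta == 0:
        return np.full(onset_age.shape, np.nan)
    v0 = np.pi / 6.0 * params.d0**3
    t = tau * np.log1p(e / (params.eta * v0 * tau))
    age = onset_age + t
    age[age >= age_cap] = np.nan
    return age


def simulate_population(params: NaturalHistoryParams, rng: np.random.Generator,
                        age_cap: int = 100) -> LatentPopulation:
    """Simulate the full latent population across birth cohorts.

    Draws, per woman: onset age (at most one tumour), the inverse growth
    rate tau, and the latent symptomatic-detection age.  The returned
    population is the fixed substrate on which screening scenarios (and
    death) are imposed.
    """
    y0, y1 = params.birth_years
    birth_year = np.repeat(np.arange(y0, y1 + 1), params.cohort_size)
    n = birth_year.size
    onset = simulate_onset(params, n, rng, age_cap=age_cap)
    tau = np.full(n, np.nan)
    sympt = np.full(n, np.nan)
    has = np.isfinite(onset)
    m = int(has.sum())
    if m:
        tau[has] = rng.gamma(params.tau_shape, params.tau_scale, size=m)
        sympt[has] = simulate_symptomatic_age(onset[has], tau[has], params, rng,
                                              age_cap=age_cap)
    return LatentPopulation(
        ids=np.arange(n),
        birth_year=birth_year,
        onset_age=onset,
        tau=tau,
        symptomatic_age=sympt,
        d0=params.d0,
    )
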