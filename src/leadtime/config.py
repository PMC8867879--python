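"""Configuration of the simulation study.

A single nested configuration covers the life table, natural history,
generating survival model, screening scenario grid, estimation settings and
experiment scale.  Defaults mirror the full study design (96 birth cohorts
of 10,000 women, 200 replicates); :func:`default_config` with ``fast=True``
returns a desk-scale profile (500 women per cohort, 20 replicates) suitable
for testing and exploration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .lifetables import LifeTable, make_synthetic_lifetable, read_lifetable
from .mortality import GeneratingFPM
from .natural_history import NaturalHistoryParams, default_onset_probabilities

__all__ = ["Config", "default_config", "load_config", "save_config", "build_lifetable",
           "build_generating_fpm", "build_natural_history"]


@dataclass
class LifeTableConfig:
    kind: str = "synthetic"  # "synthetic" | "file"
    path: str | None = None
    dialect: str = "csv"
    gompertz_a: float = 3.0e-5
    gompertz_b: float = 0.095
    makeham_c: float = 6.0e-4
    year_drift: float = 0.998
    reference_year: int = 1950
    years: tuple[int, int] = (1870, 2070)
    age_cap: int = 100


@dataclass
class NaturalHistoryConfig:
    d0: float = 0.5
    tau_shape: float = 2.0
    tau_scale: float = 0.5
    eta: float = 2.6e-4
    onset_path: str | None = None  # optional two-column CSV (age, probability)


@dataclass
class GeneratingFPMConfig:
    # knots on natural time (years since symptomatic diagnosis)
    knots_time: tuple = (0.1, 1.0, 3.0, 12.0)
    gamma: tuple = (-3.3750, 0.7896, -0.0731, 0.1090)
    alpha: float = 0.02


@dataclass
class ScreeningGridConfig:
    first_age: int = 40
    last_age: int = 74
    interval: int = 2
    sensitivities: tuple = ("low", "moderate", "high")
    attendances: tuple = ("perfect", "imperfect")
    fraction_high: float = 0.8
    p_high: float = 0.9
    fraction_low: float = 0.2
    p_low: float = 0.15


@dataclass
class EstimationConfig:
    df_baseline: int = 3
    df_tvc: int = 3
    censor_years: float = 12.0
    window: tuple[int, int] = (1970, 1975)  # [start, end) calendar years
    use_icss: bool = True
    quadrature_nodes: int = 8
    min_events: int = 10


@dataclass
class ExperimentConfig:
    n_replicates: int = 200
    cohort_size: int = 10_000
    birth_years: tuple[int, int] = (1870, 1965)
    base_seed: int = 20220223


@dataclass
class Config:
    lifetable: LifeTableConfig = field(default_factory=LifeTableConfig)
    natural_history: NaturalHistoryConfig = field(default_factory=NaturalHistoryConfig)
    generating_fpm: GeneratingFPMConfig = field(default_factory=GeneratingFPMConfig)
    screening: ScreeningGridConfig = field(default_factory=ScreeningGridConfig)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config(fast: bool = False) -> Config:
    """The study conditions; ``fast=True`` scales the cohorts and replicate
    count down for desk-scale runs without touching any other parameter."""
    cfg = Config()
    if fast:
        cfg.experiment.cohort_size = 500
        cfg.experiment.n_replicates = 20
    return cfg


def _apply(obj, data: dict):
    for key, val in data.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config key: {key}")
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            _apply(cur, val)
        else:
            if isinstance(cur, tuple) and isinstance(val, list):
                val = tuple(val)
            setattr(obj, key, val)


def load_config(path) -> Config:
    """Load a YAML configuration; unspecified blocks keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = Config()
    _apply(cfg, data)
    return cfg


def save_config(cfg: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(cfg.to_dict(), default=list)), fh)


# -- builders -----------------------------------------------------------


def build_lifetable(cfg: Config) -> LifeTable:
    lt = cfg.lifetable
    if lt.kind == "file":
        if lt.path is None:
            raise ValueError("lifetable.kind='file' requires lifetable.path")
        return read_lifetable(lt.path, dialect=lt.dialect, age_cap=lt.age_cap)
    return make_synthetic_lifetable(
        a=lt.gompertz_a,
        b=lt.gompertz_b,
        c=lt.makeham_c,
        year_drift=lt.year_drift,
        years=tuple(lt.years),
        age_cap=lt.age_cap,
        reference_year=lt.reference_year,
    )


def build_generating_fpm(cfg: Config) -> GeneratingFPM:
    g = cfg.generating_fpm
    return GeneratingFPM(
        knots=np.log(np.asarray(g.knots_time, dtype=float)),
        gamma=np.asarray(g.gamma, dtype=float),
        alpha=g.alpha,
    )


def build_natural_history(cfg: Config) -> NaturalHistoryParams:
    nh = cfg.natural_history
    if nh.onset_path is not None:
        import pandas as pd

        df = pd.read_csv(nh.onset_path)
        onset = np.zeros(cfg.lifetable.age_cap)
        ages = df.iloc[:, 0].astype(int).to_numpy()
        onset[ages] = df.iloc[:, 1].to_numpy()
    else:
        onset = default_onset_probabilities(cfg.lifetable.age_cap)
    return NaturalHistoryParams(
        onset_prob=onset,
        d0=nh.d0,
        tau_shape=nh.tau_shape,
        tau_scale=nh.tau_scale,
        eta=nh.eta,
        cohort_size=cfg.experiment.cohort_size,
        birth_years=tuple(cfg.experiment.birth_years),
    )
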