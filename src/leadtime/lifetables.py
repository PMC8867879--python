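"""Population life tables: expected mortality of a cancer-free comparison
population.

The life table houses the expected mortality rate h*(age, year) used in three
places: simulating other-cause death, the excess-hazard likelihood (expected
rate at exit), and the expected-survival integrals behind loss in life
expectancy.  Rates are treated as piecewise constant on one-year intervals of
attained age and calendar year simultaneously.  At and beyond ``age_cap``
(default 100, the longest lifetime considered) the rate is treated as
infinite, i.e. certain death.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "make_synthetic_lifetable",
    "read_lifetable",
    "expected_survival",
]


@dataclass(frozen=True)
class LifeTable:
    """Grid-complete table of expected mortality rates.

    Parameters
    ----------
    ages, years:
        Contiguous integer grids (years of age, calendar years).
    rates:
        Array of shape ``(len(ages), len(years))`` with per person-year
        mortality rates, all strictly positive.
    age_cap:
        Age at which death is certain; must be at least 100.
    """

    ages: np.ndarray
    years: np.ndarray
    rates: np.ndarray
    age_cap: int = 100
    sex: str = "female"

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        years = np.asarray(self.years, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        if ages.size == 0 or years.size == 0:
            raise ValueError("empty age or year grid")
        if not np.all(np.diff(ages) == 1) and ages.size > 1:
            raise ValueError("ages must be contiguous integers")
        if not np.all(np.diff(years) == 1) and years.size > 1:
            raise ValueError("years must be contiguous integers")
        if rates.shape != (ages.size, years.size):
            raise ValueError("rates must have shape (n_ages, n_years)")
        if not np.all(np.isfinite(rates)) or np.any(rates <= 0):
            raise ValueError("all rates must be finite and > 0")
        if self.age_cap < 100:
            raise ValueError("age_cap must be at least 100")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "rates", rates)

    # -- lookups ---------------------------------------------------------

    def rate(self, age, year):
        """Expected mortality rate at integer (age, year).

        Ages at or above ``age_cap`` return ``inf`` (certain death).  Calendar
        years beyond the last tabulated year carry the last year's rates
        forward; years before the first tabulated year raise.
        """
        age = np.asarray(age)
        year = np.asarray(year)
        if np.any(year < self.years[0]):
            raise ValueError("calendar year before the start of the table")
        a = np.floor(age).astype(int)
        if np.any((a < self.ages[0]) & (a < self.age_cap)):
            raise ValueError("age below the table's age grid")
        y_idx = np.clip(np.floor(year).astype(int) - self.years[0], 0, self.years.size - 1)
        capped = a >= self.age_cap
        a_idx = np.clip(a - self.ages[0], 0, self.ages.size - 1)
        if np.any(~capped & (a - self.ages[0] > self.ages.size - 1)):
            raise ValueError("age above the table's age grid but below age_cap")
        out = self.rates[a_idx, y_idx]
        out = np.where(capped, np.inf, out)
        return out if out.ndim else float(out)

    def cumulative_hazard(self, age_at_start: float, year_at_start: float, t):
        """Integrated expected hazard from (age, year) over elapsed times t.

        The rate is a step function on one-year intervals of attained age and
        calendar year; the integral splits at every integer crossing of
        either.  ``t`` may be a scalar or array (any order).
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        tmax = float(np.max(t)) if t.size else 0.0
        # Breakpoints where attained age or calendar year crosses an integer.
        brks = {0.0}
        for start in (age_at_start, year_at_start):
            first = np.ceil(start) - start
            if first == 0.0:
                first = 1.0
            brks.update(np.arange(first, tmax, 1.0).tolist())
        b = np.array(sorted(brks))
        mids = b + 1e-9  # just inside each segment
        seg_age = np.floor(age_at_start + mids)
        seg_year = np.floor(year_at_start + mids)
        seg_rate = np.where(
            seg_age >= self.age_cap, np.inf, self._rate_clipped(seg_age, seg_year)
        )
        widths = np.diff(np.append(b, max(tmax, b[-1] + 1.0)))
        cum = np.concatenate([[0.0], np.cumsum(seg_rate * widths)])
        idx = np.searchsorted(b, t, side="right") - 1
        with np.errstate(invalid="ignore"):
            out = cum[idx] + seg_rate[idx] * (t - b[idx])
        # inf * 0 at a segment start -> cumulative value at the breakpoint
        out = np.where(t == b[idx], cum[idx], out)
        out = np.where(np.isnan(out), np.inf, out)
        return out if out.ndim else float(out)

    def _rate_clipped(self, age, year):
        if np.any(year < self.years[0]):
            raise ValueError("calendar year before the start of the table")
        a = np.floor(age).astype(int) - self.ages[0]
        if np.any(a < 0) or np.any(a > self.ages.size - 1):
            raise ValueError("age outside the table's age grid")
        y = np.clip(np.floor(year).astype(int) - self.years[0], 0, self.years.size - 1)
        return self.rates[a, y]


def make_synthetic_lifetable(
    a: float,
    b: float,
    c: float = 0.0,
    year_drift: float = 1.0,
    years: tuple[int, int] = (1870, 2065),
    age_cap: int = 100,
    reference_year: int | None = None,
    rate_floor: float = 1e-10,
) -> LifeTable:
    """Gompertz–Makeham life table with an optional secular trend.

    ``rate(age, year) = (c + a * exp(b * age)) * year_drift**(year - ref)``,
    clamped below at ``rate_floor``.  A stand-in for registry/HMD tables.
    """
    if a <= 0 or b <= 0:
        raise ValueError("Gompertz parameters a and b must be positive")
    if c < 0:
        raise ValueError("Makeham term c must be non-negative")
    if year_drift <= 0:
        raise ValueError("year_drift must be positive")
    y0, y1 = int(years[0]), int(years[1])
    if y1 < y0:
        raise ValueError("empty year range")
    if reference_year is None:
        reference_year = y0
    ages = np.arange(0, age_cap)
    yrs = np.arange(y0, y1 + 1)
    base = c + a * np.exp(b * ages)
    drift = year_drift ** (yrs - reference_year)
    rates = np.maximum(np.outer(base, drift), rate_floor)
    return LifeTable(ages=ages, years=yrs, rates=rates, age_cap=age_cap)


def _parse_age(val) -> int:
    s = str(val).strip()
    if s.endswith("+"):
        s = s[:-1]
    return int(float(s))


def read_lifetable(path, dialect: str = "csv", age_cap: int = 100) -> LifeTable:
    """Read a life table from delimited text.

    ``dialect='csv'`` expects columns ``year, age, rate`` (comma or
    whitespace separated, header optional when the order matches).
    ``dialect='hmd'`` accepts the Human Mortality Database period life-table
    layout (``fltper_1x1``-like: ``Year Age mx ...``), taking the female
    death-rate column ``mx``.  Open age groups such as ``110+`` map to the
    integer age.  Any gap in the (age, year) grid is an error, never an
    interpolation.
    """
    if dialect == "csv":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        cols = {c.lower().strip(): c for c in df.columns}
        if not {"year", "age", "rate"} <= set(cols):
            # headerless: positional year, age, rate
            df = pd.read_csv(
                path, sep=None, engine="python", comment="#", header=None,
                names=["year", "age", "rate"],
            )
            cols = {c: c for c in df.columns}
        df = df.rename(columns={cols["year"]: "year", cols["age"]: "age", cols["rate"]: "rate"})
    elif dialect == "hmd":
        with open(path) as fh:
            lines = fh.readlines()
        header_idx = next(
            (i for i, ln in enumerate(lines) if ln.split() and ln.split()[0] == "Year"),
            None,
        )
        if header_idx is None:
            raise ValueError("no 'Year' header line found in HMD-style file")
        df = pd.read_csv(
            io.StringIO("".join(lines[header_idx:])), sep=r"\s+", na_values=["."]
        )
        rate_col = "mx" if "mx" in df.columns else "Female"
        if rate_col not in df.columns:
            raise ValueError("no death-rate column (mx/Female) in HMD-style file")
        df = df.rename(columns={"Year": "year", "Age": "age", rate_col: "rate"})
        df = df[["year", "age", "rate"]]
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    try:
        df["year"] = df["year"].astype(int)
        df["age"] = df["age"].map(_parse_age)
        df["rate"] = df["rate"].astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable life-table rows: {exc}") from exc
    if df["rate"].isna().any():
        raise ValueError("missing rates in life-table file")
    if np.any(df["rate"].to_numpy() <= 0):
        raise ValueError("non-positive rates in life-table file")

    wide = df.pivot_table(index="age", columns="year", values="rate", aggfunc="first")
    ages = np.arange(wide.index.min(), wide.index.max() + 1)
    years = np.arange(wide.columns.min(), wide.columns.max() + 1)
    wide = wide.reindex(index=ages, columns=years)
    if wide.isna().any().any():
        missing = int(wide.isna().to_numpy().sum())
        raise ValueError(f"life-table grid has {missing} missing (age, year) cells")
    return LifeTable(ages=ages, years=years, rates=wide.to_numpy(), age_cap=age_cap)


def expected_survival(table: LifeTable, age_at_start: float, year_at_start: float, t):
    """Expected (cancer-free) survival S*(t) from a starting age and year.

    ``S*(t) = exp(-int_0^t h*(age+u, year+u) du)`` with the rate piecewise
    constant on yearly attained-age/calendar intervals.  ``t`` scalar or
    array.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    if np.any(age_at_start + t_arr > table.age_cap):
        raise ValueError("horizon beyond the table's age cap")
    H = table.cumulative_hazard(age_at_start, year_at_start, t_arr)
    out = np.exp(-np.asarray(H))
    return out if out.ndim else float(out)
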