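"""Life-table construction and life-expectancy summaries.

Standard period life-table arithmetic from central death rates m_x: for a
closed interval of width n with separation factor a (average fraction of the
interval lived by those dying in it), q = n*m / (1 + (n - a*n)*m) capped at
1; the open interval closes with q = 1 and L = l/m.  Complete (single-year)
tables are built from the smooth model's predicted rates; an abridged
(5-year) constructor is provided for band-level rates.  Life expectancy at
exact age x is e_x = T_x / l_x.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hazards import QUINTILES
from .model import FittedRateModel, predict_rates

RADIX = 100_000.0
DEFAULT_A0 = 0.1          # infant separation factor (low-mortality convention)
DEFAULT_A = 0.5
DEFAULT_OPEN_AGE = 100    # open interval of model-based complete tables

LIFETABLE_COLUMNS = ["age", "m", "a", "q", "l", "d", "L", "T", "e"]


def _build_table(ages: np.ndarray, widths: np.ndarray, m: np.ndarray,
                 a_frac: np.ndarray, radix: float) -> pd.DataFrame:
    """Shared recursion; ``a_frac`` is the within-interval fraction (of the
    width) lived by decedents; the last interval is open."""
    m = np.asarray(m, dtype=float)
    bad = ~(np.isfinite(m) & (m > 0))
    if bad.any():
        raise ValueError(
            f"non-positive or non-finite death rate at age(s) {ages[bad].tolist()}")
    k = len(m)
    n = widths.astype(float)
    a_abs = a_frac * n
    q = np.empty(k)
    q[:-1] = n[:-1] * m[:-1] / (1.0 + (n[:-1] - a_abs[:-1]) * m[:-1])
    q[:-1] = np.minimum(q[:-1], 1.0)
    q[-1] = 1.0

    l = np.empty(k)
    l[0] = radix
    for i in range(k - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = np.empty(k)
    d[:-1] = l[:-1] - l[1:]
    d[-1] = l[-1]
    L = np.empty(k)
    L[:-1] = n[:-1] * l[1:] + a_abs[:-1] * d[:-1]
    L[-1] = l[-1] / m[-1]
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)
    return pd.DataFrame({"age": ages.astype(float), "m": m, "a": a_frac,
                         "q": q, "l": l, "d": d, "L": L, "T": T, "e": e})


def rates_to_lifetable(m_by_age, a0: float = DEFAULT_A0, a: float = DEFAULT_A,
                       radix: float = RADIX) -> pd.DataFrame:
    """Complete life table from single-year rates for ages 0..A (last open).

    ``m_by_age`` is a sequence of central death rates on a contiguous
    single-year grid starting at 0; the last entry is the open interval's
    rate.  ``a0`` applies to age 0, ``a`` to the other closed ages.
    """
    m = np.asarray(m_by_age, dtype=float)
    if m.ndim != 1 or len(m) < 2:
        raise ValueError("need single-year rates for at least ages 0 and the open age")
    ages = np.arange(len(m))
    widths = np.ones(len(m))
    a_frac = np.full(len(m), a)
    a_frac[0] = a0
    return _build_table(ages, widths, m, a_frac, radix)


def abridged_rates_to_lifetable(age_lower, m, a: float = 0.5,
                                radix: float = RADIX) -> pd.DataFrame:
    """Abridged life table from band rates (5-year bands, last open).

    ``a`` is the fraction of the band width lived by those dying in it
    (0.5 = mid-band, adequate for hazards without an infant spike).
    """
    ages = np.asarray(age_lower, dtype=float)
    if ages[0] != 0 or np.any(np.diff(ages) <= 0):
        raise ValueError("age_lower must start at 0 and increase")
    widths = np.empty(len(ages))
    widths[:-1] = np.diff(ages)
    widths[-1] = np.inf  # open; unused
    a_frac = np.full(len(ages), a)
    return _build_table(ages, widths, m, a_frac, radix)


def life_expectancy_at(table: pd.DataFrame, age: float) -> float:
    """Remaining life expectancy e_x at an exact age on the table's grid."""
    hit = table.index[table["age"] == float(age)]
    if len(hit) == 0:
        if age > table["age"].max():
            raise ValueError(f"age {age} lies beyond the open interval")
        raise ValueError(f"age {age} is not on the table's age grid")
    return float(table.loc[hit[0], "e"])


def _table_from_rates(m: np.ndarray, a0: float, a: float) -> pd.DataFrame:
    return rates_to_lifetable(m, a0=a0, a=a)


def quintile_lifetables(model: FittedRateModel, mode: str = "median",
                        open_age: int = DEFAULT_OPEN_AGE, a0: float = DEFAULT_A0,
                        a: float = DEFAULT_A, at_ages: tuple[float, ...] = (0.0, 75.0)
                        ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Complete life tables and LE summaries per deprivation quintile.

    Predicts single-year rates at ages 0..open_age-1 plus the open interval
    (random intercept handled per ``mode``), builds one table per quintile,
    and returns LE at the requested exact ages.  Rates beyond the last knot
    extrapolate the spline's linear tail.
    """
    ages = np.arange(0, open_age + 1, dtype=float)
    tables: dict[str, pd.DataFrame] = {}
    rows = []
    for q in model.quintile_levels:
        pred = predict_rates(model, ages, q, mode=mode)
        lt = _table_from_rates(pred["rate"].to_numpy(), a0, a)
        tables[q] = lt
        for at in at_ages:
            rows.append({"sex": model.sex, "stratum": q, "at_age": at,
                         "le": life_expectancy_at(lt, at)})
    return tables, pd.DataFrame(rows)


def area_lifetables(model: FittedRateModel, areas=None,
                    open_age: int = DEFAULT_OPEN_AGE, a0: float = DEFAULT_A0,
                    a: float = DEFAULT_A, at_ages: tuple[float, ...] = (0.0, 75.0),
                    area_quintiles: pd.Series | None = None) -> pd.DataFrame:
    """Per-area LE from tract-specific predictions.

    Each area's rates are its quintile's fixed-effect prediction scaled by
    exp(empirical-Bayes intercept); ``area_quintiles`` maps area_id ->
    quintile (required when ``areas`` alone cannot determine it).  Returns a
    row per (area, at_age).
    """
    if area_quintiles is None:
        raise ValueError("area_quintiles mapping (area_id -> quintile) is required")
    if areas is None:
        areas = list(model.area_intercepts.index)
    unknown = [a_ for a_ in areas if a_ not in model.area_intercepts.index]
    if unknown:
        raise KeyError(f"areas without fitted intercepts: {unknown[:5]}"
                       + ("..." if len(unknown) > 5 else ""))
    ages = np.arange(0, open_age + 1, dtype=float)
    base = {q: predict_rates(model, ages, q, mode="median")["rate"].to_numpy()
            for q in model.quintile_levels}
    rows = []
    for area in areas:
        q = area_quintiles.loc[area]
        scale = float(np.exp(model.area_intercepts.loc[area]))
        lt = _table_from_rates(base[q] * scale, a0, a)
        for at in at_ages:
            rows.append({"sex": model.sex, "stratum": area, "quintile": q,
                         "at_age": at, "le": life_expectancy_at(lt, at)})
    return pd.DataFrame(rows)


def write_lifetable(table: pd.DataFrame, path) -> None:
    """Write a life table as CSV with columns age, m, q, l, d, L, T, e."""
    table[["age", "m", "q", "l", "d", "L", "T", "e"]].to_csv(path, index=False)
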