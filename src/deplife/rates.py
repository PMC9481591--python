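"""Descriptive mortality layer: crude rates, indirect-method SMRs, trend test.

Crude rates carry exact Poisson (Garwood) confidence limits by default, valid
at small counts; a normal approximation is available behind a flag.  SMRs use
the indirect method (observed / expected under a reference stratum's
age-specific rates) with Byar's approximation for the interval.  The calendar
trend test is a Poisson log-linear model of yearly death totals with a log
person-years offset.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

log = logging.getLogger(__name__)

DEFAULT_SCALE = 1000.0  # display multiplier: rates reported per 1,000 person-years


@dataclass(frozen=True)
class RateEstimate:
    """Crude rate on a display scale with a 95% interval."""
    rate: float
    ci_low: float
    ci_high: float
    n_deaths: float
    person_years: float
    scale: float = DEFAULT_SCALE


@dataclass(frozen=True)
class SMREstimate:
    """Indirectly standardized mortality ratio with Byar 95% limits."""
    observed: float
    expected: float
    smr: float
    ci_low: float
    ci_high: float
    reference_label: str = ""


def poisson_ci(deaths: float, alpha: float = 0.05) -> tuple[float, float]:
    """Garwood exact Poisson limits on a count."""
    if deaths < 0:
        raise ValueError("deaths must be >= 0")
    low = 0.0 if deaths == 0 else chi2.ppf(alpha / 2, 2 * deaths) / 2
    high = chi2.ppf(1 - alpha / 2, 2 * (deaths + 1)) / 2
    return float(low), float(high)


def crude_rate(deaths: float, person_years: float, scale: float = DEFAULT_SCALE,
               alpha: float = 0.05, method: str = "garwood") -> RateEstimate:
    """Crude mortality rate with a 95% CI.

    ``method='garwood'`` (default) uses exact Poisson limits on the count;
    ``method='normal'`` the usual rate +/- z*sqrt(deaths)/person-years
    approximation.
    """
    if person_years <= 0:
        raise ValueError("person_years must be > 0")
    if deaths < 0:
        raise ValueError("deaths must be >= 0")
    rate = deaths / person_years * scale
    if method == "garwood":
        lo, hi = poisson_ci(deaths, alpha)
        lo, hi = lo / person_years * scale, hi / person_years * scale
    elif method == "normal":
        z = norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(deaths) / person_years * scale
        lo, hi = max(0.0, rate - half), rate + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return RateEstimate(rate, lo, hi, deaths, person_years, scale)


def stratum_rates(table: pd.DataFrame, by: list[str],
                  scale: float = DEFAULT_SCALE, alpha: float = 0.05,
                  method: str = "garwood") -> pd.DataFrame:
    """Crude rates per stratum, pooling deaths and person-years before dividing.

    Returns one row per stratum with the grouping keys, pooled counts and the
    rate/CI columns.  Strata with zero person-years are dropped with a warning.
    """
    missing = [k for k in by if k not in table.columns]
    if missing:
        raise KeyError(f"stratification keys not in table: {missing}")
    grouped = table.groupby(by, as_index=False, observed=True)[["deaths", "population"]].sum()
    empty = grouped["population"] <= 0
    if empty.any():
        log.warning("dropping %d empty strata (zero person-years)", int(empty.sum()))
        grouped = grouped[~empty]
    rows = []
    for _, r in grouped.iterrows():
        est = crude_rate(r["deaths"], r["population"], scale, alpha, method)
        rows.append({**{k: r[k] for k in by},
                     "deaths": r["deaths"], "population": r["population"],
                     "rate": est.rate, "ci_low": est.ci_low, "ci_high": est.ci_high})
    return pd.DataFrame(rows)


def reference_rates(reference: pd.DataFrame) -> pd.Series:
    """Age-band rates (deaths/person-years) of a reference stratum, by age_lower."""
    pooled = reference.groupby("age_lower")[["deaths", "population"]].sum()
    return pooled["deaths"] / pooled["population"]


def smr_indirect(index: pd.DataFrame, reference: pd.Series,
                 reference_label: str = "", alpha: float = 0.05) -> SMREstimate:
    """Indirect-method SMR of an index stratum against reference band rates.

    ``reference`` maps age_lower -> rate per person-year and must cover every
    band present in ``index``.  Expected deaths = sum over bands of reference
    rate x index person-years; the 95% interval is Byar's approximation on the
    observed count.
    """
    pooled = index.groupby("age_lower")[["deaths", "population"]].sum()
    missing = sorted(set(pooled.index) - set(reference.index))
    if missing:
        raise ValueError(f"reference rates missing for age bands: {missing}")
    expected = float((reference.loc[pooled.index] * pooled["population"]).sum())
    observed = float(pooled["deaths"].sum())
    if expected <= 0:
        raise ValueError("expected deaths must be > 0")
    smr = observed / expected
    z = norm.ppf(1 - alpha / 2)
    if observed > 0:
        lo = observed * (1 - 1 / (9 * observed) - z / (3 * np.sqrt(observed))) ** 3
        op = observed + 1
        hi = op * (1 - 1 / (9 * op) + z / (3 * np.sqrt(op))) ** 3
        lo, hi = lo / expected, hi / expected
    else:
        lo, hi = 0.0, chi2.ppf(1 - alpha / 2, 2) / 2 / expected
    return SMREstimate(observed, expected, smr, lo, hi, reference_label)


def smr_by_quintile(table: pd.DataFrame, reference_quintile: str = "Q1",
                    by: tuple[str, ...] = ("sex", "year")) -> pd.DataFrame:
    """SMR of each quintile against the reference quintile within sex and year."""
    rows = []
    for keys, sub in table.groupby(list(by), observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        ref = reference_rates(sub[sub["quintile"] == reference_quintile])
        for q, qsub in sub.groupby("quintile", observed=True):
            est = smr_indirect(qsub, ref, reference_label=reference_quintile)
            rows.append({**dict(zip(by, keys)), "quintile": q,
                         "observed": est.observed, "expected": est.expected,
                         "smr": est.smr, "smr_ci_low": est.ci_low,
                         "smr_ci_high": est.ci_high})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrendResult:
    slope: float           # log-rate change per calendar year
    se: float
    p_value: float
    n_years: int


def trend_test(yearly: pd.DataFrame) -> TrendResult:
    """Poisson log-linear trend of yearly death totals on calendar year.

    ``yearly`` needs columns year, deaths, population (person-years).  Fitted
    by IRLS with a log person-years offset; returns the Wald test of the year
    coefficient.
    """
    if yearly["year"].nunique() < 3:
        raise ValueError("trend test needs >= 3 distinct years")
    pooled = yearly.groupby("year", as_index=False)[["deaths", "population"]].sum()
    if (pooled["deaths"] == 0).all():
        raise ValueError("all-zero deaths: trend is undefined")
    year = pooled["year"].to_numpy(dtype=float)
    X = sm.add_constant(year - year.mean())
    fit = sm.GLM(pooled["deaths"].to_numpy(), X,
                 family=sm.families.Poisson(),
                 offset=np.log(pooled["population"].to_numpy())).fit()
    return TrendResult(float(fit.params[1]), float(fit.bse[1]),
                       float(fit.pvalues[1]), int(len(pooled)))


def load_spain_mortality() -> pd.DataFrame:
    """National deaths and person-years for Spain 2011-2013 by sex, year and
    deprivation quintile, as released with the national life-table study
    (published per-1,000 rates included for reference)."""
    ref = importlib.resources.files("deplife.data") / "spain_mortality_2011_2013.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
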