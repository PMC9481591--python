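"""Synthetic census-tract abridged mortality data with known ground truth.

Emulates the structure of small-area national mortality releases: one row
per (area, sex, calendar year, 5-year age band) carrying a death count and
person-years, areas classified into deprivation quintiles (20% of areas
each), and multiple calendar years.  Death counts are Poisson draws around
the HazardSpec's band-level central death rates times an area-level
lognormal frailty, so every downstream stage can be tested against the
closed-form oracle in :mod:`deplife.hazards`.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from .hazards import QUINTILES, HazardSpec, band_average_rate

SEXES = ("male", "female")

#: Half-open 5-year age bands [lower, upper); the last band is open (85+).
AGE_BANDS: list[tuple[int, int | None]] = [(a, a + 5) for a in range(0, 85, 5)] + [(85, None)]

#: Columns of the abridged count table, in on-disk order.
SCHEMA = ["area_id", "province_id", "quintile", "sex", "year",
          "age_lower", "age_upper", "deaths", "population"]

# Fixed population age template (shares per 5-year band, 0-4 ... 85+),
# loosely resembling a southern-European age pyramid.  Only positivity and
# full band coverage matter for correctness; normalized at import.
_POP_TEMPLATE = np.array([
    4.6, 5.0, 5.2, 5.4, 5.8, 6.4, 7.4, 8.2, 8.2, 7.6,
    7.0, 6.2, 5.4, 4.8, 4.4, 3.6, 2.6, 2.2,
])
_POP_TEMPLATE = _POP_TEMPLATE / _POP_TEMPLATE.sum()


def generate_tracts(
    n_areas: int,
    n_provinces: int = 10,
    mean_pop: float = 1311.0,
    years: tuple[int, ...] = (2011, 2012, 2013),
    seed: int = 0,
    pop_sigma: float = 0.3,
) -> pd.DataFrame:
    """Generate an area frame with populations by sex, year and age band.

    Areas receive a simulated deprivation score (standard normal); quintiles
    are assigned by score rank so each quintile holds floor(n/5) or
    ceil(n/5) areas (Q5 = most deprived).  Area total population is
    lognormal with mean ``mean_pop`` and log-sd ``pop_sigma`` (the
    inter-tract size dispersion is a modelling choice; national releases
    publish only the mean), split 50/50 by sex and spread over bands by a
    fixed template.  Deterministic given ``seed``.
    """
    if n_areas < 5:
        raise ValueError("n_areas must be >= 5 to form deprivation quintiles")
    if mean_pop <= 0:
        raise ValueError("mean_pop must be > 0")
    if n_provinces < 1:
        raise ValueError("n_provinces must be >= 1")
    rng = np.random.default_rng(seed)

    width = len(str(n_areas))
    area_ids = np.array([f"A{i:0{width}d}" for i in range(1, n_areas + 1)])
    deprivation = rng.normal(size=n_areas)
    quintile = np.empty(n_areas, dtype=object)
    order = np.argsort(deprivation, kind="stable")  # ascending: least deprived first
    for qi, chunk in enumerate(np.array_split(order, 5)):
        quintile[chunk] = QUINTILES[qi]
    province = np.array([f"P{(i * n_provinces) // n_areas + 1:02d}" for i in range(n_areas)])

    total_pop = np.maximum(
        20.0,
        np.round(rng.lognormal(np.log(mean_pop) - pop_sigma**2 / 2, pop_sigma, n_areas)),
    )

    n_bands = len(AGE_BANDS)
    lowers = np.array([b[0] for b in AGE_BANDS], dtype=float)
    uppers = np.array([np.nan if b[1] is None else b[1] for b in AGE_BANDS], dtype=float)
    # population per band per sex: template share * total / 2, at least 1
    band_pop = np.maximum(1.0, np.round(np.outer(total_pop / 2.0, _POP_TEMPLATE)))

    frames = []
    for year in years:
        for sex in SEXES:
            frames.append(pd.DataFrame({
                "area_id": np.repeat(area_ids, n_bands),
                "province_id": np.repeat(province, n_bands),
                "quintile": np.repeat(quintile, n_bands),
                "sex": sex,
                "year": int(year),
                "age_lower": np.tile(lowers, n_areas),
                "age_upper": np.tile(uppers, n_areas),
                "population": band_pop.ravel(),
            }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["area_id", "sex", "year", "age_lower"], ignore_index=True)


def _hazard_by_sex(hazard) -> dict[str, HazardSpec]:
    if isinstance(hazard, HazardSpec):
        return {s: hazard for s in SEXES}
    mapping = dict(hazard)
    missing = [s for s in SEXES if s not in mapping]
    if missing:
        raise ValueError(f"hazard mapping missing sexes: {missing}")
    return mapping


@lru_cache(maxsize=64)
def _band_rates_for(spec: HazardSpec) -> dict[tuple[str, float], float]:
    return {(q, float(lo)): band_average_rate(spec, q, lo, hi)
            for q in QUINTILES for lo, hi in AGE_BANDS}


def band_rate_table(hazard) -> dict[tuple[str, str, float], float]:
    """Central death rate per (sex, quintile, band lower age), frailty excluded."""
    rates = {}
    for sex, spec in _hazard_by_sex(hazard).items():
        for (q, lo), m in _band_rates_for(spec).items():
            rates[(sex, q, lo)] = m
    return rates


def expected_deaths(tracts: pd.DataFrame, hazard,
                    frailty: pd.Series | None = None) -> np.ndarray:
    """Poisson mean per row: person-years x band central rate x e^frailty."""
    rates = band_rate_table(hazard)
    rate = np.array([
        rates[(s, q, a)]
        for s, q, a in zip(tracts["sex"], tracts["quintile"], tracts["age_lower"])
    ])
    mean = tracts["population"].to_numpy(dtype=float) * rate
    if frailty is not None:
        mean = mean * np.exp(tracts["area_id"].map(frailty).to_numpy(dtype=float))
    return mean


def simulate_counts(tracts: pd.DataFrame, hazard, seed: int = 0) -> pd.DataFrame:
    """Draw abridged death counts for a tract frame.

    One frailty u ~ Normal(0, frailty_sd^2) per area (shared across sexes and
    years); deaths ~ Poisson(person-years x band central rate x e^u).
    Deterministic given ``seed``.
    """
    specs = _hazard_by_sex(hazard)
    sds = {spec.frailty_sd for spec in specs.values()}
    if len(sds) > 1:
        raise ValueError("frailty_sd must be identical across sexes "
                         "(one frailty per area)")
    rng = np.random.default_rng(seed)
    areas = np.sort(tracts["area_id"].unique())
    frailty = pd.Series(rng.normal(0.0, sds.pop(), len(areas)), index=areas)

    mean = expected_deaths(tracts, specs, frailty)
    if not np.all(np.isfinite(mean)) or np.any(mean < 0) or mean.max() > 1e12:
        raise ValueError("expected deaths are negative, non-finite or overflow")
    out = tracts.copy()
    out["deaths"] = rng.poisson(mean)
    return out[SCHEMA]


def write_counts(table: pd.DataFrame, path) -> None:
    """Write an abridged count table as CSV (UTF-8, header; open band's
    age_upper left empty)."""
    out = table.loc[:, SCHEMA].copy()
    out["age_lower"] = out["age_lower"].astype(int)
    out["age_upper"] = out["age_upper"].map(
        lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False, encoding="utf-8")


def read_counts(path) -> pd.DataFrame:
    """Read and validate an abridged count table written by :func:`write_counts`."""
    df = pd.read_csv(path, dtype={"area_id": str, "province_id": str,
                                  "quintile": str, "sex": str})
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    df["age_upper"] = pd.to_numeric(df["age_upper"], errors="coerce")
    validate_counts(df)
    return df[SCHEMA]


def validate_counts(df: pd.DataFrame) -> None:
    """Check count-table invariants; raise ValueError on the first violation."""
    if (df["deaths"] < 0).any() or not np.allclose(df["deaths"] % 1, 0):
        raise ValueError("deaths must be non-negative integers")
    if (df["population"] <= 0).any():
        raise ValueError("population must be strictly positive")
    keys = df[["area_id", "sex", "year", "age_lower"]]
    if keys.duplicated().any():
        raise ValueError("(area, sex, year, age band) rows must be unique")
    expected = {(float(lo), np.nan if hi is None else float(hi)) for lo, hi in AGE_BANDS}
    got = {(lo, hi if pd.notna(hi) else np.nan)
           for lo, hi in zip(df["age_lower"], df["age_upper"])}

    def _key(pairs):
        return sorted((lo, -1.0 if np.isnan(hi) else hi) for lo, hi in pairs)

    if _key(got) != _key(expected):
        raise ValueError("age bands must tile 0-4 ... 80-84, 85+ exactly")
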