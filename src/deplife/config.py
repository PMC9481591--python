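"""Pipeline configuration: defaults, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .splines import DEFAULT_CENTER_AGE, DEFAULT_KNOTS


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline.

    Synthetic-data block (ignored when ``counts_path`` is given): number of
    areas/provinces, mean tract population, calendar years, built-in Q1-Q5
    LE-at-birth gap (years) and area frailty SD.  Model block: spline knots
    (ages, years), centring age, open-band representative age, CV folds.
    Life-table block: separation factors, open age of complete tables,
    random-intercept prediction mode.  Display scale multiplies reported
    crude rates (default: per 1,000 person-years).
    """

    # input (real-data mode); None -> simulate
    counts_path: str | None = None

    # synthetic data
    n_areas: int = 500
    n_provinces: int = 10
    mean_pop: float = 1311.0
    years: tuple[int, ...] = (2011, 2012, 2013)
    gap_years: float = 3.5
    frailty_sd: float = 0.1
    seed: int = 0

    # smoothing model
    knots: tuple[float, ...] = DEFAULT_KNOTS
    center_age: float = DEFAULT_CENTER_AGE
    open_band_age: float = 90.0
    n_folds: int = 5

    # life tables
    a0: float = 0.1
    a_closed: float = 0.5
    open_age: int = 100
    prediction_mode: str = "median"   # or "mean": average over the frailty law

    # display
    display_scale: float = 1000.0

    def __post_init__(self):
        self.years = tuple(int(y) for y in self.years)
        self.knots = tuple(float(t) for t in self.knots)
        if self.prediction_mode not in ("median", "mean"):
            raise ValueError("prediction_mode must be 'median' or 'mean'")


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(cfg: PipelineConfig, path) -> None:
    data = asdict(cfg)
    data["years"] = list(cfg.years)
    data["knots"] = list(cfg.knots)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
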