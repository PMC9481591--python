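"""Geographic and quintile summaries of area life expectancy.

Province LE is the population-weighted mean of its census tracts' LE
(weights: person-years over the study period).  LE quintile maps classify
units (tracts or provinces) into five rank-based groups, Q1 = lowest LE.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def build_geo_lookup(counts: pd.DataFrame) -> pd.DataFrame:
    """Area -> province and person-years weight from a count table."""
    lk = counts.groupby("area_id", as_index=False).agg(
        province_id=("province_id", "first"),
        weight=("population", "sum"))
    if (lk["weight"] <= 0).any():
        raise ValueError("area weights must be > 0")
    return lk


def province_le(area_les: pd.DataFrame, lookup: pd.DataFrame) -> pd.DataFrame:
    """Population-weighted province LE from per-area LE results.

    ``area_les`` has columns stratum (area id), sex, at_age, le; ``lookup``
    maps area_id -> province_id with a positive weight.  Every area must be
    mapped.
    """
    merged = area_les.merge(lookup, left_on="stratum", right_on="area_id",
                            how="left")
    unmapped = merged.loc[merged["province_id"].isna(), "stratum"].unique()
    if len(unmapped):
        raise KeyError(f"areas missing from the geo lookup: {sorted(unmapped)[:10]}")
    merged["wle"] = merged["le"] * merged["weight"]
    out = merged.groupby(["sex", "at_age", "province_id"], as_index=False,
                         dropna=False).agg(wle=("wle", "sum"), w=("weight", "sum"))
    out["le"] = out["wle"] / out["w"]
    return out.rename(columns={"province_id": "stratum"})[
        ["sex", "stratum", "at_age", "le"]]


def le_quintile_bins(values: pd.Series) -> pd.Series:
    """Rank-based LE quintile label per unit (Q1 = lowest 20% of LE).

    ``values`` is indexed by unit id.  Ties break by unit id
    (lexicographic); bin sizes differ by at most 1.  Deterministic.
    """
    if len(values) < 5:
        raise ValueError("need at least 5 units to form LE quintiles")
    order = sorted(values.index, key=lambda i: (values.loc[i], str(i)))
    labels = pd.Series(index=values.index, dtype=object)
    for qi, chunk in enumerate(np.array_split(np.asarray(order, dtype=object), 5)):
        labels.loc[chunk] = f"Q{qi + 1}"
    return labels


def run_pipeline(cfg, outdir) -> dict:
    """Run the full chain: simulate/ingest -> rates -> fit -> life tables ->
    aggregation, writing all CSV products plus a JSON run log.

    Returns a dict of output paths.  Any stage failure removes the files
    written so far and re-raises with the stage name.  Outputs are
    byte-identical across reruns with the same config and seed.
    """
    # local imports keep this orchestration layer from widening the module's
    # import surface for users who only need the aggregation functions
    import json
    from pathlib import Path

    from . import __version__
    from .config import PipelineConfig
    from .hazards import default_hazard, true_life_expectancy
    from .lifetable import area_lifetables, quintile_lifetables, write_lifetable
    from .model import build_design, fit_poisson_mixed, model_to_json
    from .rates import smr_by_quintile, stratum_rates, trend_test
    from .splines import SplineSpec
    from .synthetic import (SEXES, generate_tracts, read_counts, simulate_counts,
                            write_counts)

    assert isinstance(cfg, PipelineConfig)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    import numpy
    import pandas
    import scipy
    import statsmodels

    log_info: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in vars(cfg).items()},
                      "versions": {"deplife": __version__,
                                   "numpy": numpy.__version__,
                                   "scipy": scipy.__version__,
                                   "pandas": pandas.__version__,
                                   "statsmodels": statsmodels.__version__},
                      "stages": {}}

    def _write(name, writer):
        path = outdir / name
        writer(path)
        written.append(path)
        return str(path)

    outputs: dict = {}
    stage = "setup"
    try:
        stage = "ingest"
        hazards = None
        if cfg.counts_path:
            counts = read_counts(cfg.counts_path)
        else:
            hazards = {s: default_hazard(s, cfg.gap_years, cfg.frailty_sd)
                       for s in SEXES}
            tracts = generate_tracts(cfg.n_areas, cfg.n_provinces, cfg.mean_pop,
                                     cfg.years, seed=cfg.seed)
            counts = simulate_counts(tracts, hazards, seed=cfg.seed + 1)
            outputs["counts"] = _write("counts.csv",
                                       lambda p: write_counts(counts, p))

        stage = "rates"
        by_year = stratum_rates(counts, ["sex", "year", "quintile"],
                                scale=cfg.display_scale)
        smr = smr_by_quintile(counts)
        table1 = by_year.merge(smr, on=["sex", "year", "quintile"])
        outputs["rates"] = _write("rates_table.csv",
                                  lambda p: table1.to_csv(p, index=False))
        trends = {s: vars(trend_test(counts[counts["sex"] == s]))
                  for s in sorted(counts["sex"].unique())}
        log_info["stages"]["trend"] = trends

        spec = SplineSpec(cfg.knots, cfg.center_age)
        quint_of_area = counts.groupby("area_id")["quintile"].first()
        lookup = build_geo_lookup(counts)
        summary_rows = []
        area_le_frames, prov_le_frames, quint_le_frames = [], [], []
        for sex in sorted(counts["sex"].unique()):
            stage = f"fit[{sex}]"
            design = build_design(counts[counts["sex"] == sex], spec,
                                  cfg.open_band_age)
            model = fit_poisson_mixed(design)
            outputs[f"model_{sex}"] = _write(
                f"model_{sex}.json", lambda p: model_to_json(model, p))
            log_info["stages"][f"fit_{sex}"] = {
                "sigma_u": model.sigma_u, "loglik": model.loglik,
                "n_iter": model.n_iter, "converged": model.converged,
                "knots": list(spec.knots)}

            stage = f"lifetables[{sex}]"
            tables, les = quintile_lifetables(
                model, mode=cfg.prediction_mode, open_age=cfg.open_age,
                a0=cfg.a0, a=cfg.a_closed)
            for q, lt in tables.items():
                outputs[f"lifetable_{q}_{sex}"] = _write(
                    f"lifetable_{q}_{sex}.csv",
                    lambda p, lt=lt: write_lifetable(lt, p))
            quint_le_frames.append(les)
            area_le = area_lifetables(model, open_age=cfg.open_age, a0=cfg.a0,
                                      a=cfg.a_closed,
                                      area_quintiles=quint_of_area)
            area_le_frames.append(area_le)

            stage = f"aggregate[{sex}]"
            prov = province_le(area_le[area_le["at_age"] == 0.0], lookup)
            prov_le_frames.append(prov)

            gap = (les.loc[(les["stratum"] == "Q1") & (les["at_age"] == 0), "le"].item()
                   - les.loc[(les["stratum"] == "Q5") & (les["at_age"] == 0), "le"].item())
            row = {"sex": sex, "le_gap_q1_q5_at_birth": gap}
            if hazards is not None:
                row["true_gap"] = (true_life_expectancy(hazards[sex], "Q1")
                                   - true_life_expectancy(hazards[sex], "Q5"))
            summary_rows.append(row)

        stage = "aggregate"
        area_les = pd.concat(area_le_frames, ignore_index=True)
        outputs["le_areas"] = _write(
            "le_areas.csv", lambda p: area_les.to_csv(p, index=False))
        provs = pd.concat(prov_le_frames, ignore_index=True)
        outputs["le_provinces"] = _write(
            "le_provinces.csv", lambda p: provs.to_csv(p, index=False))
        quints = pd.concat(quint_le_frames, ignore_index=True)
        outputs["le_quintiles"] = _write(
            "le_quintiles.csv", lambda p: quints.to_csv(p, index=False))

        maps = []
        for (sex, at_age), sub in area_les.groupby(["sex", "at_age"]):
            vals = sub.set_index("stratum")["le"]
            lab = le_quintile_bins(vals)
            maps.append(pd.DataFrame({"sex": sex, "at_age": at_age,
                                      "unit": lab.index, "le_quintile": lab.values}))
        for (sex, at_age), sub in provs.groupby(["sex", "at_age"]):
            vals = sub.set_index("stratum")["le"]
            lab = le_quintile_bins(vals)
            maps.append(pd.DataFrame({"sex": sex, "at_age": at_age,
                                      "unit": lab.index, "le_quintile": lab.values,
                                      "level": "province"}))
        map_df = pd.concat(maps, ignore_index=True)
        map_df["level"] = map_df.get("level", pd.Series(dtype=object)).fillna("area")
        outputs["le_quintile_maps"] = _write(
            "le_quintile_maps.csv", lambda p: map_df.to_csv(p, index=False))

        summary = pd.DataFrame(summary_rows)
        outputs["summary"] = _write(
            "summary.csv", lambda p: summary.to_csv(p, index=False))
        outputs["run_log"] = _write(
            "run_log.json",
            lambda p: Path(p).write_text(json.dumps(log_info, indent=1,
                                                    sort_keys=True)))
        return outputs
    except Exception as err:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
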