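"""Shared fixtures: deterministic synthetic datasets and fitted models.

Everything is generated in-process from seeds; no fixture files.  The
"oracle" dataset (150 exposure-rich areas, 3 years) is sized so that every
quintile has deaths across the age range, keeping the likelihood interior.
"""

import numpy as np
import pytest

from deplife import (SplineSpec, build_design, default_hazard,
                     fit_poisson_mixed, generate_tracts, simulate_counts)
from deplife.synthetic import SEXES

ORACLE_KNOTS = (2.0, 22.0, 42.0, 67.0, 82.0)


@pytest.fixture(scope="session")
def oracle_counts():
    tracts = generate_tracts(150, n_provinces=5, mean_pop=5000,
                             years=(2011, 2012, 2013), seed=11)
    return simulate_counts(tracts, {s: default_hazard(s) for s in SEXES}, seed=12)


@pytest.fixture(scope="session")
def oracle_male(oracle_counts):
    return oracle_counts[oracle_counts["sex"] == "male"].reset_index(drop=True)


@pytest.fixture(scope="session")
def oracle_male_model(oracle_male):
    design = build_design(oracle_male, SplineSpec(ORACLE_KNOTS))
    return fit_poisson_mixed(design)


@pytest.fixture(scope="session")
def default_counts():
    """Default-config synthetic country: 500 tracts, 3 years, gap 3.5 y."""
    tracts = generate_tracts(500, seed=42)
    return simulate_counts(tracts, {s: default_hazard(s) for s in SEXES}, seed=43)


@pytest.fixture(scope="session")
def default_models(default_counts):
    out = {}
    for sex in SEXES:
        design = build_design(default_counts[default_counts["sex"] == sex],
                              SplineSpec())
        out[sex] = fit_poisson_mixed(design)
    return out
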