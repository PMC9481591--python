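"""Poisson mixed-effects smoothing of abridged mortality rates.

Death counts are modelled with a log link and log person-years offset:

    log E[deaths] = log(PY) + b0 + f1(age) + sum_i b_i 1{quintile = Qi}
                    + f2(quintile x age) + u_area,

where f1 is a restricted cubic spline in the band's representative age, f2
the elementwise product of the spline columns with the quintile indicators
(Q1 is the reference), and u_area ~ Normal(0, sigma_u^2) a non-spatial area
random intercept.  Fitting maximizes the Laplace-approximated marginal
likelihood: a penalized IRLS inner loop solves jointly for (beta, u) at
fixed sigma_u, and a bounded one-dimensional search optimizes sigma_u.
Fixed-effect uncertainty comes from the inverse of the penalized Fisher
information profiled over the random effects, and predicted rates carry
delta-method intervals on the log scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .splines import DEFAULT_CENTER_AGE, SplineSpec, rcs_basis
from .hazards import QUINTILES

log = logging.getLogger(__name__)

DEFAULT_OPEN_BAND_AGE = 90.0
MAX_PREDICTION_AGE = 110.0


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

@dataclass
class ModelDesign:
    """Assembled fixed-effect matrix, response, offset and area grouping."""
    X: np.ndarray
    y: np.ndarray
    offset: np.ndarray
    group_codes: np.ndarray
    group_labels: np.ndarray
    column_names: list[str]
    spline: SplineSpec
    quintile_levels: tuple[str, ...]
    open_band_age: float
    sex: str | None
    meta: pd.DataFrame
    interactions: bool = True

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


def representative_age(age_lower, age_upper, open_band_age: float = DEFAULT_OPEN_BAND_AGE):
    """Mid-age of a closed band; a fixed representative age for the open band."""
    lower = np.asarray(age_lower, dtype=float)
    upper = np.asarray(age_upper, dtype=float)
    return np.where(np.isnan(upper), open_band_age, (lower + upper) / 2.0)


def _fixed_row_block(ages: np.ndarray, quintiles: np.ndarray, spec: SplineSpec,
                     levels: tuple[str, ...],
                     interactions: bool = True) -> tuple[np.ndarray, list[str]]:
    B = rcs_basis(ages, spec)
    cols = [np.ones(len(ages)), *B.T]
    names = ["intercept", *spec.column_names()]
    for q in levels[1:]:
        ind = (quintiles == q).astype(float)
        cols.append(ind)
        names.append(q)
    if interactions:
        for q in levels[1:]:
            ind = (quintiles == q).astype(float)
            for j, bcol in enumerate(B.T):
                cols.append(ind * bcol)
                names.append(f"{q}:rcs{j + 1}")
    return np.column_stack(cols), names


def build_design(table: pd.DataFrame, spec: SplineSpec | None = None,
                 open_band_age: float = DEFAULT_OPEN_BAND_AGE,
                 interactions: bool = True) -> ModelDesign:
    """Build the model design from a quintile-joined abridged count table.

    One row per input observation row; requires a single sex (models are
    never pooled across sexes).  ``interactions=False`` drops the
    quintile x spline columns (proportional-hazards variant, useful as a
    misspecified comparator when the deprivation effect varies with age).
    """
    spec = spec or SplineSpec()
    if "quintile" not in table.columns:
        raise ValueError("table must carry a 'quintile' column")
    unknown = sorted(set(table["quintile"]) - set(QUINTILES))
    if unknown:
        raise ValueError(f"unknown quintile labels: {unknown}")
    sex = None
    if "sex" in table.columns:
        sexes = table["sex"].unique()
        if len(sexes) > 1:
            raise ValueError("design must be built per sex; filter the table first")
        sex = str(sexes[0])
    if (table["population"] <= 0).any():
        raise ValueError("population must be > 0 on every row")

    ages = representative_age(table["age_lower"], table["age_upper"], open_band_age)
    quintiles = table["quintile"].to_numpy()
    X, names = _fixed_row_block(ages, quintiles, spec, QUINTILES, interactions)
    codes, labels = pd.factorize(table["area_id"], sort=True)
    meta = pd.DataFrame({
        "area_id": table["area_id"].to_numpy(),
        "quintile": quintiles,
        "age": ages,
        "age_lower": table["age_lower"].to_numpy(dtype=float),
        "population": table["population"].to_numpy(dtype=float),
        "deaths": table["deaths"].to_numpy(dtype=float),
    })
    return ModelDesign(
        X=X,
        y=table["deaths"].to_numpy(dtype=float),
        offset=np.log(table["population"].to_numpy(dtype=float)),
        group_codes=codes.astype(np.int64),
        group_labels=np.asarray(labels),
        column_names=names,
        spline=spec,
        quintile_levels=QUINTILES,
        open_band_age=open_band_age,
        sex=sex,
        meta=meta,
        interactions=interactions,
    )


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    s, vt = np.linalg.svd(X, full_matrices=False)[1:]
    if s[0] == 0 or s[-1] / s[0] < 1e-10:
        null = vt[s / s[0] < 1e-10]
        bad = sorted({names[j] for row in null for j in np.nonzero(np.abs(row) > 0.1)[0]})
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class FittedRateModel:
    """Fixed effects, their covariance, frailty SD and per-area intercepts."""
    beta: np.ndarray
    vcov_beta: np.ndarray
    sigma_u: float
    area_intercepts: pd.Series
    loglik: float
    converged: bool
    n_iter: int
    column_names: list[str]
    spline: SplineSpec
    quintile_levels: tuple[str, ...]
    open_band_age: float
    sex: str | None = None
    interactions: bool = True
    objective_history: list[float] = field(default_factory=list)


class _PIRLSState:
    def __init__(self, design: ModelDesign):
        n, p = design.X.shape
        self.Z = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), design.group_codes)),
            shape=(n, design.n_groups))
        self.beta = np.zeros(p)
        self.beta[0] = np.log((design.y.sum() + 0.5) / np.exp(design.offset).sum())
        self.u = np.zeros(design.n_groups)


def _penalized_loglik(design, beta, u, sig2):
    eta = design.X @ beta + u[design.group_codes] + design.offset
    mu = np.exp(eta)
    ll = float(design.y @ eta - mu.sum())
    if sig2 > 0:
        ll -= float(u @ u) / (2 * sig2)
    return ll, mu


def _pirls(design: ModelDesign, state: _PIRLSState, sig2: float,
           tol: float, max_iter: int) -> tuple[bool, int]:
    """Penalized IRLS for (beta, u) at fixed sigma_u^2, with step halving."""
    X, y, off, codes = design.X, design.y, design.offset, design.group_codes
    J = design.n_groups
    beta, u = state.beta, state.u
    pen, _ = _penalized_loglik(design, beta, u, sig2)
    stalled = False
    for it in range(1, max_iter + 1):
        eta = X @ beta + u[codes] + off
        mu = np.exp(np.clip(eta, -500, 500))
        # floor the IRLS weights: cells whose fitted mean underflows carry no
        # information but must not produce invalid working responses
        w = np.maximum(mu, 1e-10)
        z = eta - off + (y - mu) / w
        Xw = X * w[:, None]
        A = X.T @ Xw
        bvec = X.T @ (w * z)
        if sig2 > 0:
            sw = np.bincount(codes, weights=w, minlength=J)
            swz = np.bincount(codes, weights=w * z, minlength=J)
            M = state.Z.T @ Xw
            d = sw + 1.0 / sig2
            A = A - M.T @ (M / d[:, None])
            bvec = bvec - M.T @ (swz / d)
        try:
            beta_new = np.linalg.solve(A, bvec)
        except np.linalg.LinAlgError:
            raise ValueError("penalized IRLS system is singular; "
                             "check the design for collinearity") from None
        if sig2 > 0:
            u_new = (swz - M @ beta_new) / d
        else:
            u_new = np.zeros(J)
        # line search on the penalized log-likelihood
        step = 1.0
        for _ in range(30):
            b_try = beta + step * (beta_new - beta)
            u_try = u + step * (u_new - u)
            pen_try, _ = _penalized_loglik(design, b_try, u_try, sig2)
            if np.isfinite(pen_try) and pen_try >= pen - 1e-10:
                break
            step /= 2.0
        beta, u = b_try, u_try
        # one extra Newton step after the objective stalls: on flat ridges the
        # log-likelihood converges before the coefficients do
        if abs(pen_try - pen) < tol:
            if stalled:
                state.beta, state.u = beta, u
                return True, it
            stalled = True
        else:
            stalled = False
        pen = pen_try
    state.beta, state.u = beta, u
    return False, max_iter


def _laplace_loglik(design: ModelDesign, state: _PIRLSState, sig2: float) -> float:
    pen, mu = _penalized_loglik(design, state.beta, state.u, sig2)
    ll = pen - float(gammaln(design.y + 1).sum())
    if sig2 > 0:
        smu = np.bincount(design.group_codes, weights=mu, minlength=design.n_groups)
        ll -= 0.5 * float(np.log1p(sig2 * smu).sum())
    return ll


def _profile_vcov(design: ModelDesign, state: _PIRLSState, sig2: float) -> np.ndarray:
    eta = design.X @ state.beta + state.u[design.group_codes] + design.offset
    w = np.exp(eta)
    Xw = design.X * w[:, None]
    A = design.X.T @ Xw
    if sig2 > 0:
        sw = np.bincount(design.group_codes, weights=w, minlength=design.n_groups)
        M = state.Z.T @ Xw
        d = sw + 1.0 / sig2
        A = A - M.T @ (M / d[:, None])
    return np.linalg.inv(A)


def fit_poisson_mixed(design: ModelDesign, sigma_u: float | None = None,
                      tol: float = 1e-8, max_iter: int = 200,
                      sigma_bounds: tuple[float, float] = (1e-6, 2.0),
                      ) -> FittedRateModel:
    """Fit the Poisson model with an area random intercept.

    ``sigma_u=None`` estimates the frailty SD by maximizing the Laplace
    marginal log-likelihood over ``sigma_bounds``; a fixed value (e.g. 0)
    constrains it, in which case 0 reduces the fit to a plain Poisson GLM.
    Non-convergence raises with an explicit status; it is never silent.
    """
    if design.n_groups < 2:
        raise ValueError("need at least 2 areas to fit the mixed model")
    log.info("fitting Poisson mixed model: sex=%s rows=%d areas=%d knots=%s "
             "center_age=%g open_band_age=%g interactions=%s tol=%g "
             "max_iter=%d sigma_u=%s",
             design.sex, len(design.y), design.n_groups, design.spline.knots,
             design.spline.center_age, design.open_band_age,
             design.interactions, tol, max_iter,
             "estimated" if sigma_u is None else sigma_u)
    _check_rank(design.X, design.column_names)
    state = _PIRLSState(design)
    iters = 0
    history: list[float] = []

    def evaluate(sig: float) -> float:
        nonlocal iters
        sig2 = sig * sig
        ok, it = _pirls(design, state, sig2, tol, max_iter)
        iters += it
        if not ok:
            raise RuntimeError(
                f"penalized IRLS failed to converge in {max_iter} iterations "
                f"at sigma_u={sig:.6g}")
        ll = _laplace_loglik(design, state, sig2)
        history.append(ll)
        return ll

    if sigma_u is not None:
        if sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        sigma = float(sigma_u)
        ll = evaluate(sigma)
        outer_ok = True
    else:
        res = minimize_scalar(lambda s: -evaluate(s), bounds=sigma_bounds,
                              method="bounded", options={"xatol": 1e-5})
        outer_ok = bool(res.success)
        sigma = float(res.x)
        ll = evaluate(sigma)  # leave state at the optimum
        if not outer_ok:
            raise RuntimeError(f"outer sigma_u optimization did not converge: "
                               f"{res.message}")

    if np.abs(state.beta).max() > 50:
        log.warning("very large fixed-effect estimates (max |beta| = %.1f): "
                    "likely quasi-separation (strata with no deaths); "
                    "pool more data or reduce the interaction basis",
                    float(np.abs(state.beta).max()))
    vcov = _profile_vcov(design, state, sigma * sigma)
    best = list(np.maximum.accumulate(history))
    return FittedRateModel(
        beta=state.beta.copy(),
        vcov_beta=vcov,
        sigma_u=sigma,
        area_intercepts=pd.Series(state.u.copy(), index=design.group_labels),
        loglik=ll,
        converged=outer_ok,
        n_iter=iters,
        column_names=list(design.column_names),
        spline=design.spline,
        quintile_levels=design.quintile_levels,
        open_band_age=design.open_band_age,
        sex=design.sex,
        interactions=design.interactions,
        objective_history=best,
    )


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------

def prediction_rows(model: FittedRateModel, ages, quintile: str) -> np.ndarray:
    """Fixed-effect design rows for new (age, quintile) points."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if np.any((ages < 0) | (ages > MAX_PREDICTION_AGE)):
        raise ValueError(f"ages must lie in [0, {MAX_PREDICTION_AGE:g}]")
    if quintile not in model.quintile_levels:
        raise ValueError(f"unknown quintile {quintile!r}")
    X, names = _fixed_row_block(ages, np.full(len(ages), quintile, dtype=object),
                                model.spline, model.quintile_levels,
                                model.interactions)
    assert names == model.column_names
    return X


def predict_rates(model: FittedRateModel, ages, quintile: str,
                  area_id: str | None = None, z: float = 1.96,
                  mode: str = "median") -> pd.DataFrame:
    """Smoothed rates with delta-method 95% intervals on the rate scale.

    ``mode='median'`` (default) sets the random intercept to 0 (the median
    area); ``mode='mean'`` multiplies by exp(sigma_u^2/2), the mean over the
    lognormal frailty distribution.  Passing ``area_id`` uses that area's
    empirical-Bayes intercept instead.
    """
    if not model.converged:
        raise RuntimeError("model did not converge; refusing to predict")
    X = prediction_rows(model, ages, quintile)
    eta = X @ model.beta
    if area_id is not None:
        if area_id not in model.area_intercepts.index:
            raise KeyError(f"unknown area {area_id!r}")
        eta = eta + float(model.area_intercepts.loc[area_id])
    elif mode == "mean":
        eta = eta + model.sigma_u ** 2 / 2.0
    elif mode != "median":
        raise ValueError(f"unknown prediction mode {mode!r}")
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, model.vcov_beta, X))
    out = pd.DataFrame({
        "age": np.atleast_1d(np.asarray(ages, dtype=float)),
        "quintile": quintile,
        "rate": np.exp(eta),
        "se_log_rate": se,
        "ci_low": np.exp(eta - z * se),
        "ci_high": np.exp(eta + z * se),
    })
    if area_id is not None:
        out["area_id"] = area_id
    return out


# --------------------------------------------------------------------------
# knot selection
# --------------------------------------------------------------------------

@dataclass
class KnotSelection:
    chosen: SplineSpec
    cv_table: pd.DataFrame  # one row per candidate: knots, n_knots, cv_mae


def _stratified_folds(table: pd.DataFrame, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold label per row, dealt round-robin within (quintile, band) strata."""
    fold = np.empty(len(table), dtype=int)
    pos = np.arange(len(table))
    strata = pd.Series(pos).groupby(
        [table["quintile"].to_numpy(), table["age_lower"].to_numpy()])
    offset = 0
    for _, idx in strata:
        idx = idx.to_numpy()
        rng.shuffle(idx)
        fold[idx] = (np.arange(len(idx)) + offset) % n_folds
        offset += len(idx)
    return fold


def select_knots(table: pd.DataFrame, candidates, n_folds: int = 5,
                 seed: int = 0, center_age: float = DEFAULT_CENTER_AGE,
                 open_band_age: float = DEFAULT_OPEN_BAND_AGE,
                 random_intercept: bool = False) -> KnotSelection:
    """Choose knot positions by K-fold cross-validated mean absolute error.

    Folds are stratified by quintile and age band.  Per fold the model is fit
    on the training rows (fixed effects only unless ``random_intercept``) and
    held-out rates are predicted from the fixed part; the score is the mean
    absolute error between observed (deaths/person-years) and predicted rates
    pooled over held-out rows.  Ties break toward fewer knots, then smaller
    knot ages.
    """
    specs = [c if isinstance(c, SplineSpec) else SplineSpec(tuple(c), center_age)
             for c in candidates]
    if not specs:
        raise ValueError("need at least one candidate knot set")
    rng = np.random.default_rng(seed)
    for attempt in range(20):
        fold = _stratified_folds(table, n_folds, rng)
        ok = all(
            set(table.loc[fold != f, "quintile"]) == set(QUINTILES)
            for f in range(n_folds))
        if ok:
            break
        log.warning("refolding (attempt %d): a training fold lost a quintile",
                    attempt + 1)
    else:
        raise RuntimeError("could not build folds covering all quintiles")

    obs_rate = table["deaths"].to_numpy(dtype=float) / table["population"].to_numpy(dtype=float)
    rows = []
    for spec in specs:
        abs_err = np.empty(len(table))
        for f in range(n_folds):
            train = table[fold != f]
            test = table[fold == f]
            design = build_design(train, spec, open_band_age)
            model = fit_poisson_mixed(design, sigma_u=None if random_intercept else 0.0)
            ages = representative_age(test["age_lower"], test["age_upper"], open_band_age)
            pred = np.empty(len(test))
            for q in QUINTILES:
                m = (test["quintile"] == q).to_numpy()
                if m.any():
                    X = prediction_rows(model, ages[m], q)
                    pred[m] = np.exp(X @ model.beta)
            abs_err[fold == f] = np.abs(obs_rate[fold == f] - pred)
        rows.append({"knots": spec.knots, "n_knots": len(spec.knots),
                     "cv_mae": float(abs_err.mean())})
    cv = pd.DataFrame(rows)
    order = sorted(range(len(specs)),
                   key=lambda i: (cv.loc[i, "cv_mae"], cv.loc[i, "n_knots"],
                                  specs[i].knots))
    return KnotSelection(chosen=specs[order[0]], cv_table=cv)


# --------------------------------------------------------------------------
# goodness of fit
# --------------------------------------------------------------------------

def goodness_of_fit(model: FittedRateModel, table: pd.DataFrame
                    ) -> tuple[pd.DataFrame, float]:
    """Observed vs fitted rates by age band x quintile, plus summary MAE.

    Observed rates pool deaths and person-years over areas; fitted rates are
    the population-weighted mean of per-area predictions (empirical-Bayes
    intercepts included).  Suitable for a calibration plot.
    """
    if not model.converged:
        raise RuntimeError("model did not converge")
    if model.sex is not None and "sex" in table.columns:
        table = table[table["sex"] == model.sex]
    ages = representative_age(table["age_lower"], table["age_upper"],
                              model.open_band_age)
    base = {}
    for q in model.quintile_levels:
        grid = np.unique(ages)
        X = prediction_rows(model, grid, q)
        base[q] = pd.Series(np.exp(X @ model.beta), index=grid)
    u = table["area_id"].map(model.area_intercepts).to_numpy(dtype=float)
    rate = np.array([base[q].loc[a] for q, a in zip(table["quintile"], ages)])
    df = pd.DataFrame({
        "age_lower": table["age_lower"].to_numpy(dtype=float),
        "age": ages,
        "quintile": table["quintile"].to_numpy(),
        "deaths": table["deaths"].to_numpy(dtype=float),
        "population": table["population"].to_numpy(dtype=float),
        "fitted": rate * np.exp(u) * table["population"].to_numpy(dtype=float),
    })
    out = df.groupby(["age_lower", "quintile"], as_index=False).agg(
        age=("age", "first"), deaths=("deaths", "sum"),
        population=("population", "sum"), fitted_deaths=("fitted", "sum"))
    out["observed_rate"] = out["deaths"] / out["population"]
    out["fitted_rate"] = out["fitted_deaths"] / out["population"]
    mae = float(np.abs(out["observed_rate"] - out["fitted_rate"]).mean())
    return out.drop(columns="fitted_deaths"), mae


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def model_to_json(model: FittedRateModel, path) -> None:
    """Serialize a fitted model (beta, vcov, sigma_u, intercepts, spline)."""
    payload = {
        "beta": model.beta.tolist(),
        "vcov_beta": model.vcov_beta.tolist(),
        "sigma_u": model.sigma_u,
        "area_ids": [str(a) for a in model.area_intercepts.index],
        "area_intercepts": model.area_intercepts.to_list(),
        "loglik": model.loglik,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "column_names": model.column_names,
        "knots": list(model.spline.knots),
        "center_age": model.spline.center_age,
        "quintile_levels": list(model.quintile_levels),
        "open_band_age": model.open_band_age,
        "sex": model.sex,
        "interactions": model.interactions,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def model_from_json(path) -> FittedRateModel:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return FittedRateModel(
        beta=np.asarray(d["beta"]),
        vcov_beta=np.asarray(d["vcov_beta"]),
        sigma_u=float(d["sigma_u"]),
        area_intercepts=pd.Series(d["area_intercepts"], index=d["area_ids"]),
        loglik=float(d["loglik"]),
        converged=bool(d["converged"]),
        n_iter=int(d["n_iter"]),
        column_names=list(d["column_names"]),
        spline=SplineSpec(tuple(d["knots"]), float(d["center_age"])),
        quintile_levels=tuple(d["quintile_levels"]),
        open_band_age=float(d["open_band_age"]),
        sex=d["sex"],
        interactions=bool(d.get("interactions", True)),
    )
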