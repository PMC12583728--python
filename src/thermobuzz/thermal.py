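"""Thermal-performance curves: predictions, peak location, bootstrap CIs.

The acceleration and frequency models include linear and quadratic
temperature terms; with a negative quadratic coefficient the fitted curve
has an interior maximum at -b/(2c).  Confidence in the peak location is
quantified by a cluster bootstrap over bees: resample bees with
replacement, refit, predict over the observed temperature range, record
the argmax; the 2.5th/97.5th percentiles over replicates give the 95% CI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy

from ._reml import RandomStructure, fit_reml
from .lmm import LmmFit, ModelSpec, fit_model, model_aic

DEFAULT_GRID_SIZE = 200


@dataclass
class TpcPrediction:
    grid: np.ndarray
    predicted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    held_at: dict
    extrapolated: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "temperature": self.grid, "predicted": self.predicted,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


@dataclass
class PeakEstimate:
    x_peak: float
    y_peak: float
    x_ci: tuple[float, float]
    y_ci: tuple[float, float]
    n_boot: int
    seed: int
    n_failed: int = 0
    x_replicates: np.ndarray = None
    y_replicates: np.ndarray = None


def _population_design(fit: LmmFit, temp_col: str, grid: np.ndarray,
                       held_at: dict | None) -> tuple[np.ndarray, dict]:
    """Fixed-effect design rows for a temperature grid at reference covariates.

    Numeric covariates are held at their sample mean (or a value given in
    ``held_at``); categorical covariates are averaged over their observed
    levels with equal weight, which under sum-to-zero contrasts is the
    population-level (contrast-zero) prediction.
    """
    data = fit.data
    held = dict(held_at or {})
    num_cols = [c for c in data.columns
                if np.issubdtype(np.asarray(data[c]).dtype, np.number) and c != temp_col]
    cat_cols = [c for c in data.columns
                if data[c].dtype == object and c in "".join(fit.spec.fixed_terms)]
    for c in num_cols:
        held.setdefault(c, float(np.mean(data[c])))
    combos = list(itertools.product(*[sorted(data[c].unique()) for c in cat_cols])) or [()]
    rows = []
    for tval in grid:
        for combo in combos:
            row = dict(held)
            row[temp_col] = tval
            row.update(dict(zip(cat_cols, combo)))
            rows.append(row)
    newdata = pd.DataFrame(rows)
    (X,) = patsy.build_design_matrices([fit.design_info], newdata)
    X = np.asarray(X).reshape(len(grid), len(combos), -1).mean(axis=1)
    return X, held


def predict_curve(
    fit: LmmFit,
    temp_col: str,
    grid: np.ndarray,
    held_at: dict | None = None,
    level: float = 0.95,
) -> TpcPrediction:
    """Population-level predictions with delta-method confidence bands.

    Random effects are at zero; the CI comes from the fixed-effect
    covariance, x' C x per grid point.  Grids extending beyond the fitted
    temperature range are returned with an extrapolation flag.
    """
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    X, held = _population_design(fit, temp_col, grid, held_at)
    pred = X @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_beta, X))
    from scipy.stats import norm
    z = norm.ppf(0.5 + level / 2.0)
    lo, hi = float(fit.data[temp_col].min()), float(fit.data[temp_col].max())
    return TpcPrediction(
        grid=grid, predicted=pred, ci_low=pred - z * se, ci_high=pred + z * se,
        held_at=held, extrapolated=bool(grid.min() < lo or grid.max() > hi),
    )


def quadratic_vertex(fit: LmmFit, temp_col: str, held_at: dict | None = None) -> tuple[float, float]:
    """Interior maximum of the quadratic temperature response: x* = -b/(2c).

    ``b`` and ``c`` are the linear and quadratic coefficients of
    ``temp_col``; requires c < 0 (otherwise there is no interior maximum).
    ``y_peak`` is the full fixed-effect prediction at x* and the held-at
    covariates.
    """
    names = list(fit.coefficients.index)
    lin = [n for n in names if n == temp_col]
    quad = [n for n in names if n.replace(" ", "") == f"I({temp_col}**2)"]
    if not lin or not quad:
        raise ValueError(f"model lacks linear+quadratic terms in {temp_col!r}")
    b = float(fit.coefficients.loc[lin[0], "estimate"])
    c = float(fit.coefficients.loc[quad[0], "estimate"])
    if c >= 0:
        raise ValueError("quadratic coefficient is non-negative: no interior maximum")
    x_peak = -b / (2.0 * c)
    X, _ = _population_design(fit, temp_col, np.array([x_peak]), held_at)
    y_peak = float((X @ fit.beta)[0])
    return float(x_peak), y_peak


def bootstrap_peak(
    data: pd.DataFrame,
    spec: ModelSpec,
    temp_col: str,
    n_boot: int = 1000,
    seed: int = 0,
    grid_size: int = DEFAULT_GRID_SIZE,
    stratify_by: str | None = None,
    held_at: dict | None = None,
    max_fail_frac: float = 0.2,
) -> PeakEstimate:
    """Cluster bootstrap (over bees) of the thermal-performance peak.

    Per replicate: resample rows (bees) with replacement — optionally
    stratified by a grouping column — refit the model, predict across the
    observed temperature range on a fixed grid, record the argmax
    temperature and maximum response.  The 95% CI is the 2.5/97.5
    percentile of each across replicates.  Replicates that fail to
    converge are dropped and counted; more than ``max_fail_frac`` failures
    aborts with advice to inspect model and data.
    """
    full = fit_model(spec, data)
    grid = np.linspace(float(full.data[temp_col].min()),
                       float(full.data[temp_col].max()), grid_size)
    X_grid, _ = _population_design(full, temp_col, grid, held_at)
    # design arrays from the full fit: resampling rows keeps the original
    # contrast coding, so replicate coefficients stay comparable
    X = full.reml._core.X
    y = full.reml._core.y
    factors = {f: np.asarray(full.data[f]) for f in spec.random_intercepts}
    n = len(y)
    rng = np.random.default_rng(seed)
    warm = np.log(np.clip(
        np.array([full.varcomps[f] for f in spec.random_intercepts]) / full.residual_var,
        1e-4, None)) if spec.random_intercepts else None

    if stratify_by is not None:
        strata = np.asarray(full.data[stratify_by])
        groups = [np.where(strata == s)[0] for s in np.unique(strata)]
    x_reps, y_reps, failed = [], [], 0
    for _ in range(n_boot):
        if stratify_by is None:
            idx = rng.integers(0, n, n)
        else:
            idx = np.concatenate([g[rng.integers(0, len(g), len(g))] for g in groups])
        sub = pd.DataFrame({f: v[idx] for f, v in factors.items()})
        struct = RandomStructure.from_frame(sub, spec.random_intercepts) \
            if spec.random_intercepts else RandomStructure([], [], [])
        try:
            res = fit_reml(y[idx], X[idx], struct, start_log_gamma=warm, xatol=1e-4)
        except np.linalg.LinAlgError:
            failed += 1
            continue
        pred = X_grid @ res.beta
        k = int(np.argmax(pred))
        x_reps.append(grid[k])
        y_reps.append(pred[k])
    if failed > max_fail_frac * n_boot:
        raise RuntimeError(
            f"{failed}/{n_boot} bootstrap replicates failed; inspect the model "
            "specification and data before trusting the interval"
        )
    x_reps = np.asarray(x_reps)
    y_reps = np.asarray(y_reps)
    pred_full = X_grid @ full.beta
    k = int(np.argmax(pred_full))
    return PeakEstimate(
        x_peak=float(grid[k]), y_peak=float(pred_full[k]),
        x_ci=(float(np.percentile(x_reps, 2.5)), float(np.percentile(x_reps, 97.5))),
        y_ci=(float(np.percentile(y_reps, 2.5)), float(np.percentile(y_reps, 97.5))),
        n_boot=n_boot, seed=seed, n_failed=failed,
        x_replicates=x_reps, y_replicates=y_reps,
    )


def compare_air_vs_thorax(fits: dict[str, LmmFit]) -> pd.DataFrame:
    """Side-by-side coefficients, conditional R-squared and AIC.

    All fits must share the response and the data subset (same bees);
    mismatches are an error, not a silent comparison.
    """
    names = list(fits)
    resp = {fits[k].spec.response for k in names}
    ns = {fits[k].n_bees for k in names}
    if len(resp) > 1:
        raise ValueError(f"fits model different responses: {resp}")
    if len(ns) > 1:
        raise ValueError(f"fits use different data subsets (n = {ns})")
    rows = []
    for k in names:
        f = fits[k]
        rows.append({
            "model": k,
            "terms": " + ".join(f.spec.fixed_terms),
            "n_bees": f.n_bees,
            "conditional_r2": f.conditional_r2,
            "aic": model_aic(f),
        })
    out = pd.DataFrame(rows)
    out["preferred"] = out["aic"] == out["aic"].min()
    return out
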