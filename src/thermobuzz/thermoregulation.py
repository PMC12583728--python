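"""Air-to-thorax temperature relationship: sigmoid vs linear fits.

Bumblebees heat the thorax above cold air to reach a minimum operating
temperature and cap it below hot air to avoid the critical thermal
maximum, so across a wide air-temperature range the thorax response is
expected to be sigmoidal rather than linear.  Both models are fitted by
least squares — the sigmoid with the Levenberg–Marquardt algorithm — and
compared on RSS, AIC and (pseudo-)R².  Both AICs use the same Gaussian
log-likelihood convention, n log(RSS/n) + n log(2π) + n + 2k, with k
counting curve parameters plus the error variance, so AIC differences are
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

_LOG2PI = np.log(2.0 * np.pi)


def sigmoid(air: np.ndarray, lower: float, upper: float,
            midpoint: float, scale: float) -> np.ndarray:
    """Four-parameter logistic: two asymptotes, midpoint, steepness (°C)."""
    return lower + (upper - lower) / (1.0 + np.exp((midpoint - air) / scale))


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    return n * np.log(rss / n) + n * _LOG2PI + n + 2 * k


@dataclass
class SigmoidFit:
    lower: float
    upper: float
    midpoint: float
    scale: float
    rss: float
    aic: float
    pseudo_r2: float
    converged: bool
    n_iter: int
    n: int

    @property
    def params(self) -> np.ndarray:
        return np.array([self.lower, self.upper, self.midpoint, self.scale])

    def predict(self, air: np.ndarray) -> np.ndarray:
        return sigmoid(np.asarray(air, float), *self.params)


@dataclass
class LinearTRFit:
    intercept: float
    slope: float
    rss: float
    aic: float
    r2: float
    n: int

    def predict(self, air: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(air, float)


def fit_sigmoid(
    air: np.ndarray,
    thorax: np.ndarray,
    init: np.ndarray | None = None,
    max_iter: int = 2000,
    n_restarts: int = 5,
    seed: int = 0,
) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit (Levenberg–Marquardt).

    Default initialisation from data quantiles: asymptotes at the 5th/95th
    thorax percentiles, midpoint at the median air temperature, scale at a
    quarter of the air range; up to ``n_restarts`` seeded perturbed
    restarts if the first attempt fails or degrades.
    """
    air = np.asarray(air, float)
    thorax = np.asarray(thorax, float)
    if air.size < 5:
        raise ValueError("need at least 5 points for a 4-parameter sigmoid")
    if np.ptp(air) == 0:
        raise ValueError("air temperatures are all equal; sigmoid is unidentifiable")
    n = air.size
    if init is None:
        init = np.array([
            np.percentile(thorax, 5), np.percentile(thorax, 95),
            np.median(air), max(np.ptp(air) / 4.0, 1e-3),
        ])

    def resid(p):
        return sigmoid(air, *p) - thorax

    rng = np.random.default_rng(seed)
    best = None
    start = np.asarray(init, float)
    for attempt in range(n_restarts + 1):
        sol = optimize.least_squares(resid, start, method="lm", max_nfev=max_iter)
        rss = float(2.0 * sol.cost)
        if sol.success and (best is None or rss < best[1]):
            best = (sol, rss)
        if best is not None and attempt == 0:
            break  # quantile start converged; no restarts needed
        start = init * (1.0 + 0.3 * rng.standard_normal(4))
        start[3] = abs(start[3]) + 1e-3
    if best is None:
        raise RuntimeError(
            f"sigmoid fit failed to converge in {n_restarts + 1} attempts; "
            f"last optimizer status: {sol.status} ({sol.message})"
        )
    sol, rss = best
    lower, upper, midpoint, scale = sol.x
    if scale < 0:  # logistic is invariant under (scale, lower<->upper) flip
        lower, upper, scale = upper, lower, -scale
    tss = float(np.sum((thorax - thorax.mean()) ** 2))
    return SigmoidFit(
        lower=float(lower), upper=float(upper), midpoint=float(midpoint),
        scale=float(scale), rss=rss, aic=float(_gaussian_aic(rss, n, 5)),
        pseudo_r2=1.0 - rss / tss if tss > 0 else np.nan,
        converged=bool(sol.success), n_iter=int(sol.nfev), n=n,
    )


def fit_linear_tr(air: np.ndarray, thorax: np.ndarray) -> LinearTRFit:
    """OLS of thorax on air temperature, AIC on the same likelihood scale
    as the sigmoid (k = 3: intercept, slope, error variance)."""
    air = np.asarray(air, float)
    thorax = np.asarray(thorax, float)
    if air.size < 3:
        raise ValueError("need at least 3 points")
    n = air.size
    X = np.column_stack([np.ones(n), air])
    beta, *_ = np.linalg.lstsq(X, thorax, rcond=None)
    resid = thorax - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((thorax - thorax.mean()) ** 2))
    return LinearTRFit(
        intercept=float(beta[0]), slope=float(beta[1]), rss=rss,
        aic=float(_gaussian_aic(rss, n, 3)),
        r2=1.0 - rss / tss if tss > 0 else np.nan, n=n,
    )


def compare_tr_models(s: SigmoidFit, l: LinearTRFit) -> pd.DataFrame:
    """RSS / AIC / R² comparison table; the preferred model minimises AIC."""
    if s.n != l.n:
        raise ValueError(f"fits use different data (n = {s.n} vs {l.n})")
    out = pd.DataFrame([
        {"model": "sigmoid", "k": 5, "rss": s.rss, "aic": s.aic, "r2": s.pseudo_r2},
        {"model": "linear", "k": 3, "rss": l.rss, "aic": l.aic, "r2": l.r2},
    ])
    out["preferred"] = out["aic"] == out["aic"].min()
    return out


def simulate_thermoregulation(
    n_bees: int,
    seed: int,
    params: tuple[float, float, float, float] = (25.0, 40.0, 20.0, 3.0),
    noise_sd: float = 2.0,
    air_range: tuple[float, float] = (5.0, 35.0),
) -> pd.DataFrame:
    """Air/thorax pairs from a known sigmoid with Gaussian scatter."""
    rng = np.random.default_rng(seed)
    air = rng.uniform(*air_range, n_bees)
    thorax = sigmoid(air, *params) + rng.normal(0.0, noise_sd, n_bees)
    return pd.DataFrame({"T_air": air, "T_thorax": thorax})
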