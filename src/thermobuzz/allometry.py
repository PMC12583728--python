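"""Isometric-scaling test of peak acceleration against body mass.

If the thoracic muscles scale geometrically with the body, muscle
cross-sectional area — hence the force they produce, hence the peak
acceleration for a given mass — scales as mass^(2/3).  On per-bee means
this is tested by ordinary least squares of log(acceleration) on
log(mass) and a single-constraint linear-hypothesis F test of the slope
against the isometric reference exponent 0.67.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

ISOMETRIC_EXPONENT = 0.67


@dataclass
class AllometryFit:
    slope: float
    intercept: float
    slope_se: float
    n: int
    r2: float

    def summary_row(self, reference: float = ISOMETRIC_EXPONENT) -> pd.DataFrame:
        f, p = test_slope(self, reference)
        return pd.DataFrame([{
            "slope": self.slope, "slope_se": self.slope_se,
            "intercept": self.intercept, "n": self.n, "r2": self.r2,
            "reference": reference, "F": f, "p": p,
        }])


def fit_loglog(mass: np.ndarray, accel: np.ndarray) -> AllometryFit:
    """OLS of log(accel) on log(mass); the exponent is base-invariant.

    Raises on non-positive values, naming the offending rows.
    """
    mass = np.asarray(mass, float)
    accel = np.asarray(accel, float)
    if mass.shape != accel.shape or mass.ndim != 1:
        raise ValueError("mass and accel must be 1-d arrays of equal length")
    bad = np.where((mass <= 0) | (accel <= 0) | ~np.isfinite(mass) | ~np.isfinite(accel))[0]
    if bad.size:
        raise ValueError(f"non-positive or non-finite values at rows {bad.tolist()}")
    if mass.size < 3:
        raise ValueError("need at least 3 bees")
    X = sm.add_constant(np.log(mass))
    res = sm.OLS(np.log(accel), X).fit()
    return AllometryFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        slope_se=float(res.bse[1]), n=int(mass.size), r2=float(res.rsquared),
    )


def test_slope(fit: AllometryFit, reference: float = ISOMETRIC_EXPONENT) -> tuple[float, float]:
    """Linear-hypothesis F test of slope == reference (1, n-2 df).

    For a single constraint the F statistic is the squared t statistic
    (slope - reference) / slope_se.
    """
    t = (fit.slope - reference) / fit.slope_se
    f = t * t
    p = float(stats.f.sf(f, 1, fit.n - 2))
    return float(f), p


def simulate_isometric_bees(
    n_bees: int,
    seed: int,
    exponent: float = ISOMETRIC_EXPONENT,
    k: float = 600.0,
    sigma_log: float = 0.3,
    mass_range: tuple[float, float] = (0.05, 0.6),
) -> pd.DataFrame:
    """Per-bee masses and accelerations on a power law with lognormal noise.

    accel = k * mass^exponent * exp(eps), eps ~ N(0, sigma_log^2); masses
    uniform over the study's body-mass span.
    """
    rng = np.random.default_rng(seed)
    mass = rng.uniform(*mass_range, n_bees)
    accel = k * mass ** exponent * np.exp(rng.normal(0.0, sigma_log, n_bees))
    return pd.DataFrame({"mass": mass, "acceleration": accel})
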