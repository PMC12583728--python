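"""Published field estimates used as generating values and study design.

The four reference coefficient sets are the fixed-effect estimates of the
final mixed models of per-bee fundamental frequency (Hz) and peak
acceleration (m s^-2) against air or thorax temperature (deg C), mass (g)
and distribution class, fitted to 215 bees of 15 bumblebee species.  The
synthetic-data module treats them as generating truth so that parameter
recovery can be scored against known values.

The distribution coefficient applies to the sum-to-zero code
(+1 generalist, -1 specialist).
"""

from __future__ import annotations

from .lmm import ModelSpec
from .synthetic import PopulationParams

N_BEES = 215
N_SPECIES = 15
N_BEES_FULL_FIELD = 112      # field bees with mass measured
GRAND_MEAN_F0_HZ = 217.0     # grand-mean buzz fundamental frequency

# frequency ~ T_air + distribution
FREQ_AIR = {"intercept": 185.02, "T_air": 1.48, "distribution": 0.91}
# acceleration ~ T_air + T_air^2 + mass + distribution
ACCEL_AIR = {"intercept": 27.00, "T_air": 7.95, "T_air2": -0.17,
             "mass": 602.29, "distribution": -34.13}
# frequency ~ T_thorax + T_thorax^2 + distribution
FREQ_THORAX = {"intercept": 187.16, "T_thorax": -6.17, "T_thorax2": 0.21,
               "distribution": 8.35}
# acceleration ~ T_thorax + T_thorax^2 + mass + distribution
ACCEL_THORAX = {"intercept": -241.64, "T_thorax": 19.65, "T_thorax2": -0.26,
                "mass": 546.89, "distribution": -28.52}

# typical between-group and residual spreads for the synthetic populations
SD_SPECIES_FREQ, SD_CASTE_FREQ, SD_RESID_FREQ = 15.0, 5.0, 30.0
SD_SPECIES_ACCEL, SD_CASTE_ACCEL, SD_RESID_ACCEL = 15.0, 5.0, 60.0
SD_RESID_FREQ_THORAX = 25.0


def population(which: str) -> PopulationParams:
    """Generating population for one of the four reference models."""
    if which == "freq_air":
        return PopulationParams(fixed_effects=dict(FREQ_AIR),
                                sd_residual=SD_RESID_FREQ,
                                air_design="combined")
    if which == "accel_air":
        return PopulationParams(fixed_effects=dict(ACCEL_AIR),
                                sd_residual=SD_RESID_ACCEL,
                                air_design="combined")
    if which == "freq_thorax":
        return PopulationParams(fixed_effects=dict(FREQ_THORAX),
                                sd_residual=SD_RESID_FREQ_THORAX,
                                thorax_design="uniform")
    if which == "accel_thorax":
        return PopulationParams(fixed_effects=dict(ACCEL_THORAX),
                                sd_residual=SD_RESID_ACCEL,
                                thorax_design="uniform")
    raise ValueError(f"unknown reference population {which!r}")


def model_spec(which: str) -> ModelSpec:
    """Fitting spec matching each reference model's structure."""
    random = ["species", "caste"]
    if which == "freq_air":
        return ModelSpec("frequency", ["T_air", "distribution"], random)
    if which == "accel_air":
        return ModelSpec("acceleration",
                         ["T_air", "I(T_air**2)", "mass", "distribution"], random)
    if which == "freq_thorax":
        return ModelSpec("frequency",
                         ["T_thorax", "I(T_thorax**2)", "distribution"], random)
    if which == "accel_thorax":
        return ModelSpec("acceleration",
                         ["T_thorax", "I(T_thorax**2)", "mass", "distribution"], random)
    raise ValueError(f"unknown reference model {which!r}")
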