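"""Field-style biomechanics analysis on a simulated bee population.

Simulates a per-bee dataset with the published acceleration model's
coefficients as generating truth, then reruns the field workflow:

1. caste-complete subset — fixed-effect models (species and caste as
   factors) of acceleration with Type III tests;
2. full dataset — mixed models with distribution class fixed and
   species/caste random, after stepwise removal of null interactions;
3. global isometry — log-log regression of acceleration on mass and the
   F test of the slope against the isometric exponent 0.67.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from thermobuzz.allometry import fit_loglog, test_slope
from thermobuzz.lmm import ModelSpec, fit_model, stepwise_reduce, type3_table
from thermobuzz.reference import model_spec, population
from thermobuzz.synthetic import simulate_bee_dataset

OUT = Path("results/field_models")
SEED = 1
N_BEES = 215


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    data, truth = simulate_bee_dataset(population("accel_air"), N_BEES,
                                       "acceleration", SEED)
    data.to_csv(OUT / "bee_table.csv", index=False)

    # 1. caste-complete subset, fixed effects only (species subset: first 6)
    subset = data[data.species.isin(sorted(data.species.unique())[:6])]
    sub_spec = ModelSpec("acceleration", ["mass", "T_air", "caste", "species"], [])
    sub_fit = fit_model(sub_spec, subset)
    t3_sub = type3_table(sub_fit)
    t3_sub.to_csv(OUT / "subset_type3.csv", index=False)
    print(f"subset analysis ({sub_fit.n_bees} bees, 6 species):")
    print(t3_sub.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    # 2. full dataset mixed model after stepwise reduction
    full_spec = ModelSpec(
        "acceleration",
        ["mass", "T_air", "I(T_air**2)", "distribution", "mass:T_air"],
        ["species", "caste"])
    final_spec, removal_log = stepwise_reduce(full_spec, data,
                                              optional_terms=[])
    fit = fit_model(final_spec, data)
    fit.coefficients.to_csv(OUT / "full_lmm_coefficients.csv")
    type3_table(fit).to_csv(OUT / "full_lmm_type3.csv", index=False)
    print(f"\nfull mixed model ({fit.n_bees} bees): terms {final_spec.fixed_terms}")
    if removal_log:
        for e in removal_log:
            print(f"  removed {e['removed']} (p = {e['p']:.3f})")
    print(fit.coefficients.to_string(float_format=lambda v: f"{v:.3f}"))
    print(f"  variance components: {({k: round(v, 1) for k, v in fit.varcomps.items()})}, "
          f"residual {fit.residual_var:.1f}; conditional R2 = {fit.conditional_r2:.3f}")

    # 3. global isometry on the same bees
    iso = fit_loglog(data["mass"], np.clip(data["acceleration"], 1e-6, None))
    f, p = test_slope(iso, 0.67)
    iso.summary_row().to_csv(OUT / "allometry.csv", index=False)
    print(f"\nisometry: slope {iso.slope:.3f} +/- {iso.slope_se:.3f} "
          f"(n = {iso.n}); H0 slope = 0.67: F = {f:.3f}, p = {p:.3f}")


if __name__ == "__main__":
    main()
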