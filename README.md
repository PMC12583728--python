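# thermobuzz

Biomechanics and thermal performance of bumblebee defensive buzzes.

Bumblebees power non-flight vibrations (defensive buzzing, buzz
pollination) with their indirect flight muscles. Recordings of these
vibrations — an accelerometer held against the thorax, 60 s traces at
20,480 Hz — carry three biomechanical signatures per buzz: its duration,
its smoothed peak acceleration (m s⁻²), and its fundamental frequency
(Hz, the muscle contraction rate, distinct from the spectrally dominant
harmonic). This package implements the full analysis chain for such
data, aimed at researchers in insect biomechanics and thermal ecology:

1. **Feature extraction** (`thermobuzz.extraction`) — zero-phase 20 Hz
   high-pass (Hann window, 512 samples), segmentation at 8% of the
   recording's envelope maximum with a 0.1 s minimum duration, smoothed
   (2-sample) peak acceleration, and short-time lag-domain fundamental
   frequency (512-sample frames, 50% overlap, 1000 Hz cap).
2. **Allometry** (`thermobuzz.allometry`) — OLS of log *a* on log *m*
   and the F test of the slope against the isometric expectation
   *a* ∝ *m*^0.67 (muscle cross-sectional area under geometric
   similarity).
3. **Mixed models** (`thermobuzz.lmm`) — REML fits of per-bee means,
   *y* = β₀ + β₁T + β₂T² + β₃m + β₄dist + *b*_species + *b*_caste + ε,
   with crossed random intercepts, Type III F tests with Satterthwaite
   denominator degrees of freedom, stepwise interaction removal, and
   Nakagawa–Schielzeth conditional R².
4. **Thermal performance** (`thermobuzz.thermal`) — population-level
   prediction curves with delta-method 95% bands, the quadratic peak
   T\* = −β₁/(2β₂), and its 95% CI by cluster bootstrap over bees
   (2.5/97.5 percentiles of the per-replicate grid argmax).
5. **Thermoregulation** (`thermobuzz.thermoregulation`) — 4-parameter
   logistic fit of thorax on air temperature by Levenberg–Marquardt,
   compared with the linear fit on RSS, AIC (shared Gaussian likelihood
   convention) and (pseudo-)R².
6. **Synthetic data** (`thermobuzz.synthetic`) — seeded generators for
   both raw recordings (harmonic buzz bursts with known onset, f0 and
   peak) and bee-level datasets drawn from the mixed-model structure
   above, so that every stage is testable against known truth.

The `analysis/` scripts run these stages as a narrative pipeline and
write their tables under `results/`; the `thermobuzz` CLI (`synth`,
`extract`, `model`, `report`, `run`) exposes the same stages from the
shell.

## Worked example

Fit the thermoregulation models on simulated field-scale data (215 bees,
thorax scatter 4.3 °C around a known sigmoid):

```python
from thermobuzz.thermoregulation import (fit_sigmoid, fit_linear_tr,
                                         compare_tr_models,
                                         simulate_thermoregulation)

d = simulate_thermoregulation(215, seed=1, params=(25.0, 40.0, 20.0, 3.0),
                              noise_sd=4.3)
s = fit_sigmoid(d["T_air"], d["T_thorax"], seed=1)
l = fit_linear_tr(d["T_air"], d["T_thorax"])
print(compare_tr_models(s, l))
```

```
     model  k          rss          aic        r2  preferred
0  sigmoid  5  3091.839986  1193.298276  0.700454       True
1   linear  3  3508.852284  1216.484958  0.660051      False
```

The sigmoid wins by ΔAIC ≈ 23 and recovers the generating curve
(fitted asymptotes 23.9 / 40.3 °C, midpoint 20.2 °C, scale 3.1 °C): the
thorax is held ~24 °C warm in cold air and saturates near 40 °C in hot
air, rather than tracking air temperature linearly. Running
`python analysis/04_thermal_performance.py` prints the corresponding
thermal-performance side: e.g. the simulated acceleration model peaks at
21.0 °C air temperature with a 1000-replicate bootstrap 95% CI of
18.0–25.1 °C.

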