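"""Synthesize accelerometer-style buzz recordings with known ground truth.

Renders a handful of 60 s traces at 20,480 Hz — harmonic buzz bursts of
varied pitch, length and amplitude in Gaussian sensor noise — and writes
each as tab-delimited text together with its ground-truth manifest
(onset, duration, f0, peak acceleration per buzz), the scoring key for
the extraction stage.
"""

from pathlib import Path

from thermobuzz.io import write_waveform_txt
from thermobuzz.synthetic import (default_recording_plan,
                                  generate_ground_truth_manifest,
                                  synthesize_recording)

OUT = Path("results/recordings")
N_RECORDINGS = 4
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    total = 0
    for i in range(N_RECORDINGS):
        plan = default_recording_plan(seed=SEED + i, n_buzzes=6,
                                      duration_range=(0.15, 1.0),
                                      peak_range=(100.0, 300.0),
                                      noise_sd=1.0)
        w = synthesize_recording(plan)
        write_waveform_txt(OUT / f"bee_{i:02d}.txt", w)
        man = generate_ground_truth_manifest(plan)
        man.to_csv(OUT / f"bee_{i:02d}_truth.csv", index=False)
        total += len(man)
        print(f"bee_{i:02d}: {len(man)} buzzes, "
              f"f0 {man.f0_hz.min():.0f}-{man.f0_hz.max():.0f} Hz, "
              f"peaks {man.peak_accel_ms2.min():.0f}-{man.peak_accel_ms2.max():.0f} m/s^2")
    print(f"wrote {N_RECORDINGS} recordings ({total} buzzes) to {OUT}/")


if __name__ == "__main__":
    main()
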