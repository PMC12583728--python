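"""Synthetic buzz recordings and bee-level datasets with known ground truth.

Two generators:

* :func:`synthesize_recording` renders an accelerometer-style trace from a
  plan of harmonic buzz bursts (fundamental + geometrically decaying
  harmonics, attack/sustain/release envelope) in Gaussian sensor noise,
  emulating a 60 s field recording at 20,480 Hz.

* :func:`simulate_bee_dataset` draws per-bee mean responses from the same
  mixed-model structure the analysis assumes: fixed effects (temperature,
  optionally quadratic, mass, distribution class) plus independent Gaussian
  random intercepts for species and caste plus residual noise.  The true
  random-effect draws are returned alongside for parameter-recovery tests.

Everything is driven by an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .extraction import Waveform

FIELD_AIR_RANGE = (13.0, 21.1)            # deg C, field protocol
LAB_AIR_STEPS = tuple(float(t) for t in range(5, 40, 5))   # 5..35 deg C
THORAX_RANGE = (16.0, 44.0)               # deg C, observed thorax span


@dataclass
class BuzzSpec:
    """Ground truth for one synthetic buzz."""

    onset_time: float            # s
    duration: float              # s
    f0: float                    # Hz
    peak_accel: float            # m s^-2, pre-noise max |signal|
    n_harmonics: int = 3
    harmonic_decay: float = 0.5  # amplitude ratio between adjacent harmonics
    envelope: str = "asr"        # "asr" or "rectangular"
    attack_frac: float = 0.1
    release_frac: float = 0.1
    f0_jitter_sd: float = 0.0    # Hz, slow within-buzz frequency wander

    def __post_init__(self):
        if self.onset_time < 0 or self.duration <= 0:
            raise ValueError("onset_time must be >= 0 and duration > 0")
        if not 0 < self.f0 <= 1000:
            raise ValueError("f0 must be in (0, 1000] Hz")
        if self.n_harmonics < 1 or not 0 < self.harmonic_decay <= 1:
            raise ValueError("bad harmonic structure")
        if self.peak_accel <= 0:
            raise ValueError("peak_accel must be positive")
        if self.envelope not in ("asr", "rectangular"):
            raise ValueError("envelope must be 'asr' or 'rectangular'")

    @property
    def max_harmonic_hz(self) -> float:
        return self.f0 * self.n_harmonics


@dataclass
class RecordingPlan:
    """A full synthetic recording: buzzes in silence plus sensor noise."""

    buzzes: list[BuzzSpec] = field(default_factory=list)
    sampling_rate: float = 20480.0
    total_duration: float = 60.0
    noise_sd: float = 0.0        # m s^-2
    seed: int = 0

    def validate(self) -> None:
        if self.total_duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("total_duration and sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        nyq = self.sampling_rate / 2.0
        intervals = []
        for b in self.buzzes:
            if b.onset_time + b.duration > self.total_duration + 1e-12:
                raise ValueError("buzz extends past the end of the recording")
            if b.max_harmonic_hz >= nyq:
                raise ValueError(
                    f"harmonic at {b.max_harmonic_hz} Hz at or above Nyquist ({nyq} Hz)"
                )
            intervals.append((b.onset_time, b.onset_time + b.duration))
        intervals.sort()
        for (s0, e0), (s1, e1) in zip(intervals, intervals[1:]):
            if s1 < e0:
                raise ValueError("buzz intervals overlap")


def synthesize_recording(plan: RecordingPlan) -> Waveform:
    """Render the plan to a trace (identical plan + seed => identical samples).

    Within each buzz the signal is a sum of harmonics with geometric
    amplitude decay, shaped by the buzz envelope and rescaled so its
    maximum absolute value equals ``peak_accel`` before noise; outside
    buzzes there is only Gaussian noise of SD ``noise_sd``.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    n_total = int(round(plan.total_duration * plan.sampling_rate))
    fs = plan.sampling_rate
    x = np.zeros(n_total)
    for b in sorted(plan.buzzes, key=lambda s: s.onset_time):
        n = int(round(b.duration * fs))
        if n < 2:
            continue
        f_track = np.full(n, b.f0)
        if b.f0_jitter_sd > 0:
            # slow wander: heavily smoothed white noise rescaled to the target SD
            raw = rng.standard_normal(n)
            smooth = uniform_filter1d(raw, size=max(2, int(fs * 0.05)), mode="nearest")
            sd = smooth.std()
            if sd > 0:
                f_track = f_track + b.f0_jitter_sd * smooth / sd
        phase = 2.0 * np.pi * np.cumsum(f_track) / fs
        sig = np.zeros(n)
        for h in range(1, b.n_harmonics + 1):
            sig += b.harmonic_decay ** (h - 1) * np.sin(h * phase)
        sig *= _envelope(n, b)
        peak = np.abs(sig).max()
        if peak > 0:
            sig *= b.peak_accel / peak
        i0 = int(round(b.onset_time * fs))
        x[i0:i0 + n] += sig
    if plan.noise_sd > 0:
        x += rng.normal(0.0, plan.noise_sd, n_total)
    return Waveform(x, fs, source_id=f"synthetic-seed{plan.seed}")


def _envelope(n: int, b: BuzzSpec) -> np.ndarray:
    if b.envelope == "rectangular":
        return np.ones(n)
    env = np.ones(n)
    na = int(round(b.attack_frac * n))
    nr = int(round(b.release_frac * n))
    if na > 0:
        env[:na] = np.linspace(0.0, 1.0, na, endpoint=False)
    if nr > 0:
        env[n - nr:] = np.linspace(1.0, 0.0, nr)
    return env


def generate_ground_truth_manifest(plan: RecordingPlan) -> pd.DataFrame:
    """One row per planned buzz (onset-ordered) for scoring segmentation."""
    rows = [
        {"onset_s": b.onset_time, "duration_s": b.duration,
         "f0_hz": b.f0, "peak_accel_ms2": b.peak_accel}
        for b in sorted(plan.buzzes, key=lambda s: s.onset_time)
    ]
    return pd.DataFrame(rows, columns=["onset_s", "duration_s", "f0_hz", "peak_accel_ms2"])


# ---------------------------------------------------------------------------
# bee-level datasets


@dataclass
class PopulationParams:
    """Generating parameters for per-bee mean responses.

    ``fixed_effects`` maps term names to coefficients; recognised terms:
    intercept, T_air, T_air2, T_thorax, T_thorax2, mass, distribution.
    The distribution coefficient applies to a sum-to-zero code
    (+1 generalist, -1 specialist), so a fitted sum-contrast coefficient
    recovers it directly.
    """

    fixed_effects: dict[str, float]
    sd_species: float = 15.0
    sd_caste: float = 5.0
    sd_residual: float = 30.0
    n_species: int = 15
    castes: tuple[str, ...] = ("worker", "drone", "queen")
    mass_range: tuple[float, float] = (0.05, 0.6)      # g
    air_design: str = "combined"     # "field" | "lab" | "combined"
    thorax_design: str = "uniform"   # "uniform" | "sigmoid"
    thorax_range: tuple[float, float] = THORAX_RANGE
    thorax_link: tuple[float, float, float, float] | None = None  # lower, upper, midpoint, scale
    thorax_link_sd: float = 4.3      # deg C, scatter around the link (the
                                     # field sigmoid's residual SD scale)
    frac_specialist: float = 0.4     # 6 of 15 study species are specialists

    def validate(self) -> None:
        if min(self.sd_species, self.sd_caste, self.sd_residual) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_species < 1 or not self.castes:
            raise ValueError("need at least one species and one caste")
        if not 0 < self.mass_range[0] < self.mass_range[1]:
            raise ValueError("mass_range must be positive and increasing")


def simulate_bee_dataset(
    params: PopulationParams,
    n_bees: int,
    response: str,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Draw a per-bee dataset from the generating mixed-model structure.

    Returns ``(table, truth)`` where ``truth`` holds the exact species and
    caste intercept draws and the noise-free linear predictor, for
    recovery tests.  ``response`` is one of frequency / acceleration /
    duration and names the response column.
    """
    params.validate()
    if response not in ("frequency", "acceleration", "duration"):
        raise ValueError("response must be frequency, acceleration or duration")
    n_cells = params.n_species * len(params.castes)
    if n_bees < n_cells:
        raise ValueError(f"n_bees must be >= n_species x n_castes ({n_cells})")
    rng = np.random.default_rng(seed)

    species_names = [f"sp{i:02d}" for i in range(params.n_species)]
    n_spec = int(round(params.frac_specialist * params.n_species))
    dist_of_species = {
        s: ("specialist" if i < n_spec else "generalist")
        for i, s in enumerate(species_names)
    }
    # guarantee every species x caste cell, then fill the rest at random
    cells = [(s, c) for s in species_names for c in params.castes]
    extra = [
        (species_names[i], params.castes[j])
        for i, j in zip(
            rng.integers(0, params.n_species, n_bees - n_cells),
            rng.integers(0, len(params.castes), n_bees - n_cells),
        )
    ]
    assign = cells + extra
    rng.shuffle(assign)
    species = np.array([a[0] for a in assign])
    caste = np.array([a[1] for a in assign])
    distribution = np.array([dist_of_species[s] for s in species])
    dist_code = np.where(distribution == "generalist", 1.0, -1.0)

    mass = rng.uniform(*params.mass_range, n_bees)
    t_air = _draw_air(params.air_design, n_bees, rng)
    if params.thorax_design == "sigmoid" or params.thorax_link is not None:
        lo, up, mid, sc = params.thorax_link or (25.0, 40.0, 20.0, 3.0)
        t_thorax = lo + (up - lo) / (1.0 + np.exp((mid - t_air) / sc))
        t_thorax = t_thorax + rng.normal(0.0, params.thorax_link_sd, n_bees)
    else:
        t_thorax = rng.uniform(*params.thorax_range, n_bees)

    fe = params.fixed_effects
    eta = np.full(n_bees, float(fe.get("intercept", 0.0)))
    eta += fe.get("T_air", 0.0) * t_air + fe.get("T_air2", 0.0) * t_air ** 2
    eta += fe.get("T_thorax", 0.0) * t_thorax + fe.get("T_thorax2", 0.0) * t_thorax ** 2
    eta += fe.get("mass", 0.0) * mass + fe.get("distribution", 0.0) * dist_code

    sp_effects = dict(zip(species_names, rng.normal(0.0, params.sd_species, params.n_species)))
    ca_effects = dict(zip(params.castes, rng.normal(0.0, params.sd_caste, len(params.castes))))
    resid = rng.normal(0.0, params.sd_residual, n_bees)
    y = eta + np.array([sp_effects[s] for s in species]) \
            + np.array([ca_effects[c] for c in caste]) + resid

    table = pd.DataFrame({
        "bee_id": [f"bee{i:04d}" for i in range(n_bees)],
        "species": species,
        "caste": caste,
        "distribution": distribution,
        "mass": mass,
        "T_air": t_air,
        "T_thorax": t_thorax,
        response: y,
    })
    truth = {
        "species_effects": sp_effects,
        "caste_effects": ca_effects,
        "linear_predictor": eta,
        "residuals": resid,
        "fixed_effects": dict(fe),
    }
    return table, truth


def _draw_air(design: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if design == "field":
        return rng.uniform(*FIELD_AIR_RANGE, n)
    if design == "lab":
        return rng.choice(LAB_AIR_STEPS, n)
    if design == "combined":
        # roughly half the bees from each arm, mirroring the pooled analysis
        lab = rng.random(n) < 0.5
        out = rng.uniform(*FIELD_AIR_RANGE, n)
        out[lab] = rng.choice(LAB_AIR_STEPS, lab.sum())
        return out
    raise ValueError(f"unknown air design {design!r}")


def default_recording_plan(
    seed: int = 0,
    n_buzzes: int = 8,
    f0_range: tuple[float, float] = (120.0, 350.0),
    duration_range: tuple[float, float] = (0.15, 3.0),
    peak_range: tuple[float, float] = (20.0, 300.0),
    noise_sd: float = 1.0,
    total_duration: float = 60.0,
    sampling_rate: float = 20480.0,
) -> RecordingPlan:
    """A realistic random plan: buzzes of varied length/pitch in silence.

    Onsets are drawn so buzzes never overlap and are separated by at least
    0.2 s of silence.
    """
    rng = np.random.default_rng(seed)
    durs = rng.uniform(*duration_range, n_buzzes)
    gap = 0.2
    slack = total_duration - durs.sum() - gap * (n_buzzes + 1)
    if slack < 0:
        raise ValueError("buzzes do not fit in the recording")
    cuts = np.sort(rng.uniform(0.0, slack, n_buzzes))
    onsets = gap + cuts + np.concatenate([[0.0], np.cumsum(durs[:-1] + gap)])
    buzzes = [
        BuzzSpec(
            onset_time=float(o), duration=float(d),
            f0=float(rng.uniform(*f0_range)),
            peak_accel=float(rng.uniform(*peak_range)),
            f0_jitter_sd=1.0,
        )
        for o, d in zip(onsets, durs)
    ]
    return RecordingPlan(buzzes=buzzes, sampling_rate=sampling_rate,
                         total_duration=total_duration, noise_sd=noise_sd,
                         seed=seed)
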