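"""End-to-end orchestration: synth -> extract -> model -> report.

One structured config drives every stage; every run writes a JSON manifest
recording the config hash, seed, stage outputs and warnings, so any table
in the report can be traced to the stage output it was derived from.  A
stage failure aborts downstream stages and the manifest records the
partial completion.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allometry as allo
from . import thermoregulation as tr
from .extraction import ExtractionConfig, extract_features, per_bee_means
from .io import features_to_frame, read_waveform, write_wav, write_waveform_txt
from .lmm import fit_model, type3_table
from .reference import model_spec, population
from .synthetic import (default_recording_plan, generate_ground_truth_manifest,
                        simulate_bee_dataset, synthesize_recording)
from .thermal import bootstrap_peak, predict_curve

STAGES = ("synth", "extract", "model", "report")


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "results/pipeline"
    stages: tuple[str, ...] = STAGES
    # synth
    n_recordings: int = 2
    n_buzzes: int = 6
    noise_sd: float = 1.0
    recording_duration: float = 60.0
    # extraction
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    # modelling
    n_bees: int = 215
    reference_model: str = "accel_air"
    n_boot: int = 200
    write_wav_files: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ex = raw.pop("extraction", {})
        cfg = cls(**raw)
        cfg.extraction = ExtractionConfig(**ex)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages_requested": list(config.stages),
        "stages_completed": [],
        "outputs": [],
        "warnings": [],
    }

    def record(path: Path):
        manifest["outputs"].append(str(path))

    runners = {"synth": _stage_synth, "extract": _stage_extract,
               "model": _stage_model, "report": _stage_report}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            runners[stage](config, out, manifest, record)
            manifest["stages_completed"].append(stage)
        except Exception as exc:  # abort downstream, keep the partial record
            manifest["warnings"].append(
                f"stage {stage} failed: {exc!r}; downstream stages skipped")
            manifest["error_trace"] = traceback.format_exc()
            break
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_synth(cfg: PipelineConfig, out: Path, manifest: dict, record) -> None:
    for i in range(cfg.n_recordings):
        plan = default_recording_plan(
            seed=cfg.seed + i, n_buzzes=cfg.n_buzzes, noise_sd=cfg.noise_sd,
            total_duration=cfg.recording_duration)
        w = synthesize_recording(plan)
        txt = out / f"recording_{i:02d}.txt"
        write_waveform_txt(txt, w)
        record(txt)
        if cfg.write_wav_files:
            wav = out / f"recording_{i:02d}.wav"
            write_wav(wav, w)
            record(wav)
        man = generate_ground_truth_manifest(plan)
        mpath = out / f"recording_{i:02d}_truth.csv"
        man.to_csv(mpath, index=False)
        record(mpath)


def _stage_extract(cfg: PipelineConfig, out: Path, manifest: dict, record) -> None:
    frames, means = [], []
    recs = sorted(out.glob("recording_*.txt"))
    if not recs:
        raise FileNotFoundError("no recordings to extract (run the synth stage)")
    for path in recs:
        w = read_waveform(path)
        feats = extract_features(w, cfg.extraction)
        frames.append(features_to_frame(feats, path.stem))
        means.append(per_bee_means(feats, path.stem))
    per_buzz = pd.concat(frames, ignore_index=True)
    p1 = out / "per_buzz_features.csv"
    per_buzz.to_csv(p1, index=False)
    record(p1)
    p2 = out / "per_bee_means.csv"
    pd.DataFrame(means).to_csv(p2, index=False)
    record(p2)


def _stage_model(cfg: PipelineConfig, out: Path, manifest: dict, record) -> None:
    which = cfg.reference_model
    params = population(which)
    spec = model_spec(which)
    data, _ = simulate_bee_dataset(params, cfg.n_bees, spec.response, cfg.seed)
    dpath = out / "bee_table.csv"
    data.to_csv(dpath, index=False)
    record(dpath)

    fit = fit_model(spec, data)
    fit.coefficients.to_csv(out / "coefficients.csv")
    record(out / "coefficients.csv")
    type3_table(fit).to_csv(out / "type3.csv", index=False)
    record(out / "type3.csv")

    temp_col = "T_air" if "T_air" in "".join(spec.fixed_terms) else "T_thorax"
    grid = np.linspace(data[temp_col].min(), data[temp_col].max(), 200)
    pred = predict_curve(fit, temp_col, grid)
    pred.to_frame().to_csv(out / "prediction_curve.csv", index=False)
    record(out / "prediction_curve.csv")

    if any("**2" in t or "^2" in t for t in spec.fixed_terms):
        peak = bootstrap_peak(data, spec, temp_col, n_boot=cfg.n_boot,
                              seed=cfg.seed)
        (out / "peak_estimate.json").write_text(json.dumps({
            "x_peak": peak.x_peak, "y_peak": peak.y_peak,
            "x_ci": list(peak.x_ci), "y_ci": list(peak.y_ci),
            "n_boot": peak.n_boot, "seed": peak.seed,
            "n_failed": peak.n_failed,
        }, indent=2))
        record(out / "peak_estimate.json")
        pd.DataFrame({"x_rep": peak.x_replicates, "y_rep": peak.y_replicates}) \
            .to_csv(out / "peak_replicates.csv", index=False)
        record(out / "peak_replicates.csv")

    if spec.response == "acceleration":
        af = allo.fit_loglog(data["mass"], np.clip(data["acceleration"], 1e-6, None))
        af.summary_row().to_csv(out / "allometry.csv", index=False)
        record(out / "allometry.csv")

    trd = tr.simulate_thermoregulation(cfg.n_bees, cfg.seed)
    sfit = tr.fit_sigmoid(trd["T_air"], trd["T_thorax"], seed=cfg.seed)
    lfit = tr.fit_linear_tr(trd["T_air"], trd["T_thorax"])
    tr.compare_tr_models(sfit, lfit).to_csv(out / "thermoregulation.csv", index=False)
    record(out / "thermoregulation.csv")


def _stage_report(cfg: PipelineConfig, out: Path, manifest: dict, record) -> None:
    render_report(out, record=record, warn=manifest["warnings"].append)


def render_report(out_dir: str | Path, record=lambda p: None,
                  warn=lambda m: None) -> list[Path]:
    """Regenerate figures from stored stage outputs (idempotent; any panel
    whose inputs are missing is skipped with a warning)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    made: list[Path] = []

    curve = out / "prediction_curve.csv"
    bees = out / "bee_table.csv"
    if curve.exists() and bees.exists():
        c = pd.read_csv(curve)
        b = pd.read_csv(bees)
        temp_col = "T_air" if "T_air" in b.columns and b["T_air"].nunique() > 1 else "T_thorax"
        resp = [x for x in ("acceleration", "frequency", "duration") if x in b.columns][0]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(b[temp_col], b[resp], s=12, alpha=0.5, color="grey")
        ax.plot(c["temperature"], c["predicted"], color="C0")
        ax.fill_between(c["temperature"], c["ci_low"], c["ci_high"],
                        alpha=0.25, color="C0")
        pk = out / "peak_estimate.json"
        if pk.exists():
            peak = json.loads(pk.read_text())
            ax.plot(peak["x_peak"], peak["y_peak"], marker="+", ms=14,
                    mew=2.5, color="k")
        ax.set_xlabel(f"{temp_col} (°C)")
        ax.set_ylabel(resp)
        fig.tight_layout()
        p = out / "thermal_performance.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
        record(p)
    else:
        warn("thermal-performance panel skipped: missing stage outputs")

    trc = out / "thermoregulation.csv"
    if trc.exists():
        cmp_tab = pd.read_csv(trc)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(cmp_tab["model"], cmp_tab["aic"])
        ax.set_ylabel("AIC")
        fig.tight_layout()
        p = out / "thermoregulation_aic.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
        record(p)
    else:
        warn("thermoregulation panel skipped: missing stage outputs")
    return made
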