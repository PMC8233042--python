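"""File formats, pipeline configuration, and the end-to-end pipeline.

Traces are stored as one CSV per trial (columns time_s, left_deg,
right_deg) with a JSON sidecar carrying fish/stimulus metadata; gain
tables are plain CSV.  All angles in files are degrees.  The pipeline is
fully seeded: running it twice with the same config yields identical
artefacts.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .asymmetry import bias_index, fit_asymmetry_model
from .geometry import GeoCoord
from .simulate import default_cohort, default_truth, generate_dataset
from .spatial import BimodalVmfModel
from .stimulus import StimulusSpec
from .traces import EyeTrace, PiecewiseSinusoidModel, detect_saccades, okr_gain, qc_trial

__all__ = [
    "PipelineConfig",
    "write_eye_traces",
    "read_eye_traces",
    "run_pipeline",
]


class DetectorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vel_threshold: float = 40.0  # deg/s
    min_separation: float = 0.5  # s
    pad: float = 0.1  # s


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    freq_tol: float = 0.2  # soft bound on c2, fraction of envelope freq
    r2_min: float = 0.3
    drift_threshold: float = 0.2  # deg/s
    vmf_starts: int = 5
    aggregate: str = "median"  # {median, per_record}


class TruthConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kappa: float = 8.0
    peak_gain: float = 0.3
    baseline_gain: float = 0.05
    yoking_Y0: float = 0.2
    b1: float = 0.0
    b2: float = 0.0
    sigma_b3: float = 0.0
    gain_noise_sd: float = 0.0
    sigma_e: float = 0.2
    saccade_rate: float = 0.3
    drift_probability: float = 0.0


class PipelineConfig(BaseModel):
    """Schema-validated configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    n_fish: int = 7
    n_repetitions: int = 2
    crop_half_angle: float = 20.0
    phase_duration: float = 100.0
    detector: DetectorConfig = DetectorConfig()
    fit: FitConfig = FitConfig()
    truth: TruthConfig = TruthConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Trace files


def write_eye_traces(traces: list[EyeTrace], outdir: str | Path, meta: dict | None = None) -> list[Path]:
    """Write paired left/right traces, one CSV + JSON sidecar per trial."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_trial: dict[tuple, dict] = {}
    for tr in traces:
        by_trial.setdefault((tr.fish_id, tr.stimulus_id), {})[tr.eye] = tr
    written = []
    for i, ((fish, stim), eyes) in enumerate(by_trial.items()):
        any_tr = next(iter(eyes.values()))
        df = pd.DataFrame({"time_s": np.round(any_tr.t, 6)})
        for eye in ("left", "right"):
            if eye in eyes:
                df[f"{eye}_deg"] = np.round(eyes[eye].angle, 6)
        stem = f"{fish or 'fish'}_{stim or f'trial{i}'}"
        csv_path = outdir / f"{stem}.csv"
        df.to_csv(csv_path, index=False)
        sidecar = {
            "fish_id": fish,
            "stimulus_id": stim,
            "sampling_rate": any_tr.sampling_rate,
        }
        if meta:
            sidecar.update(meta)
        (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
        written.append(csv_path)
    return written


def read_eye_traces(path: str | Path) -> list[EyeTrace]:
    """Load all trace CSVs (plus sidecars) under a directory or one file."""
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no trace CSVs under {path}")
    out: list[EyeTrace] = []
    for f in files:
        df = pd.read_csv(f)
        if df.empty:
            raise ValueError(f"{f}: empty trace file")
        if "time_s" not in df.columns:
            raise ValueError(f"{f}: missing required column time_s")
        eye_cols = [c for c in df.columns if c.endswith("_deg")]
        if not eye_cols:
            raise ValueError(f"{f}: no eye-angle columns (*_deg)")
        t = df["time_s"].to_numpy(dtype=float)
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            raise ValueError(
                f"{f}: non-monotone time at data line {bad[0] + 2}"
            )
        sidecar = {}
        sc = f.with_suffix(".json")
        if sc.exists():
            sidecar = json.loads(sc.read_text())
        for col in eye_cols:
            out.append(
                EyeTrace(
                    t=t,
                    angle=df[col].to_numpy(dtype=float),
                    eye=col.removesuffix("_deg"),
                    fish_id=str(sidecar.get("fish_id", "")),
                    stimulus_id=str(sidecar.get("stimulus_id", "")),
                    sampling_rate=float(sidecar.get("sampling_rate", 60.0)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Pipeline


def _analyze_trace(trace: EyeTrace, spec: StimulusSpec, cfg: PipelineConfig):
    seg = detect_saccades(
        trace,
        vel_threshold=cfg.detector.vel_threshold,
        min_separation=cfg.detector.min_separation,
        pad=cfg.detector.pad,
    )
    fit = PiecewiseSinusoidModel(
        trace, seg, f_init=spec.envelope_frequency, freq_tol=cfg.fit.freq_tol
    ).fit()
    ok, reason = qc_trial(fit, trace, r2_min=cfg.fit.r2_min,
                          drift_threshold=cfg.fit.drift_threshold)
    return fit, ok, reason


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Simulate → saccade removal → gains → vMF maps → asymmetry → report.

    Writes gains.csv and report.json under `outdir` and returns the report
    dict.  Every excluded trial is logged with its QC reason.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tc = config.truth
    truth = default_truth(
        kappa=tc.kappa, peak_gain=tc.peak_gain, baseline_gain=tc.baseline_gain,
        yoking_Y0=tc.yoking_Y0, b1=tc.b1, b2=tc.b2, sigma_b3=tc.sigma_b3,
        gain_noise_sd=tc.gain_noise_sd, sigma_e=tc.sigma_e,
        saccade_rate=tc.saccade_rate, drift_probability=tc.drift_probability,
    )
    cohort = default_cohort(
        n_fish=config.n_fish,
        truth=truth,
        crop_half_angle=config.crop_half_angle,
        n_repetitions=config.n_repetitions,
        rng_seed=config.seed,
    )
    true_table, traces = generate_dataset(cohort, truth)
    spec_of = dict(cohort.protocol)

    records = []
    excluded = []
    meta_cols = ["azimuth", "elevation", "stimulated", "arena_orientation", "embedding"]
    meta = true_table.set_index(["fish_id", "eye", "stimulus_id", "repetition"])
    rep_counter: dict[tuple, int] = {}
    for tr in traces:
        key3 = (tr.fish_id, tr.eye, tr.stimulus_id)
        rep = rep_counter.get(key3, 0)
        rep_counter[key3] = rep + 1
        spec = spec_of[tr.stimulus_id]
        fit, ok, reason = _analyze_trace(tr, spec, config)
        row = meta.loc[(tr.fish_id, tr.eye, tr.stimulus_id, rep), meta_cols]
        if not ok:
            excluded.append(
                dict(fish_id=tr.fish_id, eye=tr.eye, stimulus_id=tr.stimulus_id,
                     repetition=rep, reason=reason)
            )
            continue
        rec = okr_gain(
            fit, spec, fish_id=tr.fish_id, eye=tr.eye, stimulus_id=tr.stimulus_id,
            repetition=rep, stimulated=row["stimulated"],
            arena_orientation=int(row["arena_orientation"]),
            embedding=row["embedding"],
        )
        d = vars(rec).copy()
        d["azimuth"] = float(row["azimuth"])
        d["elevation"] = float(row["elevation"])
        records.append(d)
    gains = pd.DataFrame(records)
    gains.to_csv(outdir / "gains.csv", index=False, float_format="%.6f")

    def vmf_summary(df):
        if df.empty:
            return None
        try:
            res = BimodalVmfModel(df, direct_only=False).fit(
                n_starts=config.fit.vmf_starts, rng_seed=config.seed
            )
        except ValueError as err:  # too few surviving positions
            return {"error": str(err)}
        c1, c2 = res.centres
        return {
            "centre1": [c1.azimuth, c1.elevation],
            "centre2": [c2.azimuth, c2.elevation],
            "kappa": [res.model.kappa1, res.model.kappa2],
            "C": [res.model.C1, res.model.C2],
            "C3": res.model.C3,
            "r_squared": res.r_squared,
        }

    vmf_fits = {}
    if gains.empty:
        vmf_fits = {"left": None, "right": None, "merged": None}
        biases = []
    else:
        for eye in ("left", "right"):
            vmf_fits[eye] = vmf_summary(gains[gains["eye"] == eye])
        vmf_fits["merged"] = vmf_summary(gains[gains["stimulated"] == "direct"])
        biases = [
            bias_index(grp, fish_id=fid)
            for fid, grp in gains.groupby("fish_id")
        ]
    asym = fit_asymmetry_model(biases) if len(biases) >= 2 else None

    report = {
        "version": __version__,
        "config": config.model_dump(),
        "n_trials": int(len(traces)),
        "n_accepted": int(len(records)),
        "excluded": excluded,
        "vmf_fits": vmf_fits,
        "asymmetry": None
        if asym is None
        else {
            "b1": asym.b1, "b2": asym.b2,
            "b3": asym.b3,
            "eta_std": asym.eta_std,
            "identifiable": asym.identifiable,
        },
    }
    text = json.dumps(report, indent=1, sort_keys=True, default=_json_default)
    (outdir / "report.json").write_text(text)
    report["report_hash"] = hashlib.sha256(text.encode()).hexdigest()
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, GeoCoord):
        return [o.azimuth, o.elevation]
    if isinstance(o, float) and math.isnan(o):
        return None
    raise TypeError(f"not JSON serialisable: {type(o)}")
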