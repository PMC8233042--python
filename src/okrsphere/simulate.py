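"""Synthetic cohorts, gain tables, and raw eye traces.

The generator emulates the statistical structure the analysis assumes:
OKR gain varies over stimulus position as a bimodal vMF surface whose
component centres default to the lateral, near-equatorial preferred
locations (−82.5°, 5.1°) and (81.7°, 1.6°); a hemispheric multiplier
realises the asymmetry decomposition φ·b1 + b2 + b3,k; the unstimulated
eye is yoked with index Y0; traces are sinusoidal slow phases with
Poisson quick-phase resets, optional drift, and Gaussian measurement
noise at 60 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import GeoCoord, geo_to_unit
from .spatial import DEFAULT_EYE_AXES, VmfModel, _vmf_component, direct_visibility, vmf_sum_eval
from .stimulus import (
    SeedConfiguration,
    StimulusSpec,
    place_stimulus_centres,
    stimulus_position_amplitude,
)
from .traces import EyeTrace

__all__ = [
    "GroundTruth",
    "FishSpec",
    "SyntheticCohort",
    "default_truth",
    "default_cohort",
    "simulate_gain",
    "simulate_trace",
    "generate_dataset",
]


def default_truth(
    kappa: float = 8.0,
    peak_gain: float = 0.3,
    baseline_gain: float = 0.05,
    centres: tuple = ((-82.5, 5.1), (81.7, 1.6)),
    **overrides,
) -> "GroundTruth":
    """Ground truth with vMF component masses chosen to hit `peak_gain`."""
    C = (peak_gain - baseline_gain) / _vmf_component(kappa, np.array(1.0))
    vmf = VmfModel(
        mu1=geo_to_unit(GeoCoord(*centres[0])),
        mu2=geo_to_unit(GeoCoord(*centres[1])),
        kappa1=kappa,
        kappa2=kappa,
        C1=float(C),
        C2=float(C),
        C3=baseline_gain,
    )
    return GroundTruth(vmf=vmf, **overrides)


@dataclass
class GroundTruth:
    """All generative parameters; every magnitude is configurable."""

    vmf: VmfModel
    yoking_Y0: float = 0.2  # 0 = perfectly conjugate, 1 = fully monocular
    b1: float = 0.0  # environmental (arena) asymmetry
    b2: float = 0.0  # shared biological bias
    sigma_b3: float = 0.0  # per-fish bias sd
    gain_noise_sd: float = 0.0  # additive sd on each gain draw
    sigma_e: float = 0.0  # trace measurement noise, degrees
    saccade_rate: float = 0.0  # Hz (Poisson quick phases)
    quick_phase_mean: float = 8.0  # degrees
    quick_phase_sd: float = 2.0  # degrees
    drift_probability: float = 0.0  # per trial
    drift_slope: float = 0.5  # degrees/s when injected

    def __post_init__(self) -> None:
        if not -1.0 <= self.yoking_Y0 <= 1.0:
            raise ValueError("yoking index must lie in [-1, 1]")
        for name in ("sigma_b3", "gain_noise_sd", "sigma_e", "saccade_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FishSpec:
    fish_id: str
    b3: float = 0.0
    phi: int = 1  # arena orientation during this fish's session
    embedding: str = "upright"
    eye_axes: dict = field(default_factory=lambda: dict(DEFAULT_EYE_AXES))


@dataclass
class SyntheticCohort:
    """Fish roster plus stimulus protocol; reproducible under rng_seed."""

    fish: list[FishSpec]
    protocol: list[tuple[str, StimulusSpec]]  # (stimulus_id, spec)
    n_repetitions: int = 2
    rng_seed: int = 0


def default_cohort(
    n_fish: int = 7,
    truth: GroundTruth | None = None,
    centres: list[GeoCoord] | None = None,
    crop_half_angle: float = 20.0,
    n_repetitions: int = 2,
    rng_seed: int = 0,
    phi: int = 1,
    embedding: str = "upright",
) -> SyntheticCohort:
    """Position-tuning cohort: 38 disk stimuli (40° diameter) per fish."""
    rng = np.random.default_rng(rng_seed)
    if centres is None:
        centres = place_stimulus_centres(SeedConfiguration())
    sigma_b3 = truth.sigma_b3 if truth is not None else 0.0
    fish = [
        FishSpec(
            fish_id=f"fish{i + 1:02d}",
            b3=float(rng.normal(0.0, sigma_b3)) if sigma_b3 > 0 else 0.0,
            phi=phi,
            embedding=embedding,
        )
        for i in range(n_fish)
    ]
    protocol = [
        (
            f"D{i + 1}",
            StimulusSpec(crop_centre=c, crop_half_angle=crop_half_angle),
        )
        for i, c in enumerate(centres)
    ]
    return SyntheticCohort(fish=fish, protocol=protocol,
                           n_repetitions=n_repetitions, rng_seed=rng_seed)


def simulate_gain(
    fish: FishSpec,
    spec: StimulusSpec,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """(g_L, g_R) for one stimulus phase.

    Base gain is the vMF surface at the stimulus centre; a multiplicative
    hemisphere factor (1 ± δ) with δ = φ·b1 + b2 + b3,k reproduces the bias
    index B ≈ δ to first order; the unstimulated eye is scaled by
    (1 − Y0)/(1 + Y0); gains are truncated at 0.
    """
    centre = spec.crop_centre if spec.crop_centre is not None else GeoCoord(0.0, 0.0)
    base = float(vmf_sum_eval(truth.vmf, centre))
    delta = fish.phi * truth.b1 + truth.b2 + fish.b3
    az = centre.azimuth
    if az != 0.0 and abs(az) != 180.0:
        base *= (1.0 + delta) if az < 0 else (1.0 - delta)
    base = max(base, 0.0)

    vis = {
        eye: direct_visibility(centre, spec.crop_half_angle, eye,
                               eye_axis=fish.eye_axes[eye])
        for eye in ("left", "right")
    }
    yoke = (1.0 - truth.yoking_Y0) / (1.0 + truth.yoking_Y0)
    if vis["left"] == vis["right"]:  # binocular (or neither): both track alike
        g_L = g_R = base
    elif vis["left"] == "direct":
        g_L, g_R = base, base * yoke
    else:
        g_L, g_R = base * yoke, base

    if truth.gain_noise_sd > 0:
        g_L += rng.normal(0.0, truth.gain_noise_sd)
        g_R += rng.normal(0.0, truth.gain_noise_sd)
    return max(g_L, 0.0), max(g_R, 0.0)


def simulate_trace(
    g: float,
    spec: StimulusSpec,
    truth: GroundTruth,
    rng: np.random.Generator,
    *,
    sampling_rate: float = 60.0,
    eye: str = "left",
    fish_id: str = "",
    stimulus_id: str = "",
) -> EyeTrace:
    """One eye-position trace for a known gain.

    Slow phase −g·a_S·cos(2πft) plus cumulative quick-phase offsets: quick
    phases arrive as a Poisson process, directed opposite to the current
    stimulus velocity with truncated-normal amplitude; additive Gaussian
    noise σ_e; optional linear drift with the configured probability.
    """
    if g < 0:
        raise ValueError("gain must be non-negative")
    f = spec.envelope_frequency
    a_s = stimulus_position_amplitude(spec)
    dt = 1.0 / sampling_rate
    t = np.arange(0.0, spec.phase_duration, dt)
    angle = -g * a_s * np.cos(2.0 * math.pi * f * t)

    if truth.saccade_rate > 0:
        n_sac = rng.poisson(truth.saccade_rate * spec.phase_duration)
        times = np.sort(rng.uniform(t[0], t[-1], n_sac))
        offset = np.zeros_like(t)
        for ts in times:
            amp = abs(rng.normal(truth.quick_phase_mean, truth.quick_phase_sd))
            v_stim = math.sin(2.0 * math.pi * f * ts)  # sign of stimulus velocity
            direction = -math.copysign(1.0, v_stim) if v_stim != 0 else rng.choice([-1.0, 1.0])
            offset[t >= ts] += direction * amp
        angle = angle + offset

    if truth.drift_probability > 0 and rng.uniform() < truth.drift_probability:
        angle = angle + math.copysign(truth.drift_slope, rng.uniform() - 0.5) * t

    if truth.sigma_e > 0:
        angle = angle + rng.normal(0.0, truth.sigma_e, t.size)

    return EyeTrace(t=t, angle=angle, eye=eye, fish_id=fish_id,
                    stimulus_id=stimulus_id, sampling_rate=sampling_rate)


def generate_dataset(
    cohort: SyntheticCohort,
    truth: GroundTruth,
    *,
    with_traces: bool = True,
) -> tuple[pd.DataFrame, list[EyeTrace]]:
    """Full synthetic dataset: gain table + (optionally) raw traces.

    One gain record (and trace) per (fish, eye, stimulus, repetition);
    deterministic under the cohort's rng_seed.  The returned table carries
    the generated ("true") gains; the trace set is what the trace-analysis
    stage re-estimates them from.
    """
    if not cohort.protocol:
        raise ValueError("empty stimulus protocol")
    rng = np.random.default_rng(cohort.rng_seed)
    rows = []
    traces: list[EyeTrace] = []
    for fish in cohort.fish:
        for stim_id, spec in cohort.protocol:
            centre = spec.crop_centre if spec.crop_centre is not None else GeoCoord(0.0, 0.0)
            for rep in range(cohort.n_repetitions):
                g_L, g_R = simulate_gain(fish, spec, truth, rng)
                for eye, g in (("left", g_L), ("right", g_R)):
                    stimulated = direct_visibility(
                        centre, spec.crop_half_angle, eye,
                        eye_axis=fish.eye_axes[eye],
                    )
                    rows.append(
                        dict(
                            fish_id=fish.fish_id,
                            eye=eye,
                            stimulus_id=stim_id,
                            repetition=rep,
                            gain=round(g, 6),
                            azimuth=centre.azimuth,
                            elevation=centre.elevation,
                            crop_half_angle=spec.crop_half_angle,
                            stimulated=stimulated,
                            arena_orientation=fish.phi,
                            embedding=fish.embedding,
                        )
                    )
                    if with_traces:
                        traces.append(
                            simulate_trace(
                                g, spec, truth, rng, eye=eye,
                                fish_id=fish.fish_id, stimulus_id=stim_id,
                            )
                        )
    return pd.DataFrame(rows), traces
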