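"""Slow-phase eye-trace analysis: saccade removal and OKR gain estimation.

The eye tracks the sinusoidal stimulus during slow phases, interrupted by
resetting saccades.  After removing saccades, all inter-saccade intervals
(ISIs) are fitted jointly with a single sinusoid sharing amplitude c1,
angular frequency c2 and phase c3, plus one free offset per ISI:

    f(t ∈ ISI_k) = −c1·cos(c2·t + c3) + c_{k+3}

The OKR gain is g = a_E / a_S = c1 / a_S, the ratio of eye-position to
stimulus-position amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .stimulus import StimulusSpec, stimulus_position_amplitude

__all__ = [
    "EyeTrace",
    "IsiSegmentation",
    "SinusoidFitResults",
    "PiecewiseSinusoidModel",
    "GainRecord",
    "detect_saccades",
    "fit_piecewise_sinusoid",
    "okr_gain",
    "bode_point",
    "qc_trial",
]


@dataclass
class EyeTrace:
    """Sampled horizontal eye position for one (fish, eye, stimulus phase)."""

    t: np.ndarray  # s, strictly increasing
    angle: np.ndarray  # degrees
    eye: str = "left"  # {left, right}
    fish_id: str = ""
    stimulus_id: str = ""
    sampling_rate: float = 60.0  # Hz

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.t.size != self.angle.size:
            raise ValueError("t and angle must have equal length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.t.size and not np.all(np.isfinite(self.angle)):
            raise ValueError("angles must be finite")


@dataclass
class IsiSegmentation:
    """Saccade windows and the complementary inter-saccade intervals."""

    saccade_intervals: list[tuple[float, float]]
    isis: list[tuple[int, int]]  # half-open sample index ranges [start, stop)

    @property
    def n_saccades(self) -> int:
        return len(self.saccade_intervals)


def detect_saccades(
    trace: EyeTrace,
    vel_threshold: float = 40.0,
    min_separation: float = 0.5,
    pad: float = 0.1,
    min_isi_samples: int = 5,
) -> IsiSegmentation:
    """Threshold the smoothed eye velocity to find quick phases.

    A saccade is any run where |dθ/dt| (Savitzky-Golay smoothed) exceeds
    `vel_threshold` °/s; runs closer than `min_separation` s are merged and
    each is widened by `pad` s on both sides.  ISIs are the complement.
    """
    if trace.t.size == 0:
        raise ValueError("empty trace")
    duration = trace.t[-1] - trace.t[0]
    if duration < 2.0:
        raise ValueError("need at least 2 s of data for saccade detection")

    dt = float(np.median(np.diff(trace.t)))
    win = max(5, int(round(0.05 / dt)) | 1)  # ~50 ms, odd; keeps onsets sharp
    if win >= trace.t.size:
        win = trace.t.size - 1 if (trace.t.size - 1) % 2 == 1 else trace.t.size - 2
    if win >= 5:
        vel = savgol_filter(trace.angle, win, polyorder=2, deriv=1, delta=dt)
    else:
        vel = np.gradient(trace.angle, trace.t)

    fast = np.abs(vel) > vel_threshold
    intervals: list[tuple[float, float]] = []
    i = 0
    n = fast.size
    while i < n:
        if fast[i]:
            j = i
            while j + 1 < n and fast[j + 1]:
                j += 1
            intervals.append((trace.t[i] - pad, trace.t[j] + pad))
            i = j + 1
        else:
            i += 1
    # merge near-coincident saccades
    merged: list[tuple[float, float]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < min_separation:
            merged[-1] = (merged[-1][0], iv[1])
        else:
            merged.append(iv)

    keep = np.ones(n, dtype=bool)
    for a, b in merged:
        keep &= ~((trace.t >= a) & (trace.t <= b))
    isis: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if keep[i]:
            j = i
            while j + 1 < n and keep[j + 1]:
                j += 1
            if j - i + 1 >= min_isi_samples:
                isis.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return IsiSegmentation(saccade_intervals=merged, isis=isis)


@dataclass
class SinusoidFitResults:
    """Fitted shared sinusoid: amplitude c1 (deg), angular frequency c2
    (rad/s), phase c3 (rad), per-ISI offsets, and fit diagnostics."""

    c1: float
    c2: float
    c3: float
    offsets: np.ndarray
    residual_rms: float
    r_squared: float
    n_obs: int
    model: "PiecewiseSinusoidModel" = field(repr=False, default=None)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.c1, self.c2, self.c3], self.offsets])

    def predict(self, t: np.ndarray, isi_index: int = 0) -> np.ndarray:
        return -self.c1 * np.cos(self.c2 * np.asarray(t) + self.c3) + self.offsets[
            isi_index
        ]

    def summary(self) -> str:
        lines = [
            "Piecewise sinusoid fit",
            "======================",
            f"amplitude c1     {self.c1:10.4f} deg",
            f"ang. freq c2     {self.c2:10.4f} rad/s"
            f"  ({self.c2 / (2 * math.pi):.4f} Hz)",
            f"phase c3         {self.c3:10.4f} rad",
            f"ISIs             {len(self.offsets):6d}",
            f"observations     {self.n_obs:6d}",
            f"residual RMS     {self.residual_rms:10.4f} deg",
            f"R^2              {self.r_squared:10.4f}",
        ]
        return "\n".join(lines)


class PiecewiseSinusoidModel:
    """Joint shared-sinusoid, per-ISI-offset model of slow-phase data.

    Amplitude and offsets enter linearly given (c2, c3), so fitting is a
    2-parameter nonlinear search with exact linear subproblem (variable
    projection); c2 is softly bounded within ±`freq_tol` of the stimulus
    envelope frequency.
    """

    def __init__(
        self,
        trace: EyeTrace,
        segmentation: IsiSegmentation | None = None,
        f_init: float = 0.1,
        freq_tol: float = 0.2,
    ) -> None:
        if segmentation is None:
            segmentation = IsiSegmentation(
                saccade_intervals=[], isis=[(0, trace.t.size)]
            )
        if not segmentation.isis:
            raise ValueError("no usable inter-saccade intervals")
        self.trace = trace
        self.segmentation = segmentation
        self.f_init = f_init
        self.freq_tol = freq_tol

        idx = []
        isi_of = []
        for k, (a, b) in enumerate(segmentation.isis):
            idx.append(np.arange(a, b))
            isi_of.append(np.full(b - a, k))
        self._idx = np.concatenate(idx)
        self._isi_of = np.concatenate(isi_of)
        self._t = trace.t[self._idx]
        self._y = trace.angle[self._idx]
        if self._t.size < 5:
            raise ValueError("fewer than 5 samples across all ISIs")
        K = len(segmentation.isis)
        self._counts = np.bincount(self._isi_of, minlength=K)
        self._ymean = np.bincount(self._isi_of, self._y, minlength=K) / self._counts
        self._yc = self._y - self._ymean[self._isi_of]

    def _solve_linear(self, c2: float, c3: float):
        """Exact amplitude + per-ISI offsets for fixed (c2, c3).

        Per-ISI intercepts are profiled out by within-ISI demeaning, so the
        shared amplitude is a one-variable regression — O(n) per call.
        """
        col = -np.cos(c2 * self._t + c3)
        cmean = np.bincount(self._isi_of, col, minlength=self._counts.size) / self._counts
        colc = col - cmean[self._isi_of]
        denom = float(colc @ colc)
        c1 = float(colc @ self._yc) / denom if denom > 0 else 0.0
        resid = self._yc - c1 * colc
        offsets = self._ymean - c1 * cmean
        return np.concatenate([[c1], offsets]), resid

    def fit(self) -> SinusoidFitResults:
        w0 = 2.0 * math.pi * self.f_init
        lo = w0 * (1.0 - self.freq_tol)
        hi = w0 * (1.0 + self.freq_tol)

        def residuals(x):
            _, r = self._solve_linear(x[0], x[1])
            return r

        best = None
        # two phase starts suffice: the profiled amplitude absorbs sign
        # flips, making the landscape pi-periodic in c3
        for c3_0 in (0.0, math.pi / 2):
            sol = least_squares(
                residuals,
                x0=[w0, c3_0],
                bounds=([lo, -2 * math.pi], [hi, 2 * math.pi]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        # status 0 (evaluation budget) with a finite solution is accepted:
        # the tight tolerances are often unreachable on noisy data
        if not np.isfinite(best.cost):
            raise RuntimeError(
                f"sinusoid fit did not converge: {best.message}; "
                f"best params {best.x}"
            )
        c2, c3 = float(best.x[0]), float(best.x[1])
        coef, resid = self._solve_linear(c2, c3)
        c1 = float(coef[0])
        offsets = np.asarray(coef[1:], dtype=float)
        if c1 < 0:  # normalise amplitude sign into the phase
            c1 = -c1
            c3 += math.pi
        c3 = math.atan2(math.sin(c3), math.cos(c3))  # wrap to (-pi, pi]
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((self._y - self._y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return SinusoidFitResults(
            c1=c1,
            c2=c2,
            c3=c3,
            offsets=offsets,
            residual_rms=math.sqrt(ss_res / self._t.size),
            r_squared=r2,
            n_obs=int(self._t.size),
            model=self,
        )


def fit_piecewise_sinusoid(
    trace: EyeTrace,
    seg: IsiSegmentation | None = None,
    f_init: float = 0.1,
) -> SinusoidFitResults:
    """Convenience wrapper around :class:`PiecewiseSinusoidModel`."""
    return PiecewiseSinusoidModel(trace, seg, f_init=f_init).fit()


@dataclass
class GainRecord:
    """One OKR gain observation for a (fish, eye, stimulus, repetition)."""

    fish_id: str
    eye: str
    stimulus_id: str
    repetition: int
    gain: float
    phase_shift: float = 0.0  # rad, relative to stimulus position
    stimulated: str = "direct"  # {direct, indirect}
    arena_orientation: int = 1  # φ ∈ {+1, −1}
    embedding: str = "upright"  # {upright, inverted}

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if self.arena_orientation not in (1, -1):
            raise ValueError("arena_orientation must be +1 or -1")


def okr_gain(
    fit: SinusoidFitResults,
    spec: StimulusSpec,
    *,
    fish_id: str = "",
    eye: str = "left",
    stimulus_id: str = "",
    repetition: int = 0,
    stimulated: str = "direct",
    arena_orientation: int = 1,
    embedding: str = "upright",
) -> GainRecord:
    """OKR gain g = c1 / a_S and phase relative to the stimulus position.

    The stimulus position reference is s(t) = −a_S·cos(2πft), time zero at
    stimulus-phase onset, so the fitted c3 is directly the phase shift.
    """
    a_s = stimulus_position_amplitude(spec)
    if a_s == 0:
        raise ValueError("stimulus position amplitude is zero")
    return GainRecord(
        fish_id=fish_id,
        eye=eye,
        stimulus_id=stimulus_id,
        repetition=repetition,
        gain=fit.c1 / a_s,
        phase_shift=fit.c3,
        stimulated=stimulated,
        arena_orientation=arena_orientation,
        embedding=embedding,
    )


def bode_point(fit: SinusoidFitResults, spec: StimulusSpec) -> tuple[float, float]:
    """(magnitude, phase°) of the eye response relative to the stimulus.

    Magnitude is the OKR gain; phase is c3 in degrees wrapped to
    (−180, 180], negative for an eye lagging the stimulus.
    """
    g = fit.c1 / stimulus_position_amplitude(spec)
    phase = math.degrees(fit.c3)
    phase = ((phase + 180.0) % 360.0) - 180.0
    if phase == -180.0:
        phase = 180.0
    return g, phase


def qc_trial(
    fit: SinusoidFitResults,
    trace: EyeTrace,
    r2_min: float = 0.3,
    drift_threshold: float = 0.2,
) -> tuple[bool, str]:
    """Accept or reject a trial.

    Rejects when a linear drift fitted to the ISI residuals exceeds
    `drift_threshold` °/s or when the fit explains too little variance
    (r² < r2_min) — drifts and spontaneous eye movements superimposed on
    OKR are excluded from analysis.  Drift is checked first: a drifting
    trace also depresses r², and the more specific reason is recorded.
    Returns (accept, reason); reason is "" on accept.
    """
    m = fit.model
    if m is not None:
        pred_col = -np.cos(fit.c2 * m._t + fit.c3) * fit.c1
        resid = m._y - pred_col - fit.offsets[m._isi_of]
        # offsets absorb the between-ISI part of any drift, so estimate the
        # drift from within-ISI residual slopes (sample-weighted mean)
        slopes, weights = [], []
        for k in range(len(fit.offsets)):
            sel = m._isi_of == k
            if sel.sum() >= 5:
                slopes.append(np.polyfit(m._t[sel], resid[sel], 1)[0])
                weights.append(sel.sum())
        if slopes:
            slope = float(np.average(slopes, weights=weights))
            if abs(slope) > drift_threshold:
                return False, "drift"
    if fit.r_squared < r2_min:
        return False, "low_r2"
    return True, ""
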