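"""Spatial tuning of OKR gain on the sphere.

The gain map over stimulus position is modelled as the sum of two von
Mises-Fisher (vMF) components plus a constant offset,

    F(ξ) = Σ_j C_j·κ_j·exp(κ_j·μ_jᵀξ) / (2π(e^{κ_j} − e^{−κ_j})) + C3,

one component per eye's preferred location (yoking makes both appear in
either eye's map).  Each component integrates to C_j over the sphere.
Also here: vMF kernel smoothing of the discrete samples, the rotated-arena
bias correction, and frequency/size tuning-curve fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .geometry import GeoCoord, geo_to_unit, great_circle_angle, unit_to_geo

__all__ = [
    "VmfModel",
    "VmfFitResults",
    "BimodalVmfModel",
    "TuningCurveFit",
    "FrequencyTuningModel",
    "SizeTuningModel",
    "vmf_sum_eval",
    "fit_bimodal_vmf",
    "vmf_kernel_smooth",
    "correct_arena_rotation",
    "frequency_tuning",
    "size_tuning_fit",
    "direct_visibility",
    "records_to_frame",
    "DEFAULT_EYE_AXES",
]

# resting optical axes (azimuth, elevation) measured for immobilised larvae
DEFAULT_EYE_AXES = {
    "left": GeoCoord(-84.8, 3.5),
    "right": GeoCoord(80.1, 4.9),
}
DEFAULT_FOV = 163.0  # degrees per eye


@dataclass
class VmfModel:
    """Parameters of the bimodal vMF gain surface."""

    mu1: np.ndarray
    mu2: np.ndarray
    kappa1: float
    kappa2: float
    C1: float
    C2: float
    C3: float

    def __post_init__(self) -> None:
        self.mu1 = np.asarray(self.mu1, dtype=float)
        self.mu2 = np.asarray(self.mu2, dtype=float)
        for mu in (self.mu1, self.mu2):
            n = np.linalg.norm(mu)
            if abs(n - 1.0) > 1e-9:
                mu /= n
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ValueError("concentrations must be positive")

    @property
    def centre1(self) -> GeoCoord:
        return unit_to_geo(self.mu1)

    @property
    def centre2(self) -> GeoCoord:
        return unit_to_geo(self.mu2)

    def __call__(self, xi: np.ndarray) -> np.ndarray | float:
        return vmf_sum_eval(self, xi)

    def to_dict(self) -> dict:
        c1, c2 = self.centre1, self.centre2
        return {
            "centre1": [c1.azimuth, c1.elevation],
            "centre2": [c2.azimuth, c2.elevation],
            "kappa1": self.kappa1, "kappa2": self.kappa2,
            "C1": self.C1, "C2": self.C2, "C3": self.C3,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VmfModel":
        return cls(
            mu1=geo_to_unit(GeoCoord(*d["centre1"])),
            mu2=geo_to_unit(GeoCoord(*d["centre2"])),
            kappa1=d["kappa1"], kappa2=d["kappa2"],
            C1=d["C1"], C2=d["C2"], C3=d["C3"],
        )


def _vmf_component(kappa: float, dot: np.ndarray) -> np.ndarray:
    """κ·exp(κ·m) / (2π(e^κ − e^{−κ})), evaluated in the log domain.

    Rewritten as κ·exp(κ(m−1)) / (2π(1 − e^{−2κ})) so the exponent never
    overflows (m ≤ 1); finite for κ up to ~700 and beyond.
    """
    return (
        kappa
        * np.exp(kappa * (dot - 1.0))
        / (2.0 * math.pi * (1.0 - math.exp(-2.0 * kappa)))
    )


def vmf_sum_eval(model: VmfModel, xi: np.ndarray | GeoCoord) -> np.ndarray | float:
    """Evaluate the bimodal vMF surface at unit vector(s) xi."""
    if isinstance(xi, (GeoCoord, tuple)):
        xi = geo_to_unit(xi)
    xi = np.asarray(xi, dtype=float)
    scalar = xi.ndim == 1
    pts = xi[None, :] if scalar else xi
    val = (
        model.C1 * _vmf_component(model.kappa1, pts @ model.mu1)
        + model.C2 * _vmf_component(model.kappa2, pts @ model.mu2)
        + model.C3
    )
    return float(val[0]) if scalar else val


def records_to_frame(records) -> pd.DataFrame:
    """GainRecord list → DataFrame (pass-through for DataFrames)."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([vars(r) for r in records])


def _aggregate_positions(df: pd.DataFrame) -> pd.DataFrame:
    """Median gain per stimulus position (across fish and repetitions)."""
    return (
        df.groupby(["azimuth", "elevation"], as_index=False)["gain"]
        .median()
    )


@dataclass
class VmfFitResults:
    """Fitted bimodal vMF surface with diagnostics.

    `model` holds (μ_j, κ_j, C_j, C3).  `peaks` are the numerically located
    maxima of F, which for overlapping components sit further apart than
    the component centres μ_j themselves.
    """

    model: VmfModel
    loss: float
    r_squared: float
    n_positions: int
    n_starts: int
    degenerate: bool = False
    peaks: tuple[GeoCoord, GeoCoord] | None = None

    @property
    def centres(self) -> tuple[GeoCoord, GeoCoord]:
        return (self.model.centre1, self.model.centre2)

    def summary(self) -> str:
        c1, c2 = self.centres
        lines = [
            "Bimodal von Mises-Fisher fit",
            "============================",
            f"centre 1 (az, el)   ({c1.azimuth:8.2f}, {c1.elevation:7.2f}) deg"
            f"   kappa {self.model.kappa1:8.3f}  mass {self.model.C1:8.4f}",
            f"centre 2 (az, el)   ({c2.azimuth:8.2f}, {c2.elevation:7.2f}) deg"
            f"   kappa {self.model.kappa2:8.3f}  mass {self.model.C2:8.4f}",
            f"offset C3           {self.model.C3:10.4f}",
            f"positions           {self.n_positions:6d}",
            f"R^2                 {self.r_squared:10.4f}",
            f"multi-starts        {self.n_starts:6d}",
        ]
        if self.peaks is not None:
            p1, p2 = self.peaks
            lines.append(
                f"surface maxima      ({p1.azimuth:8.2f}, {p1.elevation:7.2f})"
                f" / ({p2.azimuth:8.2f}, {p2.elevation:7.2f}) deg"
            )
        if self.degenerate:
            lines.append("WARNING: degenerate fit (gains carry no spatial signal)")
        return "\n".join(lines)


class BimodalVmfModel:
    """Least-squares fit of the bimodal vMF surface to a gain table.

    Expects a DataFrame with columns azimuth, elevation, gain (degrees /
    dimensionless).  Gains are aggregated to a per-position median before
    fitting unless ``aggregate=False``.  Multi-start optimisation with
    mirror-symmetric lateral initialisation (±90, 0), κ = 5.
    """

    def __init__(
        self,
        records,
        aggregate: bool = True,
        direct_only: bool = False,
    ) -> None:
        df = records_to_frame(records)
        if direct_only and "stimulated" in df.columns:
            df = df[df["stimulated"] == "direct"]
        if aggregate:
            df = _aggregate_positions(df)
        self.data = df.reset_index(drop=True)
        n_pos = self.data[["azimuth", "elevation"]].drop_duplicates().shape[0]
        if n_pos < 11:
            raise ValueError(
                f"need >= 11 distinct stimulus positions, got {n_pos}"
            )
        self.n_positions = n_pos

    @staticmethod
    def _unpack(p: np.ndarray) -> VmfModel:
        az1, el1, lk1, lc1, az2, el2, lk2, lc2, c3 = p
        return VmfModel(
            mu1=geo_to_unit(GeoCoord(_wrap_az(az1), _clip_el(el1))),
            mu2=geo_to_unit(GeoCoord(_wrap_az(az2), _clip_el(el2))),
            kappa1=math.exp(lk1),
            kappa2=math.exp(lk2),
            C1=math.exp(lc1),
            C2=math.exp(lc2),
            C3=c3,
        )

    def fit(self, n_starts: int = 5, rng_seed: int = 0) -> VmfFitResults:
        xi = np.stack(
            [
                geo_to_unit(GeoCoord(a, e))
                for a, e in zip(self.data["azimuth"], self.data["elevation"])
            ]
        )
        y = self.data["gain"].to_numpy(dtype=float)
        degenerate = bool(np.ptp(y) < 1e-12)

        def residuals(p):
            m = self._unpack(p)
            return vmf_sum_eval(m, xi) - y

        scale = max(float(np.ptp(y)), 1e-6)
        base = [
            -90.0, 0.0, math.log(5.0), math.log(scale),
            90.0, 0.0, math.log(5.0), math.log(scale),
            float(np.min(y)),
        ]
        rng = np.random.default_rng(rng_seed)
        starts = [np.array(base)]
        for _ in range(max(0, n_starts - 1)):
            jitter = np.concatenate(
                [
                    rng.uniform([-30, -20, -1, -1], [30, 20, 1, 1]),
                    rng.uniform([-30, -20, -1, -1], [30, 20, 1, 1]),
                    [0.0],
                ]
            )
            starts.append(np.array(base) + jitter)

        # box constraints keep kappa in [0.1, 700] (finite evaluation) and
        # stop the optimizer wandering into overflow territory
        lb = [-360, -90, math.log(0.1), -20, -360, -90, math.log(0.1), -20, -10]
        ub = [360, 90, math.log(700.0), 10, 360, 90, math.log(700.0), 10, 10]
        best = None
        for x0 in starts:
            x0 = np.clip(x0, lb, ub)
            try:
                sol = least_squares(residuals, x0=x0, bounds=(lb, ub),
                                    xtol=1e-12, ftol=1e-12)
            except (ValueError, FloatingPointError):
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all vMF fit starts failed")

        model = self._unpack(best.x)
        ss_res = 2.0 * best.cost
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        peaks = _surface_maxima(model)
        return VmfFitResults(
            model=model,
            loss=float(best.cost),
            r_squared=r2,
            n_positions=self.n_positions,
            n_starts=len(starts),
            degenerate=degenerate,
            peaks=peaks,
        )


def _wrap_az(az: float) -> float:
    az = ((az + 180.0) % 360.0) - 180.0
    return 180.0 if az == -180.0 else az


def _clip_el(el: float) -> float:
    return min(89.999, max(-89.999, el))


def _surface_maxima(model: VmfModel) -> tuple[GeoCoord, GeoCoord]:
    """Numerically locate the two local maxima of F by dense grid + refine."""
    az = np.linspace(-180.0, 180.0, 181)
    el = np.linspace(-89.0, 89.0, 90)
    A, E = np.meshgrid(az, el)
    ar, er = np.radians(A), np.radians(E)
    pts = np.stack(
        [np.cos(er) * np.sin(ar), np.cos(er) * np.cos(ar), np.sin(er)], axis=-1
    )
    vals = vmf_sum_eval(model, pts.reshape(-1, 3)).reshape(A.shape)
    # split by the sagittal plane to find one maximum per hemisphere
    out = []
    for side in (A < 0, A >= 0):
        masked = np.where(side, vals, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        out.append(_refine_maximum(model, GeoCoord(A[i, j], E[i, j])))
    return tuple(out)


def _refine_maximum(model: VmfModel, start: GeoCoord) -> GeoCoord:
    from scipy.optimize import minimize

    def neg(p):
        return -vmf_sum_eval(model, GeoCoord(_wrap_az(p[0]), _clip_el(p[1])))

    res = minimize(neg, x0=[start.azimuth, start.elevation], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-12})
    return GeoCoord(_wrap_az(res.x[0]), _clip_el(res.x[1]))


def fit_bimodal_vmf(records, init: str = "symmetric_lateral", **kw) -> VmfFitResults:
    """Functional wrapper around :class:`BimodalVmfModel`."""
    if init not in ("symmetric_lateral", "custom"):
        raise ValueError("init must be 'symmetric_lateral' or 'custom'")
    return BimodalVmfModel(records, **kw).fit()


# ---------------------------------------------------------------------------
# Kernel smoothing and the rotated-arena correction


def vmf_kernel_smooth(
    records,
    kappa_smooth: float = 10.0,
    grid: np.ndarray | None = None,
    grid_step: float = 5.0,
) -> pd.DataFrame:
    """Nadaraya-Watson smoothing of discrete gains with a vMF kernel.

    ĝ(ξ) = Σ_i w_i·g_i / Σ_i w_i with w_i = exp(κ·ξᵀξ_i); returns a tidy
    (azimuth, elevation, gain) frame on the evaluation grid.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records to smooth")
    xi = np.stack(
        [geo_to_unit(GeoCoord(a, e)) for a, e in zip(df["azimuth"], df["elevation"])]
    )
    g = df["gain"].to_numpy(dtype=float)

    if grid is None:
        az = np.arange(-180.0, 180.0 + 1e-9, grid_step)
        el = np.arange(-90.0, 90.0 + 1e-9, grid_step)
        A, E = np.meshgrid(az, el)
        grid_geo = np.stack([A.ravel(), E.ravel()], axis=1)
    else:
        grid_geo = np.asarray(grid, dtype=float)
    ar, er = np.radians(grid_geo[:, 0]), np.radians(grid_geo[:, 1])
    pts = np.stack(
        [np.cos(er) * np.sin(ar), np.cos(er) * np.cos(ar), np.sin(er)], axis=1
    )
    dots = pts @ xi.T  # (n_grid, n_records)
    logw = kappa_smooth * dots
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    smoothed = (w @ g) / w.sum(axis=1)
    return pd.DataFrame(
        {"azimuth": grid_geo[:, 0], "elevation": grid_geo[:, 1], "gain": smoothed}
    )


def correct_arena_rotation(
    original, rotated, *, decimals: int = 1
) -> pd.DataFrame:
    """Average per-position medians from the original and rotated arenas.

    The rotated arena swaps left/right and upper/lower LEDs as seen by the
    fish, so rotated records are remapped (az, el) → (−az, −el) before
    matching.  Per matched position the corrected gain is
    mean(median(original), median(rotated)); any additive bias that flips
    sign with arena orientation cancels in expectation.  Positions present
    in only one table are flagged and excluded.
    """
    odf = records_to_frame(original).copy()
    rdf = records_to_frame(rotated).copy()
    rdf["azimuth"] = -rdf["azimuth"]
    rdf["elevation"] = -rdf["elevation"]
    for df in (odf, rdf):
        df["azimuth"] = df["azimuth"].round(decimals)
        df["elevation"] = df["elevation"].round(decimals)
        df.loc[df["azimuth"] == -180.0, "azimuth"] = 180.0
    om = _aggregate_positions(odf).rename(columns={"gain": "gain_original"})
    rm = _aggregate_positions(rdf).rename(columns={"gain": "gain_rotated"})
    merged = om.merge(rm, on=["azimuth", "elevation"], how="outer", indicator=True)
    merged["matched"] = merged["_merge"] == "both"
    merged["gain"] = merged[["gain_original", "gain_rotated"]].mean(axis=1)
    merged.loc[~merged["matched"], "gain"] = np.nan
    return merged.drop(columns="_merge")


# ---------------------------------------------------------------------------
# Frequency and size tuning


@dataclass
class TuningCurveFit:
    """Per-location tuning-curve fit results.

    kind="frequency": log-Gaussian bump; per-location dict values are
    (peak_frequency, raw_argmax, flag).  kind="size": logistic in log size;
    values are (g_max, s50, slope_w, flag).
    """

    kind: str
    per_location: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"{self.kind.capitalize()} tuning", "=" * 20]
        for loc, vals in self.per_location.items():
            lines.append(f"  {loc}: " + ", ".join(f"{v:.4g}" if isinstance(v, float) else str(v) for v in vals))
        return "\n".join(lines)


class FrequencyTuningModel:
    """Unimodal (log-Gaussian) spatial-frequency tuning, per location."""

    def __init__(self, records) -> None:
        df = records_to_frame(records)
        if "frequency" not in df.columns:
            raise ValueError("records need a 'frequency' column (cycles/degree)")
        if df["frequency"].nunique() < 3:
            raise ValueError("need >= 3 distinct spatial frequencies")
        self.data = df

    def fit(self) -> TuningCurveFit:
        out = TuningCurveFit(kind="frequency")
        for loc, grp in self.data.groupby(["azimuth", "elevation"]):
            mean = grp.groupby("frequency")["gain"].mean()
            f = mean.index.to_numpy(dtype=float)
            g = mean.to_numpy(dtype=float)
            raw_peak = float(f[np.argmax(g)])
            flag = ""
            if np.ptp(g) < 1e-12:
                out.per_location[loc] = (math.nan, raw_peak, "flat")
                continue
            if np.argmax(g) in (0, len(g) - 1):
                flag = "boundary"

            def resid(p):
                a, lf0, lw = p
                return a * np.exp(-((np.log(f) - lf0) ** 2) / (2 * np.exp(2 * lw))) - g

            x0 = [float(g.max()), float(np.log(raw_peak)), math.log(0.7)]
            sol = least_squares(resid, x0=x0)
            peak = float(np.exp(sol.x[1]))
            if not (f.min() / 2 <= peak <= f.max() * 2):
                flag = flag or "peak_outside_range"
            out.per_location[loc] = (peak, raw_peak, flag)
        return out


class SizeTuningModel:
    """Sigmoid-in-log-size tuning: g(s) = g_max / (1 + exp(−(ln s − ln s50)/w)).

    s is the stimulus size as a fraction of the sphere surface; s50 is the
    size of half-maximum gain.
    """

    def __init__(self, records) -> None:
        df = records_to_frame(records)
        if "size" not in df.columns:
            raise ValueError("records need a 'size' column (fraction of sphere)")
        sizes = df["size"].unique()
        if len(sizes) < 4:
            raise ValueError("need >= 4 distinct stimulus sizes")
        if np.log10(sizes.max() / sizes.min()) < 1.0:
            raise ValueError("sizes must span at least one decade")
        self.data = df

    def fit(self) -> TuningCurveFit:
        out = TuningCurveFit(kind="size")
        for loc, grp in self.data.groupby(["azimuth", "elevation"]):
            mean = grp.groupby("size")["gain"].mean()
            s = mean.index.to_numpy(dtype=float)
            g = mean.to_numpy(dtype=float)
            if np.ptp(g) < 1e-12 or g.max() <= 0:
                out.per_location[loc] = (float(g.max()), math.nan, math.nan, "flat")
                continue

            def resid(p):
                gmax, ls50, lw = p
                return gmax / (1.0 + np.exp(-(np.log(s) - ls50) / np.exp(lw))) - g

            x0 = [float(g.max()), float(np.log(np.median(s))), math.log(0.5)]
            sol = least_squares(resid, x0=x0, xtol=1e-14, ftol=1e-14)
            gmax, s50, w = float(sol.x[0]), float(np.exp(sol.x[1])), float(np.exp(sol.x[2]))
            out.per_location[loc] = (gmax, s50, w, "")
        return out


def frequency_tuning(records) -> TuningCurveFit:
    return FrequencyTuningModel(records).fit()


def size_tuning_fit(records) -> TuningCurveFit:
    return SizeTuningModel(records).fit()


def direct_visibility(
    stimulus_centre: GeoCoord | tuple,
    crop_half_angle: float,
    eye: str,
    eye_axis: GeoCoord | None = None,
    fov: float = DEFAULT_FOV,
) -> str:
    """Whether a cropped stimulus is directly visible to an eye.

    "direct" iff the great-circle angle between the stimulus centre and the
    eye's optical axis is at most fov/2 + crop_half_angle; otherwise the eye
    can only respond through yoking ("indirect").
    """
    if not 0.0 < fov <= 360.0:
        raise ValueError("fov must be in (0, 360]")
    if eye_axis is None:
        eye_axis = DEFAULT_EYE_AXES[eye]
    if fov >= 360.0:
        return "direct"
    ang = great_circle_angle(stimulus_centre, eye_axis)
    return "direct" if ang <= fov / 2.0 + crop_half_angle else "indirect"
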