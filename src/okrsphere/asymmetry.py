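"""Left/right asymmetry statistics: yoking, bias, and inference.

Yoking index: Y = (g_L − g_R)/(g_L + g_R) for the two eyes' gains in the
same stimulus phase (0 = perfectly conjugate, ±1 = fully monocular).

Bias index: B = (m_L − m_R)/(m_L + m_R) where m_L, m_R are a fish's median
gains over left- and right-hemisphere stimuli.  Observed biases are
modelled as a linear combination of an environmental term that flips with
arena orientation φ ∈ {+1, −1}, a shared biological bias, and a per-fish
bias:

    B_k = φ·b1 + b2 + b3,k + η

fitted by two-stage regression: (b1, b2) by least squares with the b3,k
set aside (they average out across the population), then b3,k as each
fish's mean residual.

The embedding-direction comparison uses an exact permutation test over all
size-preserving reassignments of fish to groups; the statistic is the
difference between group elevations, each taken from a pooled bimodal vMF
fit (mean of the two hemisphere component elevations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .spatial import BimodalVmfModel, records_to_frame

__all__ = [
    "YokingResult",
    "BiasResult",
    "AsymmetryModel",
    "AsymmetryResults",
    "PermutationTestResult",
    "yoking_index",
    "bias_index",
    "assign_hemisphere",
    "fit_asymmetry_model",
    "permutation_test_elevation",
    "vmf_elevation_statistic",
]


@dataclass(frozen=True)
class YokingResult:
    Y: float
    g_L: float
    g_R: float
    condition: str = ""
    defined: bool = True


def yoking_index(g_L: float, g_R: float, condition: str = "") -> YokingResult:
    """Y = (g_L − g_R)/(g_L + g_R); undefined (flagged) when both gains are 0."""
    if g_L < 0 or g_R < 0:
        raise ValueError("gains must be non-negative")
    tot = g_L + g_R
    if tot == 0:
        return YokingResult(Y=math.nan, g_L=g_L, g_R=g_R, condition=condition,
                            defined=False)
    return YokingResult(Y=(g_L - g_R) / tot, g_L=g_L, g_R=g_R, condition=condition)


@dataclass(frozen=True)
class BiasResult:
    B: float
    m_L: float
    m_R: float
    fish_id: str = ""
    phi: int = 1


def assign_hemisphere(azimuth: float) -> str | None:
    """left / right by azimuth sign; None on the sagittal plane (0 or ±180)."""
    if azimuth == 0.0 or abs(azimuth) == 180.0:
        return None
    return "left" if azimuth < 0 else "right"


def bias_index(records, fish_id: str | None = None, phi: int | None = None) -> BiasResult:
    """Hemisphere bias of one fish's gain records.

    Records on the sagittal plane (azimuth exactly 0 or ±180) belong to
    neither pool and are dropped.
    """
    df = records_to_frame(records)
    if fish_id is None:
        fish_id = str(df["fish_id"].iloc[0]) if "fish_id" in df.columns else ""
    if phi is None:
        phi = int(df["arena_orientation"].iloc[0]) if "arena_orientation" in df.columns else 1
    hemi = df["azimuth"].map(assign_hemisphere)
    m_L = df.loc[hemi == "left", "gain"].median()
    m_R = df.loc[hemi == "right", "gain"].median()
    if pd.isna(m_L) or pd.isna(m_R):
        raise ValueError(f"fish {fish_id}: a hemisphere has no records")
    tot = m_L + m_R
    B = (m_L - m_R) / tot if tot > 0 else 0.0
    return BiasResult(B=float(B), m_L=float(m_L), m_R=float(m_R),
                      fish_id=fish_id, phi=phi)


@dataclass
class AsymmetryResults:
    """Two-stage regression estimates of the asymmetry model."""

    b1: float
    b2: float
    b3: dict  # fish_id -> b3,k
    b1_se: float
    b2_se: float
    eta_std: float  # residual noise after both stages
    n_obs: int
    identifiable: bool = True

    def summary(self) -> str:
        b3v = np.array(list(self.b3.values()))
        lines = [
            "Asymmetry model  B_k = phi*b1 + b2 + b3_k + eta",
            "===============================================",
            f"b1 (environmental)  {self.b1:12.6f}  (se {self.b1_se:.6f})",
            f"b2 (shared bias)    {self.b2:12.6f}  (se {self.b2_se:.6f})",
            f"b3 per-fish         mean {b3v.mean():.6f}  sd {b3v.std(ddof=1) if b3v.size > 1 else 0.0:.6f}"
            f"  (n = {b3v.size})",
            f"residual eta sd     {self.eta_std:12.6f}",
            f"observations        {self.n_obs:6d}",
        ]
        if not self.identifiable:
            lines.append("WARNING: single arena orientation; b1 not identifiable")
        return "\n".join(lines)


class AsymmetryModel:
    """Fits the linear asymmetry decomposition to a set of bias indices."""

    def __init__(self, biases: Sequence[BiasResult]) -> None:
        if len(biases) < 2:
            raise ValueError("need at least 2 bias observations")
        fish = {b.fish_id for b in biases}
        if len(fish) < 2:
            raise ValueError("need at least 2 fish")
        self.biases = list(biases)

    def fit(self) -> AsymmetryResults:
        B = np.array([b.B for b in self.biases])
        phi = np.array([b.phi for b in self.biases], dtype=float)
        fish = [b.fish_id for b in self.biases]
        identifiable = len(set(phi)) > 1

        X = np.column_stack([phi, np.ones_like(phi)])
        coef, res_ss, rank, _ = np.linalg.lstsq(X, B, rcond=None)
        b1, b2 = float(coef[0]), float(coef[1])
        resid = B - X @ coef
        dof = max(1, len(B) - 2)
        sigma2 = float(resid @ resid) / dof
        if identifiable:
            cov = sigma2 * np.linalg.inv(X.T @ X)
            b1_se, b2_se = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
        else:
            b1 = 0.0
            b2 = float(B.mean())
            resid = B - b2
            b1_se, b2_se = math.nan, math.sqrt(sigma2 / len(B))

        b3: dict = {}
        for fid in dict.fromkeys(fish):  # preserve order
            sel = [i for i, f in enumerate(fish) if f == fid]
            b3[fid] = float(np.mean(resid[sel]))
        eta = resid - np.array([b3[f] for f in fish])
        eta_std = float(eta.std(ddof=1)) if eta.size > 1 else 0.0
        return AsymmetryResults(
            b1=b1, b2=b2, b3=b3, b1_se=b1_se, b2_se=b2_se,
            eta_std=eta_std, n_obs=len(B), identifiable=identifiable,
        )


def fit_asymmetry_model(biases: Sequence[BiasResult]) -> AsymmetryResults:
    return AsymmetryModel(biases).fit()


# ---------------------------------------------------------------------------
# Permutation test on embedding direction


@dataclass
class PermutationTestResult:
    p_value: float
    observed: float
    distribution: np.ndarray
    n_permutations: int
    n_excluded: int = 0

    def summary(self) -> str:
        return (
            f"Permutation test: observed statistic {self.observed:.4f}, "
            f"p = {self.p_value:.4f} over {self.n_permutations} assignments"
            + (f" ({self.n_excluded} excluded as degenerate)" if self.n_excluded else "")
        )


def vmf_elevation_statistic(df_a: pd.DataFrame, df_b: pd.DataFrame) -> float:
    """Difference of group elevations from pooled bimodal vMF fits.

    Each group's elevation is the mean of its two fitted hemisphere-centre
    elevations (fish-centred coordinates).
    """

    def group_elev(df):
        res = BimodalVmfModel(df).fit(n_starts=1)
        c1, c2 = res.centres
        return (c1.elevation + c2.elevation) / 2.0

    return group_elev(df_a) - group_elev(df_b)


def permutation_test_elevation(
    group_a,
    group_b,
    statistic: Callable[[pd.DataFrame, pd.DataFrame], float] | None = None,
    *,
    max_exact: int = 20,
    n_samples: int = 2000,
    rng_seed: int = 0,
) -> PermutationTestResult:
    """Exact (or sampled) permutation test of fish-level group labels.

    `group_a` / `group_b` are sequences of per-fish gain tables.  All
    C(n_A+n_B, n_A) size-preserving reassignments are enumerated when the
    total is at most `max_exact`; otherwise `n_samples` random assignments
    are drawn with a fixed seed.  The reported p is the fraction of
    assignments whose statistic is >= the observed one; the identity
    assignment is among them, so p >= 1/P.  Assignments where the statistic
    fails (degenerate fit) are excluded and counted.
    """
    if statistic is None:
        statistic = vmf_elevation_statistic
    fish = [records_to_frame(f) for f in group_a] + [
        records_to_frame(f) for f in group_b
    ]
    n_a, n_total = len(group_a), len(fish)
    if n_a == 0 or n_total == n_a:
        raise ValueError("both groups must be non-empty")

    if n_total <= max_exact:
        assignments = list(combinations(range(n_total), n_a))
    else:
        rng = np.random.default_rng(rng_seed)
        identity = tuple(range(n_a))
        assignments = [identity] + [
            tuple(sorted(rng.choice(n_total, n_a, replace=False)))
            for _ in range(n_samples - 1)
        ]

    identity = tuple(range(n_a))
    observed = None
    stats = []
    excluded = 0
    for idx in assignments:
        sel = set(idx)
        df_a = pd.concat([fish[i] for i in idx], ignore_index=True)
        df_b = pd.concat(
            [fish[i] for i in range(n_total) if i not in sel], ignore_index=True
        )
        try:
            s = float(statistic(df_a, df_b))
        except (ValueError, RuntimeError):
            excluded += 1
            if idx == identity:
                raise
            continue
        stats.append(s)
        if idx == identity:
            observed = s
    if observed is None:
        raise RuntimeError("observed (identity) assignment could not be evaluated")
    stats = np.asarray(stats)
    p = float(np.mean(stats >= observed))
    return PermutationTestResult(
        p_value=p,
        observed=observed,
        distribution=stats,
        n_permutations=len(stats),
        n_excluded=excluded,
    )
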