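"""Pulse-labeling kinetics: precursor pool sizes from fraction-labeled time courses.

During steady-state exponential growth, cells shifted to 15N media
incorporate label into newly made protein.  A protein drawn from a large
unassembled precursor pool dilutes the label: its fraction-labeled value
lags the maximum expected labeling curve.  The lag is governed by a single
parameter P, the precursor pool size expressed as a fraction of the
standing assembled population:

    fL(t) = 1 + P * exp(-k * (1 + 1/P) * t) - (1 + P) * exp(-k * t)

with k the culture growth rate (min^-1) and t the pulse length (min).
As P -> 0 this converges to the maximum-labeling curve

    fmax(t) = 1 - exp(-k * t)

so depleted proteins (no free pool) ride fmax, while abundant precursors
(large P) lag it.  P is the only free parameter of the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.cluster import KMeans

__all__ = [
    "DEFAULT_GROWTH_RATE",
    "TimeCourse",
    "PoolFitResult",
    "PoolSizeModel",
    "f_l_model",
    "f_max",
    "fit_pool_size",
    "classify_pool_groups",
    "DegenerateDataError",
]

DEFAULT_GROWTH_RATE = float(np.log(2) / 60.0)  # 60-min doubling time, min^-1

P_MAX_DEFAULT = 10.0
_MULTISTART_GRID = (0.001, 0.01, 0.1, 1.0)
_FLAT_TOL = 1e-3


class DegenerateDataError(ValueError):
    """Time course unusable for fitting (too few points, bad values)."""


def f_max(t, k: float):
    """Maximum expected labeling ``1 - exp(-k t)`` (the no-pool limit)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if k <= 0:
        raise ValueError("k must be > 0")
    return 1.0 - np.exp(-k * t)


def f_l_model(t, P: float, k: float):
    """Fraction labeled at pulse length ``t`` for pool size ``P`` and growth rate ``k``.

    Returns the closed-form pool-dilution curve for P > 0 and its
    continuous limit fmax(t) = 1 - exp(-k t) for P = 0.  Scalar or array
    ``t``; the result lies in [0, 1].
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if k <= 0:
        raise ValueError("k must be > 0")
    if P < 0:
        raise ValueError("P must be >= 0")
    if P == 0:
        out = 1.0 - np.exp(-k * t_arr)
    else:
        # exponent written as -kt - kt/P so tiny P underflows cleanly to
        # exp(-inf) = 0 instead of producing inf * 0 = nan at t = 0
        kt = k * t_arr
        with np.errstate(over="ignore"):
            out = 1.0 + P * np.exp(-kt - kt / P) - (1.0 + P) * np.exp(-kt)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(t) else out


@dataclass
class TimeCourse:
    """Observed fraction-labeled values for one protein over pulse lengths."""

    protein_id: str
    t: np.ndarray
    f_labeled: np.ndarray
    k: float = DEFAULT_GROWTH_RATE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_labeled = np.asarray(self.f_labeled, dtype=float)
        if self.t.shape != self.f_labeled.shape:
            raise ValueError("t and f_labeled must have the same length")
        if np.any(self.t < 0):
            raise ValueError("pulse lengths must be >= 0")
        if self.k <= 0:
            raise ValueError("growth rate k must be > 0")
        if np.any((self.f_labeled < 0) | (self.f_labeled > 1)):
            warnings.warn(
                f"{self.protein_id}: fraction-labeled values outside [0, 1] clipped",
                stacklevel=2,
            )
            self.f_labeled = np.clip(self.f_labeled, 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class PoolFitResult:
    """Fitted precursor pool size with diagnostics."""

    protein_id: str
    P: float
    rss: float
    converged: bool
    n_obs: int
    k: float

    def predict(self, t) -> np.ndarray:
        return f_l_model(t, self.P, self.k)

    def summary(self) -> str:
        lines = [
            "Precursor pool size fit",
            "=======================",
            f"protein:          {self.protein_id}",
            f"n observations:   {self.n_obs}",
            f"growth rate k:    {self.k:.6g} /min",
            f"pool size P:      {self.P:.6g}  ({100 * self.P:.2f}% of standing population)",
            f"residual SS:      {self.rss:.6g}",
            f"converged:        {self.converged}",
        ]
        return "\n".join(lines)


class PoolSizeModel:
    """Single-parameter least-squares fit of the pool-dilution curve.

    P is bounded to [0, p_max]; beyond ~10x the standing population the
    objective flattens and larger pools are biologically meaningless.  The
    optimizer is deterministic: bounded scalar minimization restarted from
    a fixed grid, plus explicit evaluation of the P = 0 boundary.
    """

    def __init__(self, timecourse: TimeCourse, p_max: float = P_MAX_DEFAULT) -> None:
        usable = timecourse.t > 0
        if int(usable.sum()) < 2 or len(np.unique(timecourse.t[usable])) < 2:
            raise DegenerateDataError(
                f"{timecourse.protein_id}: need >= 2 observations at distinct t > 0"
            )
        self.timecourse = timecourse
        self.p_max = p_max

    def _rss(self, P: float) -> float:
        pred = f_l_model(self.timecourse.t, P, self.timecourse.k)
        return float(np.sum((self.timecourse.f_labeled - pred) ** 2))

    def fit(self) -> PoolFitResult:
        tc = self.timecourse
        best_p, best_rss = 0.0, self._rss(0.0)
        for start in _MULTISTART_GRID:
            lo = max(start / 10.0, 0.0)
            hi = min(start * 10.0, self.p_max)
            res = minimize_scalar(self._rss, bounds=(lo, hi), method="bounded")
            if res.fun < best_rss - 1e-15 or (
                abs(res.fun - best_rss) <= 1e-15 and res.x < best_p
            ):
                best_p, best_rss = float(res.x), float(res.fun)
        # polish over the full interval around the incumbent
        res = minimize_scalar(
            self._rss,
            bounds=(max(best_p / 3.0, 0.0), min(max(best_p * 3.0, 1e-3), self.p_max)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun <= best_rss:
            best_p, best_rss = float(res.x), float(res.fun)
        if self._rss(0.0) <= best_rss:
            best_p, best_rss = 0.0, self._rss(0.0)

        fmax = f_max(tc.t, tc.k)
        flat = bool(
            np.all(tc.f_labeled <= _FLAT_TOL)
            or np.all(np.abs(tc.f_labeled - fmax) <= _FLAT_TOL)
        )
        return PoolFitResult(
            protein_id=tc.protein_id,
            P=best_p,
            rss=best_rss,
            converged=not flat,
            n_obs=len(tc),
            k=tc.k,
        )


def fit_pool_size(timecourse: TimeCourse, p_max: float = P_MAX_DEFAULT) -> PoolFitResult:
    """Fit the pool size P of one time course (see :class:`PoolSizeModel`)."""
    return PoolSizeModel(timecourse, p_max=p_max).fit()


@dataclass(frozen=True)
class PoolGroupResult:
    """Two-group partition of proteins in (pool size, abundance) space."""

    labels: list[str]
    centers: np.ndarray = field(repr=False)
    group_names: tuple[str, str] = ("large-pool/abundant", "small-pool/depleted")


def classify_pool_groups(
    points: np.ndarray,
    outlier_factor: float = 3.0,
) -> PoolGroupResult:
    """Partition (P, relative abundance) points into two groups plus outliers.

    Points are standardized, clustered with deterministic 2-means, and any
    point farther than ``outlier_factor`` times the within-group spread
    (median member-to-center distance) from *both* centers is labeled
    ``"outlier"``.  The group containing the larger mean pool size is named
    ``"large-pool/abundant"``, the other ``"small-pool/depleted"``.  All
    identical points collapse to a single group with no outliers.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (P, abundance)")
    n = len(pts)
    if n < 2:
        raise DegenerateDataError("need >= 2 points to classify")
    scale = pts.std(axis=0, ddof=0)
    if np.all(scale == 0):
        return PoolGroupResult(
            labels=["large-pool/abundant"] * n, centers=np.vstack([pts[0], pts[0]])
        )
    scale = np.where(scale == 0, 1.0, scale)
    z = (pts - pts.mean(axis=0)) / scale

    # 2-means, iteratively dropping singleton clusters (an extreme point
    # grabbing its own center would otherwise mask itself from the
    # outlier rule)
    candidates = np.arange(n)
    for _ in range(3):
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(z[candidates])
        sizes = np.bincount(km.labels_, minlength=2)
        if sizes.min() >= 2 or len(candidates) <= 3:
            break
        keep = np.isin(km.labels_, np.flatnonzero(sizes >= 2))
        candidates = candidates[keep]
    centers = km.cluster_centers_

    dists = np.linalg.norm(z[:, None, :] - centers[None, :, :], axis=2)
    member_assign = dists[candidates].argmin(axis=1)
    spreads = np.empty(2)
    for g in (0, 1):
        member_d = dists[candidates[member_assign == g], g]
        spreads[g] = max(float(np.sqrt(np.mean(member_d**2))), 1e-9) if len(member_d) else 1e-9

    assign = dists.argmin(axis=1)
    # order groups so that index 0 has the larger mean P
    mean_p = [pts[assign == g, 0].mean() if np.any(assign == g) else -np.inf for g in (0, 1)]
    order = (0, 1) if mean_p[0] >= mean_p[1] else (1, 0)
    names = {order[0]: "large-pool/abundant", order[1]: "small-pool/depleted"}

    labels = []
    for i in range(n):
        if all(dists[i, g] > outlier_factor * spreads[g] for g in (0, 1)):
            labels.append("outlier")
        else:
            labels.append(names[assign[i]])
    centers_orig = np.vstack(
        [pts[assign == g].mean(axis=0) if np.any(assign == g) else pts.mean(axis=0) for g in order]
    )
    return PoolGroupResult(labels=labels, centers=centers_orig)
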