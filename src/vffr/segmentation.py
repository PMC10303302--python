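"""Classical lumen segmentation on polar IVUS-style frames, ECG gating, and
frame-to-arclength pullback mapping.

An intravascular ultrasound frame resampled to polar coordinates (angle x
radius, catheter at the origin) shows a dark lumen surrounded by a brighter
wall.  The lumen boundary is traced as a minimum-cost closed path over the
(angle, radius) node grid: node cost favours a strong outward (dark-to-bright)
radial intensity gradient, transitions between adjacent angle bins are limited
to a small radial jump, and closure is enforced by solving the shortest path
for each candidate start radius and keeping the cheapest closed tour.  Because
the angle axis is a DAG, the per-start shortest path is computed by dynamic
programming, which is exactly Dijkstra's result on this graph.

Pullback frames are gated to end-diastole using the ECG R-wave train (one
frame per beat, nearest in time to the R wave minus an optional offset) and
mapped to arc length assuming a uniform motorized pullback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .geometry import VesselProfile

__all__ = [
    "PolarImage",
    "Contour",
    "PullbackMap",
    "UnsegmentableFrameError",
    "trace_lumen",
    "gate_frames",
    "map_pullback",
    "contours_to_profile",
]


class UnsegmentableFrameError(RuntimeError):
    """The frame has no radial gradient structure to trace (e.g. flat image)."""


@dataclass(frozen=True)
class PolarImage:
    """Intensity grid indexed (angle_bin, radius_bin) with physical calibration."""

    intensity: np.ndarray
    mm_per_radius_bin: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 8 or arr.shape[1] < 8:
            raise ValueError("polar image must be 2-D with >= 8 angular and radial bins")
        if not np.all(np.isfinite(arr)):
            raise ValueError("polar image intensities must be finite")
        if self.mm_per_radius_bin <= 0:
            raise ValueError("mm_per_radius_bin must be > 0")
        object.__setattr__(self, "intensity", arr)

    @property
    def angular_bins(self) -> int:
        return self.intensity.shape[0]

    @property
    def radial_bins(self) -> int:
        return self.intensity.shape[1]


@dataclass(frozen=True)
class Contour:
    """Closed lumen boundary: one radius per angle bin.

    The enclosed area is the polar-sector sum A = 1/2 * sum_i r_i^2 * dtheta,
    exact for a constant radius.
    """

    radius_mm: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.radius_mm, dtype=float)
        if r.ndim != 1 or r.size < 8:
            raise ValueError("contour needs >= 8 angle bins")
        if np.any(r <= 0) or not np.all(np.isfinite(r)):
            raise ValueError("contour radii must be finite and > 0")
        object.__setattr__(self, "radius_mm", r)

    @property
    def area_mm2(self) -> float:
        dtheta = 2.0 * np.pi / self.radius_mm.size
        return float(0.5 * np.sum(self.radius_mm**2) * dtheta)


@dataclass(frozen=True)
class PullbackMap:
    """Gated frame indices mapped to centerline arc length (uniform pullback)."""

    gated_frames: np.ndarray
    arclength_mm: np.ndarray
    pullback_speed_mm_per_s: float
    frame_rate_per_s: float

    def __post_init__(self) -> None:
        g = np.asarray(self.gated_frames, dtype=int)
        s = np.asarray(self.arclength_mm, dtype=float)
        if g.size != s.size or g.size == 0:
            raise ValueError("gated frames and arc lengths must match and be non-empty")
        if np.any(np.diff(s) < 0):
            raise ValueError("arclength mapping must be monotone in frame index")
        object.__setattr__(self, "gated_frames", g)
        object.__setattr__(self, "arclength_mm", s)


def _radial_edge_cost(image: PolarImage) -> np.ndarray:
    """Node costs: low where the outward radial gradient is strong."""
    grad = np.gradient(image.intensity, axis=1)
    span = float(grad.max() - grad.min())
    scale = float(np.ptp(image.intensity))
    if scale <= 0 or span <= 1e-12 * max(1.0, abs(float(image.intensity.max()))):
        raise UnsegmentableFrameError("no radial gradient structure in frame")
    return (grad.max() - grad) / span  # in [0, 1], 0 at the strongest edge


def trace_lumen(
    image: PolarImage,
    smoothness_max_jump_bins: int = 2,
    curvature_penalty: float = 0.05,
    start_radius_stride: int = 2,
) -> Contour:
    """Trace the lumen boundary as a minimum-cost closed path.

    Parameters
    ----------
    smoothness_max_jump_bins
        Maximum |delta radius| (bins) between adjacent angle bins, enforced
        on the wrap-around pair as well.
    curvature_penalty
        Cost per radial bin of jump, discouraging jagged boundaries.
    start_radius_stride
        Candidate start radii are subsampled at this stride; the closed path
        of minimum total cost over all candidates is kept, ties broken toward
        the smaller start radius.

    Raises
    ------
    UnsegmentableFrameError
        If the frame has no gradient structure (flat or constant image).
    """
    cost = _radial_edge_cost(image)
    n_ang, n_rad = cost.shape
    J = int(smoothness_max_jump_bins)
    if J < 1:
        raise ValueError("smoothness_max_jump_bins must be >= 1")
    lam = float(curvature_penalty)
    deltas = np.arange(-J, J + 1)

    best_total = np.inf
    best_path = None
    for r0 in range(0, n_rad, max(1, int(start_radius_stride))):
        dp = np.full(n_rad, np.inf)
        dp[r0] = cost[0, r0]
        back = np.zeros((n_ang, n_rad), dtype=np.int32)
        for a in range(1, n_ang):
            cand = np.full((deltas.size, n_rad), np.inf)
            for k, d in enumerate(deltas):
                if d > 0:
                    cand[k, d:] = dp[:-d] + lam * d
                elif d < 0:
                    cand[k, :d] = dp[-d:] + lam * (-d)
                else:
                    cand[k, :] = dp
            k_best = np.argmin(cand, axis=0)
            dp = cand[k_best, np.arange(n_rad)] + cost[a]
            back[a] = np.arange(n_rad) - deltas[k_best]
        # closure: transition from the last angle bin back to the start radius
        lo, hi = max(0, r0 - J), min(n_rad, r0 + J + 1)
        closing = dp[lo:hi] + lam * np.abs(np.arange(lo, hi) - r0)
        r_last = lo + int(np.argmin(closing))
        total = float(closing[int(np.argmin(closing))])
        if total < best_total:
            path = np.zeros(n_ang, dtype=int)
            path[-1] = r_last
            for a in range(n_ang - 1, 0, -1):
                path[a - 1] = back[a, path[a]]
            best_total, best_path = total, path

    radii_mm = (best_path + 0.5) * image.mm_per_radius_bin  # bin centers
    return Contour(radius_mm=radii_mm)


def trace_path_cost(
    image: PolarImage,
    smoothness_max_jump_bins: int = 2,
    curvature_penalty: float = 0.05,
    start_radius_stride: int = 1,
) -> float:
    """Total cost of the optimal closed path (for verification against
    exhaustive enumeration on small grids)."""
    cost = _radial_edge_cost(image)
    contour = trace_lumen(
        image,
        smoothness_max_jump_bins=smoothness_max_jump_bins,
        curvature_penalty=curvature_penalty,
        start_radius_stride=start_radius_stride,
    )
    path = np.round(contour.radius_mm / image.mm_per_radius_bin - 0.5).astype(int)
    node = cost[np.arange(cost.shape[0]), path].sum()
    jumps = np.abs(np.diff(np.append(path, path[0])))
    return float(node + curvature_penalty * jumps.sum())


def gate_frames(
    frame_times_s: Sequence[float],
    r_wave_times_s: Sequence[float],
    end_diastole_offset_s: float = 0.0,
) -> np.ndarray:
    """Select one frame per heartbeat, nearest to (R-wave time - offset).

    Duplicate selections (two beats landing on the same frame) are dropped;
    order follows the R-wave sequence.
    """
    ft = np.asarray(frame_times_s, dtype=float)
    rt = np.asarray(r_wave_times_s, dtype=float)
    if ft.size == 0 or rt.size == 0:
        raise ValueError("frame and R-wave time sequences must be non-empty")
    if np.any(np.diff(ft) < 0) or np.any(np.diff(rt) < 0):
        raise ValueError("time sequences must be sorted")
    targets = rt - end_diastole_offset_s
    pos = np.searchsorted(ft, targets)
    pos = np.clip(pos, 1, ft.size - 1)
    left, right = pos - 1, pos
    choose_left = np.abs(targets - ft[left]) <= np.abs(ft[right] - targets)
    idx = np.where(choose_left, left, right)
    idx = np.where(targets <= ft[0], 0, idx)
    idx = np.where(targets >= ft[-1], ft.size - 1, idx)
    _, first = np.unique(idx, return_index=True)
    return idx[np.sort(first)]


def map_pullback(
    gated: Sequence[int],
    frame_rate_per_s: float,
    pullback_speed_mm_per_s: float,
) -> PullbackMap:
    """Map gated frame indices to arc length for a uniform motorized pullback.

    arclength(frame k) = k * speed / rate, re-zeroed at the first gated frame.
    """
    if frame_rate_per_s <= 0 or pullback_speed_mm_per_s <= 0:
        raise ValueError("frame rate and pullback speed must be > 0")
    g = np.sort(np.asarray(gated, dtype=int))
    if g.size == 0:
        raise ValueError("no gated frames")
    s = g * pullback_speed_mm_per_s / frame_rate_per_s
    return PullbackMap(
        gated_frames=g,
        arclength_mm=s - s[0],
        pullback_speed_mm_per_s=float(pullback_speed_mm_per_s),
        frame_rate_per_s=float(frame_rate_per_s),
    )


def contours_to_profile(contours: List[Contour], pullback: PullbackMap) -> VesselProfile:
    """Assemble the lumen area profile A(s) from per-gated-frame contours.

    Frames are sorted into canonical (increasing arc-length) order, so a
    reversed acquisition yields an identical profile.
    """
    if len(contours) != pullback.gated_frames.size:
        raise ValueError(
            f"{len(contours)} contours for {pullback.gated_frames.size} gated frames"
        )
    order = np.argsort(pullback.arclength_mm, kind="stable")
    s = pullback.arclength_mm[order]
    areas = np.array([contours[i].area_mm2 for i in order])
    return VesselProfile(arclength_mm=s, lumen_area_mm2=areas)
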