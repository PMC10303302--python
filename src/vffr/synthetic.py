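"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators, all pure functions of (spec, seed):

* ``make_vessel`` — parametric stenosed lumen profiles (tapered tube times
  unit-peak narrowing bumps) with analytic MLA/DS% ground truth;
* ``make_polar_stack`` — polar cross-section image stacks (dark lumen, bright
  wall, Gaussian noise) standing in for an IVUS pullback acquisition, with
  the true contours returned alongside;
* ``simulate_ecg`` — R-wave trains at a given heart rate with truncated
  Gaussian beat-to-beat jitter;
* ``simulate_cohort`` — a trivariate (IVUS-index, CT-index, invasive FFR)
  Gaussian cohort with configurable means, SDs and pairwise correlations,
  truncated by rejection into the physiological range (0.2, 1.0].  The
  defaults are the study conditions this package evaluates under: means
  0.72/0.74/0.73, SDs 0.10/0.09/0.09 and pairwise correlations
  r(ivus,ffr)=0.7913, r(ct,ffr)=0.6296, r(ivus,ct)=0.7323.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .geometry import StenosisMetrics, VesselProfile
from .segmentation import Contour, PolarImage
from .diagnostics import PairedCohort

__all__ = [
    "StenosisSpec",
    "VesselSpec",
    "CohortSpec",
    "PolarStack",
    "make_vessel",
    "make_polar_stack",
    "simulate_ecg",
    "simulate_cohort",
]


@dataclass(frozen=True)
class StenosisSpec:
    """One focal narrowing: unit-peak bump scaled to the target DS%."""

    center_mm: float
    length_mm: float
    ds_pct: float
    shape: str = "cosine"  # {"cosine", "gaussian"}

    def __post_init__(self) -> None:
        if not (0.0 <= self.ds_pct <= 95.0):
            raise ValueError("ds_pct must lie in [0, 95]")
        if self.length_mm <= 0:
            raise ValueError("stenosis length must be > 0")
        if self.shape not in ("cosine", "gaussian"):
            raise ValueError(f"unknown bump shape: {self.shape!r}")

    @property
    def interval(self) -> Tuple[float, float]:
        return (self.center_mm - self.length_mm / 2, self.center_mm + self.length_mm / 2)

    def bump(self, s: np.ndarray) -> np.ndarray:
        """Unit-peak narrowing profile, supported on the stenosis interval.

        cosine: 0.5*(1 + cos(2*pi*x)) on |x| <= 1/2 (raised-cosine);
        gaussian: exp(-x^2 / (2*(1/6)^2)) truncated at |x| = 1/2,
        with x = (s - center)/length.
        """
        x = (s - self.center_mm) / self.length_mm
        inside = np.abs(x) <= 0.5
        if self.shape == "cosine":
            b = 0.5 * (1.0 + np.cos(2.0 * np.pi * x))
        else:
            b = np.exp(-(x * x) / (2.0 * (1.0 / 6.0) ** 2))
        return np.where(inside, b, 0.0)


@dataclass(frozen=True)
class VesselSpec:
    """Parametric stenosed coronary vessel.

    Defaults emulate a typical study vessel: a 60 mm segment with a 3.0 mm
    proximal reference diameter and a mild physiological taper.
    """

    length_mm: float = 60.0
    proximal_diameter_mm: float = 3.0
    taper_mm_per_mm: float = -0.005
    stenoses: Tuple[StenosisSpec, ...] = ()
    eem_margin_pct: float = 20.0

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.proximal_diameter_mm <= 0:
            raise ValueError("length and proximal diameter must be > 0")
        sten = tuple(self.stenoses)
        for st in sten:
            lo, hi = st.interval
            if lo < 0 or hi > self.length_mm:
                raise ValueError("stenosis interval extends outside the vessel")
        ivals = sorted(st.interval for st in sten)
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if b0 < a1:
                raise ValueError("overlapping stenoses")
        object.__setattr__(self, "stenoses", sten)

    def reference_diameter(self, s: np.ndarray) -> np.ndarray:
        return self.proximal_diameter_mm + self.taper_mm_per_mm * np.asarray(s, dtype=float)

    def diameter(self, s: np.ndarray) -> np.ndarray:
        d = self.reference_diameter(s)
        for st in self.stenoses:
            d = d * (1.0 - st.ds_pct / 100.0 * st.bump(np.asarray(s, dtype=float)))
        return d


def make_vessel(spec: VesselSpec, step_mm: float = 0.1) -> Tuple[VesselProfile, StenosisMetrics]:
    """Generate a vessel profile and its analytic ground-truth lesion metrics.

    The returned metrics describe the deepest stenosis (or the whole healthy
    vessel when none): the true MLA/MLD at the bump center, the generating
    taper line as the reference, and the exact DS%/AS% by construction.
    """
    n = int(np.floor(spec.length_mm / step_mm)) + 1
    s = np.linspace(0.0, spec.length_mm, n)
    d = spec.diameter(s)
    if np.any(d <= 0):
        raise ValueError("spec produces non-positive diameters")
    area = np.pi * d * d / 4.0
    d_eem = spec.reference_diameter(s) * (1.0 + spec.eem_margin_pct / 100.0)
    eem = np.pi * d_eem * d_eem / 4.0
    profile = VesselProfile(s, area, np.maximum(eem, area))

    if spec.stenoses:
        worst = max(spec.stenoses, key=lambda st: st.ds_pct)
        c = worst.center_mm
        rvd = float(spec.reference_diameter(np.array([c]))[0])
        mld = rvd * (1.0 - worst.ds_pct / 100.0)
        mla = np.pi * mld * mld / 4.0
        rva = np.pi * rvd * rvd / 4.0
        ds = worst.ds_pct
        as_ = 100.0 * (1.0 - (1.0 - ds / 100.0) ** 2)
        lo, hi = worst.interval
        eem_c = np.pi * (rvd * (1 + spec.eem_margin_pct / 100.0)) ** 2 / 4.0
        pb = 100.0 * (eem_c - mla) / eem_c
    else:
        mla_idx = int(np.argmin(area))
        mla, mld = float(area[mla_idx]), float(d[mla_idx])
        rvd, rva = mld, float(area[mla_idx])
        ds = as_ = 0.0
        c, lo, hi = float(s[mla_idx]), 0.0, spec.length_mm
        pb = 100.0 * (eem[mla_idx] - mla) / eem[mla_idx]
    truth = StenosisMetrics(
        mla_mm2=float(mla),
        mld_mm=float(mld),
        rvd_mm=float(rvd),
        rva_mm2=float(rva),
        ds_pct=float(ds),
        as_pct=float(as_),
        mla_position_mm=float(c),
        lesion_start_mm=float(lo),
        lesion_end_mm=float(hi),
        plaque_burden_pct=float(pb),
    )
    return profile, truth


@dataclass(frozen=True)
class PolarStack:
    """A generated polar pullback: frames, timing, and ground-truth contours."""

    frames: Tuple[PolarImage, ...]
    frame_times_s: np.ndarray
    truth_contours: Tuple[Contour, ...]
    pullback_speed_mm_per_s: float
    frame_rate_per_s: float
    mm_per_radius_bin: float


def make_polar_stack(
    profile: VesselProfile,
    pullback_speed_mm_per_s: float = 0.5,
    frame_rate_per_s: float = 30.0,
    noise_sd: float = 0.05,
    edge_contrast: float = 1.0,
    seed: Optional[int] = None,
    n_angle_bins: int = 64,
    n_radius_bins: int = 96,
    edge_width_mm: float = 0.05,
) -> PolarStack:
    """Render a polar image stack for a uniform pullback through ``profile``.

    Each frame shows a circular lumen of the local radius: intensity ramps
    from 0 (lumen) to ``edge_contrast`` (wall) across a sigmoid edge of width
    ``edge_width_mm``, plus i.i.d. Gaussian noise of SD ``noise_sd``.
    """
    if edge_contrast <= 0:
        raise ValueError("edge_contrast must be > 0")
    rng = np.random.default_rng(seed)
    L = profile.length_mm
    n_frames = int(np.floor(L / pullback_speed_mm_per_s * frame_rate_per_s)) + 1
    times = np.arange(n_frames) / frame_rate_per_s
    s_frames = np.minimum(times * pullback_speed_mm_per_s, L)
    r_max_mm = 1.25 * float(profile.diameter_mm.max()) / 2.0
    mm_per_bin = r_max_mm / n_radius_bins
    r_centers = (np.arange(n_radius_bins) + 0.5) * mm_per_bin

    frames: List[PolarImage] = []
    contours: List[Contour] = []
    for s in s_frames:
        r_lumen = float(profile.diameter_at(s)) / 2.0
        base = edge_contrast / (1.0 + np.exp(-(r_centers - r_lumen) / edge_width_mm))
        img = np.tile(base, (n_angle_bins, 1))
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames.append(PolarImage(intensity=img, mm_per_radius_bin=mm_per_bin))
        contours.append(Contour(radius_mm=np.full(n_angle_bins, r_lumen)))
    return PolarStack(
        frames=tuple(frames),
        frame_times_s=times,
        truth_contours=tuple(contours),
        pullback_speed_mm_per_s=float(pullback_speed_mm_per_s),
        frame_rate_per_s=float(frame_rate_per_s),
        mm_per_radius_bin=mm_per_bin,
    )


def simulate_ecg(
    duration_s: float,
    heart_rate_bpm: float = 60.0,
    jitter_sd_s: float = 0.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """R-wave times at 60/HR spacing plus truncated (3 sigma) Gaussian jitter."""
    if heart_rate_bpm <= 0:
        raise ValueError("heart rate must be > 0")
    period = 60.0 / heart_rate_bpm
    base = np.arange(0.0, duration_s, period)
    if jitter_sd_s > 0:
        rng = np.random.default_rng(seed)
        j = rng.normal(0.0, jitter_sd_s, size=base.size)
        j = np.clip(j, -3.0 * jitter_sd_s, 3.0 * jitter_sd_s)
        base = np.sort(base + j)
        base = base[(base >= 0) & (base <= duration_s)]
    return base


@dataclass(frozen=True)
class CohortSpec:
    """Trivariate (IVUS-index, CT-index, invasive FFR) cohort parameters."""

    n_vessels: int = 36
    means: Tuple[float, float, float] = (0.72, 0.74, 0.73)  # (ivus, ct, ffr)
    sds: Tuple[float, float, float] = (0.10, 0.09, 0.09)
    r_ivus_ffr: float = 0.7913
    r_ct_ffr: float = 0.6296
    r_ivus_ct: float = 0.7323
    seed: Optional[int] = None
    bounds: Tuple[float, float] = (0.2, 1.0)
    round_decimals: Optional[int] = None  # clinical 2-decimal rounding, off by default

    def correlation_matrix(self) -> np.ndarray:
        return np.array(
            [
                [1.0, self.r_ivus_ct, self.r_ivus_ffr],
                [self.r_ivus_ct, 1.0, self.r_ct_ffr],
                [self.r_ivus_ffr, self.r_ct_ffr, 1.0],
            ]
        )


def simulate_cohort(spec: CohortSpec) -> Tuple[PairedCohort, PairedCohort, pd.DataFrame]:
    """Draw a correlated trivariate-Gaussian cohort, truncated by rejection.

    Draws are resampled (not clipped) until all three components fall in
    ``bounds`` = (0.2, 1.0], keeping the correlation structure interpretable.
    Returns the two paired cohorts (ivus-vs-FFR, ct-vs-FFR) sharing the FFR
    column, plus the full table.
    """
    corr = spec.correlation_matrix()
    eig = np.linalg.eigvalsh(corr)
    if eig.min() <= 0:
        raise ValueError(
            f"correlation matrix is not positive definite (smallest eigenvalue {eig.min():.4g})"
        )
    sds = np.asarray(spec.sds, dtype=float)
    if np.any(sds <= 0):
        raise ValueError("SDs must be > 0")
    cov = corr * np.outer(sds, sds)
    chol = np.linalg.cholesky(cov)
    means = np.asarray(spec.means, dtype=float)
    lo, hi = spec.bounds

    rng = np.random.default_rng(spec.seed)
    rows = []
    n_needed = spec.n_vessels
    while n_needed > 0:
        z = rng.standard_normal((max(n_needed * 2, 64), 3))
        draws = means + z @ chol.T
        ok = np.all((draws > lo) & (draws <= hi), axis=1)
        rows.append(draws[ok][:n_needed])
        n_needed -= rows[-1].shape[0]
    data = np.vstack(rows)
    if spec.round_decimals is not None:
        data = np.round(data, spec.round_decimals)
        data = np.clip(data, lo + 10.0**-spec.round_decimals, hi)
    ids = np.array([f"V{i:04d}" for i in range(spec.n_vessels)])
    df = pd.DataFrame(
        {"vessel_id": ids, "index_ivus": data[:, 0], "index_ct": data[:, 1], "ffr": data[:, 2]}
    )
    cohort_ivus = PairedCohort(ids, data[:, 0], data[:, 2])
    cohort_ct = PairedCohort(ids, data[:, 1], data[:, 2])
    return cohort_ivus, cohort_ct, df
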