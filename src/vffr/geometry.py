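"""Vessel lumen geometry: arc-length profiles and anatomical stenosis metrics.

The geometric substrate for everything downstream is a one-dimensional lumen
profile A(s): cross-sectional lumen area (mm^2) as a function of centerline
arc-length s (mm, 0 at the proximal end, increasing distally).  Diameters are
circular-equivalent, d(s) = 2*sqrt(A(s)/pi), since the cross-sectional area is
the primitive intravascular measurement.

The anatomical quantities computed here are the standard catheter-lab lesion
descriptors: minimum lumen area/diameter (MLA/MLD), reference vessel
diameter/area (RVD/RVA) from a linear fit of the healthy-segment diameter
taper, percent diameter and area stenosis (DS%, AS%), and plaque burden where
an external elastic membrane (EEM) profile is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "VesselProfile",
    "ReferenceLine",
    "StenosisMetrics",
    "ProfileValidationError",
    "resample_profile",
    "fit_reference",
    "detect_lesion",
    "stenosis_metrics",
]


class ProfileValidationError(ValueError):
    """Raised when a vessel profile violates its geometric invariants."""


@dataclass(frozen=True)
class VesselProfile:
    """Lumen (and optional EEM) area along the vessel centerline.

    Parameters
    ----------
    arclength_mm
        Monotone non-decreasing arc-length samples; re-zeroed so the first
        sample is 0.  Duplicate positions are dropped (first occurrence kept).
    lumen_area_mm2
        Positive lumen areas, one per arc-length sample.
    eem_area_mm2
        Optional external-elastic-membrane areas, elementwise >= lumen area.
    """

    arclength_mm: np.ndarray
    lumen_area_mm2: np.ndarray
    eem_area_mm2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        s = np.asarray(self.arclength_mm, dtype=float)
        a = np.asarray(self.lumen_area_mm2, dtype=float)
        if s.ndim != 1 or a.ndim != 1 or s.size != a.size:
            raise ProfileValidationError("arclength and area must be 1-D of equal length")
        if s.size < 2:
            raise ProfileValidationError("a profile needs at least 2 samples")
        if np.any(np.diff(s) < 0):
            raise ProfileValidationError("arclength must be monotone non-decreasing")
        e = self.eem_area_mm2
        if e is not None:
            e = np.asarray(e, dtype=float)
            if e.shape != a.shape:
                raise ProfileValidationError("eem profile length mismatch")
        # deduplicate identical arc-length positions, keep first occurrence
        keep = np.concatenate([[True], np.diff(s) > 0])
        s, a = s[keep], a[keep]
        if e is not None:
            e = e[keep]
        if s.size < 2:
            raise ProfileValidationError("fewer than 2 distinct arc-length samples")
        if not np.all(np.isfinite(a)) or np.any(a <= 0):
            raise ProfileValidationError("lumen areas must be finite and > 0")
        if e is not None:
            if not np.all(np.isfinite(e)) or np.any(e < a - 1e-12):
                raise ProfileValidationError("EEM area must be finite and >= lumen area")
        s = s - s[0]
        object.__setattr__(self, "arclength_mm", s)
        object.__setattr__(self, "lumen_area_mm2", a)
        object.__setattr__(self, "eem_area_mm2", e)

    @property
    def length_mm(self) -> float:
        return float(self.arclength_mm[-1])

    @property
    def n_samples(self) -> int:
        return int(self.arclength_mm.size)

    @property
    def diameter_mm(self) -> np.ndarray:
        """Circular-equivalent lumen diameter, d = 2*sqrt(A/pi)."""
        return 2.0 * np.sqrt(self.lumen_area_mm2 / np.pi)

    def area_at(self, s_mm) -> np.ndarray:
        """Linearly interpolated lumen area at arbitrary arc-length positions."""
        return np.interp(s_mm, self.arclength_mm, self.lumen_area_mm2)

    def diameter_at(self, s_mm) -> np.ndarray:
        return 2.0 * np.sqrt(np.asarray(self.area_at(s_mm)) / np.pi)


@dataclass(frozen=True)
class ReferenceLine:
    """Healthy-vessel diameter taper, d_ref(s) = intercept + slope * s.

    Fitted by ordinary least squares to the diameter profile outside the
    lesion; ``fit_mask`` records which samples entered the fit.
    """

    slope_mm_per_mm: float
    intercept_mm: float
    fit_mask: np.ndarray = field(repr=False)

    def diameter_at(self, s_mm) -> np.ndarray:
        return self.intercept_mm + self.slope_mm_per_mm * np.asarray(s_mm, dtype=float)

    def area_at(self, s_mm) -> np.ndarray:
        d = self.diameter_at(s_mm)
        return np.pi * d * d / 4.0


@dataclass(frozen=True)
class StenosisMetrics:
    """Anatomical lesion severity at the minimum-lumen-area cross-section."""

    mla_mm2: float
    mld_mm: float
    rvd_mm: float
    rva_mm2: float
    ds_pct: float
    as_pct: float
    mla_position_mm: float
    lesion_start_mm: float
    lesion_end_mm: float
    plaque_burden_pct: Optional[float] = None

    def as_dict(self) -> dict:
        d = {
            "mla_mm2": self.mla_mm2,
            "mld_mm": self.mld_mm,
            "rvd_mm": self.rvd_mm,
            "rva_mm2": self.rva_mm2,
            "ds_pct": self.ds_pct,
            "as_pct": self.as_pct,
            "mla_position_mm": self.mla_position_mm,
            "lesion_start_mm": self.lesion_start_mm,
            "lesion_end_mm": self.lesion_end_mm,
        }
        if self.plaque_burden_pct is not None:
            d["plaque_burden_pct"] = self.plaque_burden_pct
        return d


def resample_profile(profile: VesselProfile, step_mm: float) -> VesselProfile:
    """Resample a profile onto a uniform arc-length grid covering [0, L].

    Areas are linearly interpolated; both endpoints are preserved (the distal
    endpoint is appended when L is not a multiple of ``step_mm``).
    """
    if not step_mm > 0:
        raise ValueError("step_mm must be > 0")
    L = profile.length_mm
    grid = np.arange(0.0, L, step_mm)
    if L - grid[-1] > 1e-9:
        grid = np.append(grid, L)
    else:
        grid[-1] = L
    a = np.interp(grid, profile.arclength_mm, profile.lumen_area_mm2)
    e = None
    if profile.eem_area_mm2 is not None:
        e = np.interp(grid, profile.arclength_mm, profile.eem_area_mm2)
        e = np.maximum(e, a)  # guard interpolation round-off
    return VesselProfile(grid, a, e)


def fit_reference(
    profile: VesselProfile,
    lesion_exclusion: Optional[Tuple[float, float]] = None,
) -> ReferenceLine:
    """Least-squares line through the diameter profile of the healthy segments.

    Parameters
    ----------
    lesion_exclusion
        Optional (start_mm, end_mm) interval excluded from the fit, so the
        reference taper is estimated from presumed-healthy vessel only.
    """
    s = profile.arclength_mm
    d = profile.diameter_mm
    mask = np.ones(s.size, dtype=bool)
    if lesion_exclusion is not None:
        lo, hi = lesion_exclusion
        mask &= ~((s >= lo) & (s <= hi))
    if mask.sum() < 2:
        raise ValueError("fewer than 2 samples outside the excluded interval")
    slope, intercept = np.polyfit(s[mask], d[mask], 1)
    return ReferenceLine(float(slope), float(intercept), fit_mask=mask)


def detect_lesion(
    profile: VesselProfile,
    reference: ReferenceLine,
    ds_threshold_pct: float = 20.0,
) -> Optional[Tuple[float, float]]:
    """Delimit the lesion as the contiguous run of pointwise DS% above threshold.

    The pointwise diameter stenosis DS%(s) = 100*(1 - d(s)/d_ref(s)) is
    computed against the reference line; the returned interval is the maximal
    contiguous run exceeding ``ds_threshold_pct`` that contains the deepest
    narrowing (maximal DS%).  Returns ``None`` when no sample exceeds the
    threshold.
    """
    s = profile.arclength_mm
    d_ref = reference.diameter_at(s)
    if np.any(d_ref <= 0):
        raise ValueError("reference line yields non-positive diameter on the profile")
    ds = 100.0 * (1.0 - profile.diameter_mm / d_ref)
    above = ds > ds_threshold_pct
    if not above.any():
        return None
    anchor = int(np.argmax(ds))
    if not above[anchor]:  # cannot happen with max ds > threshold, kept defensive
        return None
    i = anchor
    while i > 0 and above[i - 1]:
        i -= 1
    j = anchor
    while j < s.size - 1 and above[j + 1]:
        j += 1
    return float(s[i]), float(s[j])


def stenosis_metrics(
    profile: VesselProfile,
    reference: ReferenceLine,
    lesion: Optional[Tuple[float, float]] = None,
) -> StenosisMetrics:
    """Compute MLA/MLD/RVD/RVA, DS%, AS% and plaque burden for a lesion.

    The MLA is the global lumen-area minimum inside ``lesion`` (whole vessel
    when no lesion interval is given); the reference diameter RVD is the
    fitted taper line evaluated at the MLA position.  A reference fit that
    falls below the measured minimum diameter clamps DS% (and AS%) at 0 with
    a warning, signalling a bad reference fit rather than a healthy vessel.
    """
    s = profile.arclength_mm
    a = profile.lumen_area_mm2
    if lesion is None:
        sel = np.ones(s.size, dtype=bool)
        lesion_start, lesion_end = float(s[0]), float(s[-1])
    else:
        lesion_start, lesion_end = float(lesion[0]), float(lesion[1])
        sel = (s >= lesion_start) & (s <= lesion_end)
        if not sel.any():
            raise ValueError("lesion interval contains no profile samples")
    idx = np.flatnonzero(sel)[np.argmin(a[sel])]
    mla = float(a[idx])
    mld = 2.0 * np.sqrt(mla / np.pi)
    pos = float(s[idx])
    rvd = float(reference.diameter_at(pos))
    rva = np.pi * rvd * rvd / 4.0
    if rvd < mld * (1.0 - 1e-12):
        warnings.warn(
            "reference diameter <= minimum lumen diameter; DS% clamped at 0 "
            "(check the reference fit / lesion exclusion)",
            RuntimeWarning,
            stacklevel=2,
        )
        ds = 0.0
        as_ = max(0.0, 100.0 * (1.0 - mla / rva))
    else:
        ds = max(0.0, 100.0 * (1.0 - mld / rvd))
        as_ = max(0.0, 100.0 * (1.0 - mla / rva))
    pb = None
    if profile.eem_area_mm2 is not None:
        eem = float(profile.eem_area_mm2[idx])
        pb = 100.0 * (eem - mla) / eem
    return StenosisMetrics(
        mla_mm2=mla,
        mld_mm=float(mld),
        rvd_mm=rvd,
        rva_mm2=float(rva),
        ds_pct=float(ds),
        as_pct=float(as_),
        mla_position_mm=pos,
        lesion_start_mm=lesion_start,
        lesion_end_mm=lesion_end,
        plaque_burden_pct=pb,
    )
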