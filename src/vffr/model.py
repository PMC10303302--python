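"""Model/Results facade over the vFFR pipeline and the evaluation layer.

Two entry points, in the fit/results idiom of the statistical-modelling
ecosystem:

* :class:`VirtualFFR` — a mechanistic model bound to one vessel's lumen
  profile.  ``fit()`` runs reference fitting, lesion delimitation, hyperemic
  flow, the chosen pressure-drop engine and the FFR pullback, returning a
  :class:`VirtualFFRResults` with the stenosis metrics, the pullback curve
  and a ``summary()`` table.

* :class:`DiagnosticComparison` — bound to a paired cohort table (two index
  columns plus invasive FFR).  ``fit()`` evaluates both indices against
  invasive FFR at the positivity cutoff and returns
  :class:`DiagnosticComparisonResults` whose ``summary()`` renders the
  side-by-side diagnostic-performance table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import diagnostics as dx
from . import geometry as geo
from . import hemodynamics as hemo

__all__ = [
    "VirtualFFR",
    "VirtualFFRResults",
    "DiagnosticComparison",
    "DiagnosticComparisonResults",
]


class VirtualFFR:
    """Virtual FFR model for a single unbranched coronary segment.

    Parameters
    ----------
    profile
        Lumen (and optional EEM) area profile.
    pa_mmhg
        Mean aortic pressure (default 90 mmHg).
    flow_mode, k_velocity_m_s_per_mm2, frame_transit, q_fixed_ml_s
        Hyperemic-flow specification (see :func:`vffr.hemodynamics.hyperemic_flow`).
    k_expansion
        Expansion (separation) energy-loss coefficient, default 1.0.
    blood
        Blood viscosity/density.
    step_mm
        Uniform resampling step applied before hemodynamics (default 0.1 mm).
    ds_threshold_pct
        Pointwise DS% threshold delimiting the lesion (default 20%).
    reference_segment_mm
        Optional (start, end) arc-length window restricting the reference fit
        to an explicitly healthy segment; by default the lesion interval from
        a first-pass fit is excluded and the fit repeated.
    """

    def __init__(
        self,
        profile: geo.VesselProfile,
        pa_mmhg: float = 90.0,
        flow_mode: str = "diameter_scaling",
        k_velocity_m_s_per_mm2: float = hemo.DEFAULT_K_VELOCITY,
        frame_transit: Optional[Tuple[float, float, float]] = None,
        q_fixed_ml_s: Optional[float] = None,
        k_expansion: float = 1.0,
        blood: hemo.BloodProperties = hemo.BloodProperties(),
        step_mm: float = 0.1,
        ds_threshold_pct: float = 20.0,
        reference_segment_mm: Optional[Tuple[float, float]] = None,
    ) -> None:
        self.profile = profile
        self.pa_mmhg = pa_mmhg
        self.flow_mode = flow_mode
        self.k_velocity = k_velocity_m_s_per_mm2
        self.frame_transit = frame_transit
        self.q_fixed_ml_s = q_fixed_ml_s
        self.k_expansion = k_expansion
        self.blood = blood
        self.step_mm = step_mm
        self.ds_threshold_pct = ds_threshold_pct
        self.reference_segment_mm = reference_segment_mm

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "VirtualFFR":
        """Build from a table with columns s_mm, lumen_area_mm2[, eem_area_mm2]."""
        from .io import profile_from_dataframe

        return cls(profile_from_dataframe(df), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "VirtualFFR":
        from .io import read_vessel_csv

        return cls(read_vessel_csv(path), **kwargs)

    def fit(self, engine: str = "reduced_order", n_cells: int = 400) -> "VirtualFFRResults":
        prof = geo.resample_profile(self.profile, self.step_mm)
        if self.reference_segment_mm is not None:
            lo, hi = self.reference_segment_mm
            s = prof.arclength_mm
            keep = (s >= lo) & (s <= hi)
            if keep.sum() < 2:
                raise ValueError("reference segment covers fewer than 2 samples")
            slope, intercept = np.polyfit(s[keep], prof.diameter_mm[keep], 1)
            reference = geo.ReferenceLine(float(slope), float(intercept), fit_mask=keep)
            lesion = geo.detect_lesion(prof, reference, self.ds_threshold_pct)
        else:
            first_pass = geo.fit_reference(prof)
            lesion = geo.detect_lesion(prof, first_pass, self.ds_threshold_pct)
            reference = geo.fit_reference(prof, lesion_exclusion=lesion)
            lesion = geo.detect_lesion(prof, reference, self.ds_threshold_pct)
        metrics = geo.stenosis_metrics(prof, reference, lesion)
        flow = hemo.hyperemic_flow(
            prof,
            reference,
            mode=self.flow_mode,
            k_velocity_m_s_per_mm2=self.k_velocity,
            frame_transit=self.frame_transit,
            q_fixed_ml_s=self.q_fixed_ml_s,
        )
        curve = hemo.compute_vffr(
            prof,
            reference=reference,
            flow=flow,
            blood=self.blood,
            pa_mmhg=self.pa_mmhg,
            engine=engine,
            k_expansion=self.k_expansion,
            step_mm=self.step_mm,
            n_cells=n_cells,
        )
        return VirtualFFRResults(
            model=self,
            reference=reference,
            lesion=lesion,
            stenosis=metrics,
            flow=flow,
            pullback=curve,
            engine=engine,
        )


@dataclass
class VirtualFFRResults:
    """Fitted vFFR pipeline outputs for one vessel."""

    model: VirtualFFR
    reference: geo.ReferenceLine
    lesion: Optional[Tuple[float, float]]
    stenosis: geo.StenosisMetrics
    flow: hemo.FlowState
    pullback: hemo.PullbackCurve
    engine: str

    @property
    def ffr_distal(self) -> float:
        return self.pullback.ffr_distal

    def to_dict(self) -> dict:
        d = self.stenosis.as_dict()
        d.update(
            ffr_distal=self.ffr_distal,
            pa_mmhg=self.pullback.pa_mmhg,
            q_ml_s=self.flow.q_ml_s,
            v_ref_m_s=self.flow.v_ref_m_s,
            flow_source=self.flow.source,
            engine=self.engine,
            reference_slope_mm_per_mm=self.reference.slope_mm_per_mm,
            reference_intercept_mm=self.reference.intercept_mm,
        )
        return d

    def summary(self) -> str:
        m = self.stenosis
        lesion = (
            f"{m.lesion_start_mm:.1f}–{m.lesion_end_mm:.1f} mm"
            if self.lesion is not None
            else "none detected"
        )
        lines = [
            "Virtual FFR results",
            "===================",
            f"engine:             {self.engine}",
            f"vessel length:      {self.model.profile.length_mm:.1f} mm",
            f"reference diameter: {self.reference.intercept_mm:.2f} mm proximal, "
            f"slope {self.reference.slope_mm_per_mm:+.4f} mm/mm",
            f"lesion:             {lesion}",
            f"MLA:                {m.mla_mm2:.2f} mm^2 at {m.mla_position_mm:.1f} mm",
            f"MLD / RVD:          {m.mld_mm:.2f} / {m.rvd_mm:.2f} mm",
            f"DS% / AS%:          {m.ds_pct:.1f} / {m.as_pct:.1f}",
        ]
        if m.plaque_burden_pct is not None:
            lines.append(f"plaque burden:      {m.plaque_burden_pct:.1f} %")
        lines += [
            f"hyperemic flow:     {self.flow.q_ml_s:.2f} mL/s "
            f"(v_ref {self.flow.v_ref_m_s:.2f} m/s, {self.flow.source})",
            f"Pa:                 {self.pullback.pa_mmhg:.0f} mmHg",
            f"FFR (distal):       {self.ffr_distal:.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        return self.pullback.plot(ax=ax)


class DiagnosticComparison:
    """Two-method diagnostic evaluation against invasive FFR.

    Built from a table with columns ``vessel_id, index_ct, index_ivus, ffr``
    (or any two index columns named explicitly).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        col_a: str = "index_ivus",
        col_b: str = "index_ct",
        label_a: str = "AccuFFRivus-like",
        label_b: str = "AccuFFRct-like",
        cutoff: float = 0.80,
    ) -> None:
        self.data = data
        self.col_a, self.col_b = col_a, col_b
        self.label_a, self.label_b = label_a, label_b
        self.cutoff = cutoff

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DiagnosticComparison":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> "DiagnosticComparisonResults":
        a = dx.PairedCohort.from_dataframe(self.data, self.col_a)
        b = dx.PairedCohort.from_dataframe(self.data, self.col_b)
        report = dx.compare_methods(
            a, b, cutoff=self.cutoff, label_a=self.label_a, label_b=self.label_b
        )
        return DiagnosticComparisonResults(model=self, report=report)


@dataclass
class DiagnosticComparisonResults:
    model: DiagnosticComparison
    report: dx.MethodComparisonReport

    def summary(self) -> str:
        return self.report.to_markdown()

    def to_dict(self) -> dict:
        return self.report.as_dict()

    def plot_bland_altman(self, which: str = "a", ax=None):
        """Bland–Altman plot of one index against invasive FFR."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.data
        col = self.model.col_a if which == "a" else self.model.col_b
        agr = self.report.agreement_a if which == "a" else self.report.agreement_b
        x = df[col].to_numpy()
        y = df["ffr"].to_numpy()
        ax.scatter((x + y) / 2, x - y, s=14)
        for val, ls in ((agr.mean_diff, "-"), (agr.loa_low, "--"), (agr.loa_high, "--")):
            ax.axhline(val, ls=ls, color="0.4", lw=0.9)
        ax.set_xlabel("mean of methods")
        ax.set_ylabel("difference (index − FFR)")
        return ax
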