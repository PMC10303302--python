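"""File formats, run configuration and provenance.

All tabular interchange is plain CSV (comma separator, '.' decimal, UTF-8,
header row required):

* vessel profile:  ``s_mm,lumen_area_mm2[,eem_area_mm2]``
* pullback curve:  ``s_mm,ffr,cum_drop_mmHg,viscous_mmHg,expansion_mmHg``
* paired cohort:   ``vessel_id,index_ct,index_ivus,ffr``
* contours:        ``frame,angle_bin,radius_mm``

Reports are emitted as JSON plus a Markdown table; every CLI run attaches a
provenance block (package version, UTC timestamp, config hash, seed) that
suffices to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from typing import List, Optional

import numpy as np
import pandas as pd

from .geometry import VesselProfile
from .hemodynamics import PullbackCurve
from .segmentation import Contour


class InputFormatError(ValueError):
    """A CSV/JSON input does not match its documented format."""


def profile_from_dataframe(df: pd.DataFrame) -> VesselProfile:
    for col in ("s_mm", "lumen_area_mm2"):
        if col not in df.columns:
            raise InputFormatError(f"vessel CSV is missing required column {col!r}")
    bad = df.index[df[["s_mm", "lumen_area_mm2"]].isna().any(axis=1)]
    if len(bad):
        raise InputFormatError(f"vessel CSV has missing values at row {int(bad[0]) + 2}")
    eem = df["eem_area_mm2"].to_numpy() if "eem_area_mm2" in df.columns else None
    return VesselProfile(df["s_mm"].to_numpy(), df["lumen_area_mm2"].to_numpy(), eem)


def read_vessel_csv(path) -> VesselProfile:
    return profile_from_dataframe(pd.read_csv(path))


def write_vessel_csv(path, profile: VesselProfile) -> None:
    cols = {"s_mm": profile.arclength_mm, "lumen_area_mm2": profile.lumen_area_mm2}
    if profile.eem_area_mm2 is not None:
        cols["eem_area_mm2"] = profile.eem_area_mm2
    pd.DataFrame(cols).to_csv(path, index=False)


def write_pullback_csv(path, curve: PullbackCurve) -> None:
    curve.to_dataframe().to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"vessel_id", "index_ct", "index_ivus", "ffr"} - set(df.columns)
    if missing:
        raise InputFormatError(f"cohort CSV is missing columns: {sorted(missing)}")
    bad = df.index[df[["index_ct", "index_ivus", "ffr"]].isna().any(axis=1)]
    if len(bad):
        raise InputFormatError(f"cohort CSV has missing values at row {int(bad[0]) + 2}")
    return df


def write_contours_csv(path, contours: List[Contour], frame_indices) -> None:
    rows = []
    for frame, c in zip(frame_indices, contours):
        for k, r in enumerate(c.radius_mm):
            rows.append((int(frame), k, float(r)))
    pd.DataFrame(rows, columns=["frame", "angle_bin", "radius_mm"]).to_csv(path, index=False)


@dataclasses.dataclass
class RunConfig:
    """JSON-round-trippable run configuration shared by the CLI subcommands."""

    seed: Optional[int] = None
    engine: str = "reduced_order"
    cutoff: float = 0.80
    ci_level: float = 0.95
    pa_mmhg: float = 90.0
    k_velocity_m_s_per_mm2: float = 0.35 / 9.0
    k_expansion: float = 1.0
    viscosity_pa_s: float = 0.0035
    density_kg_m3: float = 1060.0
    step_mm: float = 0.1
    n_cells: int = 400

    def __post_init__(self) -> None:
        for name in (
            "cutoff",
            "ci_level",
            "pa_mmhg",
            "k_velocity_m_s_per_mm2",
            "k_expansion",
            "viscosity_pa_s",
            "density_kg_m3",
            "step_mm",
        ):
            if getattr(self, name) <= 0:
                raise InputFormatError(f"config field {name!r} must be > 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        payload = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise InputFormatError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def provenance_block(config: RunConfig, extra: Optional[dict] = None) -> dict:
    from . import __version__

    block = {
        "package": "vffr",
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
    }
    if extra:
        block.update(extra)
    return block


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(path, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, cls=_NumpyJSONEncoder)
        fh.write("\n")
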