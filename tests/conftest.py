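import numpy as np
import pytest

from vffr import StenosisSpec, VesselProfile, VesselSpec, make_vessel


@pytest.fixture
def rng():
    return np.random.default_rng(20230627)


@pytest.fixture
def uniform_tube():
    """Straight 3.0 mm tube, 30 mm long, sampled every 0.5 mm."""
    s = np.arange(0.0, 30.0 + 1e-9, 0.5)
    area = np.full(s.size, np.pi * 1.5**2)
    return VesselProfile(s, area)


@pytest.fixture
def stenotic_vessel():
    """Tapered vessel with a single 60% DS cosine lesion, plus ground truth."""
    spec = VesselSpec(
        length_mm=60.0,
        proximal_diameter_mm=3.0,
        taper_mm_per_mm=-0.005,
        stenoses=(StenosisSpec(center_mm=30.0, length_mm=12.0, ds_pct=60.0),),
    )
    return make_vessel(spec, step_mm=0.1)


#: Fixed cross-verification flow (mL/s) keeping all library lesions in the
#: physical regime (drop < Pa) across the full DS 30-80% range.
LIBRARY_FLOW_ML_S = 1.0


def lesion_library():
    """Twenty generated lesions spanning DS% 30–80 and lengths 5–25 mm."""
    out = []
    ds_values = np.linspace(30.0, 80.0, 20)
    lengths = np.linspace(5.0, 25.0, 20)
    shapes = ["cosine", "gaussian"]
    for i, (ds, ln) in enumerate(zip(ds_values, lengths)):
        spec = VesselSpec(
            length_mm=60.0,
            proximal_diameter_mm=3.0,
            taper_mm_per_mm=-0.004,
            stenoses=(StenosisSpec(center_mm=30.0, length_mm=ln, ds_pct=ds, shape=shapes[i % 2]),),
        )
        out.append(make_vessel(spec, step_mm=0.1))
    return out
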