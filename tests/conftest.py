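import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cinequant.phantom import PhantomSpec, VolumeCurveModel, build_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coarse_spec():
    """UK-Biobank-like acquisition geometry with matched LV/RV stroke volumes."""
    return PhantomSpec(
        lv=VolumeCurveModel(edv=179.0, esv=77.0),
        rv=VolumeCurveModel(edv=196.0, esv=94.0),
        n_frames=50,
    )


@pytest.fixture(scope="session")
def coarse_study(coarse_spec):
    study, _ = build_phantom(coarse_spec)
    return study


@pytest.fixture(scope="session")
def coarse_truth(coarse_spec):
    _, truth = build_phantom(coarse_spec)
    return truth


@pytest.fixture(scope="session")
def fine_study_and_truth():
    """1 mm in-plane phantom with matched SAX/LAX resolution (few frames),
    for geometry-sensitive tests (alignment)."""
    spec = PhantomSpec(
        lv=VolumeCurveModel(edv=179.0, esv=77.0),
        rv=VolumeCurveModel(edv=196.0, esv=94.0),
        n_frames=3,
        voxel_size=(1.0, 1.0),
        lax_voxel=1.0,
    )
    return build_phantom(spec)
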