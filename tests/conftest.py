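import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dceperf.aif import AIFCurve
from dceperf.synthetic import PhantomConfig, TissueKineticParams, UptakeKineticParams, analytic_aif, generate_phantom

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

#: clinical-like frame grid: 70 frames, 5 s apart, bolus at frame 3
FRAME_TIMES_S = np.arange(70, dtype=float) * 5.0


@pytest.fixture(scope="session")
def frame_minutes():
    return FRAME_TIMES_S / 60.0


@pytest.fixture(scope="session")
def parker_aif(frame_minutes):
    cp = analytic_aif(frame_minutes, "parker", t0=frame_minutes[3])
    return AIFCurve(t=frame_minutes, cp=cp, source="analytic", n_voxels_used=0)


def small_phantom_config(**overrides) -> PhantomConfig:
    """A 16x16x6 phantom that keeps voxel-wise fitting tests fast."""
    kw = dict(shape=(16, 16, 6), noise_sigma=0.0, seed=99)
    kw.update(overrides)
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def small_tofts_phantom():
    """Noiseless Tofts phantom: (series, t10, truth, masks)."""
    return generate_phantom(small_phantom_config())


@pytest.fixture(scope="session")
def small_2cu_phantom():
    return generate_phantom(
        small_phantom_config(
            tumour_model="2cu",
            tumour_params=UptakeKineticParams(fp=0.6, vp=0.05, ps=0.05),
            tissue_model="2cu",
            tissue_params=UptakeKineticParams(fp=0.15, vp=0.02, ps=0.002),
        )
    )


@pytest.fixture(scope="session")
def tumour_truth() -> TissueKineticParams:
    return TissueKineticParams(0.25, 0.4, 0.05)
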