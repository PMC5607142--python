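import numpy as np
import pytest

from memgp import (
    ArcPhase,
    NoiseModel,
    PhantomSpec,
    PhasePaint,
    render_phantom,
)


def small_vesicle_spec(**overrides) -> PhantomSpec:
    """A fast 160x160 px vesicle phantom (1 um radius) for unit tests."""
    base = dict(
        image_size_px=(160, 160),
        vesicle_radius_nm=1000.0,
        phases=[ArcPhase("membrane", 0.0, 360.0, PhasePaint(channel_fraction_1=1.0))],
        psf_fwhm_nm=80.0,
        noise=NoiseModel.NONE,
        seed=0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def sted_vesicle():
    """Noise-free single-band STED vesicle with ground truth and ROIs."""
    return render_phantom(small_vesicle_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
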