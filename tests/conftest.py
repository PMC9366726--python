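import numpy as np
import pytest

from maseg.phantom import MABody, PhantomSpec, Vessel, generate_phantom


def reference_phantom_spec(**overrides) -> PhantomSpec:
    """Disk body of caliber 20 px with two width-5 parent vessels running to
    the frame border (construction BNR = 4); the module's worked reference."""
    kw = dict(
        frame_size=96,
        n_frames=60,
        ma_bodies=(MABody((48.0, 48.0), 20.0),),
        vessels=(
            Vessel(((48.0, 48.0), (48.0, 0.0)), 5.0, attached_to=0),
            Vessel(((48.0, 48.0), (48.0, 95.0)), 5.0, attached_to=0),
        ),
        flicker_amplitude=0.12,
        background_noise_sigma=0.05,
        seed=42,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def reference_bundle():
    return generate_phantom(reference_phantom_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
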