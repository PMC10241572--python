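import numpy as np
import pytest

from slicefuse.io import CTVolume
from slicefuse.phantom import PhantomSpec, generate_phantom_volume


@pytest.fixture
def small_volume() -> CTVolume:
    """A 5-slice 16x16 volume whose slice i is constant at stored value 100*i."""
    slices = np.stack([np.full((16, 16), 100 * i, dtype=np.int16) for i in range(5)])
    return CTVolume(
        patient_id="p0",
        slices=slices,
        rescale_slope=1.0,
        rescale_intercept=-1024.0,
        slice_positions=[3.0 * i for i in range(5)],
        slice_thickness=3.0,
    )


@pytest.fixture
def phantom_pair():
    """One tubular and one focal phantom volume with their annotations."""
    spec = PhantomSpec()
    vol_t, anns_t = generate_phantom_volume(
        "tubular", spec, np.random.default_rng(11), "tub0"
    )
    vol_f, anns_f = generate_phantom_volume(
        "focal", spec, np.random.default_rng(12), "foc0"
    )
    return (vol_t, anns_t), (vol_f, anns_f)
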