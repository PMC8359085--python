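import numpy as np
import pytest

from aeftex.aef import AEFMap
from aeftex.roi_texture import ROIMask


def aef_from_plane(values2d: np.ndarray) -> AEFMap:
    """Wrap a 2-D value array as a one-plane, fully valid AEF map."""
    values = np.asarray(values2d, dtype=float)[None, :, :]
    return AEFMap(values=values, valid=np.ones_like(values, dtype=bool),
                  clip_range=(float(values.min()), float(max(values.max(), values.min() + 1))))


def roi_from_plane(mask2d: np.ndarray, voxel_size=(3.0, 0.8, 0.8)) -> ROIMask:
    return ROIMask(mask=np.asarray(mask2d, dtype=bool)[None, :, :], voxel_size=voxel_size)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
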