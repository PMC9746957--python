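import numpy as np
import pytest

from dopumap import PhantomSpec, synth
from dopumap.containers import WideFieldMap


def small_spec(target=None, **kw):
    """A reduced-size phantom: same physics, smaller raster for speed."""
    defaults = dict(
        n_bscans=24, n_ascans=128, n_depth=128,
        retina_thickness_px=40, choroid_px=10,
        onh_radius_mm=0.0, seed=123,
    )
    if target is not None:
        defaults["grid_truth"] = synth.constant_pattern(target)
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_volume():
    spec = small_spec(target=0.35)
    vol, truth = synth.make_volume(spec)
    return spec, vol, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def uniform_widefield(value=0.5, half_mm=6.5, mm_per_px=0.025):
    """A constant-valued fovea-centered map covering the whole grid."""
    n = int(2 * half_mm / mm_per_px) + 1
    vals = np.full((n, n), float(value))
    origin = ((n - 1) / 2, (n - 1) / 2)
    return WideFieldMap(values=vals, mm_per_px=mm_per_px, origin_px=origin)
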