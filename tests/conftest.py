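import numpy as np
import pytest

from radicc.features.discretize import DiscretizedROI
from radicc.phantoms import PhantomSpec, make_cohort
from radicc.volumes import ImageVolume, LabelMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240614)


def random_droi(rng, shape, ng_max=6, p_background=0.25,
                spacing=(1.0, 1.5, 2.0)) -> DiscretizedROI:
    """A random discretized ROI with background holes and level gaps."""
    lv = rng.integers(1, ng_max + 1, size=shape).astype(np.int32)
    lv[rng.random(shape) < p_background] = 0
    if (lv > 0).sum() == 0:
        lv[tuple(0 for _ in shape)] = 1
    lv[lv == 3] = ng_max  # leave a gap so skipped levels are exercised
    raw = lv[lv > 0].astype(np.float64) * 10.0
    return DiscretizedROI(levels=lv, raw=raw, ng=int(lv.max()), bin_width=10.0,
                          bin_origin=5.0, spacing=spacing)


def ball_mask(shape, radius_vox, spacing=(1.0, 1.0, 1.0), center=None):
    center = np.asarray(center if center is not None
                        else [(s - 1) / 2 for s in shape])
    r2 = ((np.indices(shape) - center[:, None, None, None]) ** 2).sum(axis=0)
    return LabelMask((r2 <= radius_vox ** 2).astype(np.uint8), spacing)


def textured_tumor(rng, shape=(32, 32, 32), radius=9, spacing=(1.0, 1.0, 1.0)):
    """A small noisy image with a spherical ROI (cheap unit-test stand-in)."""
    mask = ball_mask(shape, radius, spacing)
    vox = rng.normal(0.0, 50.0, shape) + 600.0 * mask.voxels
    return ImageVolume(vox, spacing), mask


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced phantom cohort for pipeline-level tests (not the defaults)."""
    spec = PhantomSpec(n_tumors=4, grid_shape=(48, 48, 48),
                       radius_range_mm=(14.0, 17.0), seed=11)
    return make_cohort(spec)
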