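import numpy as np
import pytest

from qctlung import CTSlice, RoiMask


def make_slice(pixels, spacing=(1.0, 1.0), **kw):
    return CTSlice(
        pixels=np.asarray(pixels, dtype=float),
        spacing_row=spacing[0],
        spacing_col=spacing[1],
        **kw,
    )


def disk_mask(shape, center, radius):
    """Pixels whose centers fall inside a disk (the rasterization oracle)."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def roi_from_mask(mask, seed=None, **kw):
    mask = np.asarray(mask, dtype=bool)
    if seed is None:
        seed = tuple(int(v) for v in np.argwhere(mask)[len(np.argwhere(mask)) // 2])
    return RoiMask(mask=mask, seed=seed, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def noiseless_disk_pair():
    from qctlung import NodulePhantomSpec, generate_nodule_pair

    spec = NodulePhantomSpec(
        shape="disk", target_area_mm2=409.96, noise_sd_sharp=0.0,
        noise_sd_smooth=0.0, seed=7,
    )
    return generate_nodule_pair(spec)
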