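"""Semi-automatic tumor delineation by seeded, attenuation-based region growing.

The delineation protocol this reproduces is the interactive one used for
2-D lung-tumor ROIs: a reader clicks inside the tumor under the lung window,
the region grows to all connected pixels within an attenuation interval, and
adjacent vessels, bronchus or chest wall are then separated manually.  Here
the manual separation step is represented by scripted exclusion masks so the
whole procedure is reproducible.  Growth is 8-connected; interior holes
(air bronchograms) are deliberately left open unless explicitly filled,
because the measurement convention excludes intralesional air.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imaging import CTSlice

__all__ = [
    "RoiMask",
    "JuxtaposeReport",
    "region_grow",
    "bounds_from_seed",
    "apply_exclusion",
    "fill_holes",
    "juxtapose_check",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class RoiMask:
    """Binary tumor ROI on a CT slice grid.

    ``mask`` has the same shape as its slice; ``seed`` is the (row, col)
    click point that started the growth and always lies inside the mask;
    ``lower_hu``/``upper_hu`` are the attenuation bounds the growth used;
    ``exclusions`` records the ids of exclusion masks applied, in order.
    """

    mask: np.ndarray
    seed: tuple[int, int]
    lower_hu: float = -600.0
    upper_hu: float = 200.0
    exclusions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        r, c = self.seed
        if not (0 <= r < m.shape[0] and 0 <= c < m.shape[1]):
            raise ValueError(f"seed {self.seed} outside mask of shape {m.shape}")
        object.__setattr__(self, "mask", m)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def bounds_from_seed(
    ct: CTSlice, seed: tuple[int, int], half_width: float = 350.0
) -> tuple[float, float]:
    """Attenuation interval centred on the seed-neighbourhood median.

    The growing criterion is a fixed absolute HU interval around the median
    of the 3x3 neighbourhood of the clicked pixel; ``half_width`` (default
    350 HU) sets the interval half-width and is the main tunable of the
    segmentation stage.
    """
    r, c = seed
    h, w = ct.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"seed {seed} outside image of shape {ct.shape}")
    patch = ct.pixels[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
    med = float(np.median(patch))
    return med - half_width, med + half_width


def region_grow(
    ct: CTSlice,
    seed: tuple[int, int],
    lower_hu: float,
    upper_hu: float,
) -> RoiMask:
    """Grow an ROI from ``seed`` over 8-connected pixels with HU in bounds.

    The result is exactly the connected component, under 8-connectivity, of
    the thresholded set ``lower_hu <= HU <= upper_hu`` that contains the
    seed; it is deterministic and invariant to which in-component pixel is
    clicked.

    Raises
    ------
    ValueError
        If the seed lies outside the image, or the seed pixel's attenuation
        is outside the growing bounds ("seed outside attenuation range").
    """
    r, c = seed
    h, w = ct.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"seed {seed} outside image of shape {ct.shape}")
    if not (lower_hu <= ct.pixels[r, c] <= upper_hu):
        raise ValueError(
            f"seed outside attenuation range: HU {ct.pixels[r, c]:.1f} "
            f"not in [{lower_hu}, {upper_hu}]"
        )
    in_range = (ct.pixels >= lower_hu) & (ct.pixels <= upper_hu)
    labels, _ = ndimage.label(in_range, structure=_STRUCT8)
    mask = labels == labels[r, c]
    return RoiMask(mask=mask, seed=(r, c), lower_hu=lower_hu, upper_hu=upper_hu)


def apply_exclusion(
    roi: RoiMask, exclusion: np.ndarray, exclusion_id: str | None = None
) -> RoiMask:
    """Remove an exclusion region (vessel, bronchus, chest wall, air) from an ROI.

    Pixels under the exclusion are dropped and the mask is restricted to the
    connected component (8-connectivity) still containing the seed, so an
    exclusion that severs part of the ROI also discards the severed part.

    Raises
    ------
    ValueError
        If the exclusion is not congruent with the mask, or it removes the
        seed pixel ("seed excluded").
    """
    excl = np.asarray(exclusion, dtype=bool)
    if excl.shape != roi.mask.shape:
        raise ValueError(
            f"exclusion shape {excl.shape} incongruent with mask {roi.mask.shape}"
        )
    new = roi.mask & ~excl
    r, c = roi.seed
    if not new[r, c]:
        raise ValueError("seed excluded: exclusion mask removes the seed pixel")
    labels, _ = ndimage.label(new, structure=_STRUCT8)
    new = labels == labels[r, c]
    ident = exclusion_id if exclusion_id is not None else f"exclusion-{len(roi.exclusions) + 1}"
    return replace(roi, mask=new, exclusions=[*roi.exclusions, ident])


def fill_holes(roi: RoiMask) -> RoiMask:
    """Fill interior holes of the ROI (off by default in the pipeline).

    Provided for protocols that measure over intralesional air; the default
    measurement convention keeps air bronchograms excluded.
    """
    return replace(roi, mask=ndimage.binary_fill_holes(roi.mask))


@dataclass(frozen=True)
class JuxtaposeReport:
    dice: float
    passed: bool
    tolerance: float


def juxtapose_check(
    roi_a: RoiMask, roi_b: RoiMask, tolerance: float = 0.8
) -> JuxtaposeReport:
    """Compare two ROIs of the same tumor drawn on congruent grids.

    Returns the Dice overlap coefficient and whether it meets ``tolerance``;
    a failing check signals that one of the two ROIs (e.g. the thin- vs
    thick-slice delineation) should be re-drawn.  Masks must already live on
    a common grid; resample thick-slice masks to the thin-slice spacing
    first if the grids differ.
    """
    if roi_a.mask.shape != roi_b.mask.shape:
        raise ValueError(
            f"masks on incongruent grids: {roi_a.mask.shape} vs {roi_b.mask.shape}; "
            "resample to a common spacing first"
        )
    a = roi_a.mask
    b = roi_b.mask
    denom = int(a.sum()) + int(b.sum())
    dice = 1.0 if denom == 0 else 2.0 * int((a & b).sum()) / denom
    return JuxtaposeReport(dice=dice, passed=dice >= tolerance, tolerance=tolerance)
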