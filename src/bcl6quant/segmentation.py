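"""Gland-versus-stroma segmentation of the marker channel.

The marker stains both compartments, so intensity alone cannot separate
them.  The discriminating criterion is morphological: stromal cells
appear as small isolated objects, while glandular epithelial cells form
connected ring-like structures of much greater size.  The pipeline is

1. automatic global thresholding of the grey-level marker channel
   (Otsu's between-class-variance criterion),
2. erosion and/or opening with a structuring element sized between the
   stromal objects and the gland wall thickness, which deletes stroma
   but leaves a seed inside every gland,
3. geodesic reconstruction (iterated conditional dilation of the seed
   under the original thresholded mask), which restores the full shape
   of every surviving gland — i.e. opening by reconstruction,
4. removal of residual components below a minimum area, and connected-
   component labelling (8-connectivity) to count glands.

Structuring-element sizes are data-dependent ("appropriate sizes"): the
defaults here match the geometry of the synthetic slides and must be
re-tuned for other acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label
from skimage.morphology import disk, erosion, opening, reconstruction

from .errors import ContractError, DegenerateInputError
from .io_slides import ChannelImage

#: 3x3 all-ones footprint = 8-connectivity, so ring walls at arbitrary
#: angles remain single components.
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MorphologyParams:
    """Sizes of the morphological filters, in pixels.

    ``erosion_radius`` and ``opening_radius`` are the radii of the
    structuring elements of the sequential erosion and opening steps
    (0 disables a step).  ``structuring_element`` is ``disk`` or
    ``square`` (a square of side ``2*radius + 1``).  Components smaller
    than ``min_gland_area`` pixels are discarded after reconstruction.
    """

    erosion_radius: int = 4
    opening_radius: int = 0
    structuring_element: str = "disk"
    min_gland_area: int = 100

    def __post_init__(self) -> None:
        if self.erosion_radius < 0 or self.opening_radius < 0 or self.min_gland_area < 0:
            raise ContractError("morphology sizes must be non-negative")
        if self.structuring_element not in ("disk", "square"):
            raise ContractError("structuring_element must be 'disk' or 'square'")

    def footprint(self, radius: int) -> np.ndarray:
        if self.structuring_element == "disk":
            return disk(radius)
        return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)


@dataclass
class EpitheliumSegmentation:
    """Retained glandular epithelium: mask, component labels, gland count."""

    mask: np.ndarray
    labels: np.ndarray
    gland_count: int
    section_id: str = ""
    params: MorphologyParams | None = field(default=None, repr=False)


def otsu_threshold(img: ChannelImage | np.ndarray) -> tuple[int, np.ndarray]:
    """Automatic global threshold maximising between-class variance.

    The threshold ``t`` is the integer cut in [0, 255] that maximises
    the between-class variance of the two classes {levels <= t} and
    {levels > t}; ties resolve to the smallest such ``t``.  The returned
    boolean mask marks pixels strictly greater than ``t``.

    Raises
    ------
    DegenerateInputError
        If the image is constant (no threshold separates two classes).
    """
    pixels = img.pixels if isinstance(img, ChannelImage) else np.asarray(img)
    if pixels.dtype != np.uint8:
        raise ContractError("otsu_threshold expects uint8 grey levels")
    counts = np.bincount(pixels.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise DegenerateInputError(
            "constant image: automatic thresholding requires >= 2 distinct grey levels"
        )
    total = counts.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(counts)  # class {<= t}
    w1 = total - w0
    m0 = np.cumsum(counts * levels)
    mean_total = m0[-1] / total
    # between-class variance; undefined (0) where either class is empty
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    del mean_total
    t = int(np.argmax(sigma_b))
    return t, pixels > t


def filter_epithelium(
    mask: np.ndarray, params: MorphologyParams = MorphologyParams(), section_id: str = ""
) -> EpitheliumSegmentation:
    """Remove small isolated (stromal) objects from a thresholded mask.

    Sequentially erodes and opens the mask, then geodesically
    reconstructs the surviving seeds under the original mask, so that
    every gland whose wall survives the filtering is restored to its
    full thresholded shape while small objects vanish.  Components with
    fewer than ``params.min_gland_area`` pixels are then dropped and the
    remainder labelled with 8-connectivity.

    The output mask is always a subset of the input mask, and the
    operation is idempotent.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ContractError("mask must be a non-empty 2-D boolean raster")

    seed = mask
    if params.erosion_radius > 0:
        seed = erosion(seed, params.footprint(params.erosion_radius))
    if params.opening_radius > 0:
        seed = opening(seed, params.footprint(params.opening_radius))
    if seed is mask:
        retained = mask.copy()
    elif not seed.any():
        retained = np.zeros_like(mask)
    else:
        retained = reconstruction(
            seed.astype(np.uint8), mask.astype(np.uint8), method="dilation", footprint=_CONN8
        ).astype(bool)

    labels = label(retained, connectivity=2)
    if params.min_gland_area > 0 and labels.max() > 0:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < params.min_gland_area)
        kill = np.isin(labels, small[small > 0])
        retained[kill] = False
        labels = label(retained, connectivity=2)
    return EpitheliumSegmentation(
        mask=retained,
        labels=labels,
        gland_count=int(labels.max()),
        section_id=section_id,
        params=params,
    )


def count_glands(seg: EpitheliumSegmentation) -> int:
    """Number of connected components (8-connectivity) of the retained mask.

    Feeds the section-inclusion rule (sections need a minimum number of
    glands for their distribution to be analysed).
    """
    return int(seg.labels.max())
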