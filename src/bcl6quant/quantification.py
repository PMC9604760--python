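"""Background elimination, intensity histograms and section inclusion.

Multiplying the retained binary epithelium mask with the grey-level
marker channel zeroes everything outside the glands; the remaining
pixel values, visualised on 256 grey levels, are tallied into a
per-section intensity histogram.  Grey level 0 conflates genuine
zero-intensity epithelium with the zeroed background, so it is excluded
from the distribution by default.  Sections contribute to group-level
analysis only if they contain at least ``min_glands`` glands
(default 20).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ContractError, DegenerateInputError
from .io_slides import ChannelImage
from .segmentation import EpitheliumSegmentation

logger = logging.getLogger(__name__)

N_LEVELS = 256
DEFAULT_MIN_GLANDS = 20


@dataclass
class MaskedIntensityImage:
    """Marker channel with background eliminated (zero outside the mask)."""

    pixels: np.ndarray
    section_id: str = ""


@dataclass
class IntensityDistribution:
    """256-bin histogram of masked marker intensities for one section.

    ``counts`` is indexed by grey level 0..255.  If ``normalized``, the
    values sum to 1 and represent per-level frequencies; otherwise they
    are raw pixel counts summing to ``n_pixels``.
    """

    counts: np.ndarray
    normalized: bool
    section_id: str = ""
    n_pixels: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (N_LEVELS,):
            raise ContractError(
                f"intensity distributions live on exactly {N_LEVELS} grey levels, "
                f"got shape {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ContractError("histogram counts must be non-negative")

    @property
    def levels(self) -> np.ndarray:
        return np.arange(N_LEVELS)

    def normalize(self) -> "IntensityDistribution":
        """Return the unit-mass version of this distribution."""
        if self.normalized:
            return self
        if self.n_pixels == 0 or self.counts.sum() == 0:
            raise DegenerateInputError(
                f"section {self.section_id!r}: empty distribution cannot be normalized"
            )
        return replace(self, counts=self.counts / self.counts.sum(), normalized=True)

    def mean_intensity(self) -> float:
        """Arithmetic mean grey level of the distribution."""
        total = self.counts.sum()
        if total == 0:
            raise DegenerateInputError("empty distribution has no mean intensity")
        return float((self.counts * self.levels).sum() / total)


@dataclass
class SectionQuantification:
    """One section's gland count, intensity distribution and inclusion flag."""

    section_id: str
    gland_count: int
    distribution: IntensityDistribution
    included: bool | None = None
    group_label: str = ""


def apply_mask(
    img: ChannelImage | np.ndarray, seg: EpitheliumSegmentation | np.ndarray
) -> MaskedIntensityImage:
    """Multiply the marker channel by the binary epithelium mask.

    Element-wise product with the {0, 1} mask eliminates the background;
    epithelial pixel values pass through unchanged.
    """
    pixels = img.pixels if isinstance(img, ChannelImage) else np.asarray(img)
    mask = seg.mask if isinstance(seg, EpitheliumSegmentation) else np.asarray(seg)
    if pixels.shape != mask.shape:
        raise ContractError(
            f"channel shape {pixels.shape} != mask shape {mask.shape}"
        )
    section_id = img.section_id if isinstance(img, ChannelImage) else ""
    return MaskedIntensityImage(
        pixels=pixels * mask.astype(pixels.dtype), section_id=section_id
    )


def intensity_histogram(
    masked: MaskedIntensityImage, exclude_zero: bool = True
) -> IntensityDistribution:
    """Histogram of masked intensities over grey levels 0..255.

    With ``exclude_zero`` (default), level 0 — background after the
    mask multiplication — is removed from the tally and from
    ``n_pixels``, so the distribution describes stained-region
    intensities only.
    """
    counts = np.bincount(masked.pixels.ravel(), minlength=N_LEVELS).astype(np.float64)
    if exclude_zero:
        counts[0] = 0.0
    return IntensityDistribution(
        counts=counts,
        normalized=False,
        section_id=masked.section_id,
        n_pixels=int(counts.sum()),
    )


def apply_inclusion_rule(
    quants: list[SectionQuantification], min_glands: int = DEFAULT_MIN_GLANDS
) -> tuple[list[SectionQuantification], list[SectionQuantification]]:
    """Partition sections by the minimum-gland rule.

    A section enters group-level analysis only if it contains at least
    ``min_glands`` glands.  Both sublists preserve input order; every
    decision is logged with the gland count that produced it.
    """
    if min_glands < 0:
        raise ContractError("min_glands must be non-negative")
    included: list[SectionQuantification] = []
    excluded: list[SectionQuantification] = []
    for q in quants:
        q.included = q.gland_count >= min_glands
        if q.included:
            included.append(q)
            logger.info(
                "section %s included (%d glands >= %d)",
                q.section_id, q.gland_count, min_glands,
            )
        else:
            excluded.append(q)
            logger.info(
                "section %s EXCLUDED (%d glands < %d)",
                q.section_id, q.gland_count, min_glands,
            )
    return included, excluded
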