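"""Synthetic fluorescence-like slide generator with ground truth.

Emulates the features of scanned endometrial sections that the
pipeline's logic depends on — and nothing more: glandular epithelium as
large ring-like (annular) structures, stromal cells as small isolated
disks, group-specific marker intensity distributions in the green
channel, a nuclear-counterstain speckle in the blue channel, and
additive Gaussian acquisition noise.  Every slide carries its
ground-truth epithelium and stroma masks so segmentation accuracy and
the downstream statistics can be validated exactly.

The geometric separability premise of the real tissue is enforced by
construction: every stromal object is strictly thinner than the
default erosion structuring element, every gland wall strictly
thicker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ContractError, GenerationError
from .hscore import DEFAULT_CUTS, categorize_intensities, compute_hscore
from .io_slides import RGBImage, SectionMeta
from .quantification import IntensityDistribution, N_LEVELS

logger = logging.getLogger(__name__)

_MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class IntensitySpec:
    """Marker-intensity distribution of a tissue compartment.

    ``gaussian``: N(loc, scale) grey levels.  ``lognormal``: exp of
    N(log(loc), scale), i.e. ``loc`` is the median grey level and
    ``scale`` the log-space sigma.  Sampled values are later clipped to
    [0, 255] when rendered into the 8-bit channel.
    """

    family: str = "gaussian"
    loc: float = 130.0
    scale: float = 30.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "lognormal"):
            raise ContractError(f"unknown intensity family {self.family!r}")
        if self.scale <= 0 or self.loc <= 0:
            raise ContractError("intensity loc and scale must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "gaussian":
            return rng.normal(self.loc, self.scale, n)
        return rng.lognormal(np.log(self.loc), self.scale, n)

    def shifted(self, offset: float) -> "IntensitySpec":
        return replace(self, loc=self.loc + offset)


@dataclass(frozen=True)
class SlideSpec:
    """Geometry, intensity and noise parameters of one synthetic slide."""

    height: int = 384
    width: int = 384
    n_glands: int = 24
    gland_outer_radius_range: tuple[int, int] = (14, 18)
    gland_stroke_range: tuple[int, int] = (9, 11)
    n_stromal_objects: int = 150
    stromal_radius_range: tuple[int, int] = (1, 3)
    epithelial_intensity: IntensitySpec = field(default_factory=IntensitySpec)
    stromal_intensity: IntensitySpec = field(
        default_factory=lambda: IntensitySpec("gaussian", 110.0, 30.0)
    )
    background_level: int = 8
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ContractError("slide dimensions must be positive")
        if self.n_glands < 0 or self.n_stromal_objects < 0:
            raise ContractError("object counts must be non-negative")
        if not 0 <= self.background_level <= 255:
            raise ContractError("background_level must be in [0, 255]")
        if self.noise_sigma < 0:
            raise ContractError("noise_sigma must be non-negative")
        # separability premise: stromal diameter < gland wall thickness,
        # so one erosion size can delete all stroma yet seed every gland
        if self.n_glands and self.n_stromal_objects:
            if 2 * self.stromal_radius_range[1] >= self.gland_stroke_range[0]:
                raise ContractError(
                    "stromal objects must be strictly thinner than gland walls "
                    f"(2*{self.stromal_radius_range[1]} >= {self.gland_stroke_range[0]})"
                )


@dataclass
class SyntheticSlide:
    """A rendered slide plus its ground-truth compartment masks."""

    image: RGBImage
    truth_epithelium: np.ndarray
    truth_stroma: np.ndarray
    spec: SlideSpec


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: label, size, and marker-intensity offset.

    ``between_section_sd`` models patient-to-patient heterogeneity: each
    section's epithelial intensity location receives an additional
    N(0, sd) grey-level offset (0 disables it, making every section of
    the group an exact replicate of the shifted template).
    """

    label: str
    n_sections: int
    intensity_shift: float = 0.0
    between_section_sd: float = 0.0
    template: SlideSpec = field(default_factory=SlideSpec)

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ContractError("each group needs at least one section")
        if self.between_section_sd < 0:
            raise ContractError("between_section_sd must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """A multi-group cohort; per-section seeds derive from ``seed``."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ContractError("a cohort needs at least one group")


def _disk_at(
    mask: np.ndarray, cy: int, cx: int, r_out: float, r_in: float = -1.0
) -> None:
    """Paint an annulus (or full disk if r_in < 0) into ``mask`` in place."""
    h, w = mask.shape
    y0, y1 = max(0, int(cy - r_out) - 1), min(h, int(cy + r_out) + 2)
    x0, x1 = max(0, int(cx - r_out) - 1), min(w, int(cx + r_out) + 2)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    ring = (d2 <= r_out**2) & (d2 > r_in**2)
    mask[y0:y1, x0:x1] |= ring


def generate_slide(spec: SlideSpec) -> SyntheticSlide:
    """Render one synthetic slide, fully reproducible from ``spec.seed``.

    Glands are annuli placed without overlap by rejection sampling
    (at most 10,000 attempts, else :class:`GenerationError`); stromal
    disks are scattered in the complement.  Green-channel values are
    drawn per compartment from the spec's intensity distributions, with
    additive Gaussian read noise, rounded and clipped to [0, 255].
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    epith = np.zeros((h, w), dtype=bool)
    stroma = np.zeros((h, w), dtype=bool)

    glands: list[tuple[int, int, int]] = []  # (cy, cx, r_out)
    attempts = 0
    while len(glands) < spec.n_glands:
        attempts += 1
        if attempts > _MAX_ATTEMPTS:
            raise GenerationError(
                f"placed only {len(glands)}/{spec.n_glands} glands in "
                f"{_MAX_ATTEMPTS} attempts; use fewer or smaller objects"
            )
        r_out = int(rng.integers(spec.gland_outer_radius_range[0],
                                 spec.gland_outer_radius_range[1] + 1))
        stroke = int(rng.integers(spec.gland_stroke_range[0],
                                  spec.gland_stroke_range[1] + 1))
        stroke = min(stroke, r_out - 1)  # keep a lumen
        if r_out + 1 >= min(h, w) // 2:
            raise GenerationError("gland radius exceeds slide dimensions")
        cy = int(rng.integers(r_out + 1, h - r_out - 1))
        cx = int(rng.integers(r_out + 1, w - r_out - 1))
        if any((cy - gy) ** 2 + (cx - gx) ** 2 <= (r_out + gr + 2) ** 2
               for gy, gx, gr in glands):
            continue
        glands.append((cy, cx, r_out))
        _disk_at(epith, cy, cx, r_out, r_out - stroke)

    attempts = 0
    placed_stroma = 0
    while placed_stroma < spec.n_stromal_objects:
        attempts += 1
        if attempts > _MAX_ATTEMPTS:
            raise GenerationError(
                f"placed only {placed_stroma}/{spec.n_stromal_objects} stromal "
                f"objects in {_MAX_ATTEMPTS} attempts"
            )
        sr = int(rng.integers(spec.stromal_radius_range[0],
                              spec.stromal_radius_range[1] + 1))
        cy = int(rng.integers(sr, h - sr))
        cx = int(rng.integers(sr, w - sr))
        # keep stroma strictly outside (and clear of) every gland
        if any((cy - gy) ** 2 + (cx - gx) ** 2 <= (gr + sr + 2) ** 2
               for gy, gx, gr in glands):
            continue
        _disk_at(stroma, cy, cx, sr)
        placed_stroma += 1

    green = np.full((h, w), float(spec.background_level))
    green[epith] = spec.epithelial_intensity.sample(int(epith.sum()), rng)
    green[stroma] = spec.stromal_intensity.sample(int(stroma.sum()), rng)

    cells = epith | stroma
    blue = np.full((h, w), 4.0)
    blue[cells] = rng.uniform(100.0, 220.0, int(cells.sum()))  # nuclear speckle
    red = np.zeros((h, w))

    img = np.stack([red, green, blue], axis=2)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticSlide(
        image=RGBImage(pixels=img, section_id=""),
        truth_epithelium=epith,
        truth_stroma=stroma,
        spec=spec,
    )


def _section_seed(master: int, group_index: int, section_index: int) -> int:
    """Deterministic per-section seed derived from the cohort seed."""
    ss = np.random.SeedSequence([int(master), group_index, section_index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    spec: CohortSpec,
    simulate_observers: bool = True,
    observer_sd: float = 0.15,
) -> list[tuple[SectionMeta, SyntheticSlide]]:
    """Generate every section of a multi-group cohort.

    Each group's slides use the group template with the epithelial
    marker distribution shifted by ``intensity_shift`` grey levels.
    With ``simulate_observers``, two blinded observers' HSCOREs are
    emulated per section: the ground-truth epithelial pixel intensities
    are bucketed at the default quartile cuts and observer noise
    (sd ``observer_sd`` HSCORE units) is added.
    """
    records: list[tuple[SectionMeta, SyntheticSlide]] = []
    for gi, group in enumerate(spec.groups):
        for si in range(group.n_sections):
            seed = _section_seed(spec.seed, gi, si)
            offset = group.intensity_shift
            if group.between_section_sd > 0:
                jitter_rng = np.random.default_rng(seed + 2)
                offset += float(jitter_rng.normal(0.0, group.between_section_sd))
                # keep the location positive for lognormal templates
                offset = max(offset, 5.0 - group.template.epithelial_intensity.loc)
            slide_spec = replace(
                group.template,
                epithelial_intensity=group.template.epithelial_intensity.shifted(offset),
                seed=seed,
            )
            slide = generate_slide(slide_spec)
            section_id = f"{group.label}-{si:02d}"
            slide.image.section_id = section_id
            observers: tuple[float, ...] = ()
            if simulate_observers:
                values = slide.image.pixels[:, :, 1][slide.truth_epithelium]
                true_score = compute_hscore(
                    categorize_intensities(values, DEFAULT_CUTS)
                ).score
                obs_rng = np.random.default_rng(
                    _section_seed(spec.seed, gi, si) + 1
                )
                observers = tuple(
                    float(np.clip(true_score + obs_rng.normal(0.0, observer_sd), 0, 4))
                    for _ in range(2)
                )
            records.append(
                (
                    SectionMeta(
                        section_id=section_id,
                        group_label=group.label,
                        observer_hscores=observers,
                    ),
                    slide,
                )
            )
    return records


def sample_section_distribution(
    intensity: IntensitySpec,
    n_pixels: int = 5000,
    rng: np.random.Generator | int | None = None,
    exclude_zero: bool = True,
) -> IntensityDistribution:
    """Draw one section's normalized intensity histogram directly.

    Samples ``n_pixels`` marker intensities from ``intensity``, rounds
    and clips them to the 256 grey levels exactly as slide rendering
    does, and returns the normalized histogram.  Useful for
    distribution-level simulations where rendering full slides would
    add nothing.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = np.clip(np.rint(intensity.sample(n_pixels, rng)), 0, 255).astype(np.intp)
    counts = np.bincount(values, minlength=N_LEVELS).astype(np.float64)
    if exclude_zero:
        counts[0] = 0.0
    dist = IntensityDistribution(
        counts=counts, normalized=False, n_pixels=int(counts.sum())
    )
    return dist.normalize()


def sample_group_distributions(
    intensity: IntensitySpec,
    n_sections: int,
    n_pixels: int = 4000,
    between_section_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> list[IntensityDistribution]:
    """Draw one group's per-section normalized histograms directly.

    Hierarchical sampler mirroring :func:`generate_cohort` at the
    distribution level: each section's intensity location is the group
    location plus N(0, ``between_section_sd``) patient heterogeneity,
    then ``n_pixels`` values are drawn, rounded and histogrammed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = []
    for _ in range(n_sections):
        loc = intensity.loc
        if between_section_sd > 0:
            loc = max(5.0, loc + float(rng.normal(0.0, between_section_sd)))
        section_spec = replace(intensity, loc=loc)
        out.append(sample_section_distribution(section_spec, n_pixels, rng))
    return out


def write_cohort(
    records: Sequence[tuple[SectionMeta, SyntheticSlide]], outdir: str | Path
) -> list[Path]:
    """Write cohort slides (TIFF), truth masks (PNG) and meta.csv.

    The layout is directly consumable by the quantify pipeline:
    ``<section_id>.tif`` per slide plus a ``meta.csv`` with section
    ids, group labels and simulated observer scores.
    """
    from .io_slides import write_mask  # local import to avoid cycle at import time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    rows = []
    for meta, slide in records:
        img_path = outdir / f"{meta.section_id}.tif"
        tifffile.imwrite(img_path, slide.image.pixels, photometric="rgb")
        manifest.append(img_path)
        manifest.append(
            write_mask(slide.truth_epithelium, outdir / f"{meta.section_id}_truth_epithelium.png")
        )
        manifest.append(
            write_mask(slide.truth_stroma, outdir / f"{meta.section_id}_truth_stroma.png")
        )
        row: dict[str, object] = {
            "section_id": meta.section_id,
            "group_label": meta.group_label,
        }
        for i, score in enumerate(meta.observer_hscores, start=1):
            row[f"hscore_obs{i}"] = score
        rows.append(row)
    meta_path = outdir / "meta.csv"
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    manifest.append(meta_path)
    logger.info("wrote %d cohort files to %s", len(manifest), outdir)
    return manifest


def cohort_from_toml(path: str | Path) -> CohortSpec:
    """Parse a cohort specification from TOML.

    Top level: ``seed``; repeated ``[[group]]`` tables with ``label``,
    ``n_sections``, ``intensity_shift`` and an optional ``[group.slide]``
    table overriding :class:`SlideSpec` fields (intensity distributions
    as ``epithelial_loc``/``epithelial_scale`` etc.).
    """
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    groups = []
    for g in data.get("group", []):
        slide_kw = dict(g.get("slide", {}))
        for compartment in ("epithelial", "stromal"):
            kw = {}
            for key in ("family", "loc", "scale"):
                v = slide_kw.pop(f"{compartment}_{key}", None)
                if v is not None:
                    kw[key] = v
            if kw:
                slide_kw[f"{compartment}_intensity"] = IntensitySpec(
                    **{**{"family": "gaussian", "loc": 130.0, "scale": 30.0}, **kw}
                )
        for key in ("gland_outer_radius_range", "gland_stroke_range", "stromal_radius_range"):
            if key in slide_kw:
                slide_kw[key] = tuple(slide_kw[key])
        groups.append(
            GroupSpec(
                label=str(g["label"]),
                n_sections=int(g["n_sections"]),
                intensity_shift=float(g.get("intensity_shift", 0.0)),
                template=SlideSpec(**slide_kw),
            )
        )
    return CohortSpec(groups=tuple(groups), seed=int(data.get("seed", 0)))
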