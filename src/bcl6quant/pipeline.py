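"""End-to-end orchestration: segment, quantify, compare, correlate.

``run_pipeline`` drives one cohort from raw slide images and a metadata
table to the full set of result tables: per-section masks, gland counts
and histograms; group mean +/- SEM curves with smoothing and percentile
summaries; pairwise point-by-point Mann-Whitney tests; per-group
Gaussian fits; and the HSCORE-versus-intensity regression when observer
scores are present.  All analysis stages are deterministic — randomness
lives exclusively in the synthetic module — and the run manifest
records the configuration hash and library versions for
reproducibility.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InputError, NoSectionsIncludedError
from .hscore import DEFAULT_CUTS, consensus_scores, hscore_from_distribution
from .io_slides import extract_channel, load_rgb, read_metadata, write_results
from .quantification import (
    SectionQuantification,
    apply_inclusion_rule,
    apply_mask,
    intensity_histogram,
)
from .segmentation import MorphologyParams, filter_epithelium, otsu_threshold
from .stats import (
    DEFAULT_ALPHA,
    correlate_hscore,
    distribution_percentiles,
    fit_gaussian,
    mean_distribution,
    pointwise_mann_whitney,
    smooth_curve,
)

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of an analysis run."""

    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    min_glands: int = 20
    exclude_zero: bool = True
    alpha: float = DEFAULT_ALPHA
    grid_factor: float = 4.0
    hscore_cuts: tuple[float, float, float] = DEFAULT_CUTS
    write_plots: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InputError("alpha must be in (0, 1)")
        if self.min_glands < 0:
            raise InputError("min_glands must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hscore_cuts"] = list(self.hscore_cuts)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        morph = MorphologyParams(**data.pop("morphology", {}))
        if "hscore_cuts" in data:
            data["hscore_cuts"] = tuple(data["hscore_cuts"])
        return cls(morphology=morph, **data)


def _find_image(images_dir: Path, section_id: str) -> Path:
    for suffix in IMAGE_SUFFIXES:
        candidate = images_dir / f"{section_id}{suffix}"
        if candidate.exists():
            return candidate
    raise InputError(
        f"no image found for section {section_id!r} under {images_dir} "
        f"(tried suffixes {IMAGE_SUFFIXES})"
    )


def quantify_section(
    image_path: str | Path, config: PipelineConfig, section_id: str | None = None
):
    """Run the per-section image pipeline: threshold, filter, mask, histogram.

    Returns ``(quantification, segmentation, masked_image)``.
    """
    rgb = load_rgb(image_path, section_id=section_id)
    green = extract_channel(rgb, "green")
    _, thresh_mask = otsu_threshold(green)
    seg = filter_epithelium(thresh_mask, config.morphology, section_id=rgb.section_id)
    masked = apply_mask(green, seg)
    dist = intensity_histogram(masked, exclude_zero=config.exclude_zero)
    quant = SectionQuantification(
        section_id=rgb.section_id, gland_count=seg.gland_count, distribution=dist
    )
    return quant, seg, masked


def run_pipeline(
    images_dir: str | Path,
    meta_csv: str | Path,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path = "results",
) -> dict:
    """Analyse a cohort end to end and write all result tables.

    Sections are processed in sorted section-id order, so the output is
    invariant to input file ordering.  Sections with fewer than
    ``config.min_glands`` glands are excluded (and logged); if none
    survives, :class:`NoSectionsIncludedError` is raised.  Group
    comparisons run for every pair of groups with at least two included
    sections each; with a single group the comparison stages are
    skipped with a warning.

    Returns the run manifest (also written as ``manifest.json``).
    """
    images_dir = Path(images_dir)
    outdir = Path(outdir)
    metas = sorted(read_metadata(meta_csv), key=lambda m: m.section_id)

    tables: dict[str, pd.DataFrame] = {}
    masks: dict[str, np.ndarray] = {}
    quants: list[SectionQuantification] = []
    meta_by_id = {m.section_id: m for m in metas}

    for meta in metas:
        quant, seg, _ = quantify_section(
            _find_image(images_dir, meta.section_id), config, meta.section_id
        )
        quant.group_label = meta.group_label
        quants.append(quant)
        masks[f"{meta.section_id}_epithelium"] = seg.mask

    included, excluded = apply_inclusion_rule(quants, config.min_glands)
    if not included:
        raise NoSectionsIncludedError(
            "no section reached the minimum gland count "
            f"({config.min_glands}); gland counts: "
            + ", ".join(f"{q.section_id}={q.gland_count}" for q in excluded)
        )

    # per-section summary table
    section_rows = []
    for q in quants:
        row = {
            "section_id": q.section_id,
            "group": q.group_label,
            "gland_count": q.gland_count,
            "included": q.included,
            "n_pixels": q.distribution.n_pixels,
        }
        if q.distribution.n_pixels > 0:
            row["mean_intensity"] = q.distribution.mean_intensity()
            row["hscore_categorized"] = hscore_from_distribution(
                q.distribution.counts, config.hscore_cuts
            )
        section_rows.append(row)
    tables["sections"] = pd.DataFrame(section_rows)

    # long-format per-section distributions
    dist_rows = []
    for q in included:
        norm = q.distribution.normalize()
        for level in range(256):
            if q.distribution.counts[level] > 0:
                dist_rows.append(
                    {
                        "section_id": q.section_id,
                        "level": level,
                        "count": q.distribution.counts[level],
                        "frequency": norm.counts[level],
                    }
                )
    tables["distributions"] = pd.DataFrame(dist_rows)

    # group-level curves, percentiles, Gaussian fits
    labels = sorted({q.group_label for q in included})
    by_group = {
        lab: [q.distribution.normalize() for q in included if q.group_label == lab]
        for lab in labels
    }
    curves = {}
    pct_rows, gauss_rows = [], []
    for lab in labels:
        curve = mean_distribution(by_group[lab], group_label=lab)
        curves[lab] = curve
        smoothed = smooth_curve(curve, config.grid_factor)
        pct = distribution_percentiles(smoothed)
        pct_rows.append({"group": lab, **pct.as_dict()})
        fit = fit_gaussian(curve)
        gauss_rows.append(
            {
                "group": lab,
                "amplitude": fit.amplitude,
                "mu": fit.mu,
                "sigma": fit.sigma,
                "residual_ss": fit.residual_ss,
                "converged": fit.converged,
            }
        )
    tables["percentiles"] = pd.DataFrame(pct_rows)
    tables["gaussian_fits"] = pd.DataFrame(gauss_rows)

    # pairwise point-by-point comparisons
    comparisons = []
    if len(labels) < 2:
        logger.warning("single group: comparison stages skipped")
    for lab_a, lab_b in itertools.combinations(labels, 2):
        if len(by_group[lab_a]) < 2 or len(by_group[lab_b]) < 2:
            logger.warning(
                "skipping %s vs %s: fewer than 2 sections in a group", lab_a, lab_b
            )
            continue
        test = pointwise_mann_whitney(
            by_group[lab_a], by_group[lab_b], alpha=config.alpha
        )
        name = f"pointwise_{lab_a}_vs_{lab_b}"
        tables[name] = pd.DataFrame(
            {
                "level": test.levels.astype(int),
                "p_value": test.p_values,
                "significant": test.significant,
                "tested": test.tested,
            }
        )
        comparisons.append(name)

    # HSCORE correlation (needs observer scores on >= 3 included sections)
    consensus = consensus_scores([meta_by_id[q.section_id] for q in included])
    pairs = []
    for q in included:
        if q.section_id not in consensus or q.distribution.n_pixels == 0:
            continue
        fit = fit_gaussian(q.distribution.normalize())
        mean_value = fit.mu if fit.converged else q.distribution.mean_intensity()
        pairs.append((consensus[q.section_id], mean_value))
    regression = None
    if len(pairs) >= 3:
        try:
            regression = correlate_hscore(pairs)
            tables["hscore_regression"] = pd.DataFrame(
                [
                    {
                        "slope": regression.slope,
                        "intercept": regression.intercept,
                        "r": regression.r,
                        "p_value": regression.p_value,
                        "n": regression.n,
                    }
                ]
            )
        except Exception as exc:
            logger.warning("HSCORE regression skipped: %s", exc)

    manifest_files = write_results(tables, masks, outdir)

    if config.write_plots:
        from .plotting import plot_group_distributions, plot_hscore_regression

        manifest_files.append(
            plot_group_distributions(
                [curves[lab] for lab in labels], outdir / "group_distributions.png"
            )
        )
        if regression is not None:
            manifest_files.append(
                plot_hscore_regression(pairs, regression, outdir / "hscore_regression.png")
            )

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "versions": _library_versions(),
        "n_sections": len(quants),
        "included": [q.section_id for q in included],
        "excluded": {q.section_id: q.gland_count for q in excluded},
        "groups": labels,
        "comparisons": comparisons,
        "files": [str(p) for p in manifest_files],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _library_versions() -> dict[str, str]:
    import imageio
    import scipy
    import skimage

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "pandas": pd.__version__,
        "imageio": imageio.__version__,
    }
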