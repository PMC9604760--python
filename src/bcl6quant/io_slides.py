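"""Reading and writing of slide images, masks and result tables.

Slides are 8-bit rasters: RGB where the fluorescent marker is imaged in
the green channel and the nuclear counterstain (DAPI) in the blue
channel.  All intensity analysis downstream happens on 256 grey levels,
so inputs with a higher bit depth are rejected rather than silently
rescaled.  Coordinates are row-major with origin at the top-left corner
and 0-based indices; binary masks use 0 for background and 255 (or
``True``) for foreground.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InputError, UnsupportedFormatError

logger = logging.getLogger(__name__)

CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass
class RGBImage:
    """An 8-bit three-channel slide raster.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        Channel order red, green, blue.
    section_id : str
        Identifier of the tissue section (file stem by default).
    """

    pixels: np.ndarray
    section_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InputError(
                f"RGBImage requires an (H, W, 3) array, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise UnsupportedFormatError(
                f"RGBImage requires 8-bit channels, got dtype {self.pixels.dtype}"
            )
        if self.pixels.shape[0] == 0 or self.pixels.shape[1] == 0:
            raise InputError("RGBImage must have positive height and width")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ChannelImage:
    """One colour plane of a slide, as 2-D uint8 grey levels in [0, 255]."""

    pixels: np.ndarray
    channel_name: str
    section_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InputError("ChannelImage requires a 2-D array")
        if self.pixels.dtype != np.uint8:
            raise UnsupportedFormatError(
                f"ChannelImage requires uint8 pixels, got {self.pixels.dtype}"
            )
        if self.channel_name not in CHANNEL_INDEX:
            raise InputError(f"unknown channel name {self.channel_name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SectionMeta:
    """Per-section metadata: group membership and optional observer scores."""

    section_id: str
    group_label: str
    observer_hscores: tuple[float, ...] = field(default_factory=tuple)


def load_rgb(path: str | Path, section_id: str | None = None) -> RGBImage:
    """Load an 8-bit TIFF/PNG raster as an :class:`RGBImage`.

    Single-channel (greyscale) inputs are promoted to three channels by
    replication, with a logged warning; an alpha channel, if present, is
    dropped.  Pixel values are preserved bit-exactly.

    Raises
    ------
    InputError
        If the file does not exist or cannot be decoded.
    UnsupportedFormatError
        If the raster has more than 8 bits per channel.
    """
    path = Path(path)
    if section_id is None:
        section_id = path.stem
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise InputError(f"image file not found: {path}") from None
    except Exception as exc:  # decoder-specific error types vary
        raise InputError(f"cannot decode image file {path}: {exc}") from exc

    if arr.dtype == np.bool_:
        arr = arr.astype(np.uint8) * 255
    if arr.dtype != np.uint8:
        raise UnsupportedFormatError(
            f"{path}: only 8-bit rasters are supported (got dtype {arr.dtype}); "
            "rescaling higher depths would alter the 256-grey-level analysis"
        )
    if arr.ndim == 2:
        logger.warning("%s: greyscale input promoted to RGB by replication", path)
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("%s: alpha channel dropped", path)
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"{path}: expected a 1- or 3-channel raster, got shape {arr.shape}")
    return RGBImage(pixels=np.ascontiguousarray(arr), section_id=section_id)


def extract_channel(img: RGBImage, channel: str) -> ChannelImage:
    """Return one colour plane of ``img`` exactly as stored.

    ``channel`` is one of ``red``, ``green``, ``blue``; the marker signal
    lives in the green plane, the nuclear counterstain in the blue one.
    """
    if channel not in CHANNEL_INDEX:
        raise InputError(f"channel must be one of {sorted(CHANNEL_INDEX)}, got {channel!r}")
    plane = img.pixels[:, :, CHANNEL_INDEX[channel]].copy()
    return ChannelImage(pixels=plane, channel_name=channel, section_id=img.section_id)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as a single-channel 8-bit image (0 / 255)."""
    path = Path(path)
    arr = (np.asarray(mask).astype(bool).astype(np.uint8)) * 255
    iio.imwrite(path, arr)
    return path


def write_results(
    tables: Mapping[str, pd.DataFrame],
    masks: Mapping[str, np.ndarray],
    outdir: str | Path,
) -> list[Path]:
    """Write result tables (CSV) and masks (PNG, 0/255) under ``outdir``.

    Returns the manifest: one path per file written.  Table keys become
    ``<key>.csv``, mask keys ``<key>.png``.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise InputError(f"output directory {outdir} is not writable: {exc}") from exc

    manifest: list[Path] = []
    for name, table in tables.items():
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False)
        manifest.append(path)
    for name, mask in masks.items():
        manifest.append(write_mask(mask, outdir / f"{name}.png"))
    return manifest


def read_metadata(path: str | Path) -> list[SectionMeta]:
    """Read a cohort metadata CSV.

    Required columns: ``section_id``, ``group_label``.  Any columns whose
    name starts with ``hscore_obs`` are collected (in column order) as
    observer HSCOREs; missing values are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"metadata file not found: {path}")
    df = pd.read_csv(path)
    for col in ("section_id", "group_label"):
        if col not in df.columns:
            raise InputError(f"{path}: metadata is missing required column {col!r}")
    obs_cols = [c for c in df.columns if c.startswith("hscore_obs")]
    records = []
    for _, row in df.iterrows():
        scores = tuple(
            float(row[c]) for c in obs_cols if pd.notna(row[c])
        )
        records.append(
            SectionMeta(
                section_id=str(row["section_id"]),
                group_label=str(row["group_label"]),
                observer_hscores=scores,
            )
        )
    ids = [r.section_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise InputError(f"{path}: duplicate section ids {sorted(dupes)}")
    return records
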