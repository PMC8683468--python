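"""Micrograph and sample-table I/O.

Images are plain numpy arrays: a grayscale micrograph is a 2-D ``uint8``
array (gray levels 0–255), a color micrograph an ``(H, W, 3)`` ``uint8``
array.  All downstream operators consume the 8-bit grayscale form; color
input is reduced with standard luma weights (Rec. 601), the convention of
common desktop image-analysis tools, so that masks are bit-stable across
platforms.

Sample tables are CSV files with header
``sample_id,mii,dcw,dilution_factor,time_h`` (extra columns pass through);
they carry one row per culture sample: the measured image-intensity
statistic (MII), the dry cell weight (DCW, mg/L) where available, and
optional dilution factor and culture time.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: Rec. 601 luma weights used for color -> grayscale reduction.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

SUPPORTED_EXTENSIONS = {".tif", ".tiff", ".png", ".jpg", ".jpeg", ".bmp"}

SAMPLE_COLUMNS = ["sample_id", "mii", "dcw", "dilution_factor", "time_h"]


class FormatError(ValueError):
    """Raised for rasters in an unsupported format."""


class ValidationError(ValueError):
    """Raised when a sample table violates its invariants."""


def _validate_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"grayscale image must be a non-empty 2-D array, got shape {img.shape}")
    return img


def to_grayscale(img: np.ndarray, weights: tuple[float, float, float] = LUMA_WEIGHTS) -> np.ndarray:
    """Reduce an ``(H, W, 3)`` color image to 8-bit grayscale.

    Per-pixel luminance ``L = round(wr*R + wg*G + wb*B)``, rounded half-up
    and clipped to [0, 255].  Equal-channel pixels map to their common
    value exactly, so gray round-trips are lossless.
    """
    img = np.asarray(img)
    if img.ndim == 2:
        return _validate_gray(img).astype(np.uint8)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) color image, got shape {img.shape}")
    luma = img[..., 0] * weights[0] + img[..., 1] * weights[1] + img[..., 2] * weights[2]
    # round-half-up so results do not depend on banker's rounding
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a raster micrograph as uint8.

    Returns an ``(H, W)`` array for single-channel input and ``(H, W, 3)``
    for color input (an alpha channel, if present, is dropped).  Inputs
    deeper than 8 bits are linearly rescaled onto [0, 255] by min-max,
    since real microscopes commonly emit 12/16-bit frames.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() not in SUPPORTED_EXTENSIONS:
        raise FormatError(f"unsupported raster format: {path.suffix!r}")
    img = np.asarray(iio.imread(path))
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    if img.dtype == np.uint8:
        return img
    img = img.astype(np.float64)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo) * 255.0
    else:
        # constant high-depth frame: map to the top of the 8-bit range
        img = np.full_like(img, 255.0 if hi > 0 else 0.0)
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


def write_image(path: str | os.PathLike, img: np.ndarray) -> None:
    """Write a uint8 image as PNG or TIFF (pixel-exact round-trip)."""
    path = Path(path)
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise FormatError(f"write supports PNG/TIFF only, got {path.suffix!r}")
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def read_sample_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a calibration-sample CSV and validate its invariants.

    Requires a header with ``sample_id`` plus at least one of ``mii`` /
    ``dcw``.  Unknown columns are preserved untouched.  Raises
    :class:`ValidationError` naming offending rows for duplicate ids,
    unparseable numeric cells, MII outside [0, 255] or negative DCW.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns or not ({"mii", "dcw"} & set(df.columns)):
        raise ValidationError(
            "sample table needs a 'sample_id' column and at least one of 'mii'/'dcw'"
        )
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample_id values: {sorted(set(dup))}")
    for col in ("mii", "dcw", "dilution_factor", "time_h"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                rows = [int(i) + 2 for i in bad]  # 1-based incl. header
                raise ValidationError(f"malformed numeric cells in column {col!r}, CSV rows {rows}")
            df[col] = coerced
    if "mii" in df.columns:
        bad = df["mii"].dropna()
        offenders = df.loc[bad.index[(bad < 0) | (bad > 255)], "sample_id"].tolist()
        if offenders:
            raise ValidationError(f"mii outside [0, 255] for samples: {offenders}")
    if "dcw" in df.columns:
        bad = df["dcw"].dropna()
        offenders = df.loc[bad.index[bad < 0], "sample_id"].tolist()
        if offenders:
            raise ValidationError(f"negative dcw for samples: {offenders}")
    return df


def write_sample_table(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
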