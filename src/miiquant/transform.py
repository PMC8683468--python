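"""Micrograph transformation chain producing the microscopic image
intensity (MII) statistic.

Bright-field micrographs of submerged fungal culture show dark mycelium
(hyphae, spores, pellets) on a bright, unevenly illuminated medium.  The
chain isolates the mycelium and reduces the frame to one scalar:

1. grayscale conversion (8-bit);
2. primary global threshold (default level 154, dark-on-bright: pixels
   ``<= level`` are provisional mycelium);
3. rolling-ball background subtraction — the smooth bright background is
   estimated morphologically and removed, inverting the signal to
   bright-on-dark;
4. quantile-based linear contrast stretch;
5. secondary threshold (default level 180 on the enhanced bright-on-dark
   image, ``>= level``), gated by the dilated primary mask;
6. median filtering of the enhanced image;
7. removal of connected components too small to be mycelium (specks);
8. zeroing of all non-mask pixels and measurement of the MII.

The MII of the transformed frame is its mean gray value; it rises with
mycelial coverage and is the independent variable of the downstream
calibration model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.restoration import rolling_ball

from .io import to_grayscale

DARK_ON_BRIGHT = "dark_on_bright"
BRIGHT_ON_DARK = "bright_on_dark"


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the transformation chain.

    Defaults follow the workflow the statistic was designed with: global
    thresholds 154 and 180, a 50 px rolling-ball radius, 0.35 % contrast
    saturation, 3x3 dilation, radius-1 median filter, and a 20 px floor on
    object area for speck rejection.
    """

    threshold_primary: int = 154
    threshold_secondary: int = 180
    foreground_polarity: str = DARK_ON_BRIGHT
    background_radius: int = 50
    contrast_saturation: float = 0.0035
    dilation_selem: str = "square3"
    median_radius: int = 1
    maxima_prominence: float = 10.0
    min_object_area: int = 20
    mii_mode: str = "whole_image"

    def __post_init__(self):
        for name in ("threshold_primary", "threshold_secondary"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must lie in [0, 255], got {v}")
        if self.background_radius < 1 or self.median_radius < 1:
            raise ValueError("background_radius and median_radius must be >= 1")
        if not (0.0 <= self.contrast_saturation < 0.5):
            raise ValueError("contrast_saturation must lie in [0, 0.5)")
        if self.foreground_polarity not in (DARK_ON_BRIGHT, BRIGHT_ON_DARK):
            raise ValueError(f"unknown polarity {self.foreground_polarity!r}")
        if self.dilation_selem not in ("square3", "cross3"):
            raise ValueError(f"unknown structuring element {self.dilation_selem!r}")
        if self.mii_mode not in ("whole_image", "mask_only"):
            raise ValueError(f"unknown mii_mode {self.mii_mode!r}")
        if self.min_object_area < 0 or self.maxima_prominence < 0:
            raise ValueError("min_object_area and maxima_prominence must be non-negative")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a flat ``key = value`` text file; unknown keys are rejected."""
        fields = {f: t for f, t in cls.__annotations__.items()}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                default = getattr(cls, key)
                if isinstance(default, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(value)
                elif isinstance(default, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Stable short hash of the configuration (key order independent)."""
        payload = ",".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class TransformResult:
    """Output of :func:`transform_image` for one micrograph."""

    transformed: np.ndarray  # uint8, background forced to 0
    mask: np.ndarray  # bool, same shape
    mii: float
    provenance: list[str] = field(default_factory=list)

    @property
    def mask_area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def provenance_hash(self) -> str:
        return hashlib.sha256("|".join(self.provenance).encode()).hexdigest()[:12]


def _check_level(level: int) -> None:
    if not (0 <= level <= 255):
        raise ValueError(f"threshold level must lie in [0, 255], got {level}")


def threshold(img: np.ndarray, level: int, polarity: str = DARK_ON_BRIGHT) -> np.ndarray:
    """Global threshold. dark_on_bright keeps pixels ``<= level``;
    bright_on_dark keeps pixels ``>= level`` (both boundaries inclusive)."""
    _check_level(level)
    img = np.asarray(img)
    if polarity == DARK_ON_BRIGHT:
        return img <= level
    if polarity == BRIGHT_ON_DARK:
        return img >= level
    raise ValueError(f"unknown polarity {polarity!r}")


def subtract_background(img: np.ndarray, radius: int = 50,
                        polarity: str = DARK_ON_BRIGHT) -> np.ndarray:
    """Rolling-ball background subtraction.

    For dark-on-bright frames the bright background is estimated by
    rolling a ball of the given radius under the inverted image and the
    result is ``background - image`` clipped to [0, 255]: mycelium comes
    out bright on a dark (zero) background.  For bright-on-dark frames
    the dark background is estimated directly and subtracted.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(img, dtype=np.uint8)
    work = 255 - img if polarity == DARK_ON_BRIGHT else img
    bg = rolling_ball(work, radius=radius)
    out = work.astype(np.int16) - bg.astype(np.int16)
    return np.clip(out, 0, 255).astype(np.uint8)


def enhance_contrast(img: np.ndarray, saturation: float = 0.0035) -> np.ndarray:
    """Linear stretch mapping the ``saturation`` and ``1 - saturation``
    intensity quantiles to 0 and 255; constant frames pass unchanged."""
    if not (0.0 <= saturation < 0.5):
        raise ValueError("saturation must lie in [0, 0.5)")
    img = np.asarray(img)
    lo = float(np.quantile(img, saturation))
    hi = float(np.quantile(img, 1.0 - saturation))
    if hi <= lo:
        return img.astype(np.uint8)
    stretched = (img.astype(np.float64) - lo) / (hi - lo) * 255.0
    return np.clip(np.floor(stretched + 0.5), 0, 255).astype(np.uint8)


_SELEMS = {
    "square3": np.ones((3, 3), dtype=bool),
    "cross3": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


def dilate(mask: np.ndarray, selem: str = "square3") -> np.ndarray:
    """Binary dilation with a 3x3 square or cross; out-of-bounds is background."""
    if selem not in _SELEMS:
        raise ValueError(f"unknown structuring element {selem!r}")
    return morphology.dilation(np.asarray(mask, dtype=bool), _SELEMS[selem])


def median_filter(img: np.ndarray, radius: int = 1) -> np.ndarray:
    """Sliding-window median over (2r+1)^2 neighborhoods, edge windows
    truncated to in-bounds pixels."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(img)
    # NaN-pad instead of reflect-pad so edge medians are taken over
    # in-bounds pixels only (padded copies must not vote)
    size = 2 * radius + 1
    h, w = img.shape
    padded = np.pad(img.astype(np.float64), radius, constant_values=np.nan)
    windows = np.stack([
        padded[di:di + h, dj:dj + w]
        for di in range(size)
        for dj in range(size)
    ])
    out = np.nanmedian(windows, axis=0)
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def remove_noise_objects(mask: np.ndarray, img: np.ndarray,
                         prominence: float = 10.0, min_area: int = 20) -> np.ndarray:
    """Drop mask components that are specks rather than mycelium.

    A component is removed when its pixel area is below ``min_area``
    (8-connectivity; a component of exactly ``min_area`` is kept), or when
    it consists of an isolated intensity peak whose prominence over the
    surrounding background exceeds ``prominence`` while covering fewer
    than 9 pixels (a bare impulse).  The result is always a subset of the
    input mask.
    """
    mask = np.asarray(mask, dtype=bool)
    img = np.asarray(img)
    if mask.shape != img.shape:
        raise ValueError("mask and image dimensions must agree")
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask.copy()
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = areas >= min_area
    if prominence > 0 and not mask.all():
        # impulse check: tiny single-peak components whose max stands
        # `prominence` above the local background are specks regardless
        # of min_area
        maxima = ndi.maximum(img, labels, index=np.arange(1, n + 1))
        bg = float(np.median(img[~mask]))
        speck = (areas < 9) & (maxima - bg > prominence)
        keep &= ~speck
    out = np.zeros_like(mask)
    keep_labels = np.flatnonzero(keep) + 1
    if len(keep_labels):
        out = np.isin(labels, keep_labels)
    return out & mask


def measure_mii(transformed: np.ndarray, mask: np.ndarray | None = None,
                mode: str = "whole_image") -> float:
    """Mean gray value of the transformed frame.

    ``whole_image`` averages over every pixel (background already zeroed),
    so the statistic grows with both brightness and coverage of mycelium;
    ``mask_only`` averages over mask pixels only (0 for an empty mask).
    """
    transformed = np.asarray(transformed, dtype=np.float64)
    if mode == "whole_image":
        return float(transformed.mean())
    if mode == "mask_only":
        if mask is None:
            raise ValueError("mask_only mode requires a mask")
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != transformed.shape:
            raise ValueError("mask and image dimensions must agree")
        return float(transformed[mask].mean()) if mask.any() else 0.0
    raise ValueError(f"unknown mii mode {mode!r}")


def transform_image(img: np.ndarray, cfg: PipelineConfig | None = None) -> TransformResult:
    """Run the full chain on one micrograph and measure its MII."""
    cfg = cfg or PipelineConfig()
    prov: list[str] = []

    def log(stage: str, **params):
        prov.append(stage + "(" + ",".join(f"{k}={v}" for k, v in sorted(params.items())) + ")")

    try:
        stage = "to_grayscale"
        gray = to_grayscale(img)
        log(stage)

        stage = "threshold_primary"
        provisional = threshold(gray, cfg.threshold_primary, cfg.foreground_polarity)
        log(stage, level=cfg.threshold_primary, polarity=cfg.foreground_polarity)

        stage = "subtract_background"
        signal = subtract_background(gray, cfg.background_radius, cfg.foreground_polarity)
        log(stage, radius=cfg.background_radius)

        stage = "enhance_contrast"
        enhanced = enhance_contrast(signal, cfg.contrast_saturation)
        log(stage, saturation=cfg.contrast_saturation)

        stage = "threshold_secondary"
        # after background subtraction the signal is bright-on-dark
        # regardless of input polarity
        secondary = threshold(enhanced, cfg.threshold_secondary, BRIGHT_ON_DARK)
        gate = dilate(provisional, cfg.dilation_selem)
        mask = secondary & gate
        log(stage, level=cfg.threshold_secondary, gate=cfg.dilation_selem)

        stage = "median_filter"
        smoothed = median_filter(enhanced, cfg.median_radius)
        log(stage, radius=cfg.median_radius)

        stage = "remove_noise_objects"
        mask = remove_noise_objects(mask, smoothed, cfg.maxima_prominence, cfg.min_object_area)
        log(stage, min_area=cfg.min_object_area, prominence=cfg.maxima_prominence)

        stage = "measure_mii"
        transformed = np.where(mask, smoothed, 0).astype(np.uint8)
        mii = measure_mii(transformed, mask, cfg.mii_mode)
        log(stage, mode=cfg.mii_mode)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    return TransformResult(transformed=transformed, mask=mask, mii=mii, provenance=prov)
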