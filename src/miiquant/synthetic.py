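"""Synthetic bright-field micrographs and calibration tables with known
ground truth.

Submerged fungal culture imaged in bright field shows dark objects on a
bright, unevenly illuminated medium: compact spores early in the
fermentation, elongated branching hyphae mid-course, and dense spherical
pellets late.  The generator renders these as, respectively, small
ellipses, correlated-random-walk polylines with per-step branching, and
clustered disks, over a background with a linear illumination ramp,
additive Gaussian read noise and impulse (pepper) specks.  Ground truth —
the object mask, per-object labels and the true object pixel count used
as the biomass proxy — is recorded before any noise is applied, so every
stage of the transformation pipeline and the downstream calibration
statistics can be tested without real data.

Morphology parameters (hyphal width, branch rate, spore radii, pellet
structure) are plausible round numbers for filamentous fungi at moderate
magnification; no attempt is made to match any particular instrument.
All generators are fully deterministic under their seed, with one
independent sub-stream per object class so that adding, say, pellets to a
spec does not perturb the hyphae already drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage import draw as skdraw
from skimage.morphology import dilation, disk

from .calibration import CalibrationSample

_STREAM_HYPHAE = 1
_STREAM_SPORES = 2
_STREAM_PELLETS = 3
_STREAM_NOISE = 4
_STREAM_SPECKS = 5


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic micrograph."""

    width: int = 256
    height: int = 256
    n_spores: int = 15
    n_hyphae: int = 12
    hypha_mean_length: float = 60.0
    branch_prob: float = 0.15
    hypha_width: int = 3
    n_pellets: int = 0
    pellet_radius: float = 12.0
    background_level: int = 200
    illumination_gradient: float = 30.0
    gaussian_noise_sd: float = 5.0
    salt_speck_count: int = 30
    foreground_level: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.foreground_level >= self.background_level:
            raise ValueError("foreground must be darker than background (dark-on-bright)")
        for name in ("n_spores", "n_hyphae", "n_pellets", "salt_speck_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.width < 1 or self.height < 1:
            raise ValueError("frame must be at least 1x1")


@dataclass
class SyntheticScene:
    """A rendered micrograph plus its ground truth."""

    image: np.ndarray  # uint8 (H, W)
    truth_mask: np.ndarray  # bool (H, W), pre-noise object pixels
    true_biomass_px: int
    object_labels: np.ndarray  # int32 (H, W), 0 = background
    spec: SceneSpec


def _stream(spec_seed: int, which: int) -> np.random.Generator:
    return np.random.default_rng([spec_seed, which])


def _draw_hypha(labels: np.ndarray, label_id: int, rng: np.random.Generator,
                spec: SceneSpec) -> None:
    """One hypha: a correlated random walk with per-step branching.

    Turning angles are Gaussian (sd 0.3 rad); each growth step may spawn
    a branch with probability ``branch_prob`` that inherits 60% of the
    remaining length.  Segments leaving the frame are clipped at the
    border.
    """
    h, w = labels.shape
    length = max(5.0, rng.normal(spec.hypha_mean_length, 0.3 * spec.hypha_mean_length))
    start = (rng.uniform(0, h), rng.uniform(0, w))
    heading = rng.uniform(0, 2 * math.pi)
    stack = [(start, heading, length)]
    step = 2.5
    while stack:
        (r, c), ang, remaining = stack.pop()
        while remaining > 0:
            ang += rng.normal(0.0, 0.3)
            r2 = r + step * math.sin(ang)
            c2 = c + step * math.cos(ang)
            rr, cc = skdraw.line(int(round(r)), int(round(c)),
                                 int(round(r2)), int(round(c2)))
            inb = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            labels[rr[inb], cc[inb]] = label_id
            if rng.random() < spec.branch_prob:
                stack.append(((r, c), ang + rng.choice([-1.0, 1.0]) * rng.normal(0.9, 0.2),
                              remaining * 0.6))
            r, c = r2, c2
            remaining -= step


def _draw_spore(labels: np.ndarray, label_id: int, rng: np.random.Generator) -> None:
    h, w = labels.shape
    r, c = rng.uniform(0, h), rng.uniform(0, w)
    r_rad = rng.uniform(3.0, 5.0)
    c_rad = r_rad * rng.uniform(0.7, 1.0)
    rr, cc = skdraw.ellipse(r, c, r_rad, c_rad, shape=labels.shape,
                            rotation=rng.uniform(0, math.pi))
    labels[rr, cc] = label_id


def _draw_pellet(labels: np.ndarray, label_id: int, rng: np.random.Generator,
                 radius: float) -> None:
    h, w = labels.shape
    r, c = rng.uniform(0, h), rng.uniform(0, w)
    rr, cc = skdraw.disk((r, c), radius, shape=labels.shape)
    labels[rr, cc] = label_id
    # fuzzy rim of satellite disks, mimicking hyphae radiating off the core
    for _ in range(18):
        ang = rng.uniform(0, 2 * math.pi)
        d = rng.uniform(0.8, 1.4) * radius
        rr, cc = skdraw.disk((r + d * math.sin(ang), c + d * math.cos(ang)),
                             max(1.5, radius * 0.2), shape=labels.shape)
        labels[rr, cc] = label_id


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one micrograph from its spec (deterministic under seed)."""
    h, w = spec.height, spec.width
    labels = np.zeros((h, w), dtype=np.int32)

    next_id = 1
    rng = _stream(spec.seed, _STREAM_HYPHAE)
    skeleton = np.zeros((h, w), dtype=np.int32)
    for _ in range(spec.n_hyphae):
        _draw_hypha(skeleton, next_id, rng, spec)
        next_id += 1
    if spec.hypha_width > 1:
        # thicken skeletons to the requested width (approximate, odd widths exact)
        grown = dilation(skeleton > 0, disk(max(1, spec.hypha_width // 2)))
        # nearest-label fill for the grown rim
        from scipy import ndimage as ndi
        if skeleton.any():
            _, (ir, ic) = ndi.distance_transform_edt(skeleton == 0, return_indices=True)
            labels[grown] = skeleton[ir[grown], ic[grown]]
    else:
        labels[skeleton > 0] = skeleton[skeleton > 0]

    rng = _stream(spec.seed, _STREAM_SPORES)
    for _ in range(spec.n_spores):
        _draw_spore(labels, next_id, rng)
        next_id += 1

    rng = _stream(spec.seed, _STREAM_PELLETS)
    for _ in range(spec.n_pellets):
        _draw_pellet(labels, next_id, rng, spec.pellet_radius)
        next_id += 1

    truth = labels > 0

    col = np.linspace(-0.5, 0.5, w)[None, :]
    image = np.full((h, w), float(spec.background_level)) + spec.illumination_gradient * col
    # mild per-object intensity variation keeps objects from being a flat field
    if truth.any():
        rng = _stream(spec.seed, _STREAM_NOISE)
        jitter = rng.normal(0.0, 5.0, size=next_id)
        image[truth] = spec.foreground_level + jitter[labels[truth]]
        noise = rng.normal(0.0, spec.gaussian_noise_sd, size=(h, w))
    else:
        rng = _stream(spec.seed, _STREAM_NOISE)
        noise = rng.normal(0.0, spec.gaussian_noise_sd, size=(h, w))
    image += noise

    rng = _stream(spec.seed, _STREAM_SPECKS)
    for _ in range(spec.salt_speck_count):
        r, c = rng.integers(0, h), rng.integers(0, w)
        image[r, c] = 0.0  # impulse (pepper) speck, dark like mycelium

    image = np.clip(np.floor(image + 0.5), 0, 255).astype(np.uint8)
    return SyntheticScene(image=image, truth_mask=truth,
                          true_biomass_px=int(truth.sum()),
                          object_labels=labels, spec=spec)


def _derived_seed(seed: int, k: int) -> int:
    return (seed * 100003 + k) % (2 ** 31)


def generate_growth_series(base: SceneSpec, stages: int) -> list[SyntheticScene]:
    """Scenes emulating a fermentation time course.

    Composition shifts from spore-dominated through elongated hyphae to
    pellet-containing late stages; true biomass is made monotonically
    non-decreasing across stages (densification is enforced, mirroring
    growth, by adding hyphae to any stage that would otherwise regress).
    """
    if stages < 2:
        raise ValueError("need at least 2 stages")
    scenes: list[SyntheticScene] = []
    prev_biomass = -1
    for t in range(stages):
        frac = t / (stages - 1)
        spec_t = replace(
            base,
            n_spores=int(round(base.n_spores * (1.0 + 1.5 * (1.0 - frac)))),
            n_hyphae=int(round(base.n_hyphae * (0.15 + 1.85 * frac))),
            n_pellets=base.n_pellets if frac > 0.6 else 0,
            seed=_derived_seed(base.seed, t),
        )
        scene = generate_scene(spec_t)
        while scene.true_biomass_px < prev_biomass:
            spec_t = replace(spec_t, n_hyphae=spec_t.n_hyphae + 2)
            scene = generate_scene(spec_t)
        prev_biomass = scene.true_biomass_px
        scenes.append(scene)
    return scenes


@dataclass
class SyntheticCalibration:
    """MII–DCW pairs drawn from the linear calibration model."""

    samples: list[CalibrationSample]
    true_beta0: float
    true_beta1: float
    noise_sd: float
    seed: int


def generate_calibration(n: int = 30,
                         beta0: float = 70.095,
                         beta1: float = 5.982,
                         mii_range: tuple[float, float] = (20.0, 70.0),
                         noise_sd: float = 22.0,
                         seed: int = 0) -> SyntheticCalibration:
    """Draw MII uniformly and DCW from the calibration line plus noise.

    Defaults place the simulation in the regime of a real fermentation
    calibration: intercept ~70 mg/L, slope ~6 mg/L per intensity unit,
    intensities spanning 20–70, and residual noise giving R² near 0.94.
    DCW is truncated at zero (a dry weight cannot be negative).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    lo, hi = mii_range
    if not (0.0 <= lo < hi <= 255.0):
        raise ValueError("mii_range must be an increasing interval within [0, 255]")
    rng = np.random.default_rng(seed)
    mii = rng.uniform(lo, hi, size=n)
    dcw = np.maximum(0.0, beta0 + beta1 * mii + rng.normal(0.0, noise_sd, size=n))
    samples = [CalibrationSample(f"sim{i:03d}", float(m), float(d))
               for i, (m, d) in enumerate(zip(mii, dcw))]
    return SyntheticCalibration(samples, beta0, beta1, noise_sd, seed)


#: SceneSpec emulating one field of view of an undiluted fermentation
#: sample: far too dense to image directly (hence dilution), rendered
#: small and thin so that Poisson-thinned dilutions stay renderable.
DILUTION_BASE = SceneSpec(
    width=96, height=96,
    n_spores=0, n_hyphae=600, hypha_mean_length=8.0, branch_prob=0.05,
    hypha_width=1, n_pellets=0, salt_speck_count=0,
    gaussian_noise_sd=5.0, seed=0,
)


def scene_to_dilution_samples(base: SceneSpec = DILUTION_BASE,
                              factors: Sequence[float] = (2, 5, 10, 100, 1000),
                              replicates: int = 100,
                              mii_gain: float = 80.0,
                              read_noise_sd: float = 2.0,
                              seed: int = 0) -> list[CalibrationSample]:
    """Emulate the dilution experiment: image diluted aliquots, rescale.

    For each dilution factor and replicate, a culture of relative biomass
    ``m`` (ramped over [0.6, 1.6]) is diluted 1/factor and one field of
    view of the aliquot is rendered; dilution is modelled as Poisson
    thinning of the object counts (an undiluted aliquot, factor 1, keeps
    its counts deterministically).  The measured MII is the rendered
    object density (coverage linearized for overlap) rescaled back by the
    factor, plus Gaussian read noise, while
    the true DCW follows the bulk (undiluted) biomass.  Because a
    strongly diluted field holds very few objects, rescaling amplifies
    field-sampling noise in proportion to ``factor/sqrt(count)`` — so
    per-group calibration quality degrades mechanically as the factor
    grows, which is the phenomenon the dilution analysis quantifies.
    """
    if replicates < 3:
        raise ValueError("need at least 3 replicates per factor")
    rng = np.random.default_rng([seed, 17])
    total_px = base.width * base.height
    ramp = np.linspace(0.6, 1.6, replicates)
    samples: list[CalibrationSample] = []
    k = 0
    for f in factors:
        if f <= 0:
            raise ValueError("dilution factors must be positive")
        for i, m in enumerate(ramp):
            lam_h, lam_s = base.n_hyphae * m / f, base.n_spores * m / f
            if f == 1:
                n_hyphae, n_spores = int(round(lam_h)), int(round(lam_s))
            else:
                n_hyphae, n_spores = int(rng.poisson(lam_h)), int(rng.poisson(lam_s))
            spec_i = replace(base, n_hyphae=n_hyphae, n_spores=n_spores,
                             seed=_derived_seed(seed, k))
            scene = generate_scene(spec_i)
            coverage = scene.true_biomass_px / total_px
            # Boolean-model linearization: overlapping objects saturate raw
            # coverage, so -ln(1 - coverage) recovers a density proportional
            # to the amount of mycelium deposited in the field
            density = -math.log1p(-min(coverage, 0.99))
            mii = density * f * mii_gain + rng.normal(0.0, read_noise_sd)
            mii = float(np.clip(mii, 0.0, 255.0))
            # true biomass of the undiluted culture, as DCW in mg/L
            dcw = float(600.0 * m)
            samples.append(CalibrationSample(f"d{f:g}_{i:03d}", mii, dcw,
                                             dilution_factor=float(f)))
            k += 1
    return samples
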