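"""Synthetic microscopy degradations: shot noise, blur and undersampling.

Three degradation protocols are used both for training-time sampling and
for building calibrated test sets:

* **denoise** — Poisson shot noise.  The image (normalized to [0, 1]) is
  multiplied by a per-image photon-scale ``s``, a Poisson sample is drawn
  and divided back by ``s``, so the expectation equals the input and the
  per-pixel variance is I/s.  ``s`` is drawn from a gamma law with shape
  ``alpha`` = 4.0 and **rate** ``beta`` (mean alpha/beta).  The rate
  convention puts the mode-specific defaults in the right severity order:
  beta = 0.7 (denoising, mean s ~ 5.7, severe noise), 0.1 (deblurring,
  mean s = 40) and 0.03 (upsampling, mean s ~ 133, mild noise).
* **deblur** — isotropic Gaussian blur with s.d. drawn uniformly from 1-10
  px, scaled by (object diameter / 30); mild noise added on top.
* **upsample** — pre-blur with s.d. 0.4x the factor, decimation by an
  integer factor (every f-th pixel, phase 0), bilinear re-expansion to the
  original size; mild noise added on top.

Noise, blur and downsampling each fire with probability 0.8 in their
protocol; mode ``"all"`` picks one protocol per image with probability 1/3
each; mode ``"aniso"`` degrades the y (axial) direction only, with blur in
x ten times smaller.  The execution order is fixed: blur -> downsample ->
noise -> percentile normalization (noise is applied last before the final
normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .simcells import LabeledImage

#: default gamma rate beta per protocol
BETA_DEFAULTS = {"denoise": 0.7, "deblur": 0.1, "upsample": 0.03, "aniso": 0.1}
GAMMA_ALPHA = 4.0

MODES = ("denoise", "deblur", "upsample", "all", "aniso")


class DegenerateIntensityError(ValueError):
    """Raised when an image's 1st and 99th intensity percentiles coincide."""


@dataclass
class DegradationSpec:
    """Fully resolved degradation parameters for one image."""

    mode: str = "denoise"
    apply_noise: bool = False
    poisson_scale: float = 1.0
    apply_blur: bool = False
    blur_sigma_y: float = 0.0
    blur_sigma_x: float = 0.0
    apply_downsample: bool = False
    ds_factor: int = 1
    ds_axial_only: bool = False
    pre_blur_sigma: float = 0.0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.apply_downsample and self.ds_factor < 2:
            raise ValueError("ds_factor must be >= 2 when downsampling")
        if self.blur_sigma_y < 0 or self.blur_sigma_x < 0:
            raise ValueError("blur sigmas must be nonnegative")
        if self.apply_noise and not self.poisson_scale > 0:
            raise ValueError("poisson_scale must be positive when noise applies")


@dataclass
class DegradeConfig:
    """Sampling distribution over degradations for one training protocol."""

    mode: str = "denoise"
    alpha: float = GAMMA_ALPHA
    beta: float | None = None  # None -> protocol default
    p_noise: float = 0.8
    p_blur: float = 0.8
    p_downsample: float = 0.8
    blur_range: tuple = (1.0, 10.0)
    ds_range: tuple = (2, 7)
    pre_blur_coef: float = 0.4
    diameter_ref: float = 30.0
    aniso_blur_range: tuple = (1.0, 18.0)
    aniso_ds_range: tuple = (2, 12)
    aniso_pre_blur_coef: float = 0.5

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        for p in (self.p_noise, self.p_blur, self.p_downsample):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.blur_range[0] > self.blur_range[1] or self.ds_range[0] > self.ds_range[1]:
            raise ValueError("ranges must be ordered")

    def beta_for(self, mode: str) -> float:
        return self.beta if self.beta is not None else BETA_DEFAULTS[mode]


# -- primitives ------------------------------------------------------------

def normalize_percentile(image: np.ndarray) -> np.ndarray:
    """Map the 1st intensity percentile to 0 and the 99th to 1; clip below 0.

    Values above 1 are retained (no upper clip).  Raises
    :class:`DegenerateIntensityError` on a constant intensity range.
    """
    image = np.asarray(image, dtype=np.float64)
    q01, q99 = np.percentile(image, [1, 99])
    if not q99 > q01:
        raise DegenerateIntensityError("1st and 99th percentiles coincide")
    out = (image - q01) / (q99 - q01)
    return np.maximum(out, 0.0, out=out).astype(np.float32)


def add_poisson_noise(image: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Return Poisson(scale * I) / scale per pixel (channels independent)."""
    image = np.asarray(image)
    if not scale > 0:
        raise ValueError("scale must be positive")
    if np.any(image < 0):
        raise ValueError("image must be nonnegative; clip before adding shot noise")
    return (rng.poisson(scale * image) / scale).astype(np.float32)


def sample_poisson_scale(
    rng: np.random.Generator, alpha: float = GAMMA_ALPHA, beta: float = BETA_DEFAULTS["denoise"]
) -> float:
    """Draw the photon scale s ~ Gamma(shape=alpha, rate=beta), mean alpha/beta."""
    if not (alpha > 0 and beta > 0):
        raise ValueError("alpha and beta must be positive")
    return float(rng.gamma(shape=alpha, scale=1.0 / beta))


def gaussian_blur(image: np.ndarray, sigma_y: float, sigma_x: float) -> np.ndarray:
    """Gaussian convolution with reflective boundary; sigma 0 is the identity."""
    if sigma_y < 0 or sigma_x < 0:
        raise ValueError("sigmas must be nonnegative")
    image = np.asarray(image, dtype=np.float32)
    sigma = (sigma_y, sigma_x) + (0,) * (image.ndim - 2)
    return ndi.gaussian_filter(image, sigma=sigma, mode="reflect")


def decimate(image: np.ndarray, factor: int, axial_only: bool = False) -> np.ndarray:
    """Subsample every ``factor``-th pixel starting at index 0."""
    if axial_only:
        return image[::factor]
    return image[::factor, ::factor]


def downsample_upsample(
    image: np.ndarray,
    factor: int,
    pre_blur_sigma: float | None = None,
    axial_only: bool = False,
) -> np.ndarray:
    """Blur, decimate by an integer factor, then bilinearly resize back.

    ``pre_blur_sigma`` defaults to 0.4 * factor (the training convention;
    test generation uses 0.5 * factor).
    """
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape[:2]
    if factor < 2:
        raise ValueError("factor must be an integer >= 2")
    if factor > min(h, w) / 4:
        raise ValueError(f"factor {factor} too large for shape {(h, w)}")
    if pre_blur_sigma is None:
        pre_blur_sigma = 0.4 * factor
    if pre_blur_sigma > 0:
        sy = pre_blur_sigma
        sx = 0.0 if axial_only else pre_blur_sigma
        image = gaussian_blur(image, sy, sx)
    small = decimate(image, factor, axial_only=axial_only)
    return resize(
        small, image.shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True
    ).astype(np.float32)


# -- sampling --------------------------------------------------------------

def sample_degradation(
    config: DegradeConfig, diameter: float, rng: np.random.Generator
) -> DegradationSpec:
    """Resolve one concrete :class:`DegradationSpec` from a protocol config."""
    mode = config.mode
    if mode == "all":
        mode = ("denoise", "deblur", "upsample")[int(rng.integers(3))]

    spec = DegradationSpec(mode=mode)
    diam_scale = diameter / config.diameter_ref

    if mode == "aniso":
        if rng.random() < config.p_downsample:
            spec.apply_downsample = True
            spec.ds_axial_only = True
            lo, hi = config.aniso_ds_range
            spec.ds_factor = int(rng.integers(lo, hi + 1))
            spec.pre_blur_sigma = config.aniso_pre_blur_coef * spec.ds_factor
        elif rng.random() < config.p_blur:
            spec.apply_blur = True
            sy = rng.uniform(*config.aniso_blur_range) * diam_scale
            spec.blur_sigma_y, spec.blur_sigma_x = sy, sy / 10.0
    else:
        if mode == "deblur" and rng.random() < config.p_blur:
            spec.apply_blur = True
            s = rng.uniform(*config.blur_range) * diam_scale
            spec.blur_sigma_y = spec.blur_sigma_x = s
        if mode == "upsample" and rng.random() < config.p_downsample:
            spec.apply_downsample = True
            lo, hi = config.ds_range
            spec.ds_factor = int(rng.integers(lo, hi + 1))
            spec.pre_blur_sigma = config.pre_blur_coef * spec.ds_factor

    if rng.random() < config.p_noise:
        spec.apply_noise = True
        spec.poisson_scale = sample_poisson_scale(rng, config.alpha, config.beta_for(mode))
    return spec


def apply_degradation(
    labeled: LabeledImage | np.ndarray,
    spec: DegradationSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Execute a resolved spec: blur -> downsample -> noise -> normalize.

    Masks are never touched; only the degraded image is returned.  With all
    flags off this reduces to :func:`normalize_percentile`.
    """
    image = labeled.image if isinstance(labeled, LabeledImage) else np.asarray(labeled)
    out = normalize_percentile(image)
    if spec.apply_blur:
        out = gaussian_blur(out, spec.blur_sigma_y, spec.blur_sigma_x)
    if spec.apply_downsample:
        out = downsample_upsample(
            out, spec.ds_factor, pre_blur_sigma=spec.pre_blur_sigma, axial_only=spec.ds_axial_only
        )
    if spec.apply_noise:
        if rng is None:
            raise ValueError("rng is required when the spec applies noise")
        out = add_poisson_noise(np.maximum(out, 0.0), spec.poisson_scale, rng)
    return normalize_percentile(out)


# -- test-time calibration -------------------------------------------------

#: search ranges for calibrated test degradation
CALIB_POISSON_RANGE = (0.5, 80.0)
CALIB_BLUR_RANGE = (0.5, 10.0)
CALIB_DS_RANGE = (2, 6)
CALIB_BLUR_NOISE_SCALE = 120.0


class CalibrationError(RuntimeError):
    """Raised when the reference segmenter scores zero on the clean image."""


def _spec_for_level(mode: str, level: float) -> DegradationSpec:
    if mode == "denoise":
        return DegradationSpec(mode=mode, apply_noise=True, poisson_scale=float(level))
    if mode == "deblur":
        return DegradationSpec(
            mode=mode,
            apply_blur=True,
            blur_sigma_y=float(level),
            blur_sigma_x=float(level),
            apply_noise=True,
            poisson_scale=CALIB_BLUR_NOISE_SCALE,
        )
    if mode == "upsample":
        f = int(round(level))
        return DegradationSpec(
            mode=mode, apply_downsample=True, ds_factor=f, pre_blur_sigma=0.5 * f
        )
    raise ValueError(f"calibration not defined for mode {mode!r}")


def calibrate_test_degradation(
    labeled: LabeledImage,
    segmenter,
    mode: str = "denoise",
    target_ratio: float = 0.5,
    rng: np.random.Generator | None = None,
    n_grid: int = 12,
    n_refine: int = 3,
    n_repeats: int = 2,
):
    """Find the degradation level halving (by default) the segmenter's AP@0.5.

    ``segmenter`` is a callable ``(image, diameter) -> masks``.  The search
    is a geometric grid over the severity parameter within the published
    ranges (Poisson scale 0.5-80, blur s.d. 0.5-10, factor 2-6) followed by
    bisection refinements on continuous parameters; the segmenter AP ratio
    is monotone in severity up to sampling noise, and each level is scored
    as the mean over ``n_repeats`` independent noise draws to smooth the
    quantization of per-image AP.  Returns
    ``(degraded image, spec, achieved_ratio)`` where ``achieved_ratio`` is
    the selected level's mean ratio.
    """
    from .evalmetrics import match_and_score

    if rng is None:
        rng = np.random.default_rng(0)
    clean = normalize_percentile(labeled.image)
    clean_ap = match_and_score(segmenter(clean, labeled.diameter), labeled.masks, 0.5).ap
    if clean_ap <= 0:
        raise CalibrationError("reference segmenter scores AP 0 on the clean image")

    if target_ratio >= 1.0:
        # no-degradation limit: mildest level in range
        level = CALIB_POISSON_RANGE[1] if mode == "denoise" else (
            CALIB_BLUR_RANGE[0] if mode == "deblur" else CALIB_DS_RANGE[0]
        )
        spec = _spec_for_level(mode, level)
        return apply_degradation(labeled, spec, rng), spec, 1.0

    def ratio_at(level: float) -> float:
        spec = _spec_for_level(mode, level)
        ratios = []
        for _ in range(n_repeats):
            deg = apply_degradation(labeled, spec, np.random.default_rng(rng.integers(2**31)))
            ap = match_and_score(segmenter(deg, labeled.diameter), labeled.masks, 0.5).ap
            ratios.append(ap / clean_ap)
        return float(np.mean(ratios))

    if mode == "upsample":
        levels = list(range(CALIB_DS_RANGE[0], CALIB_DS_RANGE[1] + 1))
        refine = 0
    else:
        lo, hi = CALIB_POISSON_RANGE if mode == "denoise" else CALIB_BLUR_RANGE
        levels = list(np.geomspace(lo, hi, n_grid))
        refine = n_refine

    evals = [(lvl, ratio_at(lvl)) for lvl in levels]
    for _ in range(refine):
        evals.sort(key=lambda e: abs(e[1] - target_ratio))
        best = evals[0][0]
        ordered = sorted(lvl for lvl, _ in evals)
        i = ordered.index(best)
        for nb in (ordered[max(i - 1, 0)], ordered[min(i + 1, len(ordered) - 1)]):
            mid = float(np.sqrt(best * nb))
            if all(abs(mid - lvl) > 1e-9 for lvl, _ in evals):
                evals.append((mid, ratio_at(mid)))

    best_level, achieved = min(evals, key=lambda e: abs(e[1] - target_ratio))
    spec = _spec_for_level(mode, best_level)
    degraded = apply_degradation(labeled, spec, np.random.default_rng(rng.integers(2**31)))
    return degraded, spec, float(achieved)
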