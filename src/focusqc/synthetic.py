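"""Synthetic through-focus stacks and analytic fixture curves.

The generator emulates what a focus sweep of a near-planar textured object
produces: a fixed base texture blurred with a defocus-dependent Gaussian
kernel whose width is minimal at the ground-truth focus frame k0,

    sigma(k) = sigma_min + rate * |k - k0|,

optionally corrupted per frame by additive white Gaussian noise (AWGN) of a
stated variance on the 0-255 gray-level scale.  Under this model every
gradient-family operator's focus curve is unimodal with its peak at (or
within rounding of) k0, which is the morphology the steep/gradual
segmentation assumes.

Randomness is reproducible: one master seed spawns independent child streams
for the texture and for each frame's noise, so changing the noise variance
never changes the base texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .curve import FocalStack, FocusCurve
from .exceptions import ConfigError

__all__ = [
    "SyntheticStackConfig",
    "generate_texture",
    "generate_focal_stack",
    "add_awgn",
    "generate_fixture_curve",
    "generate_unimodal_curve",
    "FIXTURE_NAMES",
]

GRAY_MAX = 255.0


@dataclass
class SyntheticStackConfig:
    """Parameters of a synthetic focal stack.

    Defaults give a 41-frame sweep of a 128 x 128 filtered-noise texture with
    exact focus at the central frame and blur growing by 0.15 px of Gaussian
    width per frame of defocus — a stack on which all twelve operators
    recover the focus frame.
    """

    seed: int = 0
    n_frames: int = 41
    k0: float = 21.0
    d: Optional[float] = None
    texture: str = "filtered-noise"  # filtered-noise | checker | blobs
    size: Tuple[int, int] = (128, 128)
    smoothness: float = 1.5  # texture correlation length, px
    sigma_min: float = 0.0  # blur width at exact focus, px
    rate: float = 0.15  # blur growth per frame of defocus, px/frame
    noise_variance: float = 0.0  # AWGN variance, gray-level^2 (0-255 scale)

    def __post_init__(self):
        if self.n_frames < 11:
            raise ConfigError(f"n_frames = {self.n_frames} must be at least 11")
        if not (1 <= self.k0 <= self.n_frames):
            raise ConfigError(f"k0 = {self.k0} outside [1, {self.n_frames}]")
        if self.sigma_min < 0:
            raise ConfigError(f"sigma_min = {self.sigma_min} must be >= 0")
        if self.rate <= 0:
            raise ConfigError(f"rate = {self.rate} must be > 0")
        if self.noise_variance < 0:
            raise ConfigError(f"noise_variance = {self.noise_variance} must be >= 0")
        if self.d is not None and self.d <= 0:
            raise ConfigError(f"d = {self.d} must be positive when given")
        m, nc = self.size
        # 4-sigma truncated kernel must fit in the frame
        sigma_max = self.sigma_min + self.rate * max(
            self.k0 - 1, self.n_frames - self.k0
        )
        if 8 * sigma_max + 1 > min(m, nc):
            raise ConfigError(
                f"maximum blur width {sigma_max:.3g} px needs a kernel wider "
                f"than the {m}x{nc} frame; reduce rate/n_frames or enlarge size"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size"] = list(self.size)
        return d


def generate_texture(config: SyntheticStackConfig) -> np.ndarray:
    """Base (in-focus) texture on the 0-255 gray scale, deterministic in seed."""
    m, nc = config.size
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    kind = config.texture
    if kind == "filtered-noise":
        raw = rng.standard_normal((m, nc))
        img = ndimage.gaussian_filter(raw, config.smoothness, mode="reflect")
    elif kind == "checker":
        period = max(2, int(round(2 * config.smoothness)))
        yy, xx = np.mgrid[0:m, 0:nc]
        img = (((yy // period) + (xx // period)) % 2).astype(float)
        img = img + 0.05 * rng.standard_normal((m, nc))  # break exact flatness
    elif kind == "blobs":
        img = np.zeros((m, nc))
        n_blobs = max(10, m * nc // 256)
        rows = rng.integers(0, m, n_blobs)
        cols = rng.integers(0, nc, n_blobs)
        img[rows, cols] = rng.uniform(0.5, 1.0, n_blobs)
        img = ndimage.gaussian_filter(img, config.smoothness, mode="reflect")
    else:
        raise ConfigError(f"unknown texture kind {kind!r}")
    lo, hi = img.min(), img.max()
    if hi <= lo:
        raise ConfigError(f"texture kind {kind!r} produced a constant image")
    return (img - lo) / (hi - lo) * GRAY_MAX


def add_awgn(image, variance: float, seed) -> np.ndarray:
    """Add zero-mean Gaussian noise of the given variance (gray-level^2).

    Intensities stay real-valued (no re-quantization) and are clipped to the
    sensor range [0, 255].  ``seed`` may be an int, SeedSequence or Generator.
    Variance 0 returns the input unchanged.
    """
    if variance < 0:
        raise ConfigError(f"noise variance must be >= 0, got {variance}")
    arr = np.asarray(image, dtype=float)
    if variance == 0:
        return arr
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = arr + rng.normal(0.0, np.sqrt(variance), arr.shape)
    return np.clip(noisy, 0.0, GRAY_MAX)


def _blur_widths(config: SyntheticStackConfig) -> np.ndarray:
    k = np.arange(1, config.n_frames + 1, dtype=float)
    return config.sigma_min + config.rate * np.abs(k - config.k0)


def generate_focal_stack(
    config: SyntheticStackConfig, texture: Optional[np.ndarray] = None
) -> FocalStack:
    """Through-focus stack: the base texture under the defocus blur law, plus
    AWGN when ``config.noise_variance`` > 0.

    Frame k is the texture convolved with a Gaussian kernel of width
    sigma(k) (truncated at 4 sigma, unit sum; sigma = 0 is the identity).
    Identical config and seed give a bit-identical stack.
    """
    if texture is None:
        texture = generate_texture(config)
    sigmas = _blur_widths(config)
    noise_streams = np.random.SeedSequence(config.seed).spawn(1 + config.n_frames)[1:]
    frames = np.empty((config.n_frames, *texture.shape))
    for i, sigma in enumerate(sigmas):
        frame = (
            texture
            if sigma == 0
            else ndimage.gaussian_filter(texture, sigma, mode="reflect", truncate=4.0)
        )
        if config.noise_variance > 0:
            frame = add_awgn(
                frame, config.noise_variance, np.random.default_rng(noise_streams[i])
            )
        frames[i] = frame
    return FocalStack(frames=frames, d=config.d)


# ---------------------------------------------------------------------------
# Analytic fixture curves

FIXTURE_NAMES = ("tent", "reference_R", "plateau", "symmetric_peak")

_REFERENCE_R = (0.10, 0.11, 0.12, 0.40, 0.70, 1.00, 0.70, 0.40, 0.12, 0.11, 0.10)


def generate_fixture_curve(name: str, d: Optional[float] = None, **params) -> FocusCurve:
    """Named analytic focus-curve fixtures.

    * ``tent`` — flat zero tails with a linear peak; exact corner cutoffs but
      a degenerate (zero) gradual fluctuation.  Params: ``half_width`` (flank
      length, default 2), ``tail`` (flat samples per side, default 4),
      ``slope`` (default 1.0).
    * ``reference_R`` — an 11-point unimodal curve with gently rising tails
    　and linear flanks; every metric is finite on it.
    * ``plateau`` — a curve that never falls to half maximum (FWHM is NaN).
    * ``symmetric_peak`` — random curve with level peak neighbours, so
      Cp = 2 Sp at d = 1.  Params: ``seed``, ``n`` (odd, default 11).
    """
    if name == "tent":
        half_width = int(params.pop("half_width", 2))
        tail = int(params.pop("tail", 4))
        slope = float(params.pop("slope", 1.0))
        if params:
            raise ConfigError(f"unknown tent params {sorted(params)}")
        if half_width < 1 or tail < 0:
            raise ConfigError("tent needs half_width >= 1 and tail >= 0")
        rise = slope * np.arange(1, half_width + 1)
        fall = rise[-2::-1] if half_width > 1 else np.empty(0)
        values = np.concatenate([np.zeros(tail), rise, fall, np.zeros(tail)])
    elif name == "reference_R":
        if params:
            raise ConfigError(f"reference_R takes no params, got {sorted(params)}")
        values = np.array(_REFERENCE_R)
    elif name == "plateau":
        if params:
            raise ConfigError(f"plateau takes no params, got {sorted(params)}")
        values = np.array([0.8, 0.9, 1.0, 0.9, 0.8])
    elif name == "symmetric_peak":
        seed = params.pop("seed", 0)
        n = int(params.pop("n", 11))
        if params:
            raise ConfigError(f"unknown symmetric_peak params {sorted(params)}")
        if n < 5 or n % 2 == 0:
            raise ConfigError("symmetric_peak needs odd n >= 5")
        rng = np.random.default_rng(seed)
        half = np.sort(rng.uniform(0.05, 0.95, (n - 1) // 2))
        values = np.concatenate([half, [1.0], half[::-1]])
    else:
        raise ConfigError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    return FocusCurve(values=values, d=d)


def generate_unimodal_curve(seed, m: int = 3, noise: float = 0.0) -> FocusCurve:
    """Random single-peak curve with the steep-flank / flat-tail morphology.

    Each flank has a gently and strictly monotone tail (small per-step slope)
    and a much steeper linear rise to the unique peak; flank lengths, levels
    and slopes are drawn at random.  ``m`` guarantees tails and flanks long
    enough for an m-point segmentation; ``noise`` adds uniform jitter of that
    amplitude to the tail samples (kept well below the steep rise).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def flank():
        tail_len = int(rng.integers(m + 1, m + 5))
        steep_len = int(rng.integers(m, m + 3))
        tail_level = rng.uniform(0.02, 0.15)
        tail_slope = rng.uniform(0.002, 0.015)
        tail = tail_level + tail_slope * np.arange(tail_len)
        steep_slope = rng.uniform(0.2, 0.6)
        steep = tail[-1] + steep_slope * np.arange(1, steep_len + 1)
        if noise > 0:
            tail = tail + rng.uniform(0.0, noise, tail_len)
        return np.concatenate([tail, steep])

    left = flank()
    right = flank()
    peak = max(left[-1], right[-1]) + rng.uniform(0.05, 0.3)
    values = np.concatenate([left, [peak], right[::-1]])
    return FocusCurve(values=values)
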