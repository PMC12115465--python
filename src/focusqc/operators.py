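"""Focus measure operators (FMOs).

Each operator maps a 2-D grayscale image to a single scalar sharpness score
that is maximal near best focus.  Twelve classical operators are provided in
three families:

* spatial (gradient-based): SMD, Roberts, Tenengrad, Brenner, EOG, EOL, SML
* statistical: Variance, Vollath's autocorrelation
* frequency: FFT (weighted power spectrum), DCT, DWT (DB6 detail energy)

Conventions
-----------
``x`` indexes rows (1..M) and ``y`` indexes columns (1..Nc); Brenner and
Vollath's therefore difference along rows.  Summation ranges follow the
defining double sums exactly: boundary pixels outside a stencil's range
contribute nothing, and no padding is applied anywhere.  Intensities are kept
as real numbers (images are not re-quantized after e.g. noise injection).

All operators return non-negative values except Vollath's, whose
autocorrelation difference may be negative on blurred or noisy content.
"""

from __future__ import annotations

import logging
from typing import Callable, Dict, List, Tuple

import numpy as np
import pywt
from scipy import fft as _fft
from scipy.signal import correlate2d

from .exceptions import OperatorSizeError

__all__ = [
    "smd",
    "roberts",
    "tenengrad",
    "brenner",
    "eog",
    "eol",
    "sml",
    "variance",
    "vollath",
    "fft",
    "dct",
    "dwt",
    "get_operator",
    "resolve_operators",
    "operator_family",
    "OPERATOR_NAMES",
    "FAMILIES",
]

logger = logging.getLogger(__name__)

# Sobel kernels, applied by correlation; responses are squared so the sign
# convention is irrelevant.
_SOBEL_X = np.array([[1.0, 0.0, -1.0], [2.0, 0.0, -2.0], [1.0, 0.0, -1.0]])
_SOBEL_Y = np.array([[1.0, 2.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -2.0, -1.0]])


def _as_image(image, name: str, min_rows: int = 1, min_cols: int = 1) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise OperatorSizeError(
            f"{name}: expected a 2-D grayscale image, got ndim={arr.ndim} "
            "(color images are rejected, not converted)"
        )
    m, nc = arr.shape
    if m < min_rows or nc < min_cols:
        raise OperatorSizeError(
            f"{name}: image of size {m}x{nc} is below the minimum "
            f"{min_rows}x{min_cols} required by this operator"
        )
    if not np.isfinite(arr).all():
        raise OperatorSizeError(f"{name}: image contains non-finite intensities")
    return arr


def smd(image) -> float:
    """Sum of Modified Differences: absolute gray differences to the row and
    column neighbour, summed over all pixels that have both."""
    a = _as_image(image, "SMD", 2, 2)
    core = a[:-1, :-1]
    return float(np.abs(core - a[1:, :-1]).sum() + np.abs(core - a[:-1, 1:]).sum())


def roberts(image) -> float:
    """Roberts cross-gradient energy: squared diagonal cross differences."""
    a = _as_image(image, "Roberts", 2, 2)
    t1 = a[1:, 1:] - a[:-1, :-1]
    t2 = a[1:, :-1] - a[:-1, 1:]
    return float((t1 * t1).sum() + (t2 * t2).sum())


def tenengrad(image) -> float:
    """Tenengrad: squared Sobel gradient magnitude summed over interior pixels."""
    a = _as_image(image, "Tenengrad", 3, 3)
    gx = correlate2d(a, _SOBEL_X, mode="valid")
    gy = correlate2d(a, _SOBEL_Y, mode="valid")
    return float((gx * gx).sum() + (gy * gy).sum())


def brenner(image) -> float:
    """Brenner gradient: squared difference across a 2-row step (row direction
    only — the operator reads one image dimension)."""
    a = _as_image(image, "Brenner", 3, 1)
    diff = a[:-2, :] - a[2:, :]
    return float((diff * diff).sum())


def eog(image) -> float:
    """Energy of Gradient: squared first differences along rows and columns."""
    a = _as_image(image, "EOG", 2, 2)
    core = a[:-1, :-1]
    dx = a[1:, :-1] - core
    dy = a[:-1, 1:] - core
    return float((dx * dx).sum() + (dy * dy).sum())


def eol(image) -> float:
    """Energy of Laplace: squared 4-neighbour Laplacian over interior pixels."""
    a = _as_image(image, "EOL", 3, 3)
    lap = (
        a[2:, 1:-1]
        + a[:-2, 1:-1]
        + a[1:-1, 2:]
        + a[1:-1, :-2]
        - 4.0 * a[1:-1, 1:-1]
    )
    return float((lap * lap).sum())


def sml(image) -> float:
    """Sum of Modified Laplacian: the absolute second differences along rows
    and columns are added *before* squaring, so opposite-signed gradients do
    not cancel as they can in EOL."""
    a = _as_image(image, "SML", 3, 3)
    c = a[1:-1, 1:-1]
    ml = np.abs(2.0 * c - a[:-2, 1:-1] - a[2:, 1:-1]) + np.abs(
        2.0 * c - a[1:-1, :-2] - a[1:-1, 2:]
    )
    return float((ml * ml).sum())


def variance(image) -> float:
    """Gray-level variance (unnormalized sum of squared deviations from the
    mean gray value)."""
    a = _as_image(image, "Variance", 1, 1)
    dev = a - a.mean()
    return float((dev * dev).sum())


def vollath(image) -> float:
    """Vollath's F4 autocorrelation: lag-1 minus lag-2 products along rows.
    May be negative."""
    a = _as_image(image, "Vollath", 3, 1)
    return float((a[:-2, :] * (a[1:-1, :] - a[2:, :])).sum())


def fft(image) -> float:
    """Frequency-weighted power spectrum: sum of (u^2 + v^2) * P(u, v) over the
    centered frequency grid u in [-M/2, M/2), v in [-Nc/2, Nc/2).

    The forward DFT is unnormalized and P = |X|^2.  The DC term P(0, 0)
    carries weight zero, so it drops out without explicit exclusion.
    """
    a = _as_image(image, "FFT", 2, 2)
    m, nc = a.shape
    p = np.abs(np.fft.fft2(a)) ** 2
    u = np.fft.fftfreq(m, 1.0 / m)
    v = np.fft.fftfreq(nc, 1.0 / nc)
    w = u[:, None] ** 2 + v[None, :] ** 2
    return float((w * p).sum())


def dct(image) -> float:
    """DCT high-frequency content: sum of (u + v) * C(u, v)^2 with C the
    orthonormal 2-D DCT-II coefficient grid; C(0, 0) is the DC component and
    carries weight zero."""
    a = _as_image(image, "DCT", 2, 2)
    m, nc = a.shape
    c = _fft.dctn(a, norm="ortho")
    w = np.add.outer(np.arange(m, dtype=float), np.arange(nc, dtype=float))
    return float((w * c * c).sum())


def dwt(image, wavelet: str = "db6", mode: str = "reflect") -> float:
    """Wavelet detail energy: one-level 2-D decomposition (DB6 by default),
    summing squared deviations of each detail sub-image (LH, HL, HH) from its
    own mean.

    Absolute values depend on the boundary-extension ``mode`` (PyWavelets
    signal-extension names); only relative behaviour across images is
    convention-stable, which is what focus ranking uses.
    """
    a = _as_image(image, "DWT", 2, 2)
    flen = pywt.Wavelet(wavelet).dec_len
    if min(a.shape) < flen:
        logger.warning(
            "DWT: image %dx%d is smaller than the %s filter length %d; "
            "boundary effects dominate",
            a.shape[0],
            a.shape[1],
            wavelet,
            flen,
        )
    _, details = pywt.dwt2(a, wavelet, mode=mode)
    total = 0.0
    for sub in details:
        dev = sub - sub.mean()
        total += float((dev * dev).sum())
    return total


_REGISTRY: Dict[str, Tuple[str, str, Callable[..., float]]] = {
    # key -> (display name, family, function)
    "smd": ("SMD", "spatial", smd),
    "roberts": ("Roberts", "spatial", roberts),
    "tenengrad": ("Tenengrad", "spatial", tenengrad),
    "brenner": ("Brenner", "spatial", brenner),
    "eog": ("EOG", "spatial", eog),
    "eol": ("EOL", "spatial", eol),
    "sml": ("SML", "spatial", sml),
    "variance": ("Variance", "statistical", variance),
    "vollath": ("Vollath", "statistical", vollath),
    "fft": ("FFT", "frequency", fft),
    "dct": ("DCT", "frequency", dct),
    "dwt": ("DWT", "frequency", dwt),
}

OPERATOR_NAMES: List[str] = [disp for disp, _, _ in _REGISTRY.values()]
FAMILIES = ("spatial", "statistical", "frequency")


def get_operator(name: str) -> Callable[..., float]:
    """Look up a single operator by case-insensitive name."""
    key = name.strip().lower()
    if key not in _REGISTRY:
        raise KeyError(
            f"unknown operator {name!r}; known: {', '.join(sorted(_REGISTRY))}"
        )
    return _REGISTRY[key][2]


def operator_family(name: str) -> str:
    """Family ('spatial', 'statistical' or 'frequency') of an operator."""
    key = name.strip().lower()
    if key not in _REGISTRY:
        raise KeyError(f"unknown operator {name!r}")
    return _REGISTRY[key][1]


def canonical_name(name: str) -> str:
    """Display form of an operator name (e.g. 'fft' -> 'FFT')."""
    key = name.strip().lower()
    if key not in _REGISTRY:
        raise KeyError(f"unknown operator {name!r}")
    return _REGISTRY[key][0]


def resolve_operators(selector) -> List[str]:
    """Expand a selector into a list of display names.

    ``selector`` may be a family keyword ('all', 'spatial', 'statistical',
    'frequency'), a single operator name, a comma-separated string, or an
    iterable of names/keywords.  Order follows the registry; duplicates are
    dropped.
    """
    if isinstance(selector, str):
        tokens = [t for t in (s.strip() for s in selector.split(",")) if t]
    else:
        tokens = [str(t).strip() for t in selector]
    if not tokens:
        raise KeyError("empty operator selection")
    wanted = set()
    for tok in tokens:
        low = tok.lower()
        if low == "all":
            wanted.update(_REGISTRY)
        elif low in FAMILIES:
            wanted.update(k for k, (_, fam, _) in _REGISTRY.items() if fam == low)
        elif low in _REGISTRY:
            wanted.add(low)
        else:
            raise KeyError(f"unknown operator or family {tok!r}")
    return [disp for key, (disp, _, _) in _REGISTRY.items() if key in wanted]
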