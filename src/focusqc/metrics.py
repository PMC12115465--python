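"""Focus-curve metrics.

Four metrics characterize an operator from its focus curve's morphology:

* ``Ws``  — steep slope region width, d * (k_rcp - k_lcp); smaller widths mean
  higher sensitivity to focus change.
* ``Rsg`` — steep-to-gradual ratio: value drop across the steep regions over
  the fluctuation of the gradual regions; larger means better discrimination
  between sharp and blurred frames.
* ``Cp``  — discrete curvature at the curve peak; larger means higher
  sensitivity near the focal position.
* ``RRMSE`` — root-mean-square difference between the clean and
  noise-corrupted curves, relative to the clean curve's mean; smaller means
  better noise robustness.

Two conventional comparators are included: ``FWHM`` (full width at half
maximum, NaN when the curve never falls to half maximum) and ``Sp`` (peak
slope, roughly Cp/2 at symmetric peaks).

Ws, Rsg, RRMSE and FWHM are invariant under positive rescaling of the curve;
Cp and Sp scale with it, so the evaluation pipeline max-normalizes curves
before computing them.  When the physical step distance d is unknown it is
omitted (treated as 1) and widths are in frame units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .curve import FocusCurve
from .exceptions import BoundaryPeakError, DegenerateRatioError, MetricError
from .segmentation import CurveSegmentation

__all__ = [
    "MetricSet",
    "steep_width",
    "steep_gradual_ratio",
    "peak_curvature",
    "peak_slope",
    "rrmse",
    "fwhm",
]


@dataclass
class MetricSet:
    """One operator's metric record; NaN marks an undefined cell."""

    operator: str
    ws: float = math.nan
    rsg: float = math.nan
    cp: float = math.nan
    sp: float = math.nan
    rrmse: float = math.nan
    fwhm: float = math.nan
    time_ms: float = math.nan  # reporting only; hardware-dependent
    d_known: bool = False


def _step(curve: Optional[FocusCurve], d: Optional[float]) -> float:
    if d is not None:
        if d <= 0:
            raise MetricError(f"step distance must be positive, got {d}")
        return float(d)
    if curve is not None and curve.d is not None:
        return float(curve.d)
    return 1.0


def steep_width(seg: CurveSegmentation, d: Optional[float] = None) -> float:
    """Steep slope region width Ws = d * (k_rcp - k_lcp).

    With d unknown the factor is dropped and the width is in frame units.
    """
    return _step(None, d) * (seg.krcp - seg.klcp)


def steep_gradual_ratio(curve: FocusCurve, seg: CurveSegmentation) -> float:
    """Steep-to-gradual ratio Rsg.

    Numerator: 2 F(kmax) - F(k_lsm) - F(k_rsm), the drop from the peak to the
    lowest sample of each steep region.  Denominator: the peak-to-trough
    fluctuation of the two gradual regions.  All extremes are taken over the
    integer samples of the segmentation's region sets.

    A warning is issued when the number of frames N does not exceed twice the
    steep width in frames (an acquisition guideline: short stacks bias the
    gradual-region extremes).
    """
    f = curve.values

    def vals(region) -> np.ndarray:
        idx = np.asarray(list(region), dtype=int) - 1
        if idx.size == 0:
            raise MetricError("empty region in segmentation; cannot compute Rsg")
        return f[idx]

    left_steep = vals(seg.left_steep_region)
    right_steep = vals(seg.right_steep_region)
    left_grad = vals(seg.left_gradual_region)
    right_grad = vals(seg.right_gradual_region)

    num = 2.0 * f[seg.kmax - 1] - left_steep.min() - right_steep.min()
    den = (left_grad.max() - left_grad.min()) + (right_grad.max() - right_grad.min())
    if den == 0.0:
        raise DegenerateRatioError(
            "both gradual regions are exactly flat; Rsg denominator is zero"
        )
    ws_frames = seg.krcp - seg.klcp
    if curve.n <= 2.0 * ws_frames:
        warnings.warn(
            f"N = {curve.n} frames does not exceed twice the steep width "
            f"({ws_frames:.3g} frames); Rsg may be biased — acquire more frames",
            UserWarning,
            stacklevel=2,
        )
    return float(num / den)


def _peak_triplet(curve: FocusCurve):
    kmax = curve.kmax
    if kmax == 1 or kmax == curve.n:
        raise BoundaryPeakError(
            f"curve peak at frame {kmax} of {curve.n}: peak-shape metrics need "
            "an interior peak"
        )
    f = curve.values
    return f[kmax - 2], f[kmax - 1], f[kmax]


def peak_curvature(
    curve: FocusCurve,
    d: Optional[float] = None,
    second_diff_scaling: str = "linear",
) -> float:
    """Curvature of the focus curve at its peak, Cp = |F''| / (1 + F'^2)^(3/2).

    F' is the central difference (F(kmax+1) - F(kmax-1)) / (2d).  F'' is the
    second difference F(kmax+1) - 2 F(kmax) + F(kmax-1) with a 1/d prefactor
    (``second_diff_scaling='linear'``, the metric's defining convention) or
    the dimensionally conventional 1/d^2
    (``second_diff_scaling='quadratic'``).
    """
    fm, f0, fp = _peak_triplet(curve)
    d = _step(curve, d)
    fprime = (fp - fm) / (2.0 * d)
    second = fp - 2.0 * f0 + fm
    if second_diff_scaling == "linear":
        fsecond = second / d
    elif second_diff_scaling == "quadratic":
        fsecond = second / (d * d)
    else:
        raise ValueError(
            f"second_diff_scaling must be 'linear' or 'quadratic', "
            f"got {second_diff_scaling!r}"
        )
    return float(abs(fsecond) / (1.0 + fprime * fprime) ** 1.5)


def peak_slope(curve: FocusCurve, d: Optional[float] = None) -> float:
    """Peak slope Sp = (2 F(kmax) - F(kmax+1) - F(kmax-1)) / (2d).

    The mean one-sided drop at the peak; non-negative since kmax is the
    argmax.  Equals Cp/2 exactly when the peak's neighbours are level and
    d = 1.
    """
    fm, f0, fp = _peak_triplet(curve)
    d = _step(curve, d)
    return float((2.0 * f0 - fp - fm) / (2.0 * d))


def rrmse(clean: FocusCurve, noisy: FocusCurve) -> float:
    """Relative root mean square error between clean and noisy focus curves.

    RRMSE = sqrt(mean((Fn(k) - F(k))^2)) / mean(F).  Invariant under joint
    positive rescaling of both curves, so raw (un-normalized) curves give the
    same value as any consistent normalization.
    """
    if noisy.n != clean.n:
        raise MetricError(
            f"curve lengths differ: clean {clean.n}, noisy {noisy.n}"
        )
    m_f = float(clean.values.mean())
    if m_f <= 0:
        raise MetricError(f"clean-curve mean {m_f} is not positive")
    diff = noisy.values - clean.values
    return float(math.sqrt(float((diff * diff).mean())) / m_f)


def fwhm(curve: FocusCurve, d: Optional[float] = None) -> float:
    """Full width at half maximum of the focus curve.

    The half-maximum level is F(kmax)/2.  Scanning outward from the peak, the
    first linearly interpolated crossing of the level on each side bounds the
    width; NaN when either side never falls to the level (e.g. the flat
    curves the Variance operator produces on low-contrast stacks).
    """
    kmax, n = curve.kmax, curve.n
    if kmax == 1 or kmax == n:
        raise BoundaryPeakError(
            f"curve peak at frame {kmax} of {n}: FWHM needs an interior peak"
        )
    f = curve.values
    level = f[kmax - 1] / 2.0

    k_left = math.nan
    for i in range(kmax - 1, 0, -1):  # pair (i, i+1), 1-based
        lo, hi = f[i - 1], f[i]
        if lo <= level:
            k_left = float(i) if hi == lo else i + (level - lo) / (hi - lo)
            break
    k_right = math.nan
    for i in range(kmax, n):  # pair (i, i+1), 1-based
        hi, lo = f[i - 1], f[i]
        if lo <= level:
            k_right = float(i + 1) if hi == lo else i + (hi - level) / (hi - lo)
            break
    if math.isnan(k_left) or math.isnan(k_right):
        return math.nan
    return _step(curve, d) * (k_right - k_left)
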