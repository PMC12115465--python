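"""Steep/gradual segmentation of a focus curve by multipoint linear fitting.

The focus curve changes rapidly near focus (steep slope region) and slowly far
from focus (gradual slope region).  Both regions contain approximately linear
sections, so each flank is summarized by two least-squares lines fitted over
sliding m-point windows:

* the *steep* line is the window with the largest slope (left flank) or the
  steepest descent (right flank);
* the *gradual* line is chosen among windows sample-disjoint from the steep
  window, by minimal residual sum of squares (``criterion='rss'``) or, for
  small m where perfectly collinear triples make RSS degenerate, by minimal
  absolute slope (``criterion='slope'``).

The intersection of the steep and gradual lines on each flank gives the
real-valued cutoff coordinates k_lcp and k_rcp bounding the steep slope
region; the curve values there are obtained by linear interpolation.

Tie-breaking is deterministic and mirror-symmetric: steep ties resolve to the
window nearest the peak, gradual ties to the window farthest from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, List, Optional, Tuple

import numpy as np

from .curve import FocusCurve, interpolate_curve
from .exceptions import (
    CurveError,
    DegenerateIntersectionError,
    SegmentationError,
)

__all__ = [
    "FittedLine",
    "CurveSegmentation",
    "fit_window_line",
    "find_steep_line",
    "find_gradual_line",
    "segment_curve",
]

# Relative tolerance for treating two window slopes/RSS as tied.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class FittedLine:
    """Least-squares line over an inclusive 1-based index window."""

    slope: float
    intercept: float
    window: Tuple[int, int]
    rss: float

    def __call__(self, k) -> float:
        return self.slope * np.asarray(k, dtype=float) + self.intercept

    @property
    def m(self) -> int:
        return self.window[1] - self.window[0] + 1


@dataclass(frozen=True)
class CurveSegmentation:
    """Peak index, cutoff coordinates and the four fitted lines."""

    n: int
    kmax: int
    klcp: float
    krcp: float
    f_lcp: float
    f_rcp: float
    left_steep_line: FittedLine
    right_steep_line: FittedLine
    left_gradual_line: FittedLine
    right_gradual_line: FittedLine
    m: int
    criterion: str

    # Region index sets (1-based, inclusive).  Boundary samples may be shared
    # between adjacent regions; together the four regions cover 1..N.
    @property
    def left_gradual_region(self) -> range:
        return range(1, math.floor(self.klcp) + 1)

    @property
    def left_steep_region(self) -> range:
        return range(math.ceil(self.klcp), self.kmax + 1)

    @property
    def right_steep_region(self) -> range:
        return range(self.kmax, math.floor(self.krcp) + 1)

    @property
    def right_gradual_region(self) -> range:
        return range(math.ceil(self.krcp), self.n + 1)

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "kmax": self.kmax,
            "klcp": self.klcp,
            "krcp": self.krcp,
            "f_lcp": self.f_lcp,
            "f_rcp": self.f_rcp,
            "m": self.m,
            "criterion": self.criterion,
        }
        for name in (
            "left_steep_line",
            "right_steep_line",
            "left_gradual_line",
            "right_gradual_line",
        ):
            line = getattr(self, name)
            d[name] = {
                "slope": line.slope,
                "intercept": line.intercept,
                "window": list(line.window),
                "rss": line.rss,
            }
        return d


def fit_window_line(curve: FocusCurve, start: int, m: int) -> FittedLine:
    """Ordinary least squares on the m points (k, F(k)), k = start..start+m-1."""
    n = curve.n
    if m < 3:
        raise SegmentationError(f"window length m = {m} must be at least 3")
    if start < 1 or start + m - 1 > n:
        raise CurveError(
            f"window [{start}, {start + m - 1}] outside the curve range [1, {n}]"
        )
    ks = np.arange(start, start + m, dtype=float)
    ys = curve.values[start - 1 : start - 1 + m]
    kc = ks - ks.mean()
    slope = float((kc * ys).sum() / (kc * kc).sum())
    intercept = float(ys.mean() - slope * ks.mean())
    resid = ys - (slope * ks + intercept)
    return FittedLine(
        slope=slope,
        intercept=intercept,
        window=(int(start), int(start + m - 1)),
        rss=float((resid * resid).sum()),
    )


def _tied(a: float, b: float) -> bool:
    return abs(a - b) <= _TIE_RTOL * max(1.0, abs(a), abs(b))


def _window_starts(lo: int, hi: int, m: int) -> List[int]:
    """Starts of all m-point windows fully inside [lo, hi]."""
    return list(range(lo, hi - m + 2))


def find_steep_line(curve: FocusCurve, side: str, m: int) -> FittedLine:
    """Steepest m-point window on one flank of the peak.

    Left: maximal slope among windows inside [1, kmax]; right: minimal
    (most negative) slope among windows inside [kmax, N].  The peak sample
    may belong to a steep window.  Ties resolve to the window nearest the
    peak.
    """
    kmax, n = curve.kmax, curve.n
    if side == "left":
        starts = _window_starts(1, kmax, m)
        npoints = kmax
    elif side == "right":
        starts = _window_starts(kmax, n, m)
        npoints = n - kmax + 1
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if npoints < m + 1:
        raise SegmentationError(
            f"{side} flank has {npoints} points; at least {m + 1} required "
            f"for a steep-line search with m = {m}"
        )
    # Enumerate nearest-the-peak first so ties keep the nearer window.
    ordered = sorted(starts, key=lambda s: kmax - (s + m - 1) if side == "left" else s - kmax)
    best: Optional[FittedLine] = None
    for s in ordered:
        line = fit_window_line(curve, s, m)
        score = line.slope if side == "left" else -line.slope
        if best is None:
            best, best_score = line, score
        elif score > best_score and not _tied(score, best_score):
            best, best_score = line, score
    return best


def find_gradual_line(
    curve: FocusCurve,
    side: str,
    m: int,
    criterion: str = "rss",
    steep: Optional[FittedLine] = None,
) -> FittedLine:
    """Best-fitting gradual (tail) line on one flank.

    Candidate windows lie on the same flank and share no sample with the
    chosen steep window.  ``criterion='rss'`` minimizes the residual sum of
    squares; ``criterion='slope'`` minimizes |slope| (preferred for small m,
    where perfectly collinear points give RSS = 0 ties).  Ties resolve to the
    window farthest from the peak.
    """
    if criterion not in ("rss", "slope"):
        raise ValueError(f"criterion must be 'rss' or 'slope', got {criterion!r}")
    if steep is None:
        steep = find_steep_line(curve, side, m)
    kmax, n = curve.kmax, curve.n
    if side == "left":
        starts = _window_starts(1, kmax, m)
    elif side == "right":
        starts = _window_starts(kmax, n, m)
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    s0, s1 = steep.window
    disjoint = [s for s in starts if s + m - 1 < s0 or s > s1]
    if not disjoint:
        raise SegmentationError(
            f"no {side} gradual window of length m = {m} is disjoint from the "
            f"steep window {steep.window}; use a smaller m or more frames"
        )
    # Farthest-from-peak first so ties keep the outermost window.
    ordered = sorted(
        disjoint, key=lambda s: s if side == "left" else -(s + m - 1)
    )
    best: Optional[FittedLine] = None
    for s in ordered:
        line = fit_window_line(curve, s, m)
        score = line.rss if criterion == "rss" else abs(line.slope)
        if best is None:
            best, best_score = line, score
        elif score < best_score and not _tied(score, best_score):
            best, best_score = line, score
    return best


def _intersect(steep: FittedLine, gradual: FittedLine) -> float:
    denom = steep.slope - gradual.slope
    scale = max(1.0, abs(steep.slope), abs(gradual.slope))
    if abs(denom) <= 1e-12 * scale:
        raise DegenerateIntersectionError(
            f"steep line {steep} and gradual line {gradual} are parallel "
            f"(slopes {steep.slope} and {gradual.slope}); no cutoff point"
        )
    return (gradual.intercept - steep.intercept) / denom


def segment_curve(
    curve: FocusCurve, m: int, criterion: str = "rss"
) -> CurveSegmentation:
    """Partition a focus curve into steep and gradual slope regions.

    Returns the cutoff coordinates k_lcp < kmax < k_rcp where the fitted
    steep and gradual lines intersect on each flank, with curve values there
    by linear interpolation.  Requires N >= 2m + 3 so disjoint steep and
    gradual windows fit on both flanks.  Curves whose intersections fall
    outside (1, kmax) / (kmax, N) — e.g. multi-peak curves — raise
    :class:`SegmentationError`.
    """
    n = curve.n
    if m < 3:
        raise SegmentationError(f"window length m = {m} must be at least 3")
    if n < 2 * m + 3:
        raise SegmentationError(
            f"curve of {n} points is too short for m = {m}; need N >= {2 * m + 3}"
        )
    kmax = curve.kmax
    left_steep = find_steep_line(curve, "left", m)
    right_steep = find_steep_line(curve, "right", m)
    left_grad = find_gradual_line(curve, "left", m, criterion, steep=left_steep)
    right_grad = find_gradual_line(curve, "right", m, criterion, steep=right_steep)
    klcp = _intersect(left_steep, left_grad)
    krcp = _intersect(right_steep, right_grad)
    if not (1.0 < klcp < kmax):
        raise SegmentationError(
            f"left cutoff {klcp:.6g} outside (1, kmax={kmax}); "
            f"steep {left_steep}, gradual {left_grad}"
        )
    if not (kmax < krcp < n):
        raise SegmentationError(
            f"right cutoff {krcp:.6g} outside (kmax={kmax}, {n}); "
            f"steep {right_steep}, gradual {right_grad}"
        )
    return CurveSegmentation(
        n=n,
        kmax=kmax,
        klcp=float(klcp),
        krcp=float(krcp),
        f_lcp=interpolate_curve(curve, klcp),
        f_rcp=interpolate_curve(curve, krcp),
        left_steep_line=left_steep,
        right_steep_line=right_steep,
        left_gradual_line=left_grad,
        right_gradual_line=right_grad,
        m=int(m),
        criterion=criterion,
    )
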