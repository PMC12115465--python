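"""Focal stacks and focus curves.

A focal stack is an ordered sequence of same-sized grayscale frames acquired
at uniformly spaced stage positions (step distance ``d``).  Applying a focus
measure operator to every frame yields the focus curve F(k), k = 1..N, the
object all downstream metrics consume.  Curves are 1-based to match the frame
index k; file outputs state the indexing explicitly.
"""

from __future__ import annotations

import glob
import os
import time
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import CurveError, NormalizationError
from .operators import get_operator

__all__ = [
    "FocalStack",
    "FocusCurve",
    "compute_focus_curve",
    "normalize_curve",
    "interpolate_curve",
    "read_curve_csv",
    "write_curve_csv",
    "read_stack",
]

CURVE_MAGIC = "# focusqc curve v1"

#: Minimum frames for any steep/gradual segmentation (smallest window m = 3
#: needs disjoint steep and gradual windows plus the peak).
MIN_STACK_FRAMES = 5

#: A curve needs at least a peak with two neighbours for peak-shape metrics.
MIN_CURVE_POINTS = 3


@dataclass
class FocalStack:
    """Ordered grayscale frames plus an optional physical step distance."""

    frames: np.ndarray  # (N, M, Nc) float array
    d: Optional[float] = None

    def __post_init__(self):
        arr = np.asarray(self.frames, dtype=float)
        if arr.ndim != 3:
            raise CurveError(
                f"stack must be N frames of identical 2-D images, got ndim={arr.ndim}"
            )
        if arr.shape[0] < MIN_STACK_FRAMES:
            raise CurveError(
                f"stack has {arr.shape[0]} frames; at least {MIN_STACK_FRAMES} required"
            )
        if not np.isfinite(arr).all():
            raise CurveError("stack contains non-finite intensities")
        if self.d is not None and self.d <= 0:
            raise CurveError(f"step distance must be positive, got {self.d}")
        self.frames = arr

    def __len__(self) -> int:
        return self.frames.shape[0]

    @classmethod
    def from_frames(cls, frames: Sequence, d: Optional[float] = None) -> "FocalStack":
        arrs = [np.asarray(f, dtype=float) for f in frames]
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1 or arrs[0].ndim != 2:
            raise CurveError(f"all frames must share one 2-D shape, got {shapes}")
        return cls(frames=np.stack(arrs), d=d)


@dataclass
class FocusCurve:
    """Focus measure values F(k) for k = 1..N (1-based)."""

    values: np.ndarray
    d: Optional[float] = None
    normalized: bool = False
    operator: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < MIN_CURVE_POINTS:
            raise CurveError(
                f"curve has {v.size} points; at least {MIN_CURVE_POINTS} required"
            )
        if not np.isfinite(v).all():
            raise CurveError("curve contains non-finite values")
        if self.d is not None and self.d <= 0:
            raise CurveError(f"step distance must be positive, got {self.d}")
        self.values = v

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def kmax(self) -> int:
        """1-based peak index; ties resolve to the smallest index."""
        return int(np.argmax(self.values)) + 1

    def __call__(self, k) -> float:
        """F evaluated at real-valued k by linear interpolation."""
        return interpolate_curve(self, k)


def compute_focus_curve(stack: FocalStack, op) -> Tuple[FocusCurve, float]:
    """Apply an operator to every frame of a stack.

    Parameters
    ----------
    stack : FocalStack
    op : str or callable
        Operator name (registry lookup) or a callable image -> float.

    Returns
    -------
    (curve, mean_time_s)
        The focus curve in frame order (``d`` copied from the stack) and the
        mean per-frame compute time in seconds, measured with a monotonic
        clock.  Timing is reporting-only and varies with hardware.
    """
    if callable(op):
        func, name = op, getattr(op, "__name__", "custom")
    else:
        func, name = get_operator(op), str(op)
    values = np.empty(len(stack))
    t_total = 0.0
    for i, frame in enumerate(stack.frames):
        t0 = time.perf_counter()
        try:
            values[i] = func(frame)
        except Exception as exc:
            raise type(exc)(f"frame {i + 1}: {exc}") from exc
        t_total += time.perf_counter() - t0
    curve = FocusCurve(values=values, d=stack.d, operator=name)
    return curve, t_total / len(stack)


def normalize_curve(curve: FocusCurve) -> FocusCurve:
    """Divide the curve by its maximum value so max(F) = 1.

    Idempotent; preserves the argmax and all value ratios.  Raises
    :class:`NormalizationError` when the maximum is not positive.
    """
    peak = float(curve.values.max())
    if peak <= 0:
        raise NormalizationError(
            f"cannot normalize: curve maximum {peak} is not positive"
        )
    return FocusCurve(
        values=curve.values / peak,
        d=curve.d,
        normalized=True,
        operator=curve.operator,
    )


def interpolate_curve(curve: FocusCurve, k) -> float:
    """Piecewise-linear interpolation of F at real-valued k in [1, N].

    Exact at integer samples; monotone between adjacent samples.
    """
    k = float(k)
    n = curve.n
    if not (1.0 <= k <= n):
        raise CurveError(f"k = {k} outside the curve range [1, {n}]")
    return float(np.interp(k, np.arange(1, n + 1), curve.values))


# ---------------------------------------------------------------------------
# File I/O


def write_curve_csv(curve: FocusCurve, path) -> None:
    """Write a curve as CSV: ``k,F`` with a versioned header.

    Values are written with ``repr`` so the reader round-trips exactly.
    """
    lines = [CURVE_MAGIC, "# k is the 1-based frame index"]
    if curve.d is not None:
        lines.append(f"# d = {curve.d!r}")
    lines.append(f"# normalized = {str(curve.normalized).lower()}")
    if curve.operator:
        lines.append(f"# operator = {curve.operator}")
    lines.append("k,F")
    for i, v in enumerate(curve.values, start=1):
        lines.append(f"{i},{float(v)!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_curve_csv(path) -> FocusCurve:
    """Read a curve written by :func:`write_curve_csv`."""
    d = None
    normalized = False
    operator = None
    values: List[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != CURVE_MAGIC:
            raise CurveError(f"{path}: not a focusqc curve file (header {first!r})")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("d ="):
                    d = float(body.split("=", 1)[1])
                elif body.startswith("normalized ="):
                    normalized = body.split("=", 1)[1].strip() == "true"
                elif body.startswith("operator ="):
                    operator = body.split("=", 1)[1].strip()
                continue
            if line.lower() == "k,f":
                continue
            _, val = line.split(",", 1)
            values.append(float(val))
    return FocusCurve(values=np.array(values), d=d, normalized=normalized,
                      operator=operator)


def read_stack(directory, pattern: str = "*.png", d: Optional[float] = None) -> FocalStack:
    """Read a focal stack from a directory of grayscale image files.

    Frames are ordered lexicographically by filename.  Color images are
    rejected (operators are defined on grayscale).
    """
    import imageio.v3 as iio

    paths = sorted(glob.glob(os.path.join(str(directory), pattern)))
    if not paths:
        raise CurveError(f"no files matching {pattern!r} in {directory}")
    frames = []
    for p in paths:
        img = np.asarray(iio.imread(p))
        if img.ndim != 2:
            raise CurveError(
                f"{p}: expected a grayscale image, got shape {img.shape} "
                "(color inputs are rejected, not converted)"
            )
        frames.append(img.astype(float))
    return FocalStack.from_frames(frames, d=d)
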