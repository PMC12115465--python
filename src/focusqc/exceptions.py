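"""Exception hierarchy for focusqc.

Everything raised on purpose derives from :class:`FocusQCError` so callers can
catch the package's failures in one clause; size/range problems additionally
derive from ``ValueError`` for idiomatic handling.
"""


class FocusQCError(Exception):
    """Base class for all focusqc errors."""


class OperatorSizeError(FocusQCError, ValueError):
    """Image smaller than the stencil an operator requires."""


class CurveError(FocusQCError, ValueError):
    """Invalid focus curve (too short, non-finite, out-of-range query)."""


class NormalizationError(CurveError):
    """Curve cannot be max-normalized (non-positive maximum)."""


class SegmentationError(FocusQCError, RuntimeError):
    """Steep/gradual segmentation of a focus curve failed."""


class DegenerateIntersectionError(SegmentationError):
    """Steep and gradual fitted lines are parallel; no cutoff exists."""


class MetricError(FocusQCError, RuntimeError):
    """A curve metric is undefined for the given input."""


class DegenerateRatioError(MetricError):
    """Steep-to-gradual ratio denominator is zero (exactly flat tails)."""


class BoundaryPeakError(MetricError):
    """Peak sits at the first or last frame; peak-shape metrics undefined."""


class ConfigError(FocusQCError, ValueError):
    """Invalid synthetic-stack or CLI configuration."""
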