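"""Operator evaluation protocol and ranked reports.

``evaluate_operators`` runs the full benchmark on a focal stack: for each
operator it computes the focus curve (with per-frame timing), max-normalizes
it, segments it into steep/gradual regions, derives Ws, Rsg, Cp, Sp and FWHM,
and computes RRMSE against the curve of an AWGN-corrupted copy of the stack.
Each metric column is then ranked across operators.

Ranking is *competition* ("1224") ranking: tied values share the minimal
rank and the next distinct value's rank skips accordingly; NaN cells are
excluded from ranking rather than ranked last.  Smaller is better for Ws,
RRMSE, FWHM and time; larger is better for Rsg, Cp and Sp.  The time column
is hardware-dependent and is reported and ranked but never asserted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .curve import FocalStack, FocusCurve, compute_focus_curve, normalize_curve
from .exceptions import FocusQCError
from .metrics import (
    MetricSet,
    fwhm,
    peak_curvature,
    peak_slope,
    rrmse,
    steep_width,
    steep_gradual_ratio,
)
from .operators import resolve_operators
from .segmentation import segment_curve
from .synthetic import add_awgn

__all__ = ["EvaluationReport", "evaluate_operators", "rank_metrics"]

logger = logging.getLogger(__name__)

#: Metric -> ranking direction ('asc' = smaller is better).
RANK_DIRECTIONS: Dict[str, str] = {
    "Ws": "asc",
    "Rsg": "desc",
    "Cp": "desc",
    "RRMSE": "asc",
    "FWHM": "asc",
    "Sp": "desc",
    "time_ms": "asc",
}

REPORT_COLUMNS = [
    "Ws", "Ws_rank", "Rsg", "Rsg_rank", "Cp", "Cp_rank", "RRMSE", "RRMSE_rank",
    "FWHM", "FWHM_rank", "Sp", "Sp_rank", "time_ms", "time_rank",
]


def rank_metrics(values: Sequence[float], direction: str = "asc") -> np.ndarray:
    """Competition ranks of a metric column.

    Each non-NaN value's rank is 1 plus the number of strictly better values;
    ties therefore share the minimal rank and later ranks skip.  NaN entries
    receive NaN ranks.  An all-NaN column is skipped with a warning.
    """
    if direction not in ("asc", "desc"):
        raise ValueError(f"direction must be 'asc' or 'desc', got {direction!r}")
    v = np.asarray(values, dtype=float)
    valid = np.isfinite(v)
    ranks = np.full(v.shape, math.nan)
    if not valid.any():
        logger.warning("all-NaN metric column; ranking skipped")
        return ranks
    vv = v[valid]
    for i in np.flatnonzero(valid):
        better = (vv < v[i]) if direction == "asc" else (vv > v[i])
        ranks[i] = 1 + int(better.sum())
    return ranks


@dataclass
class EvaluationReport:
    """Per-operator metric table with competition ranks and provenance."""

    table: pd.DataFrame  # index: operator; columns: REPORT_COLUMNS
    provenance: Dict = field(default_factory=dict)
    curves: Dict[str, FocusCurve] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        """CSV with '#'-prefixed provenance header lines; NaN written as NaN."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# focusqc evaluation report v1\n")
            for key in sorted(self.provenance):
                fh.write(f"# {key} = {self.provenance[key]}\n")
            fh.write("# time_ms is hardware-dependent; reporting only\n")
            out = self.table.copy()
            out.insert(0, "operator", out.index)
            fh.write(out.to_csv(index=False, na_rep="NaN", float_format="%.10g"))

    def to_json(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "rows": json.loads(
                self.table.to_json(orient="index")
            ),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _noisy_stack(stack: FocalStack, variance: float, seed: int) -> FocalStack:
    streams = np.random.SeedSequence(seed).spawn(len(stack))
    frames = np.stack(
        [
            add_awgn(frame, variance, np.random.default_rng(s))
            for frame, s in zip(stack.frames, streams)
        ]
    )
    return FocalStack(frames=frames, d=stack.d)


def evaluate_operators(
    stack: FocalStack,
    ops="all",
    m: int = 5,
    criterion: str = "rss",
    noise_variance: float = 5.0,
    seed: int = 0,
    normalize: bool = True,
    second_diff_scaling: str = "linear",
    provenance: Optional[Dict] = None,
) -> EvaluationReport:
    """Run the full evaluation protocol on a stack.

    Per operator: the focus curve is computed (mean per-frame time recorded),
    optionally max-normalized, segmented with m fitting points and the given
    gradual-line criterion, and scored with Ws, Rsg, Cp, Sp and FWHM.  RRMSE
    compares the raw clean curve with the raw curve of the same stack under
    AWGN of ``noise_variance`` (the statistic is scale-invariant, so raw
    curves equal any consistent normalization).  Any per-operator metric
    failure (e.g. a degenerate Rsg) is logged and recorded as NaN; the report
    still emits.  Identical inputs and seeds give identical reports except
    the time columns.
    """
    names = resolve_operators(ops)
    noisy = (
        _noisy_stack(stack, noise_variance, seed) if noise_variance > 0 else None
    )
    rows: List[MetricSet] = []
    curves: Dict[str, FocusCurve] = {}
    for name in names:
        rec = MetricSet(operator=name, d_known=stack.d is not None)
        try:
            raw_curve, mean_t = compute_focus_curve(stack, name)
        except FocusQCError as exc:
            logger.warning("%s: curve computation failed: %s", name, exc)
            rows.append(rec)
            continue
        rec.time_ms = mean_t * 1e3
        if noisy is not None:
            try:
                noisy_curve, _ = compute_focus_curve(noisy, name)
                rec.rrmse = rrmse(raw_curve, noisy_curve)
            except FocusQCError as exc:
                logger.warning("%s: RRMSE failed: %s", name, exc)
        else:
            rec.rrmse = 0.0
        curve = raw_curve
        if normalize:
            try:
                curve = normalize_curve(raw_curve)
            except FocusQCError as exc:
                logger.warning("%s: normalization failed (%s); using raw", name, exc)
        curves[name] = curve
        try:
            seg = segment_curve(curve, m=m, criterion=criterion)
            rec.ws = steep_width(seg, d=stack.d)
            try:
                rec.rsg = steep_gradual_ratio(curve, seg)
            except FocusQCError as exc:
                logger.warning("%s: Rsg failed: %s", name, exc)
        except FocusQCError as exc:
            logger.warning("%s: segmentation failed: %s", name, exc)
        for attr, func in (
            ("cp", lambda c: peak_curvature(c, d=stack.d,
                                            second_diff_scaling=second_diff_scaling)),
            ("sp", lambda c: peak_slope(c, d=stack.d)),
            ("fwhm", lambda c: fwhm(c, d=stack.d)),
        ):
            try:
                setattr(rec, attr, func(curve))
            except FocusQCError as exc:
                logger.warning("%s: %s failed: %s", name, attr, exc)
        rows.append(rec)

    table = pd.DataFrame(
        {
            "Ws": [r.ws for r in rows],
            "Rsg": [r.rsg for r in rows],
            "Cp": [r.cp for r in rows],
            "RRMSE": [r.rrmse for r in rows],
            "FWHM": [r.fwhm for r in rows],
            "Sp": [r.sp for r in rows],
            "time_ms": [r.time_ms for r in rows],
        },
        index=pd.Index([r.operator for r in rows], name="operator"),
    )
    for col, direction in RANK_DIRECTIONS.items():
        rank_col = "time_rank" if col == "time_ms" else f"{col}_rank"
        table[rank_col] = rank_metrics(table[col].to_numpy(), direction)
    table = table[REPORT_COLUMNS]

    prov = {
        "m": m,
        "criterion": criterion,
        "noise_variance": noise_variance,
        "seed": seed,
        "normalize": normalize,
        "second_diff_scaling": second_diff_scaling,
        "d": stack.d if stack.d is not None else "unknown",
        "n_frames": len(stack),
        "operators": ",".join(names),
    }
    if provenance:
        prov.update(provenance)
    return EvaluationReport(table=table, provenance=prov, curves=curves)
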