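"""Dice similarity index and its aggregation.

With X the automatic segmentation and Y the expert reference, let A be the
number of voxels in both, B the voxels in Y only and C the voxels in X
only.  The Dice similarity index is ``2A / (2A + B + C)`` — equivalently
``2|X∩Y| / (|X| + |Y|)`` — symmetric, and 1 for perfect overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import EmptyEvaluationError, ShapeMismatchError, UnknownLabelError
from .volume_io import LabelMap


@dataclass(frozen=True)
class OverlapCounts:
    """Voxel counts A (both), B (reference only), C (prediction only)."""

    A: int
    B: int
    C: int

    @property
    def dice(self) -> float:
        if self.A + self.B + self.C == 0:
            return 1.0
        return 2.0 * self.A / (2.0 * self.A + self.B + self.C)


def overlap_counts(pred: np.ndarray, ref: np.ndarray) -> OverlapCounts:
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.shape != ref.shape:
        raise ShapeMismatchError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    a = int(np.count_nonzero(pred & ref))
    b = int(np.count_nonzero(ref & ~pred))
    c = int(np.count_nonzero(pred & ~ref))
    return OverlapCounts(A=a, B=b, C=c)


def dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice index between two binary masks.

    Both masks empty is defined as 1.0 (perfect agreement on absence) and
    emits a warning, keeping the metric total.
    """
    counts = overlap_counts(pred, ref)
    if counts.A + counts.B + counts.C == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", stacklevel=2)
    return counts.dice


def dice_per_structure(pred: LabelMap, ref: LabelMap, structure: int,
                       slices: np.ndarray | list[int] | None = None) -> float:
    """Dice for one structure code, optionally restricted to a slice subset.

    Restricting to the withheld slices of a schedule evaluates only what
    the completion actually produced; the default uses every slice.
    """
    if structure not in ref.structure_names:
        raise UnknownLabelError(f"unknown structure code {structure}")
    if pred.shape != ref.shape:
        raise ShapeMismatchError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    p = pred.labels == structure
    r = ref.labels == structure
    if slices is not None:
        idx = np.asarray(slices, dtype=int)
        if idx.size == 0:
            raise EmptyEvaluationError("empty evaluation domain: no slices selected")
        p = p[idx]
        r = r[idx]
    return dice(p, r)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (0.005 -> 0.01)."""
    factor = 10 ** decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)) if x else 0.0


@dataclass
class DiceReport:
    """Per-patient, per-column Dice values with means and ranges.

    ``table`` has one row per patient and one column per method/structure
    combination; display rounding is 2 decimals, half-up.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.empty:
            raise ValueError("empty report")

    def mean(self) -> pd.Series:
        return self.table.mean(axis=0)

    def range(self) -> dict[str, tuple[float, float]]:
        return {c: (float(self.table[c].min()), float(self.table[c].max()))
                for c in self.table.columns}

    def rounded_mean(self) -> pd.Series:
        return self.mean().map(lambda v: round_half_up(v, 2))

    def summary(self) -> str:
        lines = []
        for col in self.table.columns:
            lo, hi = self.range()[col]
            lines.append(
                f"{col}: {round_half_up(float(self.mean()[col])):.2f} "
                f"[{round_half_up(lo):.2f}-{round_half_up(hi):.2f}]"
            )
        return "\n".join(lines)


def aggregate(rows: pd.DataFrame | dict | list[dict]) -> DiceReport:
    """Build a :class:`DiceReport` from per-patient rows.

    Accepts a DataFrame (patients x columns) or anything pandas can build
    one from; every value must be a Dice index in [0, 1].
    """
    table = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    if table.empty:
        raise ValueError("empty report")
    vals = table.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1) or np.any(~np.isfinite(vals)):
        raise ValueError("Dice values must lie in [0, 1]")
    return DiceReport(table=table)


def crossing_gap(mean_dice_by_gap: dict[int, float], reference: float) -> int | None:
    """Largest gap whose mean Dice still matches the reference level.

    The comparison is made on values rounded to 2 decimals — "identical"
    in the sense of equal 2-decimal table entries — so a sweep whose
    rounded mean equals or exceeds the rounded reference at gap g counts
    as matching the inter-rater level at that gap.  Returns None when no
    gap qualifies.
    """
    if not mean_dice_by_gap:
        raise ValueError("empty sweep")
    if not (0 < reference <= 1):
        raise ValueError(f"reference must be in (0, 1], got {reference}")
    ref2 = round_half_up(reference, 2)
    qualifying = [g for g, v in mean_dice_by_gap.items() if round_half_up(v, 2) >= ref2]
    return max(qualifying) if qualifying else None
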