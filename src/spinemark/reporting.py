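"""Cohort bookkeeping: sample size, diagnosis tallies, exclusion flow,
and score summaries.

All arithmetic here is exact (integers, or decimal half-up rounding at
presentation); computation never rounds internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .landmarks import DiagnosisLabel


class ReportingError(ValueError):
    pass


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), unlike banker's round."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def sample_size(z: float, p: float, e: float) -> int:
    """Minimum cohort size n = ceil(Z^2 * p * (1-p) / E^2).

    ``z`` is the normal critical value for the confidence level, ``p``
    the assumed population proportion (0.5 maximizes n), ``e`` the
    margin of error.
    """
    if z <= 0:
        raise ReportingError("z must be > 0")
    if not 0.0 < p < 1.0:
        raise ReportingError("p must lie in (0, 1)")
    if e <= 0:
        raise ReportingError("e must be > 0")
    return math.ceil(z * z * p * (1.0 - p) / (e * e))


@dataclass
class ExclusionFlow:
    """Audited running subtraction from an initial case count."""

    initial_count: int
    exclusions: list[tuple[str, int]]
    final_count: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": "retrieved", "excluded": 0, "remaining": self.initial_count}]
        remaining = self.initial_count
        for reason, count in self.exclusions:
            remaining -= count
            rows.append({"step": reason, "excluded": count, "remaining": remaining})
        return pd.DataFrame(rows)


def exclusion_flow(initial: int,
                   exclusions: Sequence[tuple[str, int]]) -> ExclusionFlow:
    """Apply ordered exclusions to an initial count, auditing each step."""
    if initial < 0:
        raise ReportingError("initial count must be >= 0")
    remaining = initial
    for reason, count in exclusions:
        if count < 0:
            raise ReportingError(f"negative exclusion count for {reason!r}")
        remaining -= count
        if remaining < 0:
            raise ReportingError(
                f"exclusions exceed available cases at step {reason!r}")
    return ExclusionFlow(initial, list(exclusions), remaining)


_TALLY_CATEGORIES = ("flexion", "extension", "right_bending", "left_bending",
                     "right_rotation", "left_rotation")

_LABEL_TO_CATEGORY = {
    ("sagittal", "flexion"): "flexion",
    ("sagittal", "extension"): "extension",
    ("coronal", "right_bending"): "right_bending",
    ("coronal", "left_bending"): "left_bending",
    ("axial", "right_rotation"): "right_rotation",
    ("axial", "left_rotation"): "left_rotation",
}


@dataclass
class DiagnosisTally:
    """Per-rater x per-category diagnosis counts with ratio summaries."""

    counts: pd.DataFrame           # raters x categories
    totals: pd.Series = field(init=False)

    def __post_init__(self):
        self.totals = self.counts.sum(axis=0)

    @property
    def flexion_extension_ratio(self) -> float:
        """Flexion-to-extension prevalence ratio, 1 decimal half-up."""
        return round_half_up(self.totals["flexion"] / self.totals["extension"], 1)

    @property
    def left_right_rotation_ratio(self) -> float:
        return round_half_up(
            self.totals["left_rotation"] / self.totals["right_rotation"], 1)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "DiagnosisTally":
        missing = [c for c in _TALLY_CATEGORIES if c not in counts.columns]
        if missing:
            raise ReportingError(f"tally missing categories {missing}")
        return cls(counts[list(_TALLY_CATEGORIES)].copy())

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.loc["total"] = self.totals
        return out


def tally_diagnoses(labels: Iterable[DiagnosisLabel]) -> DiagnosisTally:
    """Count malposition calls by rater and category.

    Rotation is counted over L1-L4 only (the L5 rotation call exists
    only for sacral-screen passers and is excluded from tallies to keep
    a fixed denominator); neutral calls count toward no category.
    """
    labels = list(labels)
    raters = sorted({l.rater_id for l in labels})
    counts = pd.DataFrame(0, index=raters, columns=list(_TALLY_CATEGORIES))
    for l in labels:
        for dim in ("sagittal", "coronal", "axial"):
            val = getattr(l, dim)
            if dim == "axial" and l.level == "L5":
                continue
            cat = _LABEL_TO_CATEGORY.get((dim, val))
            if cat is not None:
                counts.loc[l.rater_id, cat] += 1
    return DiagnosisTally(counts)


def summarize_f1(scores: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Column mean and population SD of a per-rater score table.

    Both are rounded half-up to 2 decimals, matching how aggregate
    diagnostic-accuracy tables are conventionally printed.  Requires at
    least 2 raters (rows).
    """
    if len(scores) < 2:
        raise ReportingError("need at least 2 raters to summarize")
    means = scores.mean(axis=0).map(lambda v: round_half_up(float(v), 2))
    sds = scores.std(axis=0, ddof=0).map(lambda v: round_half_up(float(v), 2))
    return means, sds
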