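"""Diagnostic cutoff derivation by weighted-F1 maximization.

Given per-level segmental angles and rater diagnoses, this module finds
the angle cutoffs that best reproduce the raters' calls, per level and
per malposition type, under two regimes:

* **local** — a cutoff optimized for each rater separately
  (intra-rater consistency);
* **global** — a single cutoff maximizing the *mean* weighted F1
  across raters (a candidate objective diagnostic criterion).

Classification rules
--------------------
sagittal (3-class)
    ``flexion`` if angle < t_flex, ``extension`` if angle > t_ext,
    ``neutral`` otherwise, with t_flex < t_ext.
coronal / axial (binary on the magnitude)
    ``malposition`` iff |angle| >= t (boundary inclusive).

The score is the support-weighted mean of per-class F1,

    F1_W = sum_c (n_c / n) * 2*TP_c / (2*TP_c + FP_c + FN_c),

with a class's F1 defined as 0 when its denominator is 0.  As a
function of a scalar cutoff, F1_W is piecewise constant with
breakpoints only at the observed angles, so an exhaustive search over
midpoints between consecutive distinct observed values (plus sentinels
outside the range) is globally optimal; the sagittal task searches the
2-D grid of ordered candidate pairs.  Ties are broken toward the
smallest cutoff (lexicographically smallest pair).

The object-oriented surface is :class:`ThresholdModel` /
:class:`ThresholdResults`, in the style of statsmodels: build the model
from angle and label DataFrames, ``fit()``, then read the per-level
cutoff table and the per-rater score table off the results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .landmarks import AXIAL_LABELS, CORONAL_LABELS, LUMBAR_LEVELS, SAGITTAL_LABELS

MALPOSITION_TYPES = ("sagittal", "coronal", "axial")
BINARY_CLASSES = ("malposition", "neutral")

#: Grid-evaluation chunk size for the sagittal pair search (memory bound).
_CHUNK = 512


class ThresholdError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Classification and confusion primitives
# ---------------------------------------------------------------------------

def classify_sagittal(angle: float, t_flex: float, t_ext: float) -> str:
    """Three-class sagittal call from one signed angle."""
    if not t_flex < t_ext:
        raise ThresholdError(f"cutoffs must satisfy t_flex < t_ext "
                             f"(got {t_flex}, {t_ext})")
    if angle < t_flex:
        return "flexion"
    if angle > t_ext:
        return "extension"
    return "neutral"


def classify_magnitude(magnitude: float, t: float) -> str:
    """Binary malposition call from an unsigned angle (boundary inclusive)."""
    if magnitude < 0:
        raise ThresholdError(f"magnitude must be >= 0 (got {magnitude})")
    if t < 0:
        raise ThresholdError(f"cutoff must be >= 0 (got {t})")
    return "malposition" if magnitude >= t else "neutral"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[i, j] = #(rater label = classes[i], predicted = classes[j])."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (len(self.classes), len(self.classes)):
            raise ThresholdError("confusion matrix shape does not match classes")
        if (c < 0).any():
            raise ThresholdError("confusion matrix entries must be >= 0")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(truth: Sequence[str], pred: Sequence[str],
              classes: Sequence[str]) -> ConfusionMatrix:
    """Build a confusion matrix (rows = rater truth, columns = prediction)."""
    if len(truth) != len(pred):
        raise ThresholdError("truth and prediction lengths differ")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, pred):
        if t not in index or p not in index:
            raise ThresholdError(f"label outside class set: {t!r}/{p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(classes), counts)


def weighted_f1(cm: ConfusionMatrix) -> float:
    """Support-weighted mean of per-class F1 scores."""
    total = cm.total
    if total == 0:
        raise ThresholdError("weighted F1 undefined for an empty confusion matrix")
    counts = cm.counts
    support = counts.sum(axis=1)
    predicted = counts.sum(axis=0)
    tp = np.diag(counts)
    denom = support + predicted  # = 2*TP + FP + FN
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2.0 * tp / denom, 0.0)
    return float((support * f1).sum() / total)


# ---------------------------------------------------------------------------
# Candidate cutoffs and vectorized objectives
# ---------------------------------------------------------------------------

def candidate_cutoffs(values: Sequence[float]) -> np.ndarray:
    """Cutoff candidates: midpoints between consecutive distinct sorted
    values, plus one sentinel below and one above the observed range.

    F1_W as a function of the cutoff is constant between consecutive
    observed values, so this set samples every achievable classification.
    """
    v = np.unique(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ThresholdError("no observed values to build candidates from")
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate([[v[0] - 1.0], mids, [v[-1] + 1.0]])


def _binary_f1_curve(magnitudes: np.ndarray, is_malposition: np.ndarray,
                     candidates: np.ndarray) -> np.ndarray:
    """Weighted F1 at each candidate cutoff for the binary magnitude task.

    Prediction rule: malposition iff m >= t.  Uses prefix counts so each
    candidate is O(log n).
    """
    order = np.argsort(magnitudes, kind="stable")
    m = magnitudes[order]
    pos = is_malposition[order].astype(np.int64)
    n = m.size
    P = int(pos.sum())
    N = n - P
    pos_prefix = np.concatenate([[0], np.cumsum(pos)])
    idx = np.searchsorted(m, candidates, side="left")  # #(m < t) = predicted neutral
    tp = P - pos_prefix[idx]
    tn = idx - pos_prefix[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        f1_pos = np.where((n - idx) + P > 0, 2.0 * tp / ((n - idx) + P), 0.0)
        f1_neg = np.where(idx + N > 0, 2.0 * tn / (idx + N), 0.0)
    return (P * f1_pos + N * f1_neg) / n


def _sagittal_prefix(angles: np.ndarray, labels: np.ndarray):
    """Sorted angles and per-class cumulative label counts."""
    order = np.argsort(angles, kind="stable")
    a = angles[order]
    lab = labels[order]
    pref = {}
    for cls in SAGITTAL_LABELS:
        pref[cls] = np.concatenate([[0], np.cumsum(lab == cls)]).astype(np.int64)
    return a, pref


def _sagittal_f1_grid_accumulate(a_sorted, pref, candidates, out):
    """Add this rater's F1_W over the (t_flex, t_ext) candidate grid to ``out``.

    Closed forms (p = #angles < t_flex, q = #angles <= t_ext):
        F1_flexion   = 2*C_fl[p] / (p + n_fl)
        F1_extension = 2*(n_ex - C_ex[q]) / ((n - q) + n_ex)
        F1_neutral   = 2*(C_nt[q] - C_nt[p]) / ((q - p) + n_nt)
    """
    n = a_sorted.size
    n_fl = int(pref["flexion"][-1])
    n_nt = int(pref["neutral"][-1])
    n_ex = int(pref["extension"][-1])
    p = np.searchsorted(a_sorted, candidates, side="left")
    q = np.searchsorted(a_sorted, candidates, side="right")
    cfl_p = pref["flexion"][p].astype(float)
    cnt_p = pref["neutral"][p].astype(float)
    cex_q = pref["extension"][q].astype(float)
    cnt_q = pref["neutral"][q].astype(float)
    pf = p.astype(float)
    qf = q.astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        f_fl = np.where(pf + n_fl > 0, 2.0 * cfl_p / (pf + n_fl), 0.0)
        f_ex = np.where((n - qf) + n_ex > 0,
                        2.0 * (n_ex - cex_q) / ((n - qf) + n_ex), 0.0)
    k = candidates.size
    for start in range(0, k, _CHUNK):
        sl = slice(start, min(start + _CHUNK, k))
        tp_nt = cnt_q[None, :] - cnt_p[sl, None]
        den_nt = (qf[None, :] - pf[sl, None]) + n_nt
        with np.errstate(invalid="ignore", divide="ignore"):
            f_nt = np.where(den_nt > 0, 2.0 * tp_nt / den_nt, 0.0)
        out[sl, :] += (n_fl * f_fl[sl, None] + n_nt * f_nt
                       + n_ex * f_ex[None, :]) / n


def _f1_at_sagittal_pair(angles, labels, t_flex, t_ext) -> float:
    pred = np.where(angles < t_flex, "flexion",
                    np.where(angles > t_ext, "extension", "neutral"))
    return weighted_f1(confusion(list(labels), list(pred), SAGITTAL_LABELS))


def _f1_at_magnitude(magnitudes, labels, t) -> float:
    pred = np.where(magnitudes >= t, "malposition", "neutral")
    return weighted_f1(confusion(list(labels), list(pred), BINARY_CLASSES))


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    """Optimal cutoff(s) for one (type, level) under one regime."""

    malposition_type: str
    level: Optional[str]
    regime: str                      # "global" | "local"
    rater_id: Optional[str]          # local only
    cutoffs: tuple[float, ...]       # (t,) or (t_flex, t_ext)
    f1w: float
    per_rater_f1w: Optional[dict[str, float]] = None  # global only
    degenerate: bool = False

    def __post_init__(self):
        if len(self.cutoffs) == 2 and not self.cutoffs[0] < self.cutoffs[1]:
            raise ThresholdError("sagittal cutoff pair must be ordered")
        if not -1e-12 <= self.f1w <= 1 + 1e-12:
            raise ThresholdError(f"F1_W out of range: {self.f1w}")


def binarize_labels(labels: Sequence[str], malposition_type: str) -> np.ndarray:
    """Map directional coronal/axial labels onto {malposition, neutral}."""
    vocab = CORONAL_LABELS if malposition_type == "coronal" else AXIAL_LABELS
    out = []
    for l in labels:
        if l not in vocab and l != "malposition":  # already-binary labels pass through
            raise ThresholdError(f"label {l!r} outside {malposition_type} vocabulary")
        out.append("neutral" if l == "neutral" else "malposition")
    return np.asarray(out)


def sweep_local(angles: Sequence[float], labels: Sequence[str],
                malposition_type: str, *, level: Optional[str] = None,
                rater_id: Optional[str] = None) -> ThresholdResult:
    """Exhaustive optimal-cutoff search for one rater's (angle, label) pairs.

    ``angles`` are signed for the sagittal task and magnitudes for the
    coronal/axial tasks; ``labels`` use the task's native vocabulary
    (directional labels are binarized internally for coronal/axial).
    """
    if malposition_type not in MALPOSITION_TYPES:
        raise ThresholdError(f"unknown malposition type {malposition_type!r}")
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ThresholdError("no labeled pairs to sweep")
    lab = np.asarray(labels)
    if lab.size != a.size:
        raise ThresholdError("angles and labels lengths differ")
    degenerate = len(set(lab.tolist())) == 1
    cand = candidate_cutoffs(a)

    if malposition_type == "sagittal":
        bad = set(lab.tolist()) - set(SAGITTAL_LABELS)
        if bad:
            raise ThresholdError(f"labels outside sagittal vocabulary: {bad}")
        a_sorted, pref = _sagittal_prefix(a, lab)
        grid = np.zeros((cand.size, cand.size))
        _sagittal_f1_grid_accumulate(a_sorted, pref, cand, grid)
        iu = np.triu_indices(cand.size, k=1)
        flat = np.full(grid.shape, -np.inf)
        flat[iu] = grid[iu]
        i, j = np.unravel_index(np.argmax(flat), flat.shape)
        return ThresholdResult("sagittal", level, "local", rater_id,
                               (float(cand[i]), float(cand[j])),
                               float(grid[i, j]), degenerate=degenerate)

    binary = binarize_labels(lab, malposition_type)
    mags = np.abs(a)
    cand = candidate_cutoffs(mags)
    cand = cand[cand >= 0] if cand[0] < 0 else cand
    if cand.size == 0 or cand[0] > mags.min():
        cand = np.concatenate([[0.0], cand])  # ensure an "everything malpositioned" cutoff
    curve = _binary_f1_curve(mags, binary == "malposition", cand)
    k = int(np.argmax(curve))
    return ThresholdResult(malposition_type, level, "local", rater_id,
                           (float(cand[k]),), float(curve[k]),
                           degenerate=degenerate)


def sweep_global(angles_by_rater: Mapping[str, Sequence[float]],
                 labels_by_rater: Mapping[str, Sequence[str]],
                 malposition_type: str, *,
                 level: Optional[str] = None) -> ThresholdResult:
    """Find the common cutoff maximizing the mean over raters of F1_W.

    The candidate set is the union of every rater's candidate set, so
    the search remains exact (breakpoints of each rater's piecewise-
    constant F1 curve are all included).
    """
    raters = sorted(angles_by_rater)
    if len(raters) < 2:
        raise ThresholdError("global sweep needs at least 2 raters")
    if set(raters) != set(labels_by_rater):
        raise ThresholdError("rater sets of angles and labels differ")

    if malposition_type == "sagittal":
        all_angles = np.concatenate([np.asarray(angles_by_rater[r], float)
                                     for r in raters])
        cand = candidate_cutoffs(all_angles)
        grid = np.zeros((cand.size, cand.size))
        for r in raters:
            a = np.asarray(angles_by_rater[r], float)
            lab = np.asarray(labels_by_rater[r])
            a_sorted, pref = _sagittal_prefix(a, lab)
            _sagittal_f1_grid_accumulate(a_sorted, pref, cand, grid)
        grid /= len(raters)
        iu = np.triu_indices(cand.size, k=1)
        flat = np.full(grid.shape, -np.inf)
        flat[iu] = grid[iu]
        i, j = np.unravel_index(np.argmax(flat), flat.shape)
        t_pair = (float(cand[i]), float(cand[j]))
        per = {r: _f1_at_sagittal_pair(np.asarray(angles_by_rater[r], float),
                                       np.asarray(labels_by_rater[r]), *t_pair)
               for r in raters}
        return ThresholdResult("sagittal", level, "global", None, t_pair,
                               float(grid[i, j]), per_rater_f1w=per)

    mags = {r: np.abs(np.asarray(angles_by_rater[r], float)) for r in raters}
    cand = candidate_cutoffs(np.concatenate([mags[r] for r in raters]))
    cand = np.concatenate([[0.0], cand[cand > 0]])
    mean_curve = np.zeros(cand.size)
    for r in raters:
        binary = binarize_labels(np.asarray(labels_by_rater[r]), malposition_type)
        mean_curve += _binary_f1_curve(mags[r], binary == "malposition", cand)
    mean_curve /= len(raters)
    k = int(np.argmax(mean_curve))
    t = float(cand[k])
    per = {r: _f1_at_magnitude(
        mags[r], binarize_labels(np.asarray(labels_by_rater[r]), malposition_type), t)
        for r in raters}
    return ThresholdResult(malposition_type, level, "global", None, (t,),
                           float(mean_curve[k]), per_rater_f1w=per)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class ThresholdModel:
    """Diagnostic-cutoff model for a cohort of angles and rater labels.

    Parameters
    ----------
    angles : DataFrame
        Long format, one row per (case, level):
        ``case_id, level, sagittal_angle, coronal_angle, axial_angle``
        (extra columns such as ``s1_pass`` are carried but optional —
        L5 axial eligibility is conveyed by a null ``axial_angle``).
    labels : DataFrame
        One row per (case, rater, level):
        ``case_id, rater_id, level, sagittal, coronal, axial``
        (axial null at L5 for sacral-screen failures).
    """

    _ANGLE_COL = {"sagittal": "sagittal_angle", "coronal": "coronal_angle",
                  "axial": "axial_angle"}

    def __init__(self, angles: pd.DataFrame, labels: pd.DataFrame):
        need_a = {"case_id", "level", "sagittal_angle", "coronal_angle", "axial_angle"}
        need_l = {"case_id", "rater_id", "level", "sagittal", "coronal", "axial"}
        if not need_a <= set(angles.columns):
            raise ThresholdError(f"angles missing columns {need_a - set(angles.columns)}")
        if not need_l <= set(labels.columns):
            raise ThresholdError(f"labels missing columns {need_l - set(labels.columns)}")
        merged = labels.merge(angles[list(need_a)], on=["case_id", "level"],
                              how="inner", validate="many_to_one")
        self.data = merged
        self.raters = sorted(merged["rater_id"].unique())
        self.levels = [l for l in LUMBAR_LEVELS if l in set(merged["level"])]

    @classmethod
    def from_records(cls, angle_records, diagnosis_labels) -> "ThresholdModel":
        from .geometry import angles_to_frame
        from .landmarks import diagnoses_to_frame
        return cls(angles_to_frame(angle_records), diagnoses_to_frame(diagnosis_labels))

    def _pairs(self, malposition_type: str, level: str, rater: str):
        """(angles, labels) arrays for one task cell; rows with a null
        angle or label are excluded (e.g. L5 axial screen failures)."""
        col = self._ANGLE_COL[malposition_type]
        sub = self.data[(self.data["level"] == level)
                        & (self.data["rater_id"] == rater)]
        sub = sub[sub[col].notna() & sub[malposition_type].notna()]
        a = sub[col].to_numpy(dtype=float)
        if malposition_type != "sagittal":
            a = np.abs(a)
        return a, sub[malposition_type].to_numpy()

    def fit(self, regime: str = "both") -> "ThresholdResults":
        """Run the cutoff sweeps and return a :class:`ThresholdResults`."""
        if regime not in ("both", "global", "local"):
            raise ThresholdError(f"unknown regime {regime!r}")
        results: list[ThresholdResult] = []
        for mtype in MALPOSITION_TYPES:
            for level in self.levels:
                cell = {r: self._pairs(mtype, level, r) for r in self.raters}
                cell = {r: v for r, v in cell.items() if v[0].size > 0}
                if not cell:
                    continue
                if regime in ("both", "global"):
                    if len(cell) >= 2:
                        results.append(sweep_global(
                            {r: v[0] for r, v in cell.items()},
                            {r: v[1] for r, v in cell.items()}, mtype, level=level))
                    else:
                        # one rater: the global cutoff is that rater's local one
                        (r, (a, lab)), = cell.items()
                        loc = sweep_local(a, lab, mtype, level=level)
                        results.append(dataclasses.replace(
                            loc, regime="global", rater_id=None,
                            per_rater_f1w={r: loc.f1w}))
                if regime in ("both", "local"):
                    for r, (a, lab) in sorted(cell.items()):
                        results.append(sweep_local(a, lab, mtype,
                                                   level=level, rater_id=r))
        return ThresholdResults(self, results)


class ThresholdResults:
    """Fitted cutoffs, their F1_W scores, and summary tables."""

    def __init__(self, model: ThresholdModel, results: list[ThresholdResult]):
        self.model = model
        self.results = sorted(
            results, key=lambda t: (MALPOSITION_TYPES.index(t.malposition_type),
                                    t.level or "", t.regime, t.rater_id or ""))

    # -- access -----------------------------------------------------------

    def get(self, malposition_type: str, level: str, regime: str = "global",
            rater_id: Optional[str] = None) -> ThresholdResult:
        for t in self.results:
            if (t.malposition_type == malposition_type and t.level == level
                    and t.regime == regime and t.rater_id == rater_id):
                return t
        raise KeyError((malposition_type, level, regime, rater_id))

    @property
    def thresholds_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.results:
            rows.append({
                "malposition_type": t.malposition_type, "level": t.level,
                "regime": t.regime, "rater_id": t.rater_id,
                "cutoff_low": t.cutoffs[0],
                "cutoff_high": t.cutoffs[1] if len(t.cutoffs) == 2 else np.nan,
                "f1w": t.f1w, "degenerate": t.degenerate})
        return pd.DataFrame(rows)

    def optimal_angle_table(self) -> pd.DataFrame:
        """Per-level optimal angles from the global regime.

        Rows: flexion / extension (the sagittal pair), lateral_bending,
        rotation; columns L1-L5.
        """
        table = pd.DataFrame(index=["flexion", "extension", "lateral_bending",
                                    "rotation"],
                             columns=list(self.model.levels), dtype=float)
        for level in self.model.levels:
            try:
                sag = self.get("sagittal", level, "global")
                table.loc["flexion", level] = sag.cutoffs[0]
                table.loc["extension", level] = sag.cutoffs[1]
            except KeyError:
                pass
            for mtype, row in (("coronal", "lateral_bending"), ("axial", "rotation")):
                try:
                    table.loc[row, level] = self.get(mtype, level, "global").cutoffs[0]
                except KeyError:
                    pass
        return table

    def _pooled_rater_f1(self, rater: str, mtype: str, regime: str) -> float:
        """F1_W for one rater pooling all levels into one confusion matrix,
        at that regime's per-level cutoffs."""
        truth_all, pred_all = [], []
        classes = SAGITTAL_LABELS if mtype == "sagittal" else BINARY_CLASSES
        for level in self.model.levels:
            a, lab = self.model._pairs(mtype, level, rater)
            if a.size == 0:
                continue
            try:
                res = self.get(mtype, level, regime,
                               rater if regime == "local" else None)
            except KeyError:
                continue
            if mtype == "sagittal":
                pred = np.where(a < res.cutoffs[0], "flexion",
                                np.where(a > res.cutoffs[1], "extension", "neutral"))
                truth = lab
            else:
                pred = np.where(a >= res.cutoffs[0], "malposition", "neutral")
                truth = binarize_labels(lab, mtype)
            truth_all += list(truth)
            pred_all += list(pred)
        if not truth_all:
            return float("nan")
        return weighted_f1(confusion(truth_all, pred_all, classes))

    def rater_score_table(self) -> pd.DataFrame:
        """Per-rater pooled F1_W under global and local cutoffs.

        Columns are a (regime, type) MultiIndex; the last two rows hold
        the column mean and population SD rounded half-up to 2 decimals.
        """
        from .reporting import summarize_f1
        cols = pd.MultiIndex.from_product(
            [("global", "local"), MALPOSITION_TYPES], names=["regime", "type"])
        table = pd.DataFrame(index=self.model.raters, columns=cols, dtype=float)
        for rater in self.model.raters:
            for regime in ("global", "local"):
                for mtype in MALPOSITION_TYPES:
                    table.loc[rater, (regime, mtype)] = self._pooled_rater_f1(
                        rater, mtype, regime)
        means, sds = summarize_f1(table)
        table.loc["mean"] = means
        table.loc["sd"] = sds
        return table

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = ["Diagnostic threshold fit",
                 "=" * 60,
                 f"raters: {len(self.model.raters)}   levels: "
                 f"{', '.join(self.model.levels)}",
                 "",
                 "Optimal angles (global regime, degrees):",
                 self.optimal_angle_table().round(2).to_string(),
                 "",
                 "Per-rater pooled F1_W:",
                 self.rater_score_table().round(2).to_string()]
        return "\n".join(lines)


def build_threshold_table(angles: pd.DataFrame,
                          labels: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: fit both regimes and return the per-level
    optimal-angle table and the per-rater F1_W table."""
    res = ThresholdModel(angles, labels).fit("both")
    return res.optimal_angle_table(), res.rater_score_table()
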