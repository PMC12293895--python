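"""Segmental malposition angles from digital markers.

Three angles are computed per lumbar level, each relative to the next
inferior segment:

* **sagittal (flexion/extension)** — lateral view; signed angle between
  the vertebral centerlines (midpoint of the superior endplate to
  midpoint of the inferior endplate).  Positive = extension (segmental
  lordosis).  L5 is measured against the normal of the S1 superior
  line, so neutral lumbosacral alignment reads 0.
* **coronal (lateral bending)** — AP view; same centerline
  construction, reported as an unsigned magnitude with the bending side
  kept as metadata (directionality is not part of the diagnostic task).
* **axial (rotation)** — AP view; cylindrical pedicle model.  With the
  vertebral body as a cylinder of radius R (half the mean endplate
  width), the medial pedicle edges project at perpendicular distances
  X = R·sin(α+β) (patient-right) and Y = R·sin(α−β) (patient-left)
  from the centerline, where 2α is the angle subtended by the pedicle
  pair and β the axial rotation.  Inverting,

      θ1 = arcsin(X/R),  θ2 = arcsin(Y/R),
      β = (θ1 − θ2)/2,   α = (θ1 + θ2)/2.

  Positive β = rotation toward the patient's left.

Because no comparable construction exists for S1, the cohort is
screened for sacral rotation before any L5 rotation angle is accepted:
the S2 spinous midpoint is projected onto the inter-ala segment and the
asymmetry statistic r = |d1 − d2|/d1 computed; cases at or above the
boxplot outlier fence Q3 + 1.5·IQR are excluded from L5 rotation.

All constructions use ratios and angles only, so results are invariant
to rigid motion and uniform scaling of the image coordinates.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .landmarks import (
    APSacrumMarkers,
    APVertebraMarkers,
    CaseLandmarks,
    LatVertebraMarkers,
    LUMBAR_LEVELS,
    Point2D,
)

logger = logging.getLogger(__name__)

#: X/R or Y/R ratios in (1, 1 + ARCSIN_CLAMP_TOL] are clamped to 1;
#: larger ratios indicate a mislabeled pedicle and raise.
ARCSIN_CLAMP_TOL = 0.02


class GeometryError(ValueError):
    """Degenerate or inconsistent marker geometry."""


@dataclass(frozen=True)
class Line2D:
    """Directed planar segment p -> q; degenerate segments are rejected."""

    p: Point2D
    q: Point2D

    def __post_init__(self):
        if self.p.x == self.q.x and self.p.y == self.q.y:
            raise GeometryError("degenerate line: p == q")


def wrap180(angle_deg: float) -> float:
    """Wrap an angle into the half-open interval (-90, 90]."""
    a = (angle_deg + 90.0) % 180.0 - 90.0
    return 90.0 if a == -90.0 else a


def line_angle_deg(line: Line2D) -> float:
    """Orientation of an undirected line in (-90, 90] degrees.

    0 is vertical (the image y axis); positive angles tilt toward +x at
    the top of the image (y increases downward).
    """
    dx = line.q.x - line.p.x
    dy = line.q.y - line.p.y
    return wrap180(math.degrees(math.atan2(dx, -dy)))


def signed_angle_between(upper: Line2D, lower: Line2D) -> float:
    """Signed angle in (-90, 90] from ``lower``'s to ``upper``'s orientation.

    Invariant to a common rigid rotation of both lines and antisymmetric
    under argument swap (up to the -90/90 boundary identification).
    """
    return wrap180(line_angle_deg(upper) - line_angle_deg(lower))


def _midpoint(p: Point2D, q: Point2D) -> Point2D:
    return Point2D((p.x + q.x) / 2.0, (p.y + q.y) / 2.0)


def centerline_lateral(v: LatVertebraMarkers) -> Line2D:
    """Centerline of a lateral-view vertebra: superior to inferior midpoint."""
    sup, inf = _midpoint(v.g1, v.g2), _midpoint(v.h1, v.h2)
    if sup == inf:
        raise GeometryError(f"{v.level}: coincident endplate midpoints (lateral)")
    return Line2D(sup, inf)


def centerline_ap(v: APVertebraMarkers) -> Line2D:
    """Centerline of an AP-view vertebra: superior to inferior midpoint."""
    sup, inf = _midpoint(v.a1, v.a2), _midpoint(v.b1, v.b2)
    if sup == inf:
        raise GeometryError(f"{v.level}: coincident endplate midpoints (AP)")
    return Line2D(sup, inf)


def _normal_angle(line: Line2D) -> float:
    return wrap180(line_angle_deg(line) + 90.0)


def flexion_extension_angle(case: CaseLandmarks, level: str) -> float:
    """Signed sagittal angle of ``level`` against its inferior reference.

    For L1-L4 the reference is the centerline of the next lumbar level;
    for L5 it is the normal of the S1 superior line, so that a
    centerline perpendicular to the sacral plateau reads 0.
    Positive = extension.
    """
    if level not in LUMBAR_LEVELS:
        raise GeometryError(f"unknown level {level!r}")
    upper = centerline_lateral(case.lat_vertebrae[level])
    if level == "L5":
        ref = _normal_angle(Line2D(case.lat_sacrum.s1_ant, case.lat_sacrum.s1_post))
    else:
        inferior = LUMBAR_LEVELS[LUMBAR_LEVELS.index(level) + 1]
        ref = line_angle_deg(centerline_lateral(case.lat_vertebrae[inferior]))
    return wrap180(line_angle_deg(upper) - ref)


def lateral_bending_angle(case: CaseLandmarks, level: str) -> tuple[float, str]:
    """Unsigned coronal angle of ``level`` plus the bending side.

    Returns ``(magnitude_deg, side)`` with side in {"left", "right",
    "none"}; the side is bookkeeping only (tallies), never part of the
    threshold analysis.  L5 is referenced to the normal of the S1
    superior surface line (d1-d2).
    """
    if level not in LUMBAR_LEVELS:
        raise GeometryError(f"unknown level {level!r}")
    upper = centerline_ap(case.ap_vertebrae[level])
    if level == "L5":
        ref = _normal_angle(Line2D(case.ap_sacrum.d1, case.ap_sacrum.d2))
    else:
        inferior = LUMBAR_LEVELS[LUMBAR_LEVELS.index(level) + 1]
        ref = line_angle_deg(centerline_ap(case.ap_vertebrae[inferior]))
    signed = wrap180(line_angle_deg(upper) - ref)
    side = "left" if signed > 0 else ("right" if signed < 0 else "none")
    return abs(signed), side


def _point_line_distance(pt: Point2D, line: Line2D) -> float:
    dx, dy = line.q.x - line.p.x, line.q.y - line.p.y
    num = abs(dx * (line.p.y - pt.y) - dy * (line.p.x - pt.x))
    return num / math.hypot(dx, dy)


@dataclass(frozen=True)
class RotationResult:
    """Cylindrical-model rotation estimate for one AP vertebra."""

    beta_deg: float   # signed axial rotation; positive = toward patient left
    alpha_deg: float  # pedicle half-angle
    X: float          # midline -> right pedicle inner edge (pixels)
    Y: float          # midline -> left pedicle inner edge (pixels)
    R: float          # cylinder radius = half mean endplate width (pixels)


def rotation_angle(v: APVertebraMarkers,
                   clamp_tol: float = ARCSIN_CLAMP_TOL) -> RotationResult:
    """Axial rotation of one AP vertebra via the cylindrical pedicle model.

    X and Y are *perpendicular* distances from the medial pedicle points
    to the AP centerline (not raw horizontal offsets), which decouples
    the rotation estimate from any coronal tilt of the vertebra.
    """
    cl = centerline_ap(v)
    X = _point_line_distance(v.c2, cl)  # patient-right pedicle
    Y = _point_line_distance(v.c1, cl)  # patient-left pedicle
    width_sup = math.hypot(v.a1.x - v.a2.x, v.a1.y - v.a2.y)
    width_inf = math.hypot(v.b1.x - v.b2.x, v.b1.y - v.b2.y)
    R = (width_sup + width_inf) / 4.0
    if R <= 0:
        raise GeometryError(f"{v.level}: nonpositive cylinder radius")
    ratios = []
    for name, d in (("c2", X), ("c1", Y)):
        ratio = d / R
        if ratio > 1.0 + clamp_tol:
            raise GeometryError(
                f"{v.level}/{name}: pedicle offset exceeds cylinder radius "
                f"(ratio {ratio:.3f}); likely mislabeled pedicle")
        ratios.append(min(ratio, 1.0))
    theta1 = math.asin(ratios[0])
    theta2 = math.asin(ratios[1])
    return RotationResult(
        beta_deg=math.degrees((theta1 - theta2) / 2.0),
        alpha_deg=math.degrees((theta1 + theta2) / 2.0),
        X=X, Y=Y, R=R)


def sacral_rotation_r(s: APSacrumMarkers) -> float:
    """Sacral rotation asymmetry r = |d1 - d2| / d1.

    The inter-ala segment G1G2 (= e1, e2) has midpoint P1 and
    half-length d1.  The S2 spinous midpoint H (= f) is dropped
    perpendicularly onto the G1G2 line at P2; d2 is the distance from
    P2 to the nearer of G1/G2.  r = 0 means the spinous projection is
    centered (no sacral rotation).
    """
    g1, g2, h = s.e1, s.e2, s.f
    dx, dy = g2.x - g1.x, g2.y - g1.y
    norm2 = dx * dx + dy * dy
    if norm2 == 0.0:
        raise GeometryError("degenerate sacral ala segment (e1 == e2)")
    d1 = math.sqrt(norm2) / 2.0
    t = ((h.x - g1.x) * dx + (h.y - g1.y) * dy) / norm2  # projection parameter
    p2 = Point2D(g1.x + t * dx, g1.y + t * dy)
    d2 = min(math.hypot(p2.x - g1.x, p2.y - g1.y),
             math.hypot(p2.x - g2.x, p2.y - g2.y))
    return abs(d1 - d2) / d1


def s1_rotation_screen(r_values: Sequence[float]) -> tuple[float, np.ndarray]:
    """Boxplot outlier screen on sacral r values.

    Returns ``(cutoff, pass_mask)`` with cutoff = Q3 + 1.5·IQR using
    linearly interpolated quartiles; a case passes (no sacral rotation,
    L5 rotation measurable) iff r < cutoff.  Requires at least 4 values
    for the quartiles to be meaningful.
    """
    r = np.asarray(r_values, dtype=float)
    if r.size < 4:
        raise GeometryError("sacral screen needs at least 4 r values")
    q1, q3 = np.percentile(r, [25.0, 75.0])
    cutoff = float(q3 + 1.5 * (q3 - q1))
    mask = r < cutoff
    if not mask.any():
        logger.warning("degenerate sacral screen: no case passes (IQR may be 0)")
    return cutoff, mask


@dataclass
class AngleRecord:
    """Computed segmental angles for one case and level."""

    case_id: str
    level: str
    sagittal_angle: Optional[float]
    coronal_angle: Optional[float]
    coronal_side: Optional[str]
    axial_angle: Optional[float]
    s1_r: Optional[float]
    s1_pass: Optional[bool]


def compute_case_angles(cases: Iterable[CaseLandmarks],
                        clamp_tol: float = ARCSIN_CLAMP_TOL) -> list[AngleRecord]:
    """Compute all segmental angles for a cohort.

    One record per case x level.  The sacral rotation screen is applied
    cohort-wide first; L5 axial angles are reported only for screen
    passers.  Per-case geometry errors are logged and leave the
    affected field ``None`` — they never abort the batch.
    """
    cases = list(cases)
    r_vals: list[Optional[float]] = []
    for case in cases:
        try:
            r_vals.append(sacral_rotation_r(case.ap_sacrum))
        except GeometryError as exc:
            logger.warning("case %s: sacral r failed: %s", case.case_id, exc)
            r_vals.append(None)

    known = [r for r in r_vals if r is not None]
    if len(known) >= 4:
        cutoff, _ = s1_rotation_screen(known)
    else:
        logger.warning("fewer than 4 sacral r values; all cases fail the S1 screen")
        cutoff = None

    records: list[AngleRecord] = []
    for case, r in zip(cases, r_vals):
        passed = (cutoff is not None and r is not None and r < cutoff)
        for level in LUMBAR_LEVELS:
            rec = AngleRecord(case.case_id, level, None, None, None, None, r, passed)
            try:
                rec.sagittal_angle = flexion_extension_angle(case, level)
            except GeometryError as exc:
                logger.warning("case %s %s sagittal: %s", case.case_id, level, exc)
            try:
                rec.coronal_angle, rec.coronal_side = lateral_bending_angle(case, level)
            except GeometryError as exc:
                logger.warning("case %s %s coronal: %s", case.case_id, level, exc)
            if level != "L5" or passed:
                try:
                    rec.axial_angle = rotation_angle(
                        case.ap_vertebrae[level], clamp_tol).beta_deg
                except GeometryError as exc:
                    logger.warning("case %s %s axial: %s", case.case_id, level, exc)
            records.append(rec)
    return records


def angles_to_frame(records: Iterable[AngleRecord]) -> pd.DataFrame:
    """Long-format DataFrame of angle records."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def write_angle_file(records: Iterable[AngleRecord], path) -> None:
    angles_to_frame(records).to_csv(path, index=False, float_format="%.6f")


def read_angle_file(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"case_id": str, "level": str})
    if "s1_pass" in df.columns:
        df["s1_pass"] = df["s1_pass"].astype("boolean")
    return df
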