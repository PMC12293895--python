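"""Digital-marker data model for lumbar radiograph landmarks.

A *case* is one patient's paired anterior-posterior (AP) and lateral
lumbar radiographs, annotated with a fixed set of named landmark points:

AP view, per vertebra (L1-L5)
    a1/a2   left/right endpoints of the superior endplate
    b1/b2   left/right endpoints of the inferior endplate
    c1/c2   most medial points of the left/right pedicles
AP view, sacrum
    d1/d2   left/right endpoints of the S1 superior surface
    e1/e2   most lateral points of the left/right sacral ala
    f       midpoint of the S2 spinous process
Lateral view, per vertebra (L1-L5)
    g1/g2   anterior/posterior endpoints of the superior endplate
    h1/h2   anterior/posterior endpoints of the inferior endplate
Lateral view, sacrum
    s1_ant/s1_post  anterior/posterior endpoints of the S1 body

Coordinates are continuous image coordinates: x increases rightward,
y increases downward (raster convention).  In the AP view the image is
stored in standard radiographic display orientation, i.e. the patient's
left side is at larger x; point names refer to the *patient's* side, so
any image mirroring must be absorbed at ingest.  All downstream angle
computations are invariant to global translation and scaling, so
``pixel_spacing`` is carried as metadata only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

LUMBAR_LEVELS: tuple[str, ...] = ("L1", "L2", "L3", "L4", "L5")

AP_VERTEBRA_POINTS: tuple[str, ...] = ("a1", "a2", "b1", "b2", "c1", "c2")
AP_SACRUM_S1_POINTS: tuple[str, ...] = ("d1", "d2", "e1", "e2")
AP_SACRUM_S2_POINTS: tuple[str, ...] = ("f",)
LAT_VERTEBRA_POINTS: tuple[str, ...] = ("g1", "g2", "h1", "h2")
LAT_SACRUM_POINTS: tuple[str, ...] = ("s1_ant", "s1_post")

SAGITTAL_LABELS: tuple[str, ...] = ("flexion", "neutral", "extension")
CORONAL_LABELS: tuple[str, ...] = ("left_bending", "neutral", "right_bending")
AXIAL_LABELS: tuple[str, ...] = ("left_rotation", "neutral", "right_rotation")

#: Write precision for coordinate round-tripping (decimal places).
COORD_DECIMALS = 6


class LandmarkError(ValueError):
    """Base class for landmark-file problems."""


class LandmarkParseError(LandmarkError):
    """A row or field of a landmark file could not be parsed."""


class LandmarkValidationError(LandmarkError):
    """A structurally complete record violates the marker schema."""


@dataclass(frozen=True)
class Point2D:
    """A planar image coordinate (pixels)."""

    x: float
    y: float

    def is_finite(self) -> bool:
        return math.isfinite(self.x) and math.isfinite(self.y)

    def __iter__(self):
        yield self.x
        yield self.y


@dataclass(frozen=True)
class APVertebraMarkers:
    level: str
    a1: Point2D
    a2: Point2D
    b1: Point2D
    b2: Point2D
    c1: Point2D
    c2: Point2D


@dataclass(frozen=True)
class APSacrumMarkers:
    d1: Point2D
    d2: Point2D
    e1: Point2D
    e2: Point2D
    f: Point2D


@dataclass(frozen=True)
class LatVertebraMarkers:
    level: str
    g1: Point2D
    g2: Point2D
    h1: Point2D
    h2: Point2D


@dataclass(frozen=True)
class LatSacrumMarkers:
    s1_ant: Point2D
    s1_post: Point2D


@dataclass
class CaseLandmarks:
    """One case's complete AP + lateral marker set (L1-L5 + sacrum)."""

    case_id: str
    ap_vertebrae: dict[str, APVertebraMarkers]
    ap_sacrum: APSacrumMarkers
    lat_vertebrae: dict[str, LatVertebraMarkers]
    lat_sacrum: LatSacrumMarkers
    pixel_spacing: Optional[float] = None

    def iter_points(self) -> Iterable[tuple[str, str, str, Point2D]]:
        """Yield (view, level, point_name, point) for every landmark."""
        for lvl in LUMBAR_LEVELS:
            v = self.ap_vertebrae[lvl]
            for name in AP_VERTEBRA_POINTS:
                yield "AP", lvl, name, getattr(v, name)
        for name in AP_SACRUM_S1_POINTS:
            yield "AP", "S1", name, getattr(self.ap_sacrum, name)
        yield "AP", "S2", "f", self.ap_sacrum.f
        for lvl in LUMBAR_LEVELS:
            v = self.lat_vertebrae[lvl]
            for name in LAT_VERTEBRA_POINTS:
                yield "LAT", lvl, name, getattr(v, name)
        for name in LAT_SACRUM_POINTS:
            yield "LAT", "S1", name, getattr(self.lat_sacrum, name)


@dataclass(frozen=True)
class DiagnosisLabel:
    """One rater's categorical malposition call for a case/level.

    ``axial`` is ``None`` at L5 for cases that failed the sacral
    rotation screen (no rotation call can be made there).
    """

    case_id: str
    rater_id: str
    level: str
    sagittal: str
    coronal: str
    axial: Optional[str]

    def __post_init__(self):
        if self.level not in LUMBAR_LEVELS:
            raise LandmarkValidationError(f"{self.case_id}: bad level {self.level!r}")
        if self.sagittal not in SAGITTAL_LABELS:
            raise LandmarkValidationError(
                f"{self.case_id}/{self.level}: bad sagittal label {self.sagittal!r}")
        if self.coronal not in CORONAL_LABELS:
            raise LandmarkValidationError(
                f"{self.case_id}/{self.level}: bad coronal label {self.coronal!r}")
        if self.axial is None:
            if self.level != "L5":
                raise LandmarkValidationError(
                    f"{self.case_id}/{self.level}: axial label may be absent only at L5")
        elif self.axial not in AXIAL_LABELS:
            raise LandmarkValidationError(
                f"{self.case_id}/{self.level}: bad axial label {self.axial!r}")


@dataclass
class ValidationReport:
    """Named schema violations for one case; empty list means valid."""

    case_id: str
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _seg_len(p: Point2D, q: Point2D) -> float:
    return math.hypot(p.x - q.x, p.y - q.y)


def validate_case(case: CaseLandmarks, pedicle_tol: float = 2.0) -> ValidationReport:
    """Check all marker-schema invariants of one case.

    Violations are returned as data (a deterministic list of messages),
    never raised.  ``pedicle_tol`` (pixels) relaxes the requirement that
    pedicle points lie within the vertical extent of the endplate lines,
    to absorb annotation jitter.
    """
    rep = ValidationReport(case.case_id)
    for view, lvl, name, pt in case.iter_points():
        if not pt.is_finite():
            rep.violations.append(f"{view}/{lvl}/{name}: non-finite coordinate")
    if rep.violations:
        return rep

    for lvl in LUMBAR_LEVELS:
        v = case.ap_vertebrae[lvl]
        if _seg_len(v.a1, v.a2) == 0.0:
            rep.violations.append(f"AP/{lvl}: zero-length superior endplate")
        if _seg_len(v.b1, v.b2) == 0.0:
            rep.violations.append(f"AP/{lvl}: zero-length inferior endplate")
        ys = [v.a1.y, v.a2.y, v.b1.y, v.b2.y]
        lo, hi = min(ys) - pedicle_tol, max(ys) + pedicle_tol
        for name in ("c1", "c2"):
            c = getattr(v, name)
            if not (lo <= c.y <= hi):
                rep.violations.append(
                    f"AP/{lvl}/{name}: pedicle point outside endplate y-extent")
        w = case.lat_vertebrae[lvl]
        if _seg_len(w.g1, w.g2) == 0.0:
            rep.violations.append(f"LAT/{lvl}: zero-length superior endplate")
        if _seg_len(w.h1, w.h2) == 0.0:
            rep.violations.append(f"LAT/{lvl}: zero-length inferior endplate")

    s = case.ap_sacrum
    if _seg_len(s.d1, s.d2) == 0.0:
        rep.violations.append("AP/S1: zero-length superior surface line")
    if _seg_len(s.e1, s.e2) == 0.0:
        rep.violations.append("AP/S1: zero-length sacral ala segment")
    if _seg_len(case.lat_sacrum.s1_ant, case.lat_sacrum.s1_post) == 0.0:
        rep.violations.append("LAT/S1: zero-length S1 body line")
    return rep


# ---------------------------------------------------------------------------
# CSV / JSON landmark I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("case_id", "view", "level", "point_name", "x", "y")


def _expected_points() -> list[tuple[str, str, str]]:
    out: list[tuple[str, str, str]] = []
    for lvl in LUMBAR_LEVELS:
        out += [("AP", lvl, n) for n in AP_VERTEBRA_POINTS]
    out += [("AP", "S1", n) for n in AP_SACRUM_S1_POINTS]
    out += [("AP", "S2", "f")]
    for lvl in LUMBAR_LEVELS:
        out += [("LAT", lvl, n) for n in LAT_VERTEBRA_POINTS]
    out += [("LAT", "S1", n) for n in LAT_SACRUM_POINTS]
    return out


_EXPECTED_POINTS = _expected_points()


def _case_from_points(case_id: str,
                      pts: Mapping[tuple[str, str, str], Point2D],
                      pixel_spacing: Optional[float]) -> CaseLandmarks:
    missing = [k for k in _EXPECTED_POINTS if k not in pts]
    if missing:
        view, lvl, name = missing[0]
        raise LandmarkValidationError(
            f"case {case_id}: missing landmark {lvl}/{name} ({view} view)"
            + (f" and {len(missing) - 1} more" if len(missing) > 1 else ""))
    extra = set(pts) - set(_EXPECTED_POINTS)
    if extra:
        view, lvl, name = sorted(extra)[0]
        raise LandmarkValidationError(
            f"case {case_id}: unknown landmark {view}/{lvl}/{name}")

    ap = {
        lvl: APVertebraMarkers(lvl, *(pts[("AP", lvl, n)] for n in AP_VERTEBRA_POINTS))
        for lvl in LUMBAR_LEVELS
    }
    sac = APSacrumMarkers(*(pts[("AP", "S1", n)] for n in AP_SACRUM_S1_POINTS),
                          pts[("AP", "S2", "f")])
    lat = {
        lvl: LatVertebraMarkers(lvl, *(pts[("LAT", lvl, n)] for n in LAT_VERTEBRA_POINTS))
        for lvl in LUMBAR_LEVELS
    }
    lsac = LatSacrumMarkers(*(pts[("LAT", "S1", n)] for n in LAT_SACRUM_POINTS))
    return CaseLandmarks(case_id, ap, sac, lat, lsac, pixel_spacing)


def read_landmark_file(path, pedicle_tol: float = 2.0) -> list[CaseLandmarks]:
    """Read a flat landmark CSV into validated :class:`CaseLandmarks`.

    Structural problems (unparseable fields, incomplete marker sets)
    raise; cases that are complete but violate geometric invariants are
    dropped with a logged warning, mirroring the exclusion of
    unanalyzable images from a study cohort.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"case_id": str, "view": str,
                                      "level": str, "point_name": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise LandmarkParseError(f"{path}: {exc}") from exc
    missing_cols = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise LandmarkParseError(f"{path}: missing columns {missing_cols}")

    cases: list[CaseLandmarks] = []
    for case_id, grp in df.groupby("case_id", sort=True):
        pts: dict[tuple[str, str, str], Point2D] = {}
        for row in grp.itertuples(index=False):
            try:
                x, y = float(row.x), float(row.y)
            except (TypeError, ValueError) as exc:
                raise LandmarkParseError(
                    f"case {case_id}: non-numeric coordinate for "
                    f"{row.level}/{row.point_name}") from exc
            key = (str(row.view), str(row.level), str(row.point_name))
            if key in pts:
                raise LandmarkValidationError(
                    f"case {case_id}: duplicate landmark {key[1]}/{key[2]}")
            pts[key] = Point2D(x, y)
        case = _case_from_points(str(case_id), pts, None)
        rep = validate_case(case, pedicle_tol=pedicle_tol)
        if rep.ok:
            cases.append(case)
        else:
            logger.warning("excluding case %s: %s", case_id, "; ".join(rep.violations))
    return cases


def write_landmark_file(cases: Sequence[CaseLandmarks], path) -> None:
    """Write cases to the flat landmark CSV, lossless to 6 decimals."""
    path = Path(path)
    lines = [",".join(_CSV_COLUMNS)]
    for case in cases:
        for view, lvl, name, pt in case.iter_points():
            lines.append(f"{case.case_id},{view},{lvl},{name},"
                         f"{pt.x:.{COORD_DECIMALS}f},{pt.y:.{COORD_DECIMALS}f}")
    path.write_text("\n".join(lines) + "\n")


def _point_to_json(pt: Point2D) -> list[float]:
    return [round(pt.x, COORD_DECIMALS), round(pt.y, COORD_DECIMALS)]


def write_landmark_json(cases: Sequence[CaseLandmarks], path) -> None:
    """JSON mirror of the landmark file: one object per case."""
    objs = []
    for case in cases:
        obj: dict = {"case_id": case.case_id, "pixel_spacing": case.pixel_spacing,
                     "ap": {}, "lat": {}}
        for lvl in LUMBAR_LEVELS:
            v = case.ap_vertebrae[lvl]
            obj["ap"][lvl] = {n: _point_to_json(getattr(v, n)) for n in AP_VERTEBRA_POINTS}
        s = case.ap_sacrum
        obj["ap"]["sacrum"] = {n: _point_to_json(getattr(s, n))
                               for n in (*AP_SACRUM_S1_POINTS, "f")}
        for lvl in LUMBAR_LEVELS:
            v = case.lat_vertebrae[lvl]
            obj["lat"][lvl] = {n: _point_to_json(getattr(v, n)) for n in LAT_VERTEBRA_POINTS}
        obj["lat"]["sacrum"] = {n: _point_to_json(getattr(case.lat_sacrum, n))
                                for n in LAT_SACRUM_POINTS}
        objs.append(obj)
    Path(path).write_text(json.dumps(objs, indent=1) + "\n")


def read_landmark_json(path, pedicle_tol: float = 2.0) -> list[CaseLandmarks]:
    try:
        objs = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise LandmarkParseError(f"{path}: {exc}") from exc
    cases = []
    for obj in objs:
        case_id = str(obj.get("case_id"))
        pts: dict[tuple[str, str, str], Point2D] = {}
        for view_key, view in (("ap", "AP"), ("lat", "LAT")):
            for lvl, d in obj.get(view_key, {}).items():
                for name, xy in d.items():
                    level = {"sacrum": ("S2" if name == "f" else "S1")}.get(lvl, lvl)
                    pts[(view, level, name)] = Point2D(float(xy[0]), float(xy[1]))
        case = _case_from_points(case_id, pts, obj.get("pixel_spacing"))
        rep = validate_case(case, pedicle_tol=pedicle_tol)
        if rep.ok:
            cases.append(case)
        else:
            logger.warning("excluding case %s: %s", case_id, "; ".join(rep.violations))
    return cases


# ---------------------------------------------------------------------------
# Diagnosis label I/O
# ---------------------------------------------------------------------------

def write_diagnosis_file(labels: Sequence[DiagnosisLabel], path) -> None:
    rows = [{"case_id": l.case_id, "rater_id": l.rater_id, "level": l.level,
             "sagittal": l.sagittal, "coronal": l.coronal,
             "axial": "" if l.axial is None else l.axial}
            for l in labels]
    pd.DataFrame(rows, columns=["case_id", "rater_id", "level",
                                "sagittal", "coronal", "axial"]).to_csv(path, index=False)


def read_diagnosis_file(path) -> list[DiagnosisLabel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("case_id", "rater_id", "level", "sagittal", "coronal", "axial")
               if c not in df.columns]
    if missing:
        raise LandmarkParseError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        axial = row.axial if row.axial != "" else None
        out.append(DiagnosisLabel(row.case_id, row.rater_id, row.level,
                                  row.sagittal, row.coronal, axial))
    return out


def diagnoses_to_frame(labels: Iterable[DiagnosisLabel]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(l) for l in labels])
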