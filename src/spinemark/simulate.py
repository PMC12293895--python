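"""Forward generator for geometrically consistent landmark cohorts.

The generator is the study-design stand-in for a hospital radiograph
archive: it draws per-level segmental angles from configurable
distributions, builds AP and lateral landmark sets that *exactly*
realize those angles under the same geometric constructions the
analysis inverts (centerline angles, cylindrical pedicle projection,
sacral asymmetry), optionally perturbs every landmark with Gaussian
annotation jitter, and simulates raters who apply latent per-level
cutoffs with optional label noise.

Because the forward model and the measurement model share their
geometry, a zero-jitter cohort is an exact oracle: every angle computed
from the landmarks equals the generating parameter to machine
precision.  Ground truth is always recorded pre-jitter.

Default study conditions
------------------------
* 5 raters, cases partitioned evenly and *disjointly* among them (each
  rater reads their own cases, so inter-rater agreement is out of
  scope by design).
* Sagittal angle means increase caudally (2, 4, 6, 9, 12 degrees for
  L1-L5), echoing the natural lordotic curvature; SD 8 degrees.
* Coronal angles ~ N(0, 2.5 deg); axial rotations ~ N(0, 6 deg); SDs
  chosen so the default latent cutoffs sit well inside the sampled
  angle range (a recovery experiment is only informative where the
  data have density).
* Pedicle half-angle alpha ~ N(30, 3) degrees; annotation jitter SD
  0.5 px.
* Latent rater cutoffs default to the published per-level reference
  angles (flexion/extension pairs, bending and rotation magnitudes),
  which skews flexion calls far above extension calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import s1_rotation_screen, AngleRecord
from .landmarks import (
    APSacrumMarkers,
    APVertebraMarkers,
    CaseLandmarks,
    DiagnosisLabel,
    LatSacrumMarkers,
    LatVertebraMarkers,
    LUMBAR_LEVELS,
    Point2D,
    write_diagnosis_file,
    write_landmark_file,
)
from .refdata import REFERENCE_CUTOFFS
from .thresholds import classify_sagittal, classify_magnitude

_MAX_REDRAWS = 100


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SpineGenParams:
    """Cohort generation parameters (angles in degrees, lengths in pixels)."""

    n_cases: int = 100
    sagittal_mean: tuple[float, ...] = (2.0, 4.0, 6.0, 9.0, 12.0)  # L1..L5
    sagittal_sd: float = 8.0
    coronal_sd: float = 2.5
    axial_sd: float = 6.0
    alpha_mean: float = 30.0        # pedicle half-angle
    alpha_sd: float = 3.0
    width_range: tuple[float, float] = (100.0, 140.0)
    height_range: tuple[float, float] = (70.0, 100.0)
    jitter_sd: float = 0.5
    sacral_sigma: float = 0.05      # SD of the signed sacral offset; r = |offset|
    s1_tilt_sd: float = 3.0         # lateral-view S1 line tilt
    ap_s1_tilt_sd: float = 2.0      # AP-view S1 line tilt
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 0:
            raise SimulationError("n_cases must be >= 0")
        if len(self.sagittal_mean) != 5:
            raise SimulationError("sagittal_mean needs one value per lumbar level")
        for name in ("sagittal_sd", "coronal_sd", "axial_sd", "alpha_sd",
                     "jitter_sd", "sacral_sigma", "s1_tilt_sd", "ap_s1_tilt_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not (self.width_range[0] > 0 and self.height_range[0] > 0):
            raise SimulationError("widths/heights must be positive")
        if not 5.0 < self.alpha_mean < 80.0:
            raise SimulationError("alpha_mean must lie in (5, 80) degrees")


def _default_cutoffs(kind: str) -> dict[str, tuple[float, ...]]:
    if kind == "sagittal":
        return {lvl: (REFERENCE_CUTOFFS["flexion"][i], REFERENCE_CUTOFFS["extension"][i])
                for i, lvl in enumerate(LUMBAR_LEVELS)}
    key = "lateral_bending" if kind == "coronal" else "rotation"
    return {lvl: (REFERENCE_CUTOFFS[key][i],) for i, lvl in enumerate(LUMBAR_LEVELS)}


@dataclass(frozen=True)
class RaterProfile:
    """A simulated rater: latent per-level cutoffs plus label noise."""

    rater_id: str
    sagittal_cutoffs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: _default_cutoffs("sagittal"))
    coronal_cutoffs: dict[str, tuple[float]] = field(
        default_factory=lambda: _default_cutoffs("coronal"))
    axial_cutoffs: dict[str, tuple[float]] = field(
        default_factory=lambda: _default_cutoffs("axial"))
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 1.0:
            raise SimulationError("label_noise must lie in [0, 1)")
        for lvl, pair in self.sagittal_cutoffs.items():
            if not pair[0] < pair[1]:
                raise SimulationError(f"{lvl}: sagittal cutoffs must be ordered")


def default_profiles(n_raters: int = 5, label_noise: float = 0.0,
                     seed: int = 0) -> list[RaterProfile]:
    """Raters sharing the reference latent cutoffs, with distinct seeds."""
    return [RaterProfile(rater_id=f"R{i + 1}", label_noise=label_noise,
                         seed=seed + i)
            for i in range(n_raters)]


# ---------------------------------------------------------------------------
# Forward geometry
# ---------------------------------------------------------------------------

def _up(phi_deg: float) -> tuple[float, float]:
    """Unit vector pointing 'up' (superior) for a centerline orientation phi."""
    r = math.radians(phi_deg)
    return math.sin(r), -math.cos(r)


def _across(phi_deg: float) -> tuple[float, float]:
    """Unit vector across the vertebra (toward +x for phi = 0)."""
    r = math.radians(phi_deg)
    return math.cos(r), math.sin(r)


@dataclass
class _CaseDraw:
    sagittal: np.ndarray      # (5,) signed, L1..L5
    coronal: np.ndarray       # (5,) signed; + = bending toward patient left
    axial: np.ndarray         # (5,) signed; + = rotation toward patient left
    alpha: np.ndarray         # (5,) pedicle half-angle
    width: np.ndarray         # (5,)
    height: np.ndarray        # (5,)
    s1_tilt_lat: float
    s1_tilt_ap: float
    sacral_offset: float      # signed; r = |offset|


def _draw_case(params: SpineGenParams, rng: np.random.Generator) -> _CaseDraw:
    def redraw(draw, ok):
        for _ in range(_MAX_REDRAWS):
            v = draw()
            if ok(v):
                return v
        raise SimulationError("exceeded redraw budget; parameters too extreme")

    sag = np.array([redraw(lambda m=m: rng.normal(m, params.sagittal_sd),
                           lambda v: abs(v) < 45.0)
                    for m in params.sagittal_mean])
    cor = np.array([redraw(lambda: rng.normal(0.0, params.coronal_sd),
                           lambda v: abs(v) < 45.0) for _ in range(5)])
    alpha = np.array([redraw(lambda: rng.normal(params.alpha_mean, params.alpha_sd),
                             lambda v: 5.0 < v < 80.0) for _ in range(5)])
    axial = np.empty(5)
    for i in range(5):
        axial[i] = redraw(lambda: rng.normal(0.0, params.axial_sd),
                          lambda v: abs(v) < alpha[i] - 1.0
                          and alpha[i] + abs(v) < 89.0)
    width = rng.uniform(*params.width_range, size=5)
    height = rng.uniform(*params.height_range, size=5)
    s1_lat = redraw(lambda: rng.normal(0.0, params.s1_tilt_sd), lambda v: abs(v) < 30)
    s1_ap = redraw(lambda: rng.normal(0.0, params.ap_s1_tilt_sd), lambda v: abs(v) < 30)
    sac = redraw(lambda: rng.normal(0.0, params.sacral_sigma), lambda v: abs(v) < 0.9)
    return _CaseDraw(sag, cor, axial, alpha, width, height, s1_lat, s1_ap, sac)


def _build_lateral(draw: _CaseDraw) -> tuple[dict[str, LatVertebraMarkers],
                                             LatSacrumMarkers]:
    # Orientations accumulate caudally->cranially: L5 sits on the S1 normal.
    phi = {}
    phi["L5"] = draw.s1_tilt_lat + draw.sagittal[4]
    for i in (3, 2, 1, 0):
        phi[LUMBAR_LEVELS[i]] = phi[LUMBAR_LEVELS[i + 1]] + draw.sagittal[i]

    # S1 line: orientation 90 + tilt (near-horizontal), length 90 px.
    t = draw.s1_tilt_lat
    vx, vy = _across(t)  # direction of the S1 superior line
    base = (250.0, 800.0)
    s1 = LatSacrumMarkers(Point2D(base[0] - 45.0 * vx, base[1] - 45.0 * vy),
                          Point2D(base[0] + 45.0 * vx, base[1] + 45.0 * vy))

    verts: dict[str, LatVertebraMarkers] = {}
    top = base
    gap = 12.0
    for i in reversed(range(5)):
        lvl = LUMBAR_LEVELS[i]
        w, h, p = draw.width[i], draw.height[i], phi[lvl]
        ux, uy = _up(p)
        wx, wy = _across(p)
        center = (top[0] + (gap + h / 2.0) * ux, top[1] + (gap + h / 2.0) * uy)
        sup = (center[0] + ux * h / 2.0, center[1] + uy * h / 2.0)
        inf = (center[0] - ux * h / 2.0, center[1] - uy * h / 2.0)
        verts[lvl] = LatVertebraMarkers(
            lvl,
            g1=Point2D(sup[0] - wx * w / 2.0, sup[1] - wy * w / 2.0),
            g2=Point2D(sup[0] + wx * w / 2.0, sup[1] + wy * w / 2.0),
            h1=Point2D(inf[0] - wx * w / 2.0, inf[1] - wy * w / 2.0),
            h2=Point2D(inf[0] + wx * w / 2.0, inf[1] + wy * w / 2.0))
        top = sup
    return verts, s1


def _build_ap(draw: _CaseDraw) -> tuple[dict[str, APVertebraMarkers],
                                        APSacrumMarkers]:
    zeta = {}
    zeta["L5"] = draw.s1_tilt_ap + draw.coronal[4]
    for i in (3, 2, 1, 0):
        zeta[LUMBAR_LEVELS[i]] = zeta[LUMBAR_LEVELS[i + 1]] + draw.coronal[i]

    t = draw.s1_tilt_ap
    vx, vy = _across(t)
    base = (250.0, 800.0)
    sac_w = 100.0
    d1 = Point2D(base[0] + vx * sac_w / 2.0, base[1] + vy * sac_w / 2.0)  # patient left
    d2 = Point2D(base[0] - vx * sac_w / 2.0, base[1] - vy * sac_w / 2.0)
    nx, ny = -vy, vx  # perpendicular to the plateau, pointing into the sacrum
    ala_mid = (base[0] + nx * 40.0, base[1] + ny * 40.0)
    ala_half = 80.0
    e1 = Point2D(ala_mid[0] + vx * ala_half, ala_mid[1] + vy * ala_half)
    e2 = Point2D(ala_mid[0] - vx * ala_half, ala_mid[1] - vy * ala_half)
    # S2 spinous midpoint: projection offset = sacral_offset * half-span.
    f = Point2D(ala_mid[0] + vx * draw.sacral_offset * ala_half + nx * 30.0,
                ala_mid[1] + vy * draw.sacral_offset * ala_half + ny * 30.0)
    sacrum = APSacrumMarkers(d1, d2, e1, e2, f)

    verts: dict[str, APVertebraMarkers] = {}
    top = base
    gap = 12.0
    for i in reversed(range(5)):
        lvl = LUMBAR_LEVELS[i]
        w, h, z = draw.width[i], draw.height[i], zeta[lvl]
        R = w / 2.0
        a_rad = math.radians(draw.alpha[i])
        b_rad = math.radians(draw.axial[i])
        ux, uy = _up(z)
        wx, wy = _across(z)  # toward patient left
        center = (top[0] + (gap + h / 2.0) * ux, top[1] + (gap + h / 2.0) * uy)
        sup = (center[0] + ux * h / 2.0, center[1] + uy * h / 2.0)
        inf = (center[0] - ux * h / 2.0, center[1] - uy * h / 2.0)
        y_off = R * math.sin(a_rad - b_rad)   # patient-left pedicle
        x_off = R * math.sin(a_rad + b_rad)   # patient-right pedicle
        verts[lvl] = APVertebraMarkers(
            lvl,
            a1=Point2D(sup[0] + wx * w / 2.0, sup[1] + wy * w / 2.0),
            a2=Point2D(sup[0] - wx * w / 2.0, sup[1] - wy * w / 2.0),
            b1=Point2D(inf[0] + wx * w / 2.0, inf[1] + wy * w / 2.0),
            b2=Point2D(inf[0] - wx * w / 2.0, inf[1] - wy * w / 2.0),
            c1=Point2D(center[0] + wx * y_off, center[1] + wy * y_off),
            c2=Point2D(center[0] - wx * x_off, center[1] - wy * x_off))
        top = sup
    return verts, sacrum


def _jitter_case(case: CaseLandmarks, sd: float,
                 rng: np.random.Generator) -> CaseLandmarks:
    if sd == 0.0:
        return case

    def jp(pt: Point2D) -> Point2D:
        return Point2D(pt.x + rng.normal(0.0, sd), pt.y + rng.normal(0.0, sd))

    ap = {lvl: APVertebraMarkers(lvl, *(jp(getattr(v, n)) for n in
                                        ("a1", "a2", "b1", "b2", "c1", "c2")))
          for lvl, v in case.ap_vertebrae.items()}
    s = case.ap_sacrum
    sac = APSacrumMarkers(*(jp(getattr(s, n)) for n in ("d1", "d2", "e1", "e2", "f")))
    lat = {lvl: LatVertebraMarkers(lvl, *(jp(getattr(v, n)) for n in
                                          ("g1", "g2", "h1", "h2")))
           for lvl, v in case.lat_vertebrae.items()}
    lsac = LatSacrumMarkers(jp(case.lat_sacrum.s1_ant), jp(case.lat_sacrum.s1_post))
    return CaseLandmarks(case.case_id, ap, sac, lat, lsac, case.pixel_spacing)


def generate_case(params: SpineGenParams, case_index: int,
                  rng: Optional[np.random.Generator] = None
                  ) -> tuple[CaseLandmarks, list[AngleRecord]]:
    """Generate one case and its pre-jitter ground-truth angle records.

    The truth records carry ``s1_pass=None``: screen eligibility is a
    cohort-level property assigned by :func:`generate_cohort`.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + case_index)
    case_id = f"case{case_index:05d}"
    draw = _draw_case(params, rng)
    lat, lsac = _build_lateral(draw)
    ap, sac = _build_ap(draw)
    case = CaseLandmarks(case_id, ap, sac, lat, lsac)
    case = _jitter_case(case, params.jitter_sd, rng)
    truth = [AngleRecord(case_id, LUMBAR_LEVELS[i],
                         sagittal_angle=float(draw.sagittal[i]),
                         coronal_angle=float(abs(draw.coronal[i])),
                         coronal_side=("left" if draw.coronal[i] > 0
                                       else "right" if draw.coronal[i] < 0 else "none"),
                         axial_angle=float(draw.axial[i]),
                         s1_r=float(abs(draw.sacral_offset)), s1_pass=None)
             for i in range(5)]
    return case, truth


def simulate_rater(truth: Sequence[AngleRecord], profile: RaterProfile,
                   rng: Optional[np.random.Generator] = None
                   ) -> list[DiagnosisLabel]:
    """Label ground-truth angles with a rater's latent cutoffs plus noise.

    Each label is independently replaced by a uniformly chosen
    *different* label of the same dimension with probability
    ``profile.label_noise``.  L5 axial labels are produced only for
    records with ``s1_pass`` True.
    """
    if rng is None:
        rng = np.random.default_rng(profile.seed)

    def noisy(label: str, vocab: tuple[str, ...]) -> str:
        if profile.label_noise > 0 and rng.random() < profile.label_noise:
            others = [v for v in vocab if v != label]
            return others[rng.integers(len(others))]
        return label

    from .landmarks import AXIAL_LABELS, CORONAL_LABELS, SAGITTAL_LABELS
    out = []
    for rec in truth:
        lvl = rec.level
        sag = classify_sagittal(rec.sagittal_angle, *profile.sagittal_cutoffs[lvl])
        cor_mag = classify_magnitude(rec.coronal_angle,
                                     profile.coronal_cutoffs[lvl][0])
        if cor_mag == "neutral":
            cor = "neutral"
        else:
            cor = "left_bending" if rec.coronal_side == "left" else "right_bending"
        axial: Optional[str]
        if lvl == "L5" and not rec.s1_pass:
            axial = None
        else:
            ax_mag = classify_magnitude(abs(rec.axial_angle),
                                        profile.axial_cutoffs[lvl][0])
            if ax_mag == "neutral":
                axial = "neutral"
            else:
                axial = ("left_rotation" if rec.axial_angle > 0 else "right_rotation")
        out.append(DiagnosisLabel(
            rec.case_id, profile.rater_id, lvl,
            sagittal=noisy(sag, SAGITTAL_LABELS),
            coronal=noisy(cor, CORONAL_LABELS),
            axial=None if axial is None else noisy(axial, AXIAL_LABELS)))
    return out


@dataclass
class Cohort:
    """A generated cohort: landmarks, pre-jitter truth, and rater labels."""

    cases: list[CaseLandmarks]
    truth: list[AngleRecord]
    labels: list[DiagnosisLabel]
    assignments: dict[str, str]          # case_id -> rater_id
    screen_cutoff: Optional[float]

    def write(self, out_dir) -> dict[str, Path]:
        """Write landmark, label, and ground-truth files; returns paths."""
        from .geometry import write_angle_file
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"landmarks": out / "landmarks.csv",
                 "landmarks_json": out / "landmarks.json",
                 "labels": out / "diagnoses.csv",
                 "truth": out / "ground_truth.csv"}
        write_landmark_file(self.cases, paths["landmarks"])
        from .landmarks import write_landmark_json
        write_landmark_json(self.cases, paths["landmarks_json"])
        write_diagnosis_file(self.labels, paths["labels"])
        write_angle_file(self.truth, paths["truth"])
        return paths


def generate_cohort(params: SpineGenParams,
                    profiles: Sequence[RaterProfile],
                    build_landmarks: bool = True) -> Cohort:
    """Generate a full cohort and its rater labels.

    Cases are partitioned disjointly across raters round-robin (case i
    goes to profile i mod n), so n_cases = 2000 with 5 raters yields
    400 cases each.  The sacral screen (Q3 + 1.5 IQR over the cohort's
    true r values) fixes which cases are L5-rotation eligible before
    labeling.  With ``build_landmarks=False`` only truth and labels are
    produced (cheap path for labeling experiments).
    """
    if not profiles:
        raise SimulationError("at least one rater profile is required")
    rng = np.random.default_rng(params.seed)
    cases: list[CaseLandmarks] = []
    truth: list[AngleRecord] = []
    draws: list[_CaseDraw] = []
    # Draw all case parameters first, then (optionally) build/jitter the
    # landmarks: truth is then identical whether or not landmarks exist.
    for i in range(params.n_cases):
        case_id = f"case{i:05d}"
        draw = _draw_case(params, rng)
        draws.append(draw)
        truth += [AngleRecord(case_id, LUMBAR_LEVELS[k],
                              float(draw.sagittal[k]), float(abs(draw.coronal[k])),
                              ("left" if draw.coronal[k] > 0
                               else "right" if draw.coronal[k] < 0 else "none"),
                              float(draw.axial[k]),
                              float(abs(draw.sacral_offset)), None)
                  for k in range(5)]

    if build_landmarks:
        for i, draw in enumerate(draws):
            lat, lsac = _build_lateral(draw)
            ap, sac = _build_ap(draw)
            cases.append(_jitter_case(
                CaseLandmarks(f"case{i:05d}", ap, sac, lat, lsac),
                params.jitter_sd, rng))

    r_values = [abs(d.sacral_offset) for d in draws]
    if len(r_values) >= 4:
        cutoff, mask = s1_rotation_screen(r_values)
    else:
        cutoff, mask = None, np.zeros(len(r_values), dtype=bool)
    for rec in truth:
        idx = int(rec.case_id[4:])
        rec.s1_pass = bool(mask[idx])

    assignments = {f"case{i:05d}": profiles[i % len(profiles)].rater_id
                   for i in range(params.n_cases)}
    labels: list[DiagnosisLabel] = []
    for profile in profiles:
        mine = [rec for rec in truth
                if assignments[rec.case_id] == profile.rater_id]
        labels += simulate_rater(mine, profile,
                                 np.random.default_rng(profile.seed))
    return Cohort(cases, truth, labels, assignments, cutoff)
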