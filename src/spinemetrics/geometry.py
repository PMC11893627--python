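"""Clinical spinopelvic parameters from a landmark set.

Computes the seven quantities a spine surgeon reads off a bi-planar
radiograph: coronal Cobb angles (up to three curves, most caudal
first), thoracic kyphosis (THK, T5 superior to T12 inferior endplate),
lumbar lordosis (LL, L1 superior endplate to sacral endplate), sagittal
vertical axis (SVA, C7 plumb line to the posterior-superior sacral
corner), sacral slope (SS), pelvic tilt (PT) and pelvic incidence (PI).

Sign conventions (image y points down):

* :func:`endplate_angle` is the line's angle to the horizontal in
  (-90, 90], positive when the endplate goes *up to the right*
  (frontal) / up anteriorly (lateral, anterior = +x).
* THK and LL are positive for physiologic kyphosis/lordosis.
* SVA is positive when the C7 plumb line falls anterior to the sacral
  reference; PT is positive for posterior pelvic tilt (retroversion).
* PI = SS + PT is a geometric identity; PI is nevertheless computed
  independently from the endplate normal and the hip axis, and the
  identity is checked, not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmarks import LandmarkSet, Point, midpoint
from .levels import LEVELS, LEVEL_INDEX, N_LEVELS, corner_keys

__all__ = [
    "CobbCurve",
    "SpinopelvicParameters",
    "endplate_angle",
    "curves_from_inclinations",
    "cobb_angles",
    "thoracic_kyphosis",
    "lumbar_lordosis",
    "sagittal_vertical_axis",
    "sacral_slope",
    "pelvic_tilt",
    "pelvic_incidence",
    "compute_parameters",
]

SCOLIOSIS_THRESHOLD_DEG = 10.0
#: inclination magnitude below which a profile extremum is not treated
#: as a curve end vertebra (suppresses numerical jitter on straight spines)
MIN_END_TILT_DEG = 0.25


@dataclass
class CobbCurve:
    upper_end_level: str
    lower_end_level: str
    apex_level: str
    angle_deg: float
    sub_scoliotic: bool = False


@dataclass
class SpinopelvicParameters:
    """The seven clinical outputs with availability flags.

    ``cobb_curves`` is ordered most caudal first; angles are unsigned.
    ``pi_consistency_deg`` records |PI - (SS + PT)| when all three were
    computed (a geometric identity; values above 0.01 deg indicate an
    inconsistent landmark set).
    """

    cobb_curves: list[CobbCurve] = field(default_factory=list)
    thk_deg: float | None = None
    ll_deg: float | None = None
    sva_mm: float | None = None
    ss_deg: float | None = None
    pt_deg: float | None = None
    pi_deg: float | None = None
    available: dict[str, bool] = field(default_factory=dict)
    pi_consistency_deg: float | None = None

    def as_row(self) -> dict:
        row = {
            "thk_deg": self.thk_deg,
            "ll_deg": self.ll_deg,
            "sva_mm": self.sva_mm,
            "ss_deg": self.ss_deg,
            "pt_deg": self.pt_deg,
            "pi_deg": self.pi_deg,
        }
        for i in range(3):
            if i < len(self.cobb_curves):
                c = self.cobb_curves[i]
                row[f"cobb{i + 1}_deg"] = c.angle_deg
                row[f"cobb{i + 1}_apex"] = c.apex_level
                row[f"cobb{i + 1}_upper"] = c.upper_end_level
                row[f"cobb{i + 1}_lower"] = c.lower_end_level
            else:
                row[f"cobb{i + 1}_deg"] = None
                row[f"cobb{i + 1}_apex"] = None
                row[f"cobb{i + 1}_upper"] = None
                row[f"cobb{i + 1}_lower"] = None
        row.update({f"has_{k}": v for k, v in self.available.items()})
        return row


# ---------------------------------------------------------------------------
# primitives


def endplate_angle(point_a: Point, point_b: Point) -> float:
    """Signed angle (deg) of the line a-b versus the horizontal,
    in (-90, 90], corrected for the y-down image frame so an endplate
    going up to the right is positive.  Direction-free: swapping the
    points does not change the result."""
    dx = point_b[0] - point_a[0]
    dy = point_b[1] - point_a[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("endplate_angle: coincident points")
    ang = np.degrees(np.arctan2(-dy, dx))
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return float(ang)


def _superior_line(landmarks: LandmarkSet, view: str, level: str) -> tuple[Point, Point]:
    k = corner_keys(view)
    c = landmarks.vertebrae[view][level]
    return c[k[0]], c[k[1]]


def _inferior_line(landmarks: LandmarkSet, view: str, level: str) -> tuple[Point, Point]:
    k = corner_keys(view)
    c = landmarks.vertebrae[view][level]
    return c[k[2]], c[k[3]]


def _centroid(landmarks: LandmarkSet, view: str, level: str) -> np.ndarray:
    pts = np.array(list(landmarks.vertebrae[view][level].values()))
    return pts.mean(axis=0)


# ---------------------------------------------------------------------------
# Cobb angles


def curves_from_inclinations(
    inclinations_deg: np.ndarray,
    smooth_halfwidth: int = 2,
    min_tilt_deg: float = MIN_END_TILT_DEG,
) -> list[tuple[int, int]]:
    """End-vertebra search on a per-level coronal inclination profile.

    The profile is smoothed with a +/- ``smooth_halfwidth`` moving
    average, local extrema exceeding ``min_tilt_deg`` in magnitude are
    kept, each is refined to the most-tilted vertebra within one level
    on the raw profile (the smoothed profile can tie on a plateau at
    the stack boundary, and the most-tilted vertebra is the clinical
    end-vertebra definition anyway), and consecutive opposite-sign
    extrema are paired into curves.  Returns (upper_end_index,
    lower_end_index) pairs, cranial to caudal.
    """
    t = np.asarray(inclinations_deg, dtype=float)
    n = len(t)
    w = 2 * smooth_halfwidth + 1
    padded = np.pad(t, smooth_halfwidth, mode="edge")
    u = np.convolve(padded, np.ones(w) / w, mode="valid")
    ext = np.pad(u, 1, mode="constant")  # virtual zero beyond both ends
    extrema: list[int] = []
    for i in range(1, len(ext) - 1):
        if abs(ext[i]) < min_tilt_deg:
            continue
        if (ext[i] > ext[i - 1] and ext[i] >= ext[i + 1]) or (
            ext[i] < ext[i - 1] and ext[i] <= ext[i + 1]
        ):
            extrema.append(i - 1)
    refined: list[int] = []
    for e in extrema:
        sign = np.sign(u[e])
        best, best_val = e, -np.inf
        for j in range(max(0, e - 1), min(n, e + 2)):
            if np.sign(t[j]) == sign and abs(t[j]) > best_val:
                best, best_val = j, abs(t[j])
        if refined and refined[-1] == best:
            continue
        refined.append(best)
    pairs = []
    for a, b in zip(refined, refined[1:]):
        if t[a] * t[b] < 0:
            pairs.append((a, b))
    return pairs


def cobb_angles(landmarks: LandmarkSet, view: str = "frontal") -> list[CobbCurve]:
    """Coronal Cobb angles from the frontal landmark set.

    Per-vertebra inclination is the mean of the superior and inferior
    endplate angles; end vertebrae come from
    :func:`curves_from_inclinations`; each curve's angle is the
    unsigned difference between the upper end vertebra's superior and
    the lower end vertebra's inferior endplate angle.  The apex is the
    vertebra between the ends whose centroid deviates farthest from the
    line joining the end-vertebra centroids.  At most the three largest
    curves are kept, ordered most caudal first; curves under 10 deg are
    reported but flagged sub-scoliotic.
    """
    if landmarks.n_levels(view) < N_LEVELS:
        raise ValueError("cobb_angles requires all 18 labeled vertebrae")
    incl = np.empty(N_LEVELS)
    for i, level in enumerate(LEVELS):
        sup = endplate_angle(*_superior_line(landmarks, view, level))
        inf = endplate_angle(*_inferior_line(landmarks, view, level))
        incl[i] = 0.5 * (sup + inf)
    curves = []
    for ui, li in curves_from_inclinations(incl):
        upper, lower = LEVELS[ui], LEVELS[li]
        angle = abs(
            endplate_angle(*_superior_line(landmarks, view, upper))
            - endplate_angle(*_inferior_line(landmarks, view, lower))
        )
        cu, cl = _centroid(landmarks, view, upper), _centroid(landmarks, view, lower)
        axis = cl - cu
        axis /= np.hypot(*axis)
        apex, best = None, -1.0
        for j in range(ui, li + 1):
            c = _centroid(landmarks, view, LEVELS[j])
            d = c - cu
            dev = abs(axis[0] * d[1] - axis[1] * d[0])
            if dev > best:
                best, apex = dev, LEVELS[j]
        curves.append(
            CobbCurve(
                upper_end_level=upper,
                lower_end_level=lower,
                apex_level=apex,
                angle_deg=float(angle),
                sub_scoliotic=angle < SCOLIOSIS_THRESHOLD_DEG,
            )
        )
    curves.sort(key=lambda c: c.angle_deg, reverse=True)
    curves = curves[:3]
    curves.sort(key=lambda c: LEVEL_INDEX[c.apex_level], reverse=True)
    return curves


# ---------------------------------------------------------------------------
# sagittal parameters


def thoracic_kyphosis(landmarks: LandmarkSet) -> float:
    """THK (deg): T12 inferior minus T5 superior endplate angle in the
    lateral view; positive for kyphosis."""
    for lvl in ("T5", "T12"):
        if not landmarks.has_level("lateral", lvl):
            raise KeyError(f"thoracic_kyphosis: missing level {lvl}")
    return endplate_angle(*_inferior_line(landmarks, "lateral", "T12")) - endplate_angle(
        *_superior_line(landmarks, "lateral", "T5")
    )


def lumbar_lordosis(landmarks: LandmarkSet) -> float:
    """LL (deg): L1 superior endplate angle minus sacral endplate angle
    in the lateral view; positive for lordosis."""
    if not landmarks.has_level("lateral", "L1"):
        raise KeyError("lumbar_lordosis: missing level L1")
    sac = landmarks.sacral_points("lateral")
    if sac is None:
        raise KeyError("lumbar_lordosis: missing sacral endplate")
    return endplate_angle(*_superior_line(landmarks, "lateral", "L1")) - endplate_angle(
        *sac
    )


def sagittal_vertical_axis(landmarks: LandmarkSet) -> float:
    """SVA (mm): horizontal offset from the vertical through the C7
    body centroid to the posterior(-superior) sacral endplate point;
    positive when the plumb line is anterior (anterior = +x)."""
    if not landmarks.has_level("lateral", "C7"):
        raise KeyError("sagittal_vertical_axis: missing C7")
    sac = landmarks.sacral["lateral"]
    if "posterior" not in sac:
        raise KeyError("sagittal_vertical_axis: missing posterior sacral point")
    c7x = float(_centroid(landmarks, "lateral", "C7")[0])
    return (c7x - sac["posterior"][0]) * landmarks.pixel_spacing_mm


def sacral_slope(anterior: Point, posterior: Point) -> float:
    """SS (deg): inclination of the sacral endplate to the horizontal,
    unsigned, in [0, 90)."""
    return abs(endplate_angle(posterior, anterior))


def pelvic_tilt(sacral_midpoint: Point, hip_axis_midpoint: Point) -> float:
    """PT (deg): signed angle to the vertical of the line from the
    hip-axis midpoint to the sacral-endplate midpoint; positive when
    the sacral midpoint lies posterior to the hip axis."""
    vx = sacral_midpoint[0] - hip_axis_midpoint[0]
    vy = sacral_midpoint[1] - hip_axis_midpoint[1]
    if vx == 0.0 and vy == 0.0:
        raise ValueError("pelvic_tilt: coincident midpoints")
    return float(np.degrees(np.arctan2(-vx, -vy)))


def pelvic_incidence(
    anterior: Point, posterior: Point, hip_axis_midpoint: Point
) -> float:
    """PI (deg): signed angle between the caudally directed sacral
    endplate normal at the endplate midpoint and the line from that
    midpoint to the hip-axis midpoint.  Computed independently of SS
    and PT; geometrically PI = SS + PT."""
    mid = midpoint(anterior, posterior)
    ex = anterior[0] - posterior[0]
    ey = anterior[1] - posterior[1]
    norm = np.hypot(ex, ey)
    if norm == 0.0:
        raise ValueError("pelvic_incidence: degenerate sacral endplate")
    nx, ny = -ey / norm, ex / norm
    if ny < 0:  # caudally directed normal (y down)
        nx, ny = -nx, -ny
    hx = hip_axis_midpoint[0] - mid[0]
    hy = hip_axis_midpoint[1] - mid[1]
    if hx == 0.0 and hy == 0.0:
        raise ValueError("pelvic_incidence: hip axis coincides with sacral midpoint")
    a_n = np.degrees(np.arctan2(nx, ny))
    a_h = np.degrees(np.arctan2(hx, hy))
    return float(a_h - a_n)


# ---------------------------------------------------------------------------
# assembly


def compute_parameters(landmarks: LandmarkSet) -> SpinopelvicParameters:
    """All seven parameters from one landmark set, with per-parameter
    availability flags instead of exceptions for missing structures."""
    p = SpinopelvicParameters()
    avail = p.available

    try:
        p.cobb_curves = cobb_angles(landmarks)
        avail["cobb"] = True
    except (KeyError, ValueError):
        avail["cobb"] = False

    for name, fn in (("thk", thoracic_kyphosis), ("ll", lumbar_lordosis),
                     ("sva", sagittal_vertical_axis)):
        try:
            setattr(p, f"{name}_deg" if name != "sva" else "sva_mm", fn(landmarks))
            avail[name] = True
        except (KeyError, ValueError):
            avail[name] = False

    sac = landmarks.sacral_points("lateral")
    sac_mid = landmarks.sacral["lateral"].get("midpoint")
    hip_mid = landmarks.femoral["lateral"].get("hip_axis_midpoint")
    try:
        if sac is None:
            raise KeyError("sacral endplate missing")
        p.ss_deg = sacral_slope(*sac)
        avail["ss"] = True
    except (KeyError, ValueError):
        avail["ss"] = False
    try:
        if sac_mid is None or hip_mid is None:
            raise KeyError("midpoints missing")
        p.pt_deg = pelvic_tilt(sac_mid, hip_mid)
        avail["pt"] = True
    except (KeyError, ValueError):
        avail["pt"] = False
    try:
        if sac is None or hip_mid is None:
            raise KeyError("inputs missing")
        p.pi_deg = pelvic_incidence(sac[0], sac[1], hip_mid)
        avail["pi"] = True
    except (KeyError, ValueError):
        avail["pi"] = False

    if avail.get("ss") and avail.get("pt") and avail.get("pi"):
        p.pi_consistency_deg = abs(p.pi_deg - (p.ss_deg + p.pt_deg))
    return p
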