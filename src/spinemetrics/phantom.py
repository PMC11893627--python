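"""Synthetic bi-planar radiograph phantoms with exact ground truth.

The phantom emulates a standing-patient frontal/lateral radiograph pair:
18 quadrilateral vertebral bodies (C7..L5) stacked along a curved
centerline, a sacral endplate segment, two femoral-head circles, and a
smooth soft-tissue background whose horizontal projected-intensity
profile shows bright head / shoulder / pelvis bands separated by dark
neck and abdomen bands -- the structure the histogram-based ROI cropper
exploits.

Every requested clinical parameter is realized analytically, so the
emitted landmark set carries exact truth values for Cobb angles,
thoracic kyphosis (THK, T5-T12), lumbar lordosis (LL, L1-S1), sagittal
vertical axis (SVA), sacral slope (SS), pelvic tilt (PT) and pelvic
incidence (PI = SS + PT).

Conventions
-----------
Image frame: origin top-left, x rightwards, y downwards, units px;
``pixel_spacing_mm`` converts to mm.  In the lateral view anterior is
+x.  Sagittal endplate tilt ``phi`` is positive when the anterior edge
lies lower (larger y); the physiologic sacral endplate therefore has
``phi = SS``.  Frontal endplate tilt ``tau`` is positive when the
endplate goes up to the right ("clinically up-to-the-right").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .levels import (
    FRONTAL_CORNERS,
    LATERAL_CORNERS,
    LEVEL_INDEX,
    LEVELS,
    N_LEVELS,
    VIEWS,
)

__all__ = [
    "PhantomConfig",
    "BandModel",
    "SpineGeometry",
    "RadiographPair",
    "MaskSet",
    "UnrealizableGeometryError",
    "generate_geometry",
    "render_pair",
    "rasterize_masks",
]

#: half-span, in levels, between a curve apex and each end vertebra
CURVE_END_OFFSET = 3
#: levels at which a curve's tilt contribution has decayed back to zero
CURVE_SUPPORT = 6


class UnrealizableGeometryError(ValueError):
    """Raised when a requested configuration cannot be realized
    (e.g. coronal curves that would make vertebrae overlap or leave
    the image)."""


@dataclass(frozen=True)
class BandModel:
    """Soft-tissue background intensity model for one view.

    Three bright Gaussian bands (head, shoulder girdle, pelvis) and two
    dark bands (neck, abdomen) ride on a constant base; a horizontal
    Gaussian torso profile multiplies everything so the vertical
    projected profile has a single peak.
    Band positions are y coordinates in px; amplitudes are fractions of
    the unit intensity range.
    """

    head_y: float
    shoulder_y: float
    pelvis_y: float
    neck_y: float
    abdomen_y: float
    torso_x: float
    base: float = 0.30
    bright_amp: tuple[float, float, float] = (0.50, 0.55, 0.60)
    bright_sigma: tuple[float, float, float] = (35.0, 30.0, 35.0)
    dark_amp: tuple[float, float] = (0.15, 0.12)
    dark_sigma: tuple[float, float] = (18.0, 45.0)
    torso_sigma: float = 120.0

    def row_intensity(self, height: int) -> np.ndarray:
        """Background intensity as a function of y (before the torso
        profile)."""
        y = np.arange(height, dtype=float)
        out = np.full(height, self.base)
        for c, a, s in zip(
            (self.head_y, self.shoulder_y, self.pelvis_y),
            self.bright_amp,
            self.bright_sigma,
        ):
            out += a * np.exp(-0.5 * ((y - c) / s) ** 2)
        for c, a, s in zip(
            (self.neck_y, self.abdomen_y), self.dark_amp, self.dark_sigma
        ):
            out -= a * np.exp(-0.5 * ((y - c) / s) ** 2)
        return np.clip(out, 0.02, 1.0)

    def torso_profile(self, width: int) -> np.ndarray:
        x = np.arange(width, dtype=float)
        return np.exp(-0.5 * ((x - self.torso_x) / self.torso_sigma) ** 2)

    def render(self, height: int, width: int) -> np.ndarray:
        return np.outer(self.row_intensity(height), self.torso_profile(width))


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic subject.

    ``coronal_curves`` lists up to three scoliotic curves as
    ``(apex_level, target_cobb_deg)``; apexes must lie between T3 and L1
    and be at least ``CURVE_SUPPORT`` levels apart.  Curve convexity
    alternates, most caudal curve first.
    """

    image_height_px: int = 960
    image_width_px: int = 512
    pixel_spacing_mm: float = 1.0
    coronal_curves: tuple[tuple[str, float], ...] = ()
    thk_deg: float = 35.0
    ll_deg: float = 50.0
    ss_deg: float = 40.0
    pt_deg: float = 15.0
    vertebra_height_mm: float = 20.0
    disk_gap_mm: float = 8.0
    vertebra_width_mm: tuple[float, float] = (25.0, 35.0)  # C7 -> L5 taper
    sacral_endplate_mm: float = 45.0
    sacral_disk_radius_mm: float = 5.0
    femoral_radius_mm: float = 11.0
    hip_offset_mm: float = 70.0
    noise_sd: float = 0.02
    spine_top_y_px: float = 200.0
    lateral_spine_x_px: float = 300.0
    frontal_spine_x_px: float = 256.0
    background_bands: dict[str, BandModel] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not 0 <= len(self.coronal_curves) <= 3:
            raise ValueError("0-3 coronal curves supported")
        if not 0.0 < self.ss_deg + self.pt_deg < 90.0:
            raise ValueError("ss_deg + pt_deg must lie in (0, 90) degrees")
        if self.vertebra_height_mm <= 0 or min(self.vertebra_width_mm) <= 0:
            raise ValueError("vertebra dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        apexes = []
        for level, cobb in self.coronal_curves:
            if level not in LEVEL_INDEX:
                raise ValueError(f"unknown apex level {level!r}")
            idx = LEVEL_INDEX[level]
            if not CURVE_END_OFFSET <= idx <= N_LEVELS - 1 - CURVE_END_OFFSET:
                raise UnrealizableGeometryError(
                    f"apex {level} too close to the stack end for a "
                    f"+/-{CURVE_END_OFFSET}-level curve"
                )
            if cobb <= 0:
                raise ValueError("target Cobb angles must be positive")
            apexes.append(idx)
        for a, b in zip(sorted(apexes), sorted(apexes)[1:]):
            if b - a < CURVE_SUPPORT:
                raise UnrealizableGeometryError(
                    "coronal curve apexes must be >= "
                    f"{CURVE_SUPPORT} levels apart"
                )


@dataclass
class SpineGeometry:
    """Exact landmark set for one subject in both views.

    ``vertebrae[view][level]`` maps corner name -> (x, y) px; sacral
    landmarks are ``{anterior, posterior}`` laterally and
    ``{left, right}`` frontally; femoral heads are two circle centers
    plus a common radius per view.  ``truth`` holds the seven clinical
    parameters implied by construction.
    """

    pixel_spacing_mm: float
    vertebrae: dict[str, dict[str, dict[str, tuple[float, float]]]]
    sacral: dict[str, dict[str, tuple[float, float]]]
    femoral: dict[str, dict[str, object]]
    truth: dict[str, object]

    def all_landmarks(self, view: str) -> list[tuple[str, float, float]]:
        """Flatten every landmark of one view as (name, x, y)."""
        out = []
        for level, corners in self.vertebrae[view].items():
            for cname, (x, y) in corners.items():
                out.append((f"{level}.{cname}", x, y))
        for k, (x, y) in self.sacral[view].items():
            out.append((f"sacral.{k}", x, y))
        for i, (x, y) in enumerate(self.femoral[view]["centers"]):
            out.append((f"femoral.{i}", x, y))
        return out


@dataclass
class RadiographPair:
    frontal_image: np.ndarray
    lateral_image: np.ndarray
    pixel_spacing_mm: float
    config: PhantomConfig

    def image(self, view: str) -> np.ndarray:
        return self.frontal_image if view == "frontal" else self.lateral_image


@dataclass
class MaskSet:
    """Binary ground-truth masks aligned to the images.

    Per view: ``vertebra`` is the union of the 18 filled corner
    quadrilaterals, ``c7`` the neck-class target (C7 only), the two
    sacral disks sit on the endplate corner points (anterior/posterior
    laterally, left/right frontally), and ``femoral`` holds both head
    disks.
    """

    masks: dict[str, dict[str, np.ndarray]]  # view -> class -> bool array

    CLASSES = (
        "vertebra",
        "c7",
        "sacral_anterior",
        "sacral_posterior",
        "femoral_a",
        "femoral_b",
    )

    def view(self, view: str) -> dict[str, np.ndarray]:
        return self.masks[view]


# ---------------------------------------------------------------------------
# tilt profiles


def sagittal_tilt_profile(config: PhantomConfig) -> np.ndarray:
    """Per-level sagittal endplate tilt ``phi`` (deg, anterior-down
    positive) realizing THK (T5 sup vs T12 inf) and LL (L1 sup vs sacral
    endplate) exactly.

    Lumbar lordosis is distributed linearly over L5..L1; the thoracic
    tilt ramps linearly from T12 to T5; above T5 the spine curves back
    so the cervicothoracic junction is near vertical.
    """
    ss, ll, thk = config.ss_deg, config.ll_deg, config.thk_deg
    phi = np.zeros(N_LEVELS)
    for k in range(1, 6):  # L1..L5
        phi[LEVEL_INDEX[f"L{k}"]] = ss - ll * (6 - k) / 5.0
    phi_t12 = phi[LEVEL_INDEX["L1"]]
    phi[LEVEL_INDEX["T12"]] = phi_t12
    phi_t5 = phi_t12 + thk
    i5, i12 = LEVEL_INDEX["T5"], LEVEL_INDEX["T12"]
    for i in range(i5, i12 + 1):
        phi[i] = phi_t12 + thk * (i12 - i) / (i12 - i5)
    phi_c7 = phi_t5 - 0.6 * thk
    for i in range(0, i5):
        phi[i] = phi_c7 + (phi_t5 - phi_c7) * i / i5
    return phi


def _curve_basis(apex_idx: int, idx: np.ndarray) -> np.ndarray:
    """Smooth tilt bump of one coronal curve: a sine lobe with unit
    extremes at apex -/+ CURVE_END_OFFSET, decaying to zero at
    apex -/+ CURVE_SUPPORT."""
    d = apex_idx - idx.astype(float)
    s = np.sin(np.pi * d / (2.0 * CURVE_END_OFFSET))
    s[np.abs(d) > CURVE_SUPPORT] = 0.0
    return s


def coronal_tilt_profile(config: PhantomConfig) -> tuple[np.ndarray, list[dict]]:
    """Per-level frontal endplate tilt ``tau`` (deg, up-to-right
    positive) whose end-vertebra tilt differences equal the requested
    Cobb angles exactly.

    Overlapping tails of adjacent curves are compensated by solving a
    small linear system for the lobe amplitudes.  Returns the profile
    and the curve records (caudal first).
    """
    idx = np.arange(N_LEVELS)
    curves = sorted(
        config.coronal_curves, key=lambda c: LEVEL_INDEX[c[0]], reverse=True
    )
    if not curves:
        return np.zeros(N_LEVELS), []
    from .geometry import curves_from_inclinations

    m = len(curves)
    pol = np.array([(-1.0) ** j for j in range(m)])  # caudal curve convex right
    apex = np.array([LEVEL_INDEX[lvl] for lvl, _ in curves])
    target = np.array([c for _, c in curves])
    basis = np.stack([_curve_basis(a, idx) for a in apex])  # (m, 18)
    upper = apex - CURVE_END_OFFSET
    lower = apex + CURVE_END_OFFSET

    # Fixed point: solve lobe amplitudes so the signed tilt difference
    # across each curve's end vertebrae equals its target Cobb, then
    # let the downstream end-vertebra search re-identify the ends
    # (smoothing and boundary clipping can move them by a level) and
    # re-solve at the recovered ends until both agree.  Truth records
    # then carry exactly the ends the measurement will find, with the
    # target angle realized at those ends.
    tau = None
    for _ in range(6):
        A = np.empty((m, m))
        for j in range(m):
            for k in range(m):
                A[j, k] = pol[k] * (basis[k, upper[j]] - basis[k, lower[j]])
        try:
            amp = np.linalg.solve(A, pol * target)
        except np.linalg.LinAlgError:
            raise UnrealizableGeometryError(
                "coronal curve end vertebrae coincide; apexes too close"
            ) from None
        if np.any(amp <= 0):
            raise UnrealizableGeometryError(
                "coronal curve combination not realizable with "
                "alternating convexity"
            )
        tau = (pol * amp) @ basis
        pairs = curves_from_inclinations(tau)
        if len(pairs) != m:
            raise UnrealizableGeometryError(
                f"end-vertebra search finds {len(pairs)} curves, "
                f"{m} requested; increase apex separation"
            )
        found = pairs[::-1]  # caudal first, matching curve order
        if all(
            f == (u, l) for f, u, l in zip(found, upper, lower)
        ):
            break
        upper = np.array([f[0] for f in found])
        lower = np.array([f[1] for f in found])
        if np.any(upper >= apex) or np.any(lower <= apex):
            raise UnrealizableGeometryError(
                "recovered end vertebrae do not bracket a requested apex"
            )
    else:
        raise UnrealizableGeometryError(
            "end-vertebra placement did not converge; configuration "
            "unrealizable"
        )

    for j in range(m):
        realized = abs(tau[upper[j]] - tau[lower[j]])
        if abs(realized - target[j]) > 0.49:
            raise UnrealizableGeometryError(
                f"realized Cobb {realized:.2f} deg deviates from target "
                f"{target[j]:.2f} deg"
            )
    records = []
    for j in range(m):
        records.append(
            {
                "angle_deg": float(target[j]),
                "apex_level": LEVELS[apex[j]],
                "upper_end_level": LEVELS[upper[j]],
                "lower_end_level": LEVELS[lower[j]],
            }
        )
    return tau, records


# ---------------------------------------------------------------------------
# geometry construction


def _stack_centers(
    anchor: tuple[float, float],
    tilt_deg: np.ndarray,
    heights_px: np.ndarray,
    gap_px: float,
    down_normal,
) -> np.ndarray:
    """Stack 18 vertebra centers from C7 downward along the local
    endplate normals."""
    centers = np.empty((N_LEVELS, 2))
    centers[0] = anchor
    for i in range(1, N_LEVELS):
        d_prev = down_normal(tilt_deg[i - 1])
        d_cur = down_normal(tilt_deg[i])
        m = d_prev + d_cur
        m /= np.hypot(*m)
        step = heights_px[i - 1] / 2.0 + gap_px + heights_px[i] / 2.0
        centers[i] = centers[i - 1] + m * step
    return centers


def _lateral_down(phi_deg: float) -> np.ndarray:
    p = np.deg2rad(phi_deg)
    return np.array([-np.sin(p), np.cos(p)])


def _frontal_down(tau_deg: float) -> np.ndarray:
    t = np.deg2rad(tau_deg)
    return np.array([np.sin(t), np.cos(t)])


def _quad_corners_lateral(center, phi_deg, w, h):
    p = np.deg2rad(phi_deg)
    u = np.array([np.cos(p), np.sin(p)])  # posterior -> anterior
    n = np.array([np.sin(p), -np.cos(p)])  # up
    c = np.asarray(center)
    return {
        "superior_anterior": tuple(c + n * h / 2 + u * w / 2),
        "superior_posterior": tuple(c + n * h / 2 - u * w / 2),
        "inferior_anterior": tuple(c - n * h / 2 + u * w / 2),
        "inferior_posterior": tuple(c - n * h / 2 - u * w / 2),
    }


def _quad_corners_frontal(center, tau_deg, w, h):
    t = np.deg2rad(tau_deg)
    u = np.array([np.cos(t), -np.sin(t)])  # left -> right, up-to-right positive
    n = np.array([-np.sin(t), -np.cos(t)])  # up
    c = np.asarray(center)
    return {
        "superior_left": tuple(c + n * h / 2 - u * w / 2),
        "superior_right": tuple(c + n * h / 2 + u * w / 2),
        "inferior_left": tuple(c - n * h / 2 - u * w / 2),
        "inferior_right": tuple(c - n * h / 2 + u * w / 2),
    }


def _check_disjoint(view: str, verts: dict[str, dict[str, tuple[float, float]]]):
    polys = []
    for level in LEVELS:
        c = verts[level]
        keys = LATERAL_CORNERS if view == "lateral" else FRONTAL_CORNERS
        ring = [c[keys[0]], c[keys[1]], c[keys[3]], c[keys[2]]]
        poly = Polygon(ring)
        if not poly.is_valid or poly.area <= 0:
            raise UnrealizableGeometryError(
                f"{view} {level} quadrilateral degenerate or self-intersecting"
            )
        polys.append(poly)
    for a, b in zip(polys, polys[1:]):
        if a.intersects(b):
            raise UnrealizableGeometryError(
                f"{view} vertebrae overlap; configuration unrealizable"
            )


def generate_geometry(
    config: PhantomConfig, rng: np.random.Generator | None = None
) -> SpineGeometry:
    """Build the exact landmark set realizing ``config``.

    Deterministic given ``config.seed``; ``rng`` (or a generator seeded
    from the config) only jitters nothing structural -- it is accepted
    for interface symmetry with :func:`render_pair`.
    """
    config.validate()
    sp = config.pixel_spacing_mm
    phi = sagittal_tilt_profile(config)
    tau, cobb_records = coronal_tilt_profile(config)

    h_px = np.full(N_LEVELS, config.vertebra_height_mm / sp)
    w0, w1 = config.vertebra_width_mm
    w_px = np.linspace(w0, w1, N_LEVELS) / sp
    gap_px = config.disk_gap_mm / sp

    lat_centers = _stack_centers(
        (config.lateral_spine_x_px, config.spine_top_y_px),
        phi,
        h_px,
        gap_px,
        _lateral_down,
    )
    fro_centers = _stack_centers(
        (config.frontal_spine_x_px, config.spine_top_y_px),
        tau,
        h_px,
        gap_px,
        _frontal_down,
    )
    # center each stack about the configured column so the torso peak
    # (which anchors the ROI crops left-right) stays over the spine
    lat_centers[:, 0] += config.lateral_spine_x_px - lat_centers[:, 0].mean()
    fro_centers[:, 0] += config.frontal_spine_x_px - fro_centers[:, 0].mean()

    # truth apex = the most laterally deviated vertebra of the realized
    # curve (the clinical definition); asymmetric lobe interactions can
    # place it one level off the nominal apex the lobe was centered on
    for rec in cobb_records:
        ui = LEVEL_INDEX[rec["upper_end_level"]]
        li = LEVEL_INDEX[rec["lower_end_level"]]
        cu, cl = fro_centers[ui], fro_centers[li]
        axis = cl - cu
        axis = axis / np.hypot(*axis)
        devs = [
            abs(axis[0] * (fro_centers[j] - cu)[1] - axis[1] * (fro_centers[j] - cu)[0])
            for j in range(ui, li + 1)
        ]
        rec["apex_level"] = LEVELS[ui + int(np.argmax(devs))]

    vertebrae: dict[str, dict] = {"frontal": {}, "lateral": {}}
    for i, level in enumerate(LEVELS):
        vertebrae["lateral"][level] = _quad_corners_lateral(
            lat_centers[i], phi[i], w_px[i], h_px[i]
        )
        vertebrae["frontal"][level] = _quad_corners_frontal(
            fro_centers[i], tau[i], w_px[i], h_px[i]
        )
    for view in VIEWS:
        _check_disjoint(view, vertebrae[view])

    # sacral endplate -- lateral realizes SS exactly
    ss_r = np.deg2rad(config.ss_deg)
    e_dir = np.array([np.cos(ss_r), np.sin(ss_r)])  # posterior -> anterior
    n_sac = np.array([-np.sin(ss_r), np.cos(ss_r)])  # down
    l5 = lat_centers[-1]
    sac_mid_lat = l5 + 0.5 * (
        _lateral_down(phi[-1]) + n_sac
    ) / np.hypot(*(_lateral_down(phi[-1]) + n_sac)) * (
        h_px[-1] / 2 + gap_px + 3.0 / sp
    )
    half = config.sacral_endplate_mm / sp / 2.0
    sacral_lat = {
        "anterior": tuple(sac_mid_lat + e_dir * half),
        "posterior": tuple(sac_mid_lat - e_dir * half),
    }
    # hip axis -- lateral realizes PT exactly
    pt_r = np.deg2rad(config.pt_deg)
    hip_mid_lat = sac_mid_lat + (config.hip_offset_mm / sp) * np.array(
        [np.sin(pt_r), np.cos(pt_r)]
    )
    head_dx = 6.0 / sp
    femoral_lat = {
        "centers": [
            tuple(hip_mid_lat - np.array([head_dx, 0.0])),
            tuple(hip_mid_lat + np.array([head_dx, 0.0])),
        ],
        "radius_px": config.femoral_radius_mm / sp,
    }

    l5f = fro_centers[-1]
    sac_mid_fro = l5f + np.array([0.0, h_px[-1] / 2 + gap_px + 3.0 / sp])
    sacral_fro = {
        "left": tuple(sac_mid_fro - np.array([half, 0.0])),
        "right": tuple(sac_mid_fro + np.array([half, 0.0])),
    }
    femoral_fro = {
        "centers": [
            tuple(sac_mid_fro + np.array([-75.0 / sp, 55.0 / sp])),
            tuple(sac_mid_fro + np.array([75.0 / sp, 55.0 / sp])),
        ],
        "radius_px": config.femoral_radius_mm / sp,
    }

    c7_center = lat_centers[0]
    sva_mm = (c7_center[0] - sacral_lat["posterior"][0]) * sp

    truth = {
        "cobb": cobb_records,
        "thk_deg": float(config.thk_deg),
        "ll_deg": float(config.ll_deg),
        "ss_deg": float(config.ss_deg),
        "pt_deg": float(config.pt_deg),
        "pi_deg": float(config.ss_deg + config.pt_deg),
        "sva_mm": float(sva_mm),
    }
    return SpineGeometry(
        pixel_spacing_mm=sp,
        vertebrae=vertebrae,
        sacral={"frontal": sacral_fro, "lateral": sacral_lat},
        femoral={"frontal": femoral_fro, "lateral": femoral_lat},
        truth=truth,
    )


# ---------------------------------------------------------------------------
# rendering


def default_bands(geometry: SpineGeometry, config: PhantomConfig) -> dict[str, BandModel]:
    """Derive the background band model from the realized geometry so
    the bright/dark bands sit where the anatomy is."""
    bands = {}
    for view in VIEWS:
        verts = geometry.vertebrae[view]
        c7_y = np.mean([p[1] for p in verts["C7"].values()])
        t2_y = np.mean([p[1] for p in verts["T2"].values()])
        l1_y = np.mean([p[1] for p in verts["L1"].values()])
        hips = geometry.femoral[view]["centers"]
        hip_y = np.mean([p[1] for p in hips])
        spine_x = np.mean([p[0] for p in verts["T7"].values()])
        bands[view] = BandModel(
            head_y=c7_y - 110.0,
            shoulder_y=t2_y,
            pelvis_y=hip_y,
            neck_y=c7_y - 45.0,
            abdomen_y=l1_y,
            torso_x=spine_x,
        )
    return bands


def _bounds_errors(geometry: SpineGeometry, h: int, w: int) -> list[str]:
    bad = []
    for view in VIEWS:
        r = geometry.femoral[view]["radius_px"]
        for name, x, y in geometry.all_landmarks(view):
            margin = r if name.startswith("femoral") else 0.0
            if not (margin <= x < w - margin and margin <= y < h - margin):
                bad.append(f"{view}:{name} at ({x:.1f},{y:.1f})")
    return bad


def _paint_spine(img: np.ndarray, geometry: SpineGeometry, view: str) -> None:
    h, w = img.shape
    keys = LATERAL_CORNERS if view == "lateral" else FRONTAL_CORNERS
    for level in LEVELS:
        c = geometry.vertebrae[view][level]
        ring = [c[keys[0]], c[keys[1]], c[keys[3]], c[keys[2]]]
        rr, cc = draw_polygon(
            [p[1] for p in ring], [p[0] for p in ring], shape=(h, w)
        )
        img[rr, cc] += 0.35
    r_disk = 5.0
    for pt in geometry.sacral[view].values():
        rr, cc = draw_disk((pt[1], pt[0]), r_disk, shape=(h, w))
        img[rr, cc] += 0.40
    fr = geometry.femoral[view]["radius_px"]
    for ctr in geometry.femoral[view]["centers"]:
        rr, cc = draw_disk((ctr[1], ctr[0]), fr, shape=(h, w))
        img[rr, cc] += 0.40


def render_pair(
    geometry: SpineGeometry,
    config: PhantomConfig,
    rng: np.random.Generator | None = None,
) -> RadiographPair:
    """Render both views: background band model + bright bone content +
    additive Gaussian noise (sd ``config.noise_sd``).  Bit-identical
    under a fixed seed."""
    h, w = config.image_height_px, config.image_width_px
    bad = _bounds_errors(geometry, h, w)
    if bad:
        raise UnrealizableGeometryError(
            "geometry outside image bounds: " + "; ".join(bad[:8])
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    bands = config.background_bands or default_bands(geometry, config)
    images = {}
    for view in VIEWS:
        img = bands[view].render(h, w)
        _paint_spine(img, geometry, view)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        images[view] = np.clip(img, 0.0, 1.0).astype(np.float64)
    return RadiographPair(
        frontal_image=images["frontal"],
        lateral_image=images["lateral"],
        pixel_spacing_mm=config.pixel_spacing_mm,
        config=config,
    )


# ---------------------------------------------------------------------------
# masks


def _rasterize_quad(corners: dict, keys, shape) -> np.ndarray:
    ring = [corners[keys[0]], corners[keys[1]], corners[keys[3]], corners[keys[2]]]
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon([p[1] for p in ring], [p[0] for p in ring], shape=shape)
    if rr.size == 0:
        raise ValueError("degenerate (zero-area) vertebra quadrilateral")
    mask[rr, cc] = True
    return mask


def rasterize_masks(geometry: SpineGeometry, config: PhantomConfig) -> MaskSet:
    """Rasterize ground-truth masks: filled vertebra quadrilaterals
    (18 connected components), sacral endplate disks of
    ``sacral_disk_radius_mm`` and femoral-head disks."""
    h, w = config.image_height_px, config.image_width_px
    sp = config.pixel_spacing_mm
    masks: dict[str, dict[str, np.ndarray]] = {}
    for view in VIEWS:
        keys = LATERAL_CORNERS if view == "lateral" else FRONTAL_CORNERS
        vert = np.zeros((h, w), dtype=bool)
        for level in LEVELS:
            vert |= _rasterize_quad(geometry.vertebrae[view][level], keys, (h, w))
        c7 = _rasterize_quad(geometry.vertebrae[view]["C7"], keys, (h, w))
        r_disk = config.sacral_disk_radius_mm / sp
        sac_pts = list(geometry.sacral[view].values())  # (ant, post) or (l, r)
        sac_masks = []
        for pt in sac_pts:
            m = np.zeros((h, w), dtype=bool)
            rr, cc = draw_disk((pt[1], pt[0]), r_disk, shape=(h, w))
            m[rr, cc] = True
            sac_masks.append(m)
        fr = geometry.femoral[view]["radius_px"]
        fem_masks = []
        for ctr in sorted(geometry.femoral[view]["centers"], key=lambda c: c[0]):
            m = np.zeros((h, w), dtype=bool)
            rr, cc = draw_disk((ctr[1], ctr[0]), fr, shape=(h, w))
            m[rr, cc] = True
            fem_masks.append(m)
        masks[view] = {
            "vertebra": vert,
            "c7": c7,
            "sacral_anterior": sac_masks[0],
            "sacral_posterior": sac_masks[1],
            "femoral_a": fem_masks[0],
            "femoral_b": fem_masks[1],
        }
    return MaskSet(masks=masks)


def random_config(
    rng: np.random.Generator,
    n_curves: int | None = None,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> PhantomConfig:
    """Draw a physiologically plausible random subject configuration.

    Ranges reflect the adult ranges the pipeline is meant to cover:
    SS 25-50 deg, PT 5-25 deg, THK 15-45 deg, Cobb 12-40 deg with 0-2
    curves by default.  LL is drawn as SS plus 5-25 deg, mirroring the
    physiologic correlation between lumbar lordosis and sacral slope
    (sampling them independently produces sagittal profiles no
    standing patient exhibits).
    """
    if n_curves is None:
        n_curves = int(rng.integers(0, 3))
    curves: list[tuple[str, float]] = []
    if n_curves == 1:
        apex = LEVELS[int(rng.integers(6, 15))]
        curves = [(apex, float(rng.uniform(12, 40)))]
    elif n_curves == 2:
        caudal = int(rng.integers(12, 15))
        cranial = caudal - int(rng.integers(6, 8))
        major = float(rng.uniform(18, 32))
        curves = [
            (LEVELS[caudal], major),
            (LEVELS[cranial], major * float(rng.uniform(0.55, 0.9))),
        ]
    ss = float(rng.uniform(25, 50))
    cfg = PhantomConfig(
        coronal_curves=tuple(curves),
        thk_deg=float(rng.uniform(15, 45)),
        ll_deg=ss + float(rng.uniform(5, 25)),
        ss_deg=ss,
        pt_deg=float(rng.uniform(5, 25)),
        noise_sd=0.02 if noise_sd is None else noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)) if seed is None else seed,
    )
    return cfg


def random_subject(
    rng: np.random.Generator,
    n_curves: int | None = None,
    noise_sd: float | None = None,
    max_tries: int = 25,
) -> tuple[PhantomConfig, SpineGeometry]:
    """Rejection-sample :func:`random_config` until the configuration
    is realizable (tight double curves occasionally are not), returning
    the config together with its geometry.  Deterministic given the
    generator state."""
    for _ in range(max_tries):
        cfg = random_config(rng, n_curves=n_curves, noise_sd=noise_sd)
        try:
            return cfg, generate_geometry(cfg)
        except UnrealizableGeometryError:
            continue
    raise UnrealizableGeometryError(
        f"no realizable configuration found in {max_tries} draws"
    )
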