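"""From binary ROI masks to named landmarks in full-image coordinates.

The segmenter emits one binary mask per ROI class.  This module turns
them into the landmark set the parameter geometry needs:

1. the neck-ROI C7 prediction replaces whatever the spine ROI put at
   C7's location (the spine network is unreliable at its cranial edge);
2. components caudal to the predicted sacral endplate line are removed
   (the spine network sometimes hallucinates sacral segments);
3. remaining connected components are area-filtered, ordered cranially
   to caudally and labeled C7, T1, .., L5;
4. each component's four corners come from its minimum-area rotated
   rectangle, refined by edge refits to the boundary pixels;
5. sacral endplate points and femoral-head centers are component
   centroids; midpoints are exact averages;
6. everything is mapped back to full-image coordinates through the
   recorded ROI windows.

A sample is a "reasonable segmentation" only if every ROI produced a
prediction and the spine ROI yielded at least 18 vertebral bodies;
failures are flags, not exceptions, so cohort statistics can count
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint

from .landmarks import LandmarkSet, midpoint
from .levels import LEVELS, N_LEVELS, corner_keys
from .preprocess import RoiWindow, forward_to_roi_frame, invert_to_full_frame

__all__ = [
    "VertebraComponent",
    "merge_neck_into_spine",
    "caudal_correction",
    "components_to_vertebrae",
    "extract_corners",
    "sacral_landmarks",
    "femoral_landmarks",
    "assemble_landmark_set",
]

#: components smaller than this fraction of the median component area
#: are treated as specks
MIN_AREA_FRACTION = 0.25
#: absolute floor (px) below which a component is never a vertebra
MIN_AREA_PX = 12


@dataclass
class VertebraComponent:
    """One connected region of the spine mask with its geometry."""

    pixels: np.ndarray  # (n, 2) array of (x, y) pixel coordinates
    centroid: tuple[float, float]
    area: int
    corners: dict[str, tuple[float, float]] | None = None
    level: str | None = None


def _label_components(mask: np.ndarray):
    """8-connected component labeling."""
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndimage.label(mask, structure=structure)
    return labels, n


def merge_neck_into_spine(
    spine_mask: np.ndarray,
    neck_mask: np.ndarray,
    spine_window: RoiWindow,
    neck_window: RoiWindow,
) -> tuple[np.ndarray, dict]:
    """Replace the spine ROI's cranial content with the neck ROI's C7.

    The largest neck-ROI component is taken as C7, mapped into the
    spine ROI frame; spine components whose centroid lies cranial to
    the bottom of the mapped C7 blob (minus half its height) are
    removed, then the blob is pasted in.  An empty neck mask passes the
    spine mask through with a warning flag.
    """
    flags = {"neck_empty": False}
    spine = spine_mask.astype(bool).copy()
    if not neck_mask.any():
        flags["neck_empty"] = True
        return spine, flags

    labels, n = _label_components(neck_mask.astype(bool))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    c7_blob = labels == (1 + int(np.argmax(sizes)))
    ys, xs = np.nonzero(c7_blob)
    pts_roi = np.column_stack([xs, ys]).astype(float)
    full = invert_to_full_frame(pts_roi, neck_window)
    in_spine = forward_to_roi_frame(full, spine_window)
    h, w = spine.shape
    c7_in_spine = np.zeros_like(spine)
    ix = np.round(in_spine[:, 0]).astype(int)
    iy = np.round(in_spine[:, 1]).astype(int)
    ok = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
    c7_in_spine[iy[ok], ix[ok]] = True
    if not c7_in_spine.any():
        flags["neck_empty"] = True
        return spine, flags
    # nearest-neighbour transfer between grids can leave pinholes when
    # the neck ROI is coarser than the spine ROI
    c7_in_spine = ndimage.binary_closing(c7_in_spine, np.ones((3, 3)))

    cy = np.nonzero(c7_in_spine)[0]
    cutoff = cy.max() - 0.5 * (cy.max() - cy.min())
    labels_s, n_s = _label_components(spine)
    for i in range(1, n_s + 1):
        comp = labels_s == i
        if np.nonzero(comp)[0].mean() < cutoff:
            spine[comp] = False
    return spine | c7_in_spine, flags


def caudal_correction(
    spine_mask: np.ndarray,
    sacral_anterior: tuple[float, float] | None,
    sacral_posterior: tuple[float, float] | None,
) -> tuple[np.ndarray, dict]:
    """Remove components whose centroid lies caudal to (below) the
    sacral endplate line; coordinates are in the spine ROI frame.
    Without sacral points the mask passes through flagged."""
    flags = {"no_sacral_points": False}
    spine = spine_mask.astype(bool).copy()
    if sacral_anterior is None or sacral_posterior is None:
        flags["no_sacral_points"] = True
        return spine, flags
    ax, ay = sacral_anterior
    bx, by = sacral_posterior
    labels, n = _label_components(spine)
    for i in range(1, n + 1):
        comp = labels == i
        ys, xs = np.nonzero(comp)
        cx, cy = xs.mean(), ys.mean()
        if bx == ax:
            line_y = (ay + by) / 2.0
        else:
            line_y = ay + (by - ay) * (cx - ax) / (bx - ax)
        if cy > line_y:
            spine[comp] = False
    return spine, flags


def components_to_vertebrae(
    mask: np.ndarray,
) -> tuple[list[VertebraComponent], dict]:
    """Label, area-filter, sort cranio-caudally and assign level names.

    Components below ``MIN_AREA_FRACTION`` of the median area (or the
    absolute floor) are dropped as specks.  The topmost surviving
    component is C7; extra components beyond L5 are truncated caudally
    and flagged.  Fewer than 18 survivors mark the sample incomplete.
    """
    labels, n = _label_components(mask.astype(bool))
    comps: list[VertebraComponent] = []
    areas = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(labels == i)
        areas.append(len(xs))
        comps.append(
            VertebraComponent(
                pixels=np.column_stack([xs, ys]),
                centroid=(float(xs.mean()), float(ys.mean())),
                area=len(xs),
            )
        )
    flags = {"n_components": n, "truncated": False, "complete": False}
    if not comps:
        return [], flags
    med = float(np.median(areas))
    keep = [
        c
        for c in comps
        if c.area >= max(MIN_AREA_PX, MIN_AREA_FRACTION * med)
    ]
    keep.sort(key=lambda c: c.centroid[1])
    if len(keep) > N_LEVELS:
        keep = keep[:N_LEVELS]
        flags["truncated"] = True
    for c, level in zip(keep, LEVELS):
        c.level = level
    flags["n_components"] = len(keep)
    flags["complete"] = len(keep) == N_LEVELS
    return keep, flags


def _min_area_rect_corners(pixels: np.ndarray) -> np.ndarray:
    """Corners of the minimum-area rotated rectangle around the pixel
    centers, via rotating calipers on the convex hull."""
    rect = MultiPoint([tuple(p) for p in pixels]).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # collinear pixels collapse to a line
        raise ValueError("degenerate (line-like) component")
    xy = np.asarray(rect.exterior.coords)[:4]
    return xy


def _snap_to_boundary(corner: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    d = np.hypot(pixels[:, 0] - corner[0], pixels[:, 1] - corner[1])
    return pixels[int(np.argmin(d))].astype(float)


def _boundary_pixels(pixels: np.ndarray) -> np.ndarray:
    """Pixels with at least one missing 4-neighbour."""
    cells = {(int(x), int(y)) for x, y in pixels}
    out = [
        (x, y)
        for x, y in cells
        if not all(
            (x + dx, y + dy) in cells
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1))
        )
    ]
    return np.asarray(out, dtype=float)


def _fit_edge(boundary: np.ndarray, p0: np.ndarray, p1: np.ndarray):
    """Total-least-squares refit of one rectangle edge from the
    boundary pixels lying along the initial edge segment."""
    d = p1 - p0
    length = np.hypot(*d)
    d = d / length
    rel = boundary - p0
    proj = rel @ d
    dist = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])
    sel = boundary[(dist <= 1.3) & (proj >= -1.5) & (proj <= length + 1.5)]
    if len(sel) < 4:
        return p0, d
    c = sel.mean(axis=0)
    _, _, vt = np.linalg.svd(sel - c, full_matrices=False)
    e = vt[0]
    if e @ d < 0:
        e = -e
    return c, e


def _intersect_lines(c1, d1, c2, d2) -> np.ndarray:
    A = np.column_stack([d1, -d2])
    if abs(np.linalg.det(A)) < 1e-9:
        raise ValueError("parallel rectangle edges; degenerate component")
    t = np.linalg.solve(A, c2 - c1)
    return c1 + t[0] * d1


def extract_corners(
    component: VertebraComponent, view: str, snap: bool = False
) -> dict[str, tuple[float, float]]:
    """Four named corners of a rectangular vertebra component.

    The minimum-area rotated rectangle provides the initial edges; each
    edge is then refit by total least squares to the boundary pixels
    lying along it (the min-rect alone is driven by a handful of
    extreme staircase pixels and its orientation jitters by 1-3 deg,
    which endplate angles cannot afford), and corners are the
    intersections of adjacent refitted edges.  The two long edges are
    the endplates, the one with smaller mean y is superior; within each
    endplate, corners are named by x (anterior = +x laterally,
    left/right frontally).  ``snap=True`` moves each corner to the
    nearest component pixel.
    """
    if component.area < MIN_AREA_PX:
        raise ValueError("component too small for corner extraction")
    xy = _min_area_rect_corners(component.pixels)
    if xy.shape[0] < 4 or np.linalg.matrix_rank(xy - xy.mean(0)) < 2:
        raise ValueError("degenerate (line-like) component")
    boundary = _boundary_pixels(component.pixels)
    centroid = component.pixels.mean(axis=0)
    edges = []
    for i in range(4):
        c, e = _fit_edge(boundary, xy[i], xy[(i + 1) % 4])
        # boundary pixel centers sit half a pixel inside the true edge
        n = np.array([-e[1], e[0]])
        if n @ (c - centroid) < 0:
            n = -n
        edges.append((c + 0.5 * n, e))
    xy = np.array(
        [
            _intersect_lines(*edges[(i - 1) % 4], *edges[i])
            for i in range(4)
        ]
    )
    if snap:
        xy = np.array([_snap_to_boundary(c, component.pixels) for c in xy])
    # edges of the rect ring: (0,1),(1,2),(2,3),(3,0); long edges are
    # the endplates (vertebral bodies are wider than tall)
    e01 = np.linalg.norm(xy[0] - xy[1])
    e12 = np.linalg.norm(xy[1] - xy[2])
    if e01 >= e12:
        pairs = [(xy[0], xy[1]), (xy[3], xy[2])]
    else:
        pairs = [(xy[1], xy[2]), (xy[0], xy[3])]
    pairs.sort(key=lambda p: (p[0][1] + p[1][1]))  # superior first
    sup = sorted(pairs[0], key=lambda p: p[0])  # by x ascending
    inf = sorted(pairs[1], key=lambda p: p[0])
    k = corner_keys(view)
    if view == "lateral":
        # anterior = larger x
        return {
            k[0]: tuple(sup[1]),
            k[1]: tuple(sup[0]),
            k[2]: tuple(inf[1]),
            k[3]: tuple(inf[0]),
        }
    return {
        k[0]: tuple(sup[0]),
        k[1]: tuple(sup[1]),
        k[2]: tuple(inf[0]),
        k[3]: tuple(inf[1]),
    }


def _centroid_of(mask: np.ndarray) -> tuple[float, float] | None:
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        return None
    return float(xs.mean()), float(ys.mean())


def sacral_landmarks(
    anterior_mask: np.ndarray, posterior_mask: np.ndarray
) -> tuple[tuple, tuple, tuple] | None:
    """Sacral endplate points as disk-mask centroids plus their exact
    midpoint; ``None`` (failure flag upstream) if either is empty."""
    a = _centroid_of(anterior_mask)
    p = _centroid_of(posterior_mask)
    if a is None or p is None:
        return None
    return a, p, midpoint(a, p)


def _largest_component_centroid(mask: np.ndarray) -> tuple[float, float] | None:
    labels, n = _label_components(mask.astype(bool))
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return _centroid_of(labels == (1 + int(np.argmax(sizes))))


def femoral_landmarks(
    head_mask_a: np.ndarray, head_mask_b: np.ndarray
) -> tuple[list[tuple], tuple, dict] | None:
    """Femoral-head centers from the two head-class masks (one per
    head: posterior/anterior laterally, left/right frontally), with
    the hip-axis midpoint as their exact average.

    With only one nonempty mask that center doubles as the axis point,
    flagged.  Returns ``None`` when both masks are empty.
    """
    centers = [
        c
        for c in (
            _largest_component_centroid(head_mask_a),
            _largest_component_centroid(head_mask_b),
        )
        if c is not None
    ]
    if not centers:
        return None
    centers.sort(key=lambda c: c[0])
    flags = {"single_head": len(centers) == 1}
    if len(centers) == 2:
        mid = midpoint(centers[0], centers[1])
    else:
        mid = centers[0]
    return centers, mid, flags


def assemble_landmark_set(
    per_view_masks: dict[str, dict[str, np.ndarray]],
    windows: dict[str, dict[str, RoiWindow]],
    pixel_spacing_mm: float,
) -> LandmarkSet:
    """Run the full postprocessing chain for both views and map every
    landmark into full-image coordinates.

    ``per_view_masks[view]`` holds binary masks per class in their ROI
    frames: ``spine`` (vertebra class in the spine window), ``neck``
    (C7 class in the neck window), ``sacral_anterior`` /
    ``sacral_posterior`` (sacrum window) and ``femoral`` (femur
    window).  Missing ROIs are simply absent keys.
    """
    ls = LandmarkSet(pixel_spacing_mm=pixel_spacing_mm)
    roi_success: dict[str, dict[str, bool]] = {}
    reasonable = True
    for view, masks in per_view_masks.items():
        wins = windows[view]
        success = {"neck": False, "spine": False, "sacrum": False, "femur": False}

        # sacrum first: its landmarks steer the caudal correction
        sac = None
        if (
            "sacral_anterior" in masks
            and "sacral_posterior" in masks
            and "sacrum" in wins
        ):
            sac = sacral_landmarks(masks["sacral_anterior"], masks["sacral_posterior"])
        if sac is not None:
            names = (
                ("anterior", "posterior") if view == "lateral" else ("left", "right")
            )
            a_full = invert_to_full_frame([sac[0]], wins["sacrum"])[0]
            p_full = invert_to_full_frame([sac[1]], wins["sacrum"])[0]
            ls.sacral[view] = {
                names[0]: tuple(a_full),
                names[1]: tuple(p_full),
                "midpoint": midpoint(tuple(a_full), tuple(p_full)),
            }
            success["sacrum"] = True

        fem = None
        if "femoral_a" in masks and "femoral_b" in masks and "femur" in wins:
            fem = femoral_landmarks(masks["femoral_a"], masks["femoral_b"])
        if fem is not None:
            centers_full = [
                tuple(invert_to_full_frame([c], wins["femur"])[0]) for c in fem[0]
            ]
            if len(centers_full) == 2:
                hip_mid = midpoint(centers_full[0], centers_full[1])
            else:
                hip_mid = centers_full[0]
            ls.femoral[view] = {
                "centers": centers_full,
                "hip_axis_midpoint": hip_mid,
                **({"single_head": True} if fem[2]["single_head"] else {}),
            }
            success["femur"] = not fem[2]["single_head"]

        if "spine" in masks and "spine" in wins:
            spine = masks["spine"]
            merge_flags = {}
            if "neck" in masks and "neck" in wins:
                spine, merge_flags = merge_neck_into_spine(
                    spine, masks["neck"], wins["spine"], wins["neck"]
                )
                success["neck"] = not merge_flags.get("neck_empty", False)
            sac_in_spine = (None, None)
            if sac is not None:
                names = (
                    ("anterior", "posterior") if view == "lateral" else ("left", "right")
                )
                pts = [ls.sacral[view][names[0]], ls.sacral[view][names[1]]]
                mapped = forward_to_roi_frame(pts, wins["spine"])
                sac_in_spine = (tuple(mapped[0]), tuple(mapped[1]))
            spine, _ = caudal_correction(spine, *sac_in_spine)
            comps, comp_flags = components_to_vertebrae(spine)
            sy = wins["spine"]
            # corner extraction in an isotropic frame: anisotropic ROI
            # scaling would bias the rotated-rectangle fit
            for c in comps:
                if c.level is None:
                    continue
                try:
                    full_pix = invert_to_full_frame(c.pixels.astype(float), sy)
                    iso = VertebraComponent(
                        pixels=full_pix, centroid=c.centroid, area=c.area
                    )
                    corners = extract_corners(iso, view, snap=False)
                except ValueError:
                    continue
                ls.vertebrae[view][c.level] = corners
            success["spine"] = comp_flags["complete"] and len(ls.vertebrae[view]) == N_LEVELS
        roi_success[view] = success
        if not (success["spine"] and success["sacrum"] and success["femur"]
                and success["neck"]):
            reasonable = False
    ls.flags = {
        "roi_success": roi_success,
        "reasonable": reasonable,
        "complete": reasonable,
    }
    return ls
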