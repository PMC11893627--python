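"""Histogram-driven ROI cropping with an invertible transform record.

Each radiograph is cropped into four regions of interest -- neck,
spine, sacrum, femur -- located from projected intensity profiles:
summing pixel values along rows gives a horizontal profile whose bright
head / shoulder girdle / pelvis bands form prominent maxima separated
by neck and abdomen minima; summing along columns gives a vertical
profile with a single torso peak.  Maxima are accepted above a normed
intensity threshold of 0.6; the minimum between two accepted maxima is
taken as the separating minimum.

Every crop/resize/normalisation is recorded in a :class:`RoiWindow`
whose forward and inverse mappings round-trip to well under half a
pixel, so landmarks found in ROI frames can be placed back onto the
full radiograph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "IntensityProfile",
    "RoiWindow",
    "ExtremaError",
    "ROI_NAMES",
    "DEFAULT_ROI_SIZES",
    "project_profiles",
    "detect_extrema",
    "derive_windows",
    "crop_resize_normalize",
    "invert_to_full_frame",
    "forward_to_roi_frame",
]

ROI_NAMES = ("neck", "spine", "sacrum", "femur")

#: ROI target sizes (h, w) in px; the spine ROI is tall and narrow
DEFAULT_ROI_SIZES: dict[str, tuple[int, int]] = {
    "neck": (96, 96),
    "spine": (256, 128),
    "sacrum": (128, 128),
    "femur": (128, 128),
}

#: half-widths (px at 1 mm/px) of the left-right crop about the torso peak
ROI_HALF_WIDTHS: dict[str, float] = {
    "neck": 130.0,
    "spine": 140.0,
    "sacrum": 110.0,
    "femur": 130.0,
}

NORMED_THRESHOLD = 0.6
#: moving-average smoothing width as a fraction of the profile length
SMOOTH_FRACTION = 0.02
#: fractional padding added on each side of a derived window
WINDOW_PAD = 0.05


class ExtremaError(ValueError):
    """Structured failure of extremum detection: names the profile and
    how many qualifying extrema were found (feeds the preprocessing
    success statistic)."""

    def __init__(self, axis: str, n_found: int, n_required: int):
        self.axis, self.n_found, self.n_required = axis, n_found, n_required
        super().__init__(
            f"{axis} profile: found {n_found} maxima above threshold, "
            f"need {n_required}"
        )


@dataclass
class IntensityProfile:
    """Projected intensity along one axis, normalized to max 1.

    ``axis`` is ``"horizontal"`` (one value per row: sums across
    columns) or ``"vertical"`` (one value per column)."""

    axis: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class RoiWindow:
    """Invertible crop/resize/normalize record.

    Crop box is the half-open pixel window [x0, x1) x [y0, y1) in
    full-image coordinates; the crop is resized to ``target_hw``.
    ``norm_min``/``norm_max`` record the min-max normalisation applied
    to the resized crop.
    """

    roi_name: str
    view: str
    x0: int
    x1: int
    y0: int
    y1: int
    target_hw: tuple[int, int]
    norm_min: float = 0.0
    norm_max: float = 1.0

    @property
    def scale_y(self) -> float:
        return self.target_hw[0] / (self.y1 - self.y0)

    @property
    def scale_x(self) -> float:
        return self.target_hw[1] / (self.x1 - self.x0)

    def to_dict(self) -> dict:
        return {
            "roi_name": self.roi_name,
            "view": self.view,
            "box": [self.x0, self.x1, self.y0, self.y1],
            "target_hw": list(self.target_hw),
            "norm_min": self.norm_min,
            "norm_max": self.norm_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoiWindow":
        x0, x1, y0, y1 = d["box"]
        return cls(
            roi_name=d["roi_name"],
            view=d["view"],
            x0=x0,
            x1=x1,
            y0=y0,
            y1=y1,
            target_hw=tuple(d["target_hw"]),
            norm_min=d.get("norm_min", 0.0),
            norm_max=d.get("norm_max", 1.0),
        )

    def contains(self, x: float, y: float) -> bool:
        """Strict containment of a full-frame point in the crop box."""
        return self.x0 < x < self.x1 - 1 and self.y0 < y < self.y1 - 1


# ---------------------------------------------------------------------------


def project_profiles(image: np.ndarray) -> tuple[IntensityProfile, IntensityProfile]:
    """Row- and column-sum intensity profiles, each normalized so its
    maximum is 1."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("project_profiles expects a non-empty 2-D image")
    rows = img.sum(axis=1)
    cols = img.sum(axis=0)
    if rows.max() <= 0 or cols.max() <= 0:
        raise ValueError("all-zero image: normalized profile undefined")
    return (
        IntensityProfile("horizontal", rows / rows.max()),
        IntensityProfile("vertical", cols / cols.max()),
    )


def _smooth(values: np.ndarray, fraction: float = SMOOTH_FRACTION) -> np.ndarray:
    half = max(1, int(round(fraction * len(values) / 2)))
    w = 2 * half + 1
    padded = np.pad(values, half, mode="edge")
    return np.convolve(padded, np.ones(w) / w, mode="valid")


def detect_extrema(
    profile: IntensityProfile,
    threshold: float = NORMED_THRESHOLD,
    n_required: int = 0,
) -> list[tuple[int, str]]:
    """Local maxima of the smoothed profile with (re-normalized) value
    >= ``threshold``, plus the global minimum between each pair of
    consecutive accepted maxima.  Returns (index, "max"|"min") sorted
    by index; equal-height plateau maxima keep the earliest index."""
    u = _smooth(profile.values)
    u = u / u.max()
    maxima: list[int] = []
    i = 1
    n = len(u)
    while i < n - 1:
        if u[i] > u[i - 1]:
            j = i
            while j + 1 < n and u[j + 1] == u[j]:
                j += 1
            if j + 1 < n and u[j + 1] < u[i]:
                if u[i] >= threshold:
                    maxima.append(i)
                i = j + 1
                continue
        i += 1
    if len(maxima) < n_required:
        raise ExtremaError(profile.axis, len(maxima), n_required)
    out: list[tuple[int, str]] = []
    for k, m in enumerate(maxima):
        out.append((m, "max"))
        if k + 1 < len(maxima):
            a, b = m, maxima[k + 1]
            out.append((a + 1 + int(np.argmin(u[a + 1 : b])), "min"))
    return out


def _clip_box(x0, x1, y0, y1, shape):
    h, w = shape
    x0 = int(max(0, min(w - 2, round(x0))))
    x1 = int(max(x0 + 1, min(w, round(x1))))
    y0 = int(max(0, min(h - 2, round(y0))))
    y1 = int(max(y0 + 1, min(h, round(y1))))
    return x0, x1, y0, y1


def derive_windows(
    horizontal_extrema: list[tuple[int, str]],
    vertical_extrema: list[tuple[int, str]],
    image_shape: tuple[int, int],
    view: str,
    roi_sizes: dict[str, tuple[int, int]] | None = None,
    pixel_spacing_mm: float = 1.0,
) -> tuple[dict[str, RoiWindow], dict[str, bool]]:
    """Map profile extrema to the four ROI crop boxes.

    Expects three horizontal maxima (head, shoulder, pelvis; the three
    tallest are used if more were detected) with the neck minimum
    between head and shoulder and the abdomen minimum between shoulder
    and pelvis, and a single vertical maximum (torso center).  Rows:

    * neck   -- around the neck minimum, down to the shoulder maximum;
    * spine  -- neck minimum to most of the abdomen-to-pelvis span;
    * sacrum -- upper pelvis region around the sacral endplate;
    * femur  -- pelvis maximum and below (femoral heads).

    Returns (windows, success flags); a missing extremum fails the ROIs
    that need it while the others are still produced.
    """
    roi_sizes = roi_sizes or DEFAULT_ROI_SIZES
    windows: dict[str, RoiWindow] = {}
    success = {name: False for name in ROI_NAMES}

    maxima = [i for i, kind in horizontal_extrema if kind == "max"]
    minima = [i for i, kind in horizontal_extrema if kind == "min"]
    v_maxima = [i for i, kind in vertical_extrema if kind == "max"]
    if not v_maxima:
        return windows, success
    xc = float(np.median(v_maxima))

    if len(maxima) < 2:
        return windows, success
    maxima = sorted(maxima)
    head = maxima[0]
    shoulder = maxima[1]
    pelvis = maxima[-1] if len(maxima) >= 3 else None
    neck_min = next((m for m in minima if head < m < shoulder), None)
    abdomen_min = (
        next((m for m in minima if shoulder < m < pelvis), None)
        if pelvis is not None
        else None
    )

    def make(name, y0, y1):
        half = ROI_HALF_WIDTHS[name] / pixel_spacing_mm
        pad = WINDOW_PAD * (y1 - y0)
        x0, x1, y0c, y1c = _clip_box(
            xc - half, xc + half, y0 - pad, y1 + pad, image_shape
        )
        windows[name] = RoiWindow(
            roi_name=name, view=view, x0=x0, x1=x1, y0=y0c, y1=y1c,
            target_hw=tuple(roi_sizes[name]),
        )
        success[name] = True

    if neck_min is not None:
        make("neck", neck_min - 0.45 * (shoulder - neck_min), shoulder)
    if neck_min is not None and pelvis is not None and abdomen_min is not None:
        make("spine", neck_min, abdomen_min + 0.72 * (pelvis - abdomen_min))
    if pelvis is not None and abdomen_min is not None:
        span = pelvis - abdomen_min
        make("sacrum", abdomen_min + 0.45 * span, pelvis + 0.30 * span)
        make("femur", pelvis - 0.35 * span, pelvis + 0.65 * span)
    return windows, success


def crop_resize_normalize(image: np.ndarray, window: RoiWindow) -> np.ndarray:
    """Crop the window from the full image, resize to the target size,
    min-max normalize to [0, 1] and record the constants on the window."""
    crop = np.asarray(image, dtype=float)[window.y0 : window.y1, window.x0 : window.x1]
    if crop.shape != tuple(window.target_hw):
        crop = _sk_resize(
            crop, window.target_hw, order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    lo, hi = float(crop.min()), float(crop.max())
    window.norm_min, window.norm_max = lo, hi
    if hi > lo:
        crop = (crop - lo) / (hi - lo)
    else:
        crop = np.zeros_like(crop)
    return crop


def crop_resize_mask(mask: np.ndarray, window: RoiWindow) -> np.ndarray:
    """Crop/resize a binary mask through a window (nearest-neighbour,
    no normalization) so image and mask stay aligned in the ROI frame."""
    crop = np.asarray(mask, dtype=float)[window.y0 : window.y1, window.x0 : window.x1]
    if crop.shape != tuple(window.target_hw):
        crop = _sk_resize(
            crop, window.target_hw, order=0, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    return crop >= 0.5


def forward_to_roi_frame(points, window: RoiWindow) -> np.ndarray:
    """Map full-image (x, y) points into the window's ROI frame."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty_like(pts)
    out[:, 0] = (pts[:, 0] - window.x0) * window.scale_x
    out[:, 1] = (pts[:, 1] - window.y0) * window.scale_y
    return out


def invert_to_full_frame(points, window: RoiWindow) -> np.ndarray:
    """Map ROI-frame (x, y) points back to full-image coordinates.
    Forward-then-inverse round-trips exactly (affine algebra)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty_like(pts)
    out[:, 0] = pts[:, 0] / window.scale_x + window.x0
    out[:, 1] = pts[:, 1] / window.scale_y + window.y0
    return out
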