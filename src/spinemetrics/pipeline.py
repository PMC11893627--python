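"""End-to-end orchestration: phantom -> preprocess -> segment ->
postprocess -> parameters.

Two operating modes share all plumbing:

* ``oracle_masks=True`` bypasses the networks and feeds the rasterized
  ground-truth masks through the ROI windows into postprocessing --
  the testing seam that isolates the geometric stages from
  segmentation quality.  Oracle windows keep their native crop size
  (no resize), preserving full landmark resolution.
* with trained models, each ROI image is segmented and binarized at
  0.7 before postprocessing.

Per-sample failures (missing extrema, missing ROIs, incomplete
vertebra counts) are recorded as flags on the result, never raised, so
cohort success statistics can be tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SpinopelvicParameters, compute_parameters
from .landmarks import LandmarkSet
from .levels import LEVELS, VIEWS
from .phantom import (
    MaskSet,
    PhantomConfig,
    RadiographPair,
    SpineGeometry,
    generate_geometry,
    rasterize_masks,
    render_pair,
)
from .postprocess import assemble_landmark_set
from .preprocess import (
    ROI_NAMES,
    ExtremaError,
    RoiWindow,
    crop_resize_mask,
    crop_resize_normalize,
    detect_extrema,
    derive_windows,
    project_profiles,
)
from .segment import BINARIZE_THRESHOLD, InceptionUNet, binarize, predict

__all__ = ["SubjectResult", "preprocess_views", "run_subject", "landmark_rois"]

#: ground-truth landmark names per ROI (for the containment criterion)
def landmark_rois(landmarks: LandmarkSet, view: str) -> dict[str, list[str]]:
    named = dict(landmarks.iter_named(view))
    return {
        "neck": [n for n in named if n.startswith("C7.")],
        "spine": [n for n in named if n.split(".")[0] in LEVELS],
        "sacrum": [n for n in named if n.startswith("sacral.")],
        "femur": [n for n in named if n.startswith("femoral.")],
    }


@dataclass
class SubjectResult:
    config: PhantomConfig
    geometry: SpineGeometry
    truth_landmarks: LandmarkSet
    windows: dict[str, dict[str, RoiWindow]]
    preprocess_success: dict[str, dict[str, bool]]
    preprocess_contained: bool
    predicted_landmarks: LandmarkSet | None
    parameters: SpinopelvicParameters | None
    flags: dict = field(default_factory=dict)

    @property
    def reasonable(self) -> bool:
        return bool(
            self.predicted_landmarks
            and self.predicted_landmarks.flags.get("reasonable", False)
        )


def preprocess_views(
    pair: RadiographPair,
    roi_sizes: dict[str, tuple[int, int]] | None = None,
    resize: bool = True,
) -> tuple[dict[str, dict[str, RoiWindow]], dict[str, dict[str, bool]]]:
    """Derive the four ROI windows for both views from projected
    intensity profiles.  With ``resize=False`` each window keeps its
    native crop size (used in oracle-mask mode)."""
    windows: dict[str, dict[str, RoiWindow]] = {}
    success: dict[str, dict[str, bool]] = {}
    for view in VIEWS:
        img = pair.image(view)
        try:
            hp, vp = project_profiles(img)
            he = detect_extrema(hp)
            ve = detect_extrema(vp)
            wins, succ = derive_windows(
                he,
                ve,
                img.shape,
                view,
                roi_sizes=roi_sizes,
                pixel_spacing_mm=pair.pixel_spacing_mm,
            )
        except (ExtremaError, ValueError):
            wins, succ = {}, {name: False for name in ROI_NAMES}
        if not resize:
            for w in wins.values():
                w.target_hw = (w.y1 - w.y0, w.x1 - w.x0)
        windows[view] = wins
        success[view] = succ
    return windows, success


def _containment(
    landmarks: LandmarkSet, windows: dict[str, dict[str, RoiWindow]]
) -> bool:
    """The preprocessing success rule: every ground-truth landmark of
    every ROI lies strictly inside its window."""
    for view in VIEWS:
        named = dict(landmarks.iter_named(view))
        members = landmark_rois(landmarks, view)
        for roi, names in members.items():
            if roi not in windows[view]:
                return False
            w = windows[view][roi]
            for n in names:
                x, y = named[n]
                if not w.contains(x, y):
                    return False
    return True


def _oracle_roi_masks(
    masks: MaskSet, windows: dict[str, RoiWindow], view: str
) -> dict[str, np.ndarray]:
    out = {}
    classes = masks.view(view)
    if "spine" in windows:
        out["spine"] = crop_resize_mask(classes["vertebra"], windows["spine"])
    if "neck" in windows:
        out["neck"] = crop_resize_mask(classes["c7"], windows["neck"])
    if "sacrum" in windows:
        out["sacral_anterior"] = crop_resize_mask(
            classes["sacral_anterior"], windows["sacrum"]
        )
        out["sacral_posterior"] = crop_resize_mask(
            classes["sacral_posterior"], windows["sacrum"]
        )
    if "femur" in windows:
        out["femoral_a"] = crop_resize_mask(classes["femoral_a"], windows["femur"])
        out["femoral_b"] = crop_resize_mask(classes["femoral_b"], windows["femur"])
    return out


def _predicted_roi_masks(
    pair: RadiographPair,
    windows: dict[str, RoiWindow],
    view: str,
    models: dict[str, InceptionUNet],
) -> dict[str, np.ndarray]:
    """Segment each ROI crop with its trained network and binarize."""
    img = pair.image(view)
    out = {}
    for roi, w in windows.items():
        roi_img = crop_resize_normalize(img, w)
        for cls in _classes_for(roi):
            key = f"{view}:{roi}:{cls}" if f"{view}:{roi}:{cls}" in models else f"{roi}:{cls}"
            if key not in models:
                continue
            prob = predict(models[key], roi_img)
            out[cls] = binarize(prob, BINARIZE_THRESHOLD)
    return out


def _classes_for(roi: str) -> tuple[str, ...]:
    if roi == "sacrum":
        return ("sacral_anterior", "sacral_posterior")
    if roi == "spine":
        return ("spine",)
    if roi == "neck":
        return ("neck",)
    return ("femoral_a", "femoral_b")


def run_subject(
    config: PhantomConfig,
    oracle_masks: bool = True,
    models: dict[str, InceptionUNet] | None = None,
    roi_sizes: dict[str, tuple[int, int]] | None = None,
) -> SubjectResult:
    """Generate one phantom subject and run the full pipeline on it."""
    geometry = generate_geometry(config)
    pair = render_pair(geometry, config)
    truth = LandmarkSet.from_geometry(geometry)
    windows, success = preprocess_views(
        pair, roi_sizes=roi_sizes, resize=not oracle_masks
    )
    contained = _containment(truth, windows)

    per_view_masks: dict[str, dict[str, np.ndarray]] = {}
    if oracle_masks:
        masks = rasterize_masks(geometry, config)
        for view in VIEWS:
            per_view_masks[view] = _oracle_roi_masks(masks, windows[view], view)
    else:
        if not models:
            raise ValueError("run_subject without oracle masks needs models")
        for view in VIEWS:
            per_view_masks[view] = _predicted_roi_masks(
                pair, windows[view], view, models
            )

    predicted = assemble_landmark_set(
        per_view_masks, windows, config.pixel_spacing_mm
    )
    params = compute_parameters(predicted) if predicted.flags.get("reasonable") else None
    return SubjectResult(
        config=config,
        geometry=geometry,
        truth_landmarks=truth,
        windows=windows,
        preprocess_success=success,
        preprocess_contained=contained,
        predicted_landmarks=predicted,
        parameters=params,
    )
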