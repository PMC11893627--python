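"""File formats: 16-bit grayscale images, 8-bit masks, landmark JSON,
window sidecars, manifest and parameter tables.

Images are written as 16-bit PNG (or TIFF by extension) with
intensities scaled from the internal [0, 1] range; masks as 8-bit PNG
(0/255).  Landmark sets use the JSON schema of
:class:`~spinemetrics.landmarks.LandmarkSet`; ROI windows get one JSON
sidecar per subject so postprocessing can invert every crop.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .landmarks import LandmarkSet
from .preprocess import RoiWindow

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_landmarks",
    "read_landmarks",
    "write_windows",
    "read_windows",
    "write_parameter_table",
]


def write_image(path, image01: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(image01, dtype=float), 0.0, 1.0)
    u16 = np.round(arr * 65535).astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, u16)
    else:
        iio.imwrite(path, u16)


def read_image(path) -> np.ndarray:
    """Read a grayscale image into the internal [0, 1] float range."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]
    info = np.iinfo(arr.dtype) if arr.dtype.kind in "iu" else None
    out = arr.astype(float)
    if info is not None and info.max > 0:
        out /= info.max
    return out


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    landmarks.save(path)


def read_landmarks(path) -> LandmarkSet:
    return LandmarkSet.load(path)


def write_windows(windows: dict[str, dict[str, RoiWindow]], path) -> None:
    d = {
        view: {roi: w.to_dict() for roi, w in wins.items()}
        for view, wins in windows.items()
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def read_windows(path) -> dict[str, dict[str, RoiWindow]]:
    with open(path) as fh:
        d = json.load(fh)
    return {
        view: {roi: RoiWindow.from_dict(wd) for roi, wd in wins.items()}
        for view, wins in d.items()
    }


def write_parameter_table(rows: list[dict], path) -> pd.DataFrame:
    """One CSV row per subject: id, completeness, Cobb curves (most
    caudal first), THK, LL, SVA, SS, PT, PI and flags."""
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
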