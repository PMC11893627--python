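"""The pipeline's central intermediate: named anatomical landmarks in
full-image pixel coordinates, for both views.

The same container holds phantom ground truth and pipeline predictions,
so the two are directly comparable (landmark MAD, parameter agreement).
Missing structures are represented by absent keys plus per-ROI
completeness flags, never by sentinel coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

from .levels import LEVELS, VIEWS, corner_keys

Point = tuple[float, float]


def midpoint(a: Point, b: Point) -> Point:
    return ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)


@dataclass
class LandmarkSet:
    """Per view: vertebra corner quadruples (possibly missing levels),
    sacral endplate points with their midpoint, femoral-head centers
    with the hip-axis midpoint; everything in full-image px."""

    pixel_spacing_mm: float
    vertebrae: dict[str, dict[str, dict[str, Point]]] = field(
        default_factory=lambda: {"frontal": {}, "lateral": {}}
    )
    sacral: dict[str, dict[str, Point]] = field(
        default_factory=lambda: {"frontal": {}, "lateral": {}}
    )
    femoral: dict[str, dict] = field(
        default_factory=lambda: {"frontal": {}, "lateral": {}}
    )
    flags: dict[str, object] = field(default_factory=dict)

    # -- construction -------------------------------------------------
    @classmethod
    def from_geometry(cls, geometry) -> "LandmarkSet":
        """Ground-truth landmark set from a phantom geometry."""
        ls = cls(pixel_spacing_mm=geometry.pixel_spacing_mm)
        for view in VIEWS:
            ls.vertebrae[view] = {
                lvl: dict(corners)
                for lvl, corners in geometry.vertebrae[view].items()
            }
            sac = dict(geometry.sacral[view])
            keys = list(sac)
            sac["midpoint"] = midpoint(sac[keys[0]], sac[keys[1]])
            ls.sacral[view] = sac
            centers = [tuple(c) for c in geometry.femoral[view]["centers"]]
            ls.femoral[view] = {
                "centers": centers,
                "hip_axis_midpoint": midpoint(centers[0], centers[1]),
            }
        ls.flags = {
            "complete": True,
            "reasonable": True,
            "roi_success": {v: {"neck": True, "spine": True, "sacrum": True,
                                "femur": True} for v in VIEWS},
        }
        return ls

    # -- queries ------------------------------------------------------
    def has_level(self, view: str, level: str) -> bool:
        return level in self.vertebrae[view]

    def n_levels(self, view: str) -> int:
        return len(self.vertebrae[view])

    def sacral_points(self, view: str) -> tuple[Point, Point] | None:
        """(anterior, posterior) laterally; (left, right) frontally."""
        sac = self.sacral[view]
        names = ("anterior", "posterior") if view == "lateral" else ("left", "right")
        if all(n in sac for n in names):
            return sac[names[0]], sac[names[1]]
        return None

    def iter_named(self, view: str) -> Iterable[tuple[str, Point]]:
        for lvl, corners in self.vertebrae[view].items():
            for cname, pt in corners.items():
                yield f"{lvl}.{cname}", pt
        for k, pt in self.sacral[view].items():
            yield f"sacral.{k}", pt
        fem = self.femoral[view]
        for i, pt in enumerate(fem.get("centers", [])):
            yield f"femoral.center{i}", pt
        if "hip_axis_midpoint" in fem:
            yield "femoral.hip_axis_midpoint", fem["hip_axis_midpoint"]

    # -- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict:
        def pt(p):
            return [float(p[0]), float(p[1])]

        d = {"pixel_spacing_mm": self.pixel_spacing_mm, "views": {}, "flags": self.flags}
        for view in VIEWS:
            d["views"][view] = {
                "vertebrae": {
                    lvl: {k: pt(p) for k, p in corners.items()}
                    for lvl, corners in self.vertebrae[view].items()
                },
                "sacral": {k: pt(p) for k, p in self.sacral[view].items()},
                "femoral": {
                    "centers": [pt(c) for c in self.femoral[view].get("centers", [])],
                    **(
                        {"hip_axis_midpoint": pt(self.femoral[view]["hip_axis_midpoint"])}
                        if "hip_axis_midpoint" in self.femoral[view]
                        else {}
                    ),
                },
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        try:
            ls = cls(pixel_spacing_mm=float(d["pixel_spacing_mm"]))
            for view in VIEWS:
                v = d["views"][view]
                for lvl, corners in v["vertebrae"].items():
                    if lvl not in LEVELS:
                        raise KeyError(f"views.{view}.vertebrae.{lvl}")
                    want = set(corner_keys(view))
                    if set(corners) != want:
                        raise KeyError(
                            f"views.{view}.vertebrae.{lvl}: expected corners {sorted(want)}"
                        )
                    ls.vertebrae[view][lvl] = {
                        k: (float(p[0]), float(p[1])) for k, p in corners.items()
                    }
                ls.sacral[view] = {
                    k: (float(p[0]), float(p[1])) for k, p in v["sacral"].items()
                }
                fem = {"centers": [tuple(map(float, c)) for c in v["femoral"]["centers"]]}
                if "hip_axis_midpoint" in v["femoral"]:
                    fem["hip_axis_midpoint"] = tuple(
                        map(float, v["femoral"]["hip_axis_midpoint"])
                    )
                ls.femoral[view] = fem
            ls.flags = d.get("flags", {})
        except KeyError as exc:
            raise ValueError(f"landmark schema violation at key {exc}") from exc
        return ls

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
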