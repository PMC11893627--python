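"""Histogram-based ROI cropping on a rendered phantom.

Projects image intensity onto the vertical axis, finds the bright
head/shoulder/pelvis bands and dark neck/abdomen bands, derives the
four ROI windows, and checks that every ground-truth landmark landed
inside its window -- the criterion under which a sample counts as
correctly preprocessed.
"""

from spinemetrics import LandmarkSet, PhantomConfig, generate_geometry, render_pair
from spinemetrics.pipeline import landmark_rois, preprocess_views

config = PhantomConfig(seed=7)
geometry = generate_geometry(config)
pair = render_pair(geometry, config)
truth = LandmarkSet.from_geometry(geometry)

windows, success = preprocess_views(pair)
for view in ("frontal", "lateral"):
    named = dict(truth.iter_named(view))
    print(f"{view}:")
    for roi, w in windows[view].items():
        inside = all(
            w.contains(*named[n]) for n in landmark_rois(truth, view)[roi]
        )
        print(f"  {roi:7s} rows {w.y0:4d}-{w.y1:4d} cols {w.x0:3d}-{w.x1:3d} "
              f"landmarks inside: {inside}")
# all four ROIs succeeding in both views = one correctly preprocessed sample
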