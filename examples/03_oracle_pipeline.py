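"""Oracle-mask pipeline: measure parameters from perfect segmentations.

Feeds rasterized ground-truth masks through ROI cropping,
postprocessing (corner extraction, sacral/femoral centroids) and the
parameter geometry, then compares against the phantom's truth.  This
isolates the geometric stages: any error seen here is introduced by
rasterization and landmark extraction, not by a network.
"""

import numpy as np

from spinemetrics import PhantomConfig, run_subject

config = PhantomConfig(coronal_curves=(("T9", 30.0),), seed=3)
result = run_subject(config, oracle_masks=True)

print("reasonable segmentation:", result.reasonable)
p, t = result.parameters, result.geometry.truth
rows = [
    ("THK (deg)", p.thk_deg, t["thk_deg"]),
    ("LL (deg)", p.ll_deg, t["ll_deg"]),
    ("SVA (mm)", p.sva_mm, t["sva_mm"]),
    ("SS (deg)", p.ss_deg, t["ss_deg"]),
    ("PT (deg)", p.pt_deg, t["pt_deg"]),
    ("PI (deg)", p.pi_deg, t["pi_deg"]),
]
print(f"{'parameter':10s} {'measured':>9s} {'truth':>9s} {'error':>7s}")
for name, got, want in rows:
    print(f"{name:10s} {got:9.2f} {want:9.2f} {abs(got - want):7.3f}")
for c in p.cobb_curves:
    print(f"Cobb {c.angle_deg:5.2f} deg (truth {t['cobb'][0]['angle_deg']:.2f}), "
          f"apex {c.apex_level}")
# sub-degree errors: the rasterize -> extract-corners round trip is
# nearly lossless at 1 mm/px
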