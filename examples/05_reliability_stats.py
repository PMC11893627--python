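"""Inter-rater reliability statistics on a small ratings table.

Simulates three raters measuring lumbar lordosis on 10 subjects (two
consistent raters, one with a systematic +3 degree offset) and
computes the absolute-agreement ICC with its 95% CI and reliability
grade.  Absolute agreement penalizes the offset; the consistency-form
ICC would not.
"""

import numpy as np

from spinemetrics import RatingsMatrix, dice_f1, icc_absolute_agreement

rng = np.random.default_rng(0)
truth = rng.normal(50, 8, size=(10, 1))           # true LL per subject
noise = rng.normal(0, 1.5, size=(10, 3))
ratings = truth + noise
ratings[:, 2] += 3.0                              # rater 3 reads high

res = icc_absolute_agreement(RatingsMatrix(ratings, parameter="LL"))
print(f"ICC(A,1) = {res.icc:.3f}  95% CI [{res.ci95[0]:.3f}, {res.ci95[1]:.3f}]")
print(f"grade: {res.grade}")
print(f"ANOVA mean squares: rows {res.msr:.2f}, raters {res.msc:.2f}, "
      f"residual {res.mse:.2f}")
# an ICC near 0.9 despite sub-2-degree noise: the systematic offset
# costs agreement, which is exactly what the absolute form measures
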