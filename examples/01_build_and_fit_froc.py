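"""Build an fROC from confidence counts and fit the mixture model.

A small group dataset (similar-lure and new-item rating counts on a
6-point scale) is tabulated, cumulated into false-memory ROC points, and
fit by least squares.  The printed parameters are the probability of false
recollection (left intercept of the fitted curve), the probability of
recollection rejection (one minus the right intercept), and false
familiarity d' (the curvature); the SSE says how closely the 5 observed
points sit to the fitted curve.
"""

import numpy as np

from frocfit import (
    ConfidenceCounts,
    FitConfig,
    ItemClass,
    RatingScale,
    build_froc,
    fit_sse,
    goodness_of_fit,
)

scale = RatingScale(k_levels=6)  # 1 = sure new ... 6 = sure old
lure = ConfidenceCounts(ItemClass.LURE, np.array([300, 184, 170, 238, 437, 471]), scale)
new = ConfidenceCounts(ItemClass.NEW, np.array([741, 355, 216, 194, 224, 70]), scale)

froc = build_froc(lure, new)
print("fROC x (new):", froc.x.round(3))
print("fROC y (lure):", froc.y.round(3))

result = fit_sse(froc, FitConfig(n_starts=20, seed=0))
report = goodness_of_fit(result, froc)

print(f"false recollection  R_f = {result.params.r_false:.3f}")
print(f"recollection reject R_r = {result.params.r_reject:.3f}")
print(f"false familiarity   d'  = {result.params.d_prime:.3f}")
print(f"sum of squared errors   = {report.sse:.2e}")
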