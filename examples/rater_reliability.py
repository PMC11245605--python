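"""Inter-rater reliability of manual bout scoring via ICC(A,k).

Simulates three raters rescoring the same 56 bouts with per-rater bias and
cell-level noise, then computes the two-way random-effects,
absolute-agreement, average-measure intraclass correlation plus the
pairwise Pearson correlations. An ICC above ~0.9 indicates excellent
agreement — rating noise is small against real bout-to-bout variation.
"""

import numpy as np

from srtkit import icc_absolute_agreement, pearson_r_ci, simulate_raters

rng = np.random.default_rng(4)
truth = rng.gamma(4.0, 2.0, size=56)          # true bout durations, ~8 s mean
ratings = simulate_raters(truth, k=3, noise_sd=1.0, bias_sd=0.5, seed=4)

res = icc_absolute_agreement(ratings)
print(f"ICC(A,k) = {res.icc:.2f}, CI95 {res.ci[0]:.2f}-{res.ci[1]:.2f}, "
      f"F({res.df1:.0f},{res.df2:.0f}) = {res.f:.2f}, p = {res.p:.2g}")
print(f"model: {res.model}")
for i, j in ((0, 1), (0, 2), (1, 2)):
    r, ci, t = pearson_r_ci(ratings[:, i], ratings[:, j])
    print(f"rater {i + 1} vs rater {j + 1}: r({t.df:.0f}) = {r:.2f}, "
          f"CI95 {ci[0]:.2f}-{ci[1]:.2f}")
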