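"""The two association analyses: latitude regression and frequency shift.

First, target-allele frequency is regressed on the absolute latitude of
each sampled population's collection centroid (recently migrated
populations excluded upstream).  Second, a paired Wilcoxon signed-rank
test asks whether European target-allele frequencies are shifted
relative to African ones over a shared site list, with the
Hodges-Lehmann pseudomedian as the shift estimate.
"""

import numpy as np

from mirvar import centroid_latitude, fit_latitude_model, paired_shift_test

# latitude gradient: frequency falls by 0.01 per degree of |latitude|
rng = np.random.default_rng(7)
lats = rng.uniform(0, 60, 18)
freqs = 0.8 - 0.01 * lats + rng.normal(0, 0.02, lats.size)
fit = fit_latitude_model(list(zip(lats, freqs)))
print(f"slope {fit.slope:+.5f} per degree, intercept {fit.intercept:.3f}, "
      f"adj R^2 {fit.r2_adjusted:.3f}, p {fit.p_value:.2e}, n {fit.n}")

# a population sampled at two collection points: plate carree centroid
print("effective |latitude| of two points:",
      centroid_latitude([(10.0, 40.0), (20.0, 44.0)]))

# EUR-minus-AFR frequency shift over 500 shared sites, true shift +0.02
afr = rng.uniform(0.05, 0.9, 500)
eur = np.clip(afr + rng.normal(0.02, 0.05, 500), 0, 1)
res = paired_shift_test(afr, eur)
print(f"n {res.n_pairs}, p {res.p_value:.2e}, "
      f"HL shift {res.shift_median:.4f}, 95% CI ({res.ci95[0]:.4f}, {res.ci95[1]:.4f})")
# A positive shift median means the target allele is more frequent in
# the European than in the African frequency vector.
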