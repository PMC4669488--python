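"""Generate a synthetic liver-donor cohort and inspect its MPPGL distribution.

The generator is calibrated so marginal trait distributions match published
population summaries of a 128-donor liver bank; every donor carries a latent
MPPGL used later to verify estimator round-trips.
"""

import numpy as np

from hepscale import default_cohort_spec, generate_cohort, summarize_mppgl

cohort = generate_cohort(default_cohort_spec(n_donors=128, seed=1))
mppgl = [d.true_mppgl for d in cohort]
summary = summarize_mppgl(mppgl)

print(f"donors: {len(cohort)}")
print(f"MPPGL mean ± SD: {summary.stats.mean:.2f} ± {summary.stats.sd:.2f} mg/g")
print(f"range: {summary.stats.min:.2f}–{summary.stats.max:.2f} mg/g "
      f"({summary.stats.fold_minmax:.1f}-fold)")
print(f"95% PI: {summary.stats.p2_5:.2f}–{summary.stats.p97_5:.2f} mg/g "
      f"({summary.stats.fold_pi:.1f}-fold)")
print(f"female fraction: {np.mean([d.gender == 'female' for d in cohort]):.2f}")
# The mean sits near 39.46 mg/g with an SD near 21.57 and a 10–19-fold spread:
# microsomal yield per gram of liver varies enormously between individuals.
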