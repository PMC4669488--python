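"""Estimate MPPGL from POR (cytochrome-c reduction) activities.

Shows both entry points: an absorbance trace converted to a POR rate via
Beer–Lambert, and the homogenate/microsome rate ratio that yields MPPGL.
"""

import numpy as np

from hepscale import (
    AbsorbanceTrace,
    PORPair,
    estimate_mppgl,
    generate_por_pairs,
    default_cohort_spec,
    generate_cohort,
    por_rate_from_trace,
)

# a clean kinetic read: 0.0211 AU/min over 5 min, 5 µg protein in 220 µL
t = np.linspace(0, 5, 11)
trace = AbsorbanceTrace(t, 0.10 + 0.0211 * t, protein_mass_mg=0.005)
rate = por_rate_from_trace(trace)
print(f"microsomal POR rate: {rate.rate:.1f} nmol/min/mg (R² = {rate.r_squared:.4f})")

# the ratio estimator: homogenate activity per g over microsomal per mg
pair = PORPair("demo", homogenate_rate=394.6, microsome_rate=10.0)
print(f"MPPGL = 394.6 / 10.0 = {estimate_mppgl(pair).mppgl:.2f} mg/g")

# round-trip on synthetic donors: the ratio recovers the latent value exactly
cohort = generate_cohort(default_cohort_spec(n_donors=3, seed=2))
for donor, p in zip(cohort, generate_por_pairs(cohort, seed=2)):
    est = estimate_mppgl(p)
    print(f"{donor.donor_id}: latent {donor.true_mppgl:.3f} -> estimated {est.mppgl:.3f} mg/g")
# Matched pairs share the assay noise, so the ratio inverts exactly.
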