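"""Per-liver CYP activities (V_L) and the V_M -> V_L rank-change analysis.

Scaling microsomal rates by each donor's MPPGL widens apparent variability
and reshuffles donor rankings — the point of expressing activity per gram
of liver rather than per mg of microsomal protein.
"""

from hepscale import (
    CYP_VM_SPECS,
    compute_vl,
    default_cohort_spec,
    generate_cohort,
    generate_vm_table,
    rank_change_analysis,
    summarize_activity,
)

cohort = generate_cohort(default_cohort_spec(n_donors=78, seed=3))
vm = generate_vm_table(cohort, CYP_VM_SPECS, seed=3)
vl = compute_vl(vm, {d.donor_id: d.true_mppgl for d in cohort})

print("isoform    fold(V_M)  fold(V_L)")
for iso, grp in vl.groupby("isoform"):
    f_vm = summarize_activity(grp["vm_pmol_min_mg"]).fold_minmax
    f_vl = summarize_activity(grp["vl_nmol_min_g"]).fold_minmax
    print(f"{iso:10s} {f_vm:8.1f} {f_vl:10.1f}")

report = rank_change_analysis(vl)
shares = report.band_shares.set_index("isoform")
print("\nshare of donors whose rank moved >20% of the cohort:")
for iso, row in shares.iterrows():
    print(f"  {iso:10s} {100 * (row['obvious'] + row['dramatic']):5.1f}%")
# V_L fold-changes exceed the corresponding V_M fold-changes because MPPGL
# variability compounds the microsomal variability, and a third or more of
# donors shift their population rank noticeably once MPPGL is applied.
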