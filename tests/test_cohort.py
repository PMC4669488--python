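"""Synthetic cohort generator: calibration, determinism, round-trips."""

import dataclasses

import numpy as np
import pytest

from hepscale import (
    CohortSpec,
    TraitSpec,
    cohort_to_frame,
    default_cohort_spec,
    estimate_mppgl,
    fit_michaelis_menten,
    generate_cohort,
    generate_kinetics,
    generate_por_pairs,
    generate_vm_table,
)
from hepscale.datasets import CYP_VM_SPECS


class TestGenerateCohort:
    def test_empty_cohort(self):
        assert generate_cohort(default_cohort_spec(n_donors=0)) == []

    def test_degenerate_sd_gives_constant_trait(self):
        spec = default_cohort_spec(n_donors=5)
        spec.mppgl = TraitSpec(39.46, 0.0, (6.71, 127.95))
        cohort = generate_cohort(spec)
        assert all(d.true_mppgl == 39.46 for d in cohort)

    def test_deterministic_given_seed(self):
        a = cohort_to_frame(generate_cohort(default_cohort_spec(64, seed=7)))
        b = cohort_to_frame(generate_cohort(default_cohort_spec(64, seed=7)))
        c = cohort_to_frame(generate_cohort(default_cohort_spec(64, seed=8)))
        assert a.equals(b)
        assert not a.equals(c)

    def test_calibrated_mppgl_mean_within_10pct(self):
        cohort = generate_cohort(default_cohort_spec(n_donors=128, seed=0))
        mean = np.mean([d.true_mppgl for d in cohort])
        assert abs(mean - 39.46) / 39.46 < 0.10
        assert all(6.71 <= d.true_mppgl <= 127.95 for d in cohort)

    def test_moment_calibration_with_wide_bounds(self):
        spec = default_cohort_spec(n_donors=10_000, seed=5)
        spec.mppgl = TraitSpec(39.46, 21.57, (1e-6, 1e6))
        spec.vmax = TraitSpec(255.82, 79.48, (1e-6, 1e6))
        cohort = generate_cohort(spec)
        mppgl = np.array([d.true_mppgl for d in cohort])
        vmax = np.array([d.true_vmax for d in cohort])
        assert abs(mppgl.mean() - 39.46) / 39.46 < 0.02
        assert abs(mppgl.std(ddof=1) - 21.57) / 21.57 < 0.02
        assert abs(vmax.mean() - 255.82) / 255.82 < 0.02
        assert abs(vmax.std(ddof=1) - 79.48) / 79.48 < 0.02

    def test_all_quantities_positive_and_bounded(self, cohort78):
        spec = default_cohort_spec()
        for d in cohort78:
            assert d.body_weight > 0 and d.cardiac_output > 0
            assert spec.body_weight.bounds[0] <= d.body_weight <= spec.body_weight.bounds[1]
            assert spec.km.bounds[0] <= d.true_km <= spec.km.bounds[1]
            assert d.age >= 18

    def test_categorical_frequencies_converge(self):
        cohort = generate_cohort(default_cohort_spec(n_donors=20_000, seed=2))
        frac_male = np.mean([d.gender == "male" for d in cohort])
        frac_smoking = np.mean([d.smoking for d in cohort])
        assert abs(frac_male - 40 / 128) < 0.02
        assert abs(frac_smoking - 13 / 128) < 0.02

    @pytest.mark.parametrize(
        "field,value,fragment",
        [
            ("mppgl", TraitSpec(39.46, -1.0, (6.71, 127.95)), "sd"),
            ("mppgl", TraitSpec(39.46, 21.57, (127.95, 6.71)), "bounds"),
            ("mppgl", TraitSpec(500.0, 21.57, (6.71, 127.95)), "mean"),
            ("gender_proportions", {"male": 0.7, "female": 0.7}, "gender_proportions"),
            ("smoking_rate", 1.5, "smoking_rate"),
        ],
    )
    def test_invalid_spec_names_offending_field(self, field, value, fragment):
        spec = default_cohort_spec(n_donors=4)
        setattr(spec, field, value)
        with pytest.raises(ValueError, match=fragment):
            generate_cohort(spec)


class TestGeneratePorPairs:
    def test_homogenate_is_definitional_product(self, small_cohort):
        pairs = generate_por_pairs(small_cohort, microsome_rate_mean=10.0, noise_cv=0.0, seed=0)
        for donor, pair in zip(small_cohort, pairs):
            assert pair.microsome_rate == 10.0
            assert pair.homogenate_rate == pytest.approx(10.0 * donor.true_mppgl)

    def test_roundtrip_recovers_latent_mppgl(self, cohort78):
        pairs = generate_por_pairs(cohort78, noise_cv=0.3, seed=9)
        for donor, pair in zip(cohort78, pairs):
            est = estimate_mppgl(pair)
            assert est.mppgl == pytest.approx(donor.true_mppgl, rel=1e-9)

    def test_negative_noise_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="noise_cv"):
            generate_por_pairs(small_cohort, noise_cv=-0.1)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            generate_por_pairs([])


class TestGenerateKinetics:
    def test_half_saturation_rate(self, small_cohort):
        series = generate_kinetics(
            small_cohort,
            vmax_per_donor=[200.0] * 8,
            km_per_donor=[200.0] * 8,
            grid=[100.0, 200.0, 400.0],
            noise_cv=0.0,
        )
        for s in series:
            assert s.rates[1] == pytest.approx(100.0)  # v = Vmax/2 at C = Km

    def test_direct_evaluation_at_top_concentration(self, small_cohort):
        series = generate_kinetics(
            small_cohort,
            vmax_per_donor=[255.82] * 8,
            km_per_donor=[235.73] * 8,
            noise_cv=0.0,
        )
        # 255.82 * 2000 / 2235.73, hand-computed
        assert series[0].rates[-1] == pytest.approx(228.847, abs=5e-3)

    def test_noiseless_series_recover_parameters(self, small_cohort):
        series = generate_kinetics(small_cohort, noise_cv=0.0)
        for donor, s in zip(small_cohort, series):
            fit = fit_michaelis_menten(s)
            assert fit.vmax == pytest.approx(donor.true_vmax, rel=1e-6)
            assert fit.km == pytest.approx(donor.true_km, rel=1e-6)

    def test_nonpositive_parameters_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="positive"):
            generate_kinetics(small_cohort, vmax_per_donor=[0.0] * 8, km_per_donor=[100.0] * 8)

    def test_deterministic_given_seed(self, small_cohort):
        a = generate_kinetics(small_cohort, noise_cv=0.1, seed=4)
        b = generate_kinetics(small_cohort, noise_cv=0.1, seed=4)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.rates, sb.rates)


class TestGenerateVmTable:
    def test_lognormal_medians_converge(self):
        cohort = generate_cohort(default_cohort_spec(n_donors=5000, seed=3))
        table = generate_vm_table(cohort, CYP_VM_SPECS, seed=3)
        for iso, spec in CYP_VM_SPECS.items():
            vals = table.loc[table["isoform"] == iso, "vm_pmol_min_mg"]
            assert np.median(vals) == pytest.approx(spec.median, rel=0.05)
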