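"""Per-liver activity scaling, variability summaries, rank changes, screens."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepscale import (
    compute_vl,
    correlate,
    group_compare,
    rank_change_analysis,
    summarize_activity,
)
from hepscale.activity import RANK_CHANGE_BANDS, _band


def vm_frame(values_by_donor, isoform="CYP2C9"):
    return pd.DataFrame(
        {
            "donor_id": list(values_by_donor),
            "isoform": isoform,
            "vm_pmol_min_mg": list(values_by_donor.values()),
        }
    )


class TestComputeVl:
    def test_unit_conversion_arithmetic(self):
        vl = compute_vl(vm_frame({"d1": 677.94}), {"d1": 32.63})
        assert vl["vl_nmol_min_g"].iloc[0] == pytest.approx(22.12, abs=5e-3)

    def test_mppgl_1000_is_identity(self):
        vl = compute_vl(vm_frame({"d1": 1.0}), {"d1": 1000.0})
        assert vl["vl_nmol_min_g"].iloc[0] == pytest.approx(1.0)

    def test_missing_mppgl_lists_donors(self):
        with pytest.raises(KeyError, match="d2"):
            compute_vl(vm_frame({"d1": 1.0, "d2": 2.0}), {"d1": 30.0})

    def test_nonpositive_mppgl_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            compute_vl(vm_frame({"d1": 1.0}), {"d1": 0.0})

    def test_within_donor_isoform_ratios_preserved(self, rng):
        donors = [f"d{i}" for i in range(6)]
        mppgl = {d: float(rng.uniform(10, 100)) for d in donors}
        frames = []
        for iso in ("CYP1A2", "CYP2C9"):
            vals = {d: float(rng.uniform(10, 500)) for d in donors}
            frames.append(vm_frame(vals, isoform=iso))
        table = pd.concat(frames, ignore_index=True)
        vl = compute_vl(table, mppgl)
        wide_vm = vl.pivot(index="donor_id", columns="isoform", values="vm_pmol_min_mg")
        wide_vl = vl.pivot(index="donor_id", columns="isoform", values="vl_nmol_min_g")
        np.testing.assert_allclose(
            wide_vl["CYP1A2"] / wide_vl["CYP2C9"],
            wide_vm["CYP1A2"] / wide_vm["CYP2C9"],
            rtol=1e-12,
        )


class TestSummarizeActivity:
    def test_printed_range_fold_change(self):
        s = summarize_activity([70.00, 150.0, 222.70, 461.07])
        assert s.fold_minmax == pytest.approx(461.07 / 70.00)
        assert round(s.fold_minmax, 2) == 6.59

    def test_constant_vector_fold_one(self):
        s = summarize_activity([5.0] * 10)
        assert s.fold_minmax == 1.0
        assert s.fold_pi == 1.0

    def test_nonpositive_values_rejected_for_folds(self):
        with pytest.raises(ValueError, match="positive"):
            summarize_activity([1.0, 0.0, 2.0])

    @given(st.integers(5, 500), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_percentiles_match_bruteforce_interpolation(self, n, seed):
        x = np.random.default_rng(seed).uniform(0.1, 100, size=n)
        s = summarize_activity(x)
        xs = np.sort(x)

        def brute(q):  # linear interpolation between closest order statistics
            h = (n - 1) * q
            lo = math.floor(h)
            hi = min(lo + 1, n - 1)
            return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

        assert s.p2_5 == pytest.approx(brute(0.025), rel=1e-12)
        assert s.p97_5 == pytest.approx(brute(0.975), rel=1e-12)
        assert s.fold_minmax >= s.fold_pi >= 1.0


class TestRankChange:
    @staticmethod
    def table(vm, mppgl):
        donors = [f"d{i}" for i in range(len(vm))]
        df = pd.DataFrame({"donor_id": donors, "isoform": "CYP2C9", "vm_pmol_min_mg": vm})
        return compute_vl(df, dict(zip(donors, mppgl)))

    def test_constant_mppgl_gives_zero_change(self):
        report = rank_change_analysis(self.table([10, 40, 20, 30], [50.0] * 4))
        assert (report.per_donor["abs_rank_change"] == 0).all()
        assert (report.per_donor["band"] == "tiny").all()
        shares = report.band_shares.set_index("isoform").loc["CYP2C9"]
        assert shares["tiny"] == 1.0

    def test_four_donor_toy_matches_exhaustive_enumeration(self):
        vm = [10.0, 20.0, 30.0, 40.0]
        # mppgl chosen so donor 0 and donor 3 swap ends of the V_L ordering
        mppgl = [100.0, 30.0, 30.0, 5.0]
        report = rank_change_analysis(self.table(vm, mppgl))
        vl = [v * m for v, m in zip(vm, mppgl)]
        # brute-force ranks by sorting index enumeration
        expected = {}
        for vals, key in ((vm, "rank_vm"), (vl, "rank_vl")):
            order = sorted(range(4), key=lambda i: vals[i])
            for rank, i in enumerate(order, start=1):
                expected.setdefault(f"d{i}", {})[key] = rank
        for row in report.per_donor.itertuples():
            assert row.rank_vm == expected[row.donor_id]["rank_vm"]
            assert row.rank_vl == expected[row.donor_id]["rank_vl"]
            assert row.abs_rank_change == abs(
                expected[row.donor_id]["rank_vm"] - expected[row.donor_id]["rank_vl"]
            )
            assert row.pct_change == pytest.approx(row.abs_rank_change / 4)

    def test_band_edges(self):
        assert _band(54 / 78) == "dramatic"  # a 54-place move in 78 donors (69%)
        assert _band(0.0) == "tiny"
        assert _band(0.10) == "moderate"
        assert _band(0.20) == "obvious"
        assert _band(0.50) == "dramatic"

    def test_band_shares_sum_to_one(self, rng):
        vm = rng.uniform(1, 100, 20)
        mppgl = rng.uniform(5, 120, 20)
        report = rank_change_analysis(self.table(vm, mppgl))
        shares = report.band_shares[[b[0] for b in RANK_CHANGE_BANDS]].sum(axis=1)
        np.testing.assert_allclose(shares, 1.0)

    def test_single_donor_rejected(self):
        with pytest.raises(ValueError, match="2 donors"):
            rank_change_analysis(self.table([10.0], [50.0]))


class TestGroupCompare:
    def test_identical_groups_no_shift(self, rng):
        x = rng.uniform(0, 1, 30)
        values = np.concatenate([x, x])
        groups = np.array(["a"] * 30 + ["b"] * 30)
        res = group_compare(values, groups)
        assert res.test == "mann-whitney"
        assert res.pvalue > 0.9

    def test_separated_groups_attain_exact_minimal_p(self):
        values = np.concatenate([np.arange(10), np.arange(100, 110)])
        groups = np.array(["lo"] * 10 + ["hi"] * 10)
        res = group_compare(values, groups)
        # exact two-sided p for U = 0: both one-sided tails of 1/C(20,10)
        assert res.pvalue == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_three_groups_use_kruskal_wallis(self, rng):
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        assert group_compare(values, groups).test == "kruskal-wallis"

    def test_kruskal_type_one_error_rate(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            values = rng.normal(size=45)
            groups = np.repeat(["a", "b", "c"], 15)
            if group_compare(values, groups).pvalue < 0.05:
                rejections += 1
        assert 0.03 < rejections / n_rep < 0.07

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            group_compare([1.0, 2.0], ["a", "a"])


class TestCorrelate:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert correlate(x, x).rho == pytest.approx(1.0)
        assert correlate(x, -x).rho == pytest.approx(-1.0)

    def test_strength_bands(self, rng):
        x = np.arange(100.0)
        noisy = x + rng.normal(0, 60, 100)
        res = correlate(x, noisy)
        assert res.strength in {"strong", "moderate", "weak"}
        assert correlate(x, x).strength == "strong"

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate(np.ones(5), np.arange(5.0))

    def test_vl_correlates_with_mppgl_by_construction(self, rng):
        mppgl = rng.lognormal(3.5, 0.5, 60)
        vm = rng.lognormal(5.0, 0.6, 60)
        vl = vm * mppgl / 1000
        res = correlate(vl, mppgl)
        assert res.rho > 0
        assert res.pvalue < 0.01
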