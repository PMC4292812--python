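"""Delta-beta statistics: calibration, reversal counting, histograms, concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdxmeth import fidelity, synth


class TestCalibrateThreshold:
    def test_published_bounds_give_051(self):
        thr = fidelity.ReversalThreshold(unmeth_upper=0.31, meth_lower=0.82)
        assert thr.threshold == pytest.approx(0.51)
        assert fidelity.ReversalThreshold().threshold == pytest.approx(0.51)

    def test_perfectly_separated_states_give_one(self):
        thr = fidelity.calibrate_threshold([0.0] * 10, [1.0] * 10)
        assert thr.threshold == pytest.approx(1.0)

    def test_quantiles_match_explicit_sort(self, rng):
        unmeth = rng.uniform(0, 0.4, size=1_000)
        meth = rng.uniform(0.7, 1.0, size=1_000)
        thr = fidelity.calibrate_threshold(unmeth, meth, coverage=0.95)
        su, sm = np.sort(unmeth), np.sort(meth)
        # nearest-rank: smallest order statistic with cumulative fraction >= q
        expected_upper = su[int(np.ceil(0.95 * 1_000)) - 1]
        expected_lower = sm[int(np.ceil(0.05 * 1_000)) - 1]
        assert thr.unmeth_upper == pytest.approx(expected_upper)
        assert thr.meth_lower == pytest.approx(expected_lower)
        assert thr.threshold == pytest.approx(expected_lower - expected_upper)

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fidelity.calibrate_threshold([0.9] * 5, [0.1] * 5)


class TestDeltaBeta:
    def test_identical_columns_zero_delta(self, beta):
        df = beta.copy()
        df["twin"] = df["S001"]
        pair = fidelity.delta_beta(df, "S001", "twin")
        assert (pair.delta == 0).all()

    def test_antisymmetric_under_swap(self, beta):
        fwd = fidelity.delta_beta(beta, "S001", "S002")
        rev = fidelity.delta_beta(beta, "S002", "S001")
        assert np.allclose(fwd.delta, -rev.delta)

    def test_missing_sample_rejected(self, beta):
        with pytest.raises(KeyError, match="nope"):
            fidelity.delta_beta(beta, "S001", "nope")


class TestReversedFraction:
    def test_inclusive_boundary_example(self):
        delta = pd.Series(
            [0.6, -0.52, 0.50, 0.51, -0.3],
            index=[f"cg{i}" for i in range(1, 6)],
        )
        pair = fidelity.PairDelta("p", "x", delta)
        summary = fidelity.reversed_fraction(pair, 0.51)
        assert summary.count == 3
        assert set(summary.probes) == {"cg1", "cg2", "cg4"}
        assert summary.percent == pytest.approx(60.0)

    def test_zero_delta_zero_count(self):
        pair = fidelity.PairDelta("p", "x", pd.Series([0.0] * 8))
        summary = fidelity.reversed_fraction(pair)
        assert summary.count == 0 and summary.percent == 0.0

    @given(st.floats(min_value=0.05, max_value=1.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_count_monotone_in_threshold(self, t):
        rng = np.random.default_rng(0)
        delta = pd.Series(rng.uniform(-1, 1, 300))
        pair = fidelity.PairDelta("p", "x", delta)
        low = fidelity.reversed_fraction(pair, max(t / 2, 1e-3)).count
        high = fidelity.reversed_fraction(pair, t).count
        assert high <= low


class TestHistograms:
    def test_zero_delta_all_in_first_bin(self):
        pair = fidelity.PairDelta("p", "x", pd.Series([0.0] * 50))
        hist = fidelity.delta_histogram(pair)
        assert hist["count"].iloc[0] == 50 and hist["count"].sum() == 50

    def test_counts_conserve_probe_total(self, beta):
        pair = fidelity.delta_beta(beta, "S001", "S002")
        hist = fidelity.delta_histogram(pair, bin_width=0.05)
        assert hist["count"].sum() == pair.n_probes

    def test_final_bin_closed(self):
        pair = fidelity.PairDelta("p", "x", pd.Series([1.0, -1.0]))
        hist = fidelity.delta_histogram(pair)
        assert hist["count"].iloc[-1] == 2

    def test_invalid_bin_width_rejected(self, beta):
        pair = fidelity.delta_beta(beta, "S001", "S002")
        with pytest.raises(ValueError, match="bin_width"):
            fidelity.delta_histogram(pair, bin_width=0.03)


class TestThresholdSensitivity:
    def test_single_pair_zero_sem(self, beta):
        pair = fidelity.delta_beta(beta, "S001", "S002")
        out = fidelity.threshold_sensitivity([pair])
        assert (out["sem"] == 0).all()

    def test_means_increase_as_threshold_decreases(self, beta):
        pairs = [
            fidelity.delta_beta(beta, "S001", "S002"),
            fidelity.delta_beta(beta, "S003", "S004"),
        ]
        out = fidelity.threshold_sensitivity(pairs, thresholds=(0.51, 0.41, 0.31, 0.21))
        means = out["mean_percent"].to_numpy()
        assert (np.diff(means) >= 0).all()

    def test_planted_uniform_shifts_flat_across_grid(self, beta):
        plan = synth.PairPlan(frac_changing=0.05, min_shift=0.51, seed=8)
        xeno, _ = synth.generate_pdx_pair(beta["S001"], plan)
        pair = fidelity.PairDelta("S001", "X", beta["S001"] - xeno)
        out = fidelity.threshold_sensitivity([pair])
        assert out["mean_percent"].nunique() == 1

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValueError):
            fidelity.threshold_sensitivity([])


class TestFeatureHistograms:
    def test_constant_beta_single_bin(self, toy_annotation):
        beta = pd.DataFrame(
            {"S1": np.full(10, 0.5)}, index=toy_annotation.index
        )
        hist = fidelity.feature_histograms(beta, toy_annotation)
        occupied = hist[hist["percent"] > 0]
        assert (occupied["bin_lo"] == 0.5).all()

    def test_percentages_sum_to_hundred(self, beta, annotation):
        hist = fidelity.feature_histograms(beta, annotation, bin_width=0.05)
        sums = hist.groupby(["sample", "category"])["percent"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_whole_genome_category_present(self, beta, annotation):
        hist = fidelity.feature_histograms(beta, annotation, bin_width=0.1)
        assert fidelity.WHOLE_GENOME in set(hist["category"])

    def test_unknown_feature_label_rejected(self, toy_annotation):
        bad = toy_annotation.copy()
        bad.loc[bad.index[0], "feature"] = "Promoter"
        beta = pd.DataFrame({"S1": np.full(10, 0.5)}, index=bad.index)
        with pytest.raises(ValueError, match="Promoter"):
            fidelity.feature_histograms(beta, bad)


class TestSubstituteConcordance:
    def test_identical_pairs_all_zero(self, beta):
        pair = fidelity.delta_beta(beta, "S001", "S002")
        out = fidelity.substitute_concordance(pair, pair)
        assert (out.ddb == 0).all()
        assert out.concordant_fraction == 1.0

    def test_bounded_by_two(self, beta):
        a = fidelity.delta_beta(beta, "S001", "S002")
        b = fidelity.delta_beta(beta, "S003", "S004")
        out = fidelity.substitute_concordance(a, b)
        assert out.ddb.abs().max() <= 2.0

    def test_matches_per_probe_recomputation(self, beta, rng):
        a = fidelity.delta_beta(beta, "S001", "S002")
        b = fidelity.delta_beta(beta, "S003", "S004")
        out = fidelity.substitute_concordance(a, b)
        probes = rng.choice(beta.index, size=100, replace=False)
        for p in probes:
            expected = abs(a.delta[p]) - abs(b.delta[p])
            assert out.ddb[p] == pytest.approx(expected)

    def test_universe_mismatch_rejected(self, beta):
        a = fidelity.delta_beta(beta, "S001", "S002")
        short = fidelity.PairDelta("p", "x", a.delta.iloc[:-1])
        with pytest.raises(ValueError, match="universe"):
            fidelity.substitute_concordance(a, short)


class TestSetConcordance:
    def test_identical_signed_sets(self):
        a = {f"cg{i}": 1 if i % 2 else -1 for i in range(10)}
        shared, conc = fidelity.set_concordance(a, dict(a))
        assert shared == 10 and conc == 1.0

    def test_disjoint_sets_not_applicable(self):
        shared, conc = fidelity.set_concordance({"a": 1}, {"b": 1})
        assert shared == 0 and conc is None

    def test_one_flip_of_ten(self):
        a = {f"cg{i}": 1 for i in range(10)}
        b = dict(a)
        b["cg0"] = -1
        shared, conc = fidelity.set_concordance(a, b)
        assert shared == 10 and conc == pytest.approx(0.9)
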