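"""Plug-in MI, Miller-Madow correction, permutation inference, lag pairing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from choicehist import mutual_information as mi
from choicehist import synthetic_data as synth

LN2 = np.log(2.0)


def _mi_direct_from_table(table):
    """Exhaustive direct evaluation of the MI definition on a count table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    total = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            pxy = table[i, j] / n
            if pxy == 0:
                continue
            px = table[i, :].sum() / n
            py = table[:, j].sum() / n
            total += pxy * np.log2(pxy / (px * py))
    return total


def _table_to_series(table):
    xs, ys = [], []
    for i, j in itertools.product(range(table.shape[0]), range(table.shape[1])):
        xs += [i] * int(table[i, j])
        ys += [j] * int(table[i, j])
    return np.array(xs), np.array(ys)


class TestMIPlugin:
    def test_hand_evaluated_2x2_example(self):
        # joint counts [[2,1],[1,2]] over 6 trials
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1]
        expected = (2 / 3) * np.log2(4 / 3) + (1 / 3) * np.log2(2 / 3)
        assert mi.mi_plugin(x, y) == pytest.approx(expected, abs=1e-12)

    def test_perfect_binary_dependence_is_one_bit(self):
        x = [0, 1] * 10
        assert mi.mi_plugin(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_carries_zero_bits(self):
        assert mi.mi_plugin([1] * 8, [0, 1] * 4) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mi.mi_plugin([0, 1], [0, 1, 0])

    def test_matches_exhaustive_evaluation_on_all_small_tables(self):
        # every 3x3 joint count table with N <= 8
        for n in range(1, 9):
            for flat in itertools.combinations_with_replacement(range(9), n):
                table = np.bincount(flat, minlength=9).reshape(3, 3)
                x, y = _table_to_series(table)
                assert mi.mi_plugin(x, y) == pytest.approx(
                    _mi_direct_from_table(table), abs=1e-12
                )

    @given(
        data=st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 2)), min_size=2, max_size=60
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_symmetry_and_bounds(self, data):
        x = np.array([a for a, _ in data])
        y = np.array([b for _, b in data])
        forward = mi.mi_plugin(x, y)
        assert forward == pytest.approx(mi.mi_plugin(y, x), abs=1e-12)
        cap = min(np.log2(len(np.unique(x))), np.log2(len(np.unique(y))))
        assert -1e-12 <= forward <= cap + 1e-12

    def test_merging_orientation_bins_never_increases_mi(self):
        design = synth.generate_design(seed=51)
        t = synth.simulate_observer(design, synth.ObserverParams(), seed=52)
        resp = t["response"].to_numpy()
        fine = mi.mi_plugin(t["orientation"], resp)
        seven = mi.mi_plugin(mi.bin_orientation(t["orientation"].to_numpy()), resp)
        coarse = mi.mi_plugin(np.sign(t["orientation"].to_numpy()), resp)
        assert fine >= seven - 1e-12
        assert seven >= coarse - 1e-12


class TestMillerMadow:
    def test_printed_formula_at_lag1_trial_count(self):
        # |X|=7, |Y|=2, N=415 -> 6 / (830 ln 2)
        assert mi.miller_madow_bias(7, 2, 415) == pytest.approx(6 / (830 * LN2), abs=1e-15)
        assert mi.miller_madow(0.05, 7, 2, 415) == pytest.approx(
            0.05 - 6 / (830 * LN2), abs=1e-15
        )

    def test_constant_variable_has_zero_bias(self):
        assert mi.miller_madow_bias(1, 4, 100) == 0.0

    def test_bias_halves_when_n_doubles(self):
        assert mi.miller_madow_bias(7, 2, 830) == pytest.approx(
            mi.miller_madow_bias(7, 2, 415) / 2, abs=1e-15
        )

    def test_corrected_mi_centers_on_zero_under_independence(self):
        rng = np.random.default_rng(0)
        reps = 1000
        vals = np.empty(reps)
        for i in range(reps):
            x = rng.integers(0, 7, 415)
            y = rng.integers(0, 2, 415)
            vals[i] = mi.miller_madow(mi.mi_plugin(x, y), 7, 2, 415)
        mc_se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean()) < 2 * mc_se


class TestPermutationTest:
    def test_strong_dependence_gets_minimal_p(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 7, 415)
        res = mi.permutation_test(x, x, n_perm=1000, seed=2)
        assert res.p_value == pytest.approx(1 / 1001, abs=1e-12)
        assert res.significant

    def test_constant_series_never_significant(self):
        res = mi.permutation_test(np.zeros(100), np.arange(100) % 2, n_perm=200, seed=3)
        assert res.mi_raw == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0
        assert not res.significant

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            mi.permutation_test([0, 1] * 10, [0, 1] * 10, n_perm=50, seed=0)


class TestOrientationBinsAndPairs:
    def test_bin_mapping(self):
        assert mi.bin_orientation(0.0) == 4
        assert mi.bin_orientation(-18.0) == mi.bin_orientation(-15.0) == 1
        assert list(mi.bin_orientation([-12, -9, -6, -3, 3, 6, 9, 12, 15, 18])) == [
            2, 2, 3, 3, 5, 5, 6, 6, 7, 7,
        ]

    def test_off_grid_orientation_rejected(self):
        with pytest.raises(ValueError):
            mi.bin_orientation(7.0)

    def test_history_pairing(self):
        past, present = mi.history_pair(["A", "B", "C"], lag=1)
        assert list(past) == ["A", "B"]
        assert list(present) == ["B", "C"]
        s = np.arange(50)
        past, present = mi.history_pair(s, lag=1)
        assert len(past) == len(present) == 49
        with pytest.raises(ValueError):
            mi.history_pair(s, lag=50)


class TestMISuite:
    def test_evidence_dominates_history_for_sensitive_observer(self, null_observer):
        suite = mi.mi_suite(null_observer, n_perm=150, seed=5)
        assert set(suite) == set(mi.MI_QUANTITIES)
        assert suite["orient_resp"].mi_corrected > suite["resp1_resp"].mi_corrected
        assert suite["orient_resp"].significant
        # confidence cardinality reflects ratings actually used
        assert suite["conf1_conf"].cardinality_y == null_observer["confidence"].nunique()

    def test_strong_confidence_bias_detected(self, conf_biased_observer):
        sub = conf_biased_observer.iloc[:416].reset_index(drop=True)
        suite = mi.mi_suite(sub, n_perm=300, seed=6)
        assert suite["conf1_conf"].significant
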