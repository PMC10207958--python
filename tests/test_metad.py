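"""Type-1 SDT arithmetic and the maximum-likelihood meta-d' fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from choicehist import metad as md
from choicehist import synthetic_data as synth


def _counts_from_rates(hr, far, n=1000):
    """Build an unpadded count table with given hit/false-alarm rates."""
    s2 = np.zeros(8)
    s1 = np.zeros(8)
    s2[4] = hr * n  # resp right, conf 1
    s2[3] = (1 - hr) * n  # resp left, conf 1
    s1[4] = far * n
    s1[3] = (1 - far) * n
    return md.ResponseCountTable(K=4, counts_s1=s1, counts_s2=s2, pad=0.0)


class TestCountsFromTrials:
    def test_hand_tally_of_small_fixture(self):
        trials = pd.DataFrame(
            {
                "participant": "p",
                "trial": range(1, 9),
                "orientation": [6.0, 6.0, -6.0, -6.0, 6.0, -6.0, 6.0, -6.0],
                "response": ["right", "left", "left", "right", "right", "left", "right", "left"],
                "confidence": [4, 2, 3, 1, 4, 2, 1, 3],
                "correct": [1, 0, 1, 0, 1, 1, 1, 1.0],
            }
        )
        counts = md.counts_from_trials(trials, 6.0, pad=False)
        # S2 (right tilt): resp left conf 2 -> cell 2; resp right conf 4 -> cell 7 (x2); conf 1 -> cell 4
        assert list(counts.counts_s2) == [0, 0, 1, 0, 1, 0, 0, 2]
        # S1 (left tilt): resp left conf 3 -> cell 1 (x2); conf 2 -> cell 2; resp right conf 1 -> cell 4
        assert list(counts.counts_s1) == [0, 2, 1, 0, 1, 0, 0, 0]

    def test_padding_fills_empty_cells_with_1_over_2K(self, null_observer):
        counts = md.counts_from_trials(null_observer, 18.0, pad=True)
        raw = md.counts_from_trials(null_observer, 18.0, pad=False)
        empty = raw.counts_s1 == 0
        assert empty.any()
        assert np.allclose(counts.counts_s1[empty], 1 / 8)

    def test_zero_degrees_rejected(self, null_observer):
        with pytest.raises(ValueError, match="0 degrees"):
            md.counts_from_trials(null_observer, 0.0)

    def test_missing_stimulus_class_rejected(self, null_observer):
        one_sided = null_observer[null_observer["orientation"] >= 0]
        with pytest.raises(md.InsufficientDataError):
            md.counts_from_trials(one_sided, 6.0)


class TestFitType1:
    def test_normal_quantile_arithmetic(self):
        d, c = md.fit_type1(_counts_from_rates(0.84, 0.16))
        assert d == pytest.approx(norm.ppf(0.84) - norm.ppf(0.16), abs=1e-9)
        assert d == pytest.approx(1.9889, abs=1e-3)
        assert c == pytest.approx(0.0, abs=1e-9)

    def test_equal_rates_give_zero_dprime(self):
        d, _ = md.fit_type1(_counts_from_rates(0.4, 0.4))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_mirror_symmetric_counts_give_zero_criterion(self, null_observer):
        counts = md.counts_from_trials(null_observer, 12.0, pad=False)
        mirrored = md.ResponseCountTable(
            K=4, counts_s1=counts.counts_s2[::-1].copy(), counts_s2=counts.counts_s2, pad=0.0
        )
        _, c = md.fit_type1(mirrored)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_of_rates(self, null_observer):
        counts = md.counts_from_trials(null_observer, 12.0, pad=False)
        doubled = md.ResponseCountTable(
            K=4, counts_s1=2 * counts.counts_s1, counts_s2=2 * counts.counts_s2, pad=0.0
        )
        assert md.fit_type1(counts) == pytest.approx(md.fit_type1(doubled), abs=1e-12)


@pytest.fixture(scope="module")
def ideal_counts():
    design = synth.generate_design(n_reps=10_000, levels=(-12.0, 12.0), seed=61)
    t = synth.simulate_ideal_confidence_observer(design, sensitivity=0.09, seed=62)
    return md.counts_from_trials(t, 12.0)


class TestFitMetaD:
    def test_ideal_observer_meta_d_matches_d(self, ideal_counts):
        fit = md.fit_metad(ideal_counts)
        assert fit.converged
        assert abs(fit.m_diff) < 0.15
        assert fit.m_ratio == pytest.approx(1.0, abs=0.1)

    def test_shuffled_ratings_destroy_type2_sensitivity(self, ideal_counts):
        # shuffling ratings within response = rating distribution independent
        # of stimulus given response; redistribute counts accordingly
        K = 4
        s1, s2 = ideal_counts.counts_s1, ideal_counts.counts_s2
        pooled = s1 + s2
        shuffled = []
        for vec in (s1, s2):
            out = np.empty(2 * K)
            for sl in (slice(0, K), slice(K, 2 * K)):
                total = vec[sl].sum()
                out[sl] = total * pooled[sl] / pooled[sl].sum()
            shuffled.append(out)
        fit = md.fit_metad(
            md.ResponseCountTable(K=K, counts_s1=shuffled[0], counts_s2=shuffled[1], pad=1 / 8)
        )
        assert abs(fit.meta_d) < 0.15

    def test_generate_and_refit_recovers_meta_d(self):
        true_meta_d, true_d, c = 1.2, 2.0, 0.3
        t1c = (c / true_d) * true_meta_d
        left = np.array([0.4, 0.9, 1.5])
        right = np.array([0.5, 1.0, 1.6])
        p_s1_meta, p_s2_meta = md.cell_probabilities(true_meta_d, t1c, left, right)
        rng = np.random.default_rng(63)
        tables = []
        for p_meta, p_left_t1 in (
            (p_s1_meta, norm.cdf(c + true_d / 2)),
            (p_s2_meta, norm.cdf(c - true_d / 2)),
        ):
            cond = np.concatenate(
                (p_meta[:4] / p_meta[:4].sum(), p_meta[4:] / p_meta[4:].sum())
            )
            cells = np.concatenate((cond[:4] * p_left_t1, cond[4:] * (1 - p_left_t1)))
            tables.append(rng.multinomial(10_000, cells).astype(float) + 1 / 8)
        fit = md.fit_metad(
            md.ResponseCountTable(K=4, counts_s1=tables[0], counts_s2=tables[1], pad=1 / 8)
        )
        assert abs(fit.d_prime - true_d) < 0.1
        assert abs(fit.meta_d - true_meta_d) < 0.2

    def test_type2_likelihood_beats_ideal_observer_point(self, ideal_counts):
        fit = md.fit_metad(ideal_counts)
        obs = np.stack((ideal_counts.counts_s1, ideal_counts.counts_s2))
        c_prime = fit.criterion / fit.d_prime
        at_ideal = -md._type2_nll(
            np.concatenate(([fit.d_prime], np.full(6, 0.4))), obs, 4, c_prime
        )
        assert fit.loglik_type2 >= at_ideal - 1e-6

    def test_meta_d_degrades_monotonically_with_type2_noise(self):
        meta_ds = []
        for i, noise in enumerate((0.0, 0.6, 1.5)):
            design = synth.generate_design(n_reps=2000, levels=(-12.0, 12.0), seed=70 + i)
            params = synth.ObserverParams(
                sensitivity=0.09, lapse_rate=0.0, conf_noise_sd=noise
            )
            t = synth.simulate_observer(design, params, seed=80 + i)
            meta_ds.append(md.fit_metad(md.counts_from_trials(t, 12.0)).meta_d)
        assert meta_ds[0] > meta_ds[1] > meta_ds[2]

    def test_meta_criteria_ordered_and_distances_consistent(self, ideal_counts):
        fit = md.fit_metad(ideal_counts)
        assert (np.diff(fit.meta_c) >= 0).all()
        t1c = (fit.criterion / fit.d_prime) * fit.meta_d
        left = t1c - fit.meta_c[:3]
        right = fit.meta_c[3:] - t1c
        assert fit.metac_dist_left == pytest.approx(left.mean(), abs=1e-9)
        assert fit.metac_dist_right == pytest.approx(right.mean(), abs=1e-9)


class TestBinnedSDT:
    def test_unknown_binner_rejected(self, null_observer):
        with pytest.raises(ValueError):
            md.binned_sdt_analysis(null_observer, "nonsense")

    def test_prev_response_bins_cover_levels(self, null_observer):
        res = md.binned_sdt_analysis(null_observer, "prev-response")
        assert set(res["bin"]) == {"post-left", "post-right"}
        assert set(res["level"]) == set(md.SDT_LEVELS)
        kept = res[~res["dropped"]]
        assert (kept["n_s1"] >= 10).all() and (kept["n_s2"] >= 10).all()
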