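"""Statistic oracles: hand-computed Hu/chance/d', enumeration Wilcoxon,
noncentral-t power, and the behavioural checks (bias, fatigue, outliers)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from vocaffect import perceptstats as ps
from vocaffect.perceptstats import (
    ConfusionMatrix, arcsine_transform, confusion_matrix, dprime,
    dprime_vs_chance, fatigue_check, hu_table, power_n_ttest,
    recode_and_score_ratings, screen_outliers, signed_rank_test,
    unbiased_hit_rate, valence_accuracy_contrast, valence_bias, wagner_chance,
    wilcoxon_vs_chance,
)


def cm(counts):
    k = len(counts)
    labels = tuple(f"c{i}" for i in range(k))
    return ConfusionMatrix(np.asarray(counts), labels, labels)


class TestHuAndChance:
    def test_hand_worked_two_by_two(self):
        m = cm([[3, 1], [2, 4]])
        np.testing.assert_allclose(unbiased_hit_rate(m), [9 / 20, 16 / 30])
        np.testing.assert_allclose(wagner_chance(m), [4 * 5 / 100, 6 * 5 / 100])

    def test_perfect_and_empty_diagonals(self):
        assert np.all(unbiased_hit_rate(cm([[7, 0], [0, 9]])) == 1.0)
        m = cm([[0, 5], [3, 2]])
        assert unbiased_hit_rate(m)[0] == 0.0
        # category never presented: row marginal 0 -> chance 0
        assert wagner_chance(cm([[0, 0], [3, 2]]))[0] == 0.0

    @given(st.integers(2, 6), st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_hu_equals_hit_rate_times_precision(self, k, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=(k, k))
        m = cm(counts)
        hu = unbiased_hit_rate(m)
        row, col, d = m.row_marginals, m.col_marginals, np.diag(counts)
        for i in range(k):
            if row[i] and col[i]:
                assert hu[i] == pytest.approx((d[i] / row[i]) * (d[i] / col[i]))

    def test_chance_sums_below_one(self):
        """Cauchy-Schwarz: sum_i row_i col_i / N^2 <= 1 on random matrices."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = rng.integers(2, 8)
            counts = rng.integers(0, 30, size=(k, k))
            if counts.sum() == 0:
                continue
            assert wagner_chance(cm(counts)).sum() <= 1 + 1e-12

    def test_uniform_guesser_hu_approaches_chance(self):
        """E[Hu] converges to the Wagner chance level as trials grow."""
        rng = np.random.default_rng(1)
        k, n, reps = 10, 100_000, 20
        hu_sum = np.zeros(k)
        ch_sum = np.zeros(k)
        for _ in range(reps):
            true = rng.integers(0, k, n)
            resp = rng.integers(0, k, n)
            counts = np.zeros((k, k), int)
            np.add.at(counts, (true, resp), 1)
            m = cm(counts)
            hu_sum += unbiased_hit_rate(m)
            ch_sum += wagner_chance(m)
        assert np.all(np.abs(hu_sum - ch_sum) / ch_sum < 0.05)

    def test_response_outside_categories_rejected(self):
        df = pd.DataFrame({"true_context": ["c1"], "chosen_context": ["zz"]})
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix(df, ["c1", "c2"])

    def test_hand_tallied_five_trials(self):
        df = pd.DataFrame({
            "true_context": ["a", "a", "b", "b", "b"],
            "chosen_context": ["a", "b", "b", "a", "b"]})
        m = confusion_matrix(df, ["a", "b"])
        np.testing.assert_array_equal(m.counts, [[1, 1], [1, 2]])


class TestArcsine:
    @pytest.mark.parametrize("p,expected",
                             [(0.0, 0.0), (1.0, math.pi / 2), (0.5, math.pi / 4)])
    def test_known_values(self, p, expected):
        assert arcsine_transform(p) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            arcsine_transform(1.2)


class TestSignedRank:
    def test_all_zero_differences_give_p_one(self):
        stat, p, n = signed_rank_test(np.zeros(8))
        assert (stat, p, n) == (0.0, 1.0, 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_sign_enumeration(self, seed):
        """Exact two-sided p equals brute force over all 2^n sign vectors."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        d = rng.standard_normal(n) + 0.4
        _, p, _ = signed_rank_test(d)
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        dist = np.array([np.sum(ranks[list(signs)])
                         for signs in itertools.product([False, True], repeat=n)])
        p_lo = np.mean(dist <= w_obs)
        p_hi = np.mean(dist >= w_obs)
        assert p == pytest.approx(min(1.0, 2 * min(p_lo, p_hi)), abs=1e-12)

    def test_wilcoxon_vs_chance_table(self):
        rng = np.random.default_rng(2)
        rows = []
        for pid in range(12):
            for cat in ("x", "y"):
                boost = 0.4 if cat == "x" else 0.0
                rows.append({"participant_id": pid, "category": cat,
                             "hu": 0.5, "chance": 0.5,
                             "hu_arcsine": 0.6 + boost + rng.normal(0, 0.05),
                             "chance_arcsine": 0.6})
        out = wilcoxon_vs_chance(pd.DataFrame(rows), alpha=0.05)
        assert out.loc[out["category"] == "x", "significant"].item()
        assert not out.loc[out["category"] == "y", "significant"].item()
        assert np.allclose(out["alpha_corrected"], 0.025)


class TestRatings:
    @pytest.mark.parametrize("rating,truth,kind,value,correct", [
        (5, "high", "arousal", 2, True),
        (3, "medium", "arousal", 0, True),
        (1, "low", "arousal", -2, True),
        (4, "negative", "valence", 1, False),
        (2, "negative", "valence", -1, True),
    ])
    def test_recode_and_correctness(self, rating, truth, kind, value, correct):
        out = recode_and_score_ratings([rating], [truth], kind)
        assert out["value"].item() == value
        assert out["correct"].item() == correct

    def test_no_valence_stimuli_excluded(self):
        out = recode_and_score_ratings([4, 2], ["none", "positive"], "valence")
        assert len(out) == 1

    def test_valence_bias_detects_negative_shift(self):
        df = pd.DataFrame({"participant_id": np.repeat(range(12), 10),
                           "value": -1.0})
        means, res = valence_bias(df)
        assert res["mean"] == -1.0 and res["p"] < 0.01
        sym = pd.DataFrame({"participant_id": np.repeat(range(12), 2),
                            "value": [-1, 1] * 12})
        _, res0 = valence_bias(sym)
        assert res0["p"] == 1.0


class TestFatigue:
    @staticmethod
    def _trials(n_part=20, n_trial=60, drift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_part):
            for t in range(1, n_trial + 1):
                p_correct = 0.6 - drift * (t - 1) / n_trial
                rows.append({"participant_id": p, "trial_index": t,
                             "correct_context": rng.random() < p_correct,
                             "correct_arousal": rng.random() < p_correct,
                             "correct_valence": rng.random() < p_correct})
        return pd.DataFrame(rows)

    def test_stationary_listener_shows_no_decline(self):
        out = fatigue_check(self._trials())
        assert (out["p"] > 0.05).all()

    def test_drifting_listener_detected(self):
        out = fatigue_check(self._trials(drift=0.35, seed=1))
        assert (out["p"] < 0.05).all()
        assert (out["mean_early"] > out["mean_late"]).all()

    def test_sixty_trials_partition_the_session(self):
        df = self._trials(n_part=3, n_trial=60)
        out = fatigue_check(df)
        overall = df.groupby("participant_id")["correct_context"].mean().mean()
        half = out.loc[out["judgment"] == "context",
                       ["mean_early", "mean_late"]].mean(axis=1).item()
        assert half == pytest.approx(overall, abs=1e-12)
        with pytest.raises(ValueError, match=">= 60"):
            fatigue_check(self._trials(n_trial=50))


class TestDprime:
    @staticmethod
    def _table(yes_sig, n_sig, yes_noi, n_noi):
        return pd.DataFrame({
            "participant_id": "p1",
            "is_match": [True] * n_sig + [False] * n_noi,
            "response_yes": ([True] * yes_sig + [False] * (n_sig - yes_sig)
                             + [True] * yes_noi + [False] * (n_noi - yes_noi))})

    def test_equal_rates_give_zero(self):
        assert dprime(self._table(4, 8, 4, 8)).dprime == pytest.approx(0.0)

    def test_textbook_unit_dprime(self):
        # z(0.69146) = 0.5 and z(0.30854) = -0.5
        r = dprime(self._table(69146, 100000, 30854, 100000))
        assert r.dprime == pytest.approx(1.0, abs=1e-3)

    def test_extreme_rate_adjustment(self):
        r = dprime(self._table(8, 8, 0, 24))
        assert r.hit_adj == pytest.approx(7.5 / 8)
        assert r.fa_adj == pytest.approx(0.5 / 24)
        expected = stats.norm.ppf(7.5 / 8) - stats.norm.ppf(0.5 / 24)
        assert r.dprime == pytest.approx(expected)

    @given(st.integers(0, 8), st.integers(0, 24))
    @settings(max_examples=40, deadline=None)
    def test_antisymmetry_under_rate_swap(self, k_sig, k_noi):
        a = dprime(self._table(k_sig, 8, k_noi, 24))
        # swapped design: hits become false alarms on matched trial counts
        b = dprime(self._table(8 - k_sig, 8, 24 - k_noi, 24))
        assert a.dprime == pytest.approx(-b.dprime, abs=1e-12)

    def test_requires_both_trial_types(self):
        with pytest.raises(ValueError):
            dprime(pd.DataFrame({"participant_id": "p", "is_match": [True],
                                 "response_yes": [True]}))

    def test_dprime_vs_chance(self):
        rng = np.random.default_rng(3)
        dp = pd.DataFrame({
            "condition_context": ["a"] * 40 + ["b"] * 40,
            "dprime": np.r_[rng.normal(0.6, 0.3, 40), np.zeros(40)]})
        out = dprime_vs_chance(dp, alpha=0.005)
        assert out.loc[out["condition_context"] == "a", "significant"].item()
        assert out.loc[out["condition_context"] == "b", "zero_variance"].item()


class TestValenceContrast:
    def test_identical_distributions_not_significant(self):
        df = pd.DataFrame({
            "participant_id": np.repeat(range(15), 2),
            "valence": ["negative", "positive"] * 15,
            "value": np.tile([0.5, 0.5], 15)})
        res = valence_accuracy_contrast(df, "exp1")
        assert res["p"] == 1.0

    def test_constructed_asymmetry_detected_exp1(self):
        rng = np.random.default_rng(4)
        rows = []
        for p in range(20):
            rows.append({"participant_id": p, "valence": "negative",
                         "value": 0.8 + rng.normal(0, 0.05)})
            rows.append({"participant_id": p, "valence": "positive",
                         "value": 0.5 + rng.normal(0, 0.05)})
        res = valence_accuracy_contrast(pd.DataFrame(rows), "exp1")
        assert res["p"] < 0.01 and res["direction"] == "negative > positive"

    def test_exp2_anova_mode(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "participant_id": range(120),
            "valence": ["negative"] * 60 + ["positive"] * 60,
            "value": np.r_[rng.normal(0.5, 0.3, 60), rng.normal(0.1, 0.3, 60)]})
        res = valence_accuracy_contrast(df, "exp2")
        assert res["p"] < 0.01 and res["direction"] == "negative > positive"

    def test_missing_group_rejected(self):
        df = pd.DataFrame({"participant_id": [1], "valence": ["negative"],
                           "value": [0.5]})
        with pytest.raises(ValueError):
            valence_accuracy_contrast(df, "exp1")


class TestOutliers:
    def test_homogeneous_sample_keeps_everyone(self):
        acc = pd.Series(np.random.default_rng(0).normal(0.5, 0.02, 30))
        retained, excluded, _ = screen_outliers(acc)
        assert len(excluded) == 0 and len(retained) == 30

    def test_constructed_outlier_excluded(self):
        rng = np.random.default_rng(1)
        acc = pd.Series(np.r_[rng.normal(0.5, 0.01, 49), 0.1])
        retained, excluded, thr = screen_outliers(acc)
        assert list(excluded) == [49]
        assert 0.1 <= thr

    def test_zero_variance_keeps_everyone(self):
        retained, excluded, _ = screen_outliers(pd.Series([0.4, 0.4, 0.4]))
        assert len(excluded) == 0


class TestPower:
    def test_published_design_sizes(self):
        assert power_n_ttest(0.2, 0.005, 0.80, "one") == 296
        assert power_n_ttest(0.2, 0.05, 0.80, "one") == 156

    def test_large_effect_brute_force(self):
        """Oracle: scan n=2..50 with the noncentral-t power directly."""
        expected = next(n for n in range(2, 51)
                        if ps._t_power(n, 1.0, 0.05, "one") >= 0.80)
        assert power_n_ttest(1.0, 0.05, 0.80, "one") == expected == 8

    def test_monotonicity_grid(self):
        base = power_n_ttest(0.3, 0.05, 0.8, "one")
        assert power_n_ttest(0.5, 0.05, 0.8, "one") <= base      # larger d
        assert power_n_ttest(0.3, 0.01, 0.8, "one") >= base      # stricter alpha
        assert power_n_ttest(0.3, 0.05, 0.95, "one") >= base     # more power
        assert power_n_ttest(0.3, 0.05, 0.8, "two") >= base      # two-tailed

    def test_invalid_arguments(self):
        for bad in [dict(effect_size_d=0), dict(alpha=0), dict(power=1.0),
                    dict(tail="three")]:
            kwargs = dict(effect_size_d=0.2, alpha=0.05, power=0.8, tail="one")
            kwargs.update(bad)
            with pytest.raises(ValueError):
                power_n_ttest(**kwargs)


class TestHuTablePipeline:
    def test_hu_table_matches_single_matrix_path(self, stimuli_meta):
        from vocaffect import synthcorpus
        resp = synthcorpus.simulate_exp1(stimuli_meta, 3,
                                         synthcorpus.default_listener(), 5)
        scored = ps.score_exp1_responses(resp, stimuli_meta)
        contexts = list(dict.fromkeys(stimuli_meta["context_id"]))
        table = hu_table(scored, contexts)
        assert len(table) == 30
        one = scored[scored["participant_id"] == "p0001"]
        m = confusion_matrix(one, contexts)
        np.testing.assert_allclose(
            table.loc[table["participant_id"] == "p0001", "hu"],
            unbiased_hit_rate(m))
        assert m.n == 155
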