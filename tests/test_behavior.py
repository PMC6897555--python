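"""Learning-curve classification, CP statistics, effect sizes, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cplearn.behavior import (
    CPStats,
    RatingTable,
    TrialLog,
    block_summaries,
    classify_learner,
    cohens_d_from_t,
    cp_stats,
    paired_cohens_d,
    spearman_fisher,
    split_trials,
    window_accuracy,
)


def make_log(correct, rt=None, subject_id="s"):
    n = len(correct)
    if rt is None:
        rt = np.full(n, 1.0)
    cats = ["K"] * n
    resp = ["K" if c else "L" for c in correct]
    return TrialLog(
        subject_id=subject_id,
        trials=pd.DataFrame(
            {
                "trial": np.arange(1, n + 1),
                "stimulus_id": [f"K{i:03d}" for i in range(n)],
                "category": cats,
                "response": resp,
                "correct": np.asarray(correct, dtype=int),
                "rt": rt,
            }
        ),
    )


def oracle_classify(acc, width=20, criterion=0.80, min_remaining=60):
    """Exhaustive sustain-run enumeration, independent of the implementation."""
    n = len(acc)
    for b in range(n):  # earliest qualifying start wins
        run_ok = all(acc[j] >= criterion for j in range(b, n))
        if run_ok and (n - b) * width >= min_remaining:
            return ("Immediate" if b == 0 else "Learner", b * width + 1)
    if any(a >= criterion for a in acc):
        return ("Borderline", None)
    return ("NonLearner", None)


class TestWindowAccuracy:
    def test_all_correct(self):
        acc = window_accuracy(make_log([1] * 400))
        assert acc.shape == (20,)
        assert (acc == 1.0).all()

    def test_alternating(self):
        acc = window_accuracy(make_log([1, 0] * 200))
        assert np.allclose(acc, 0.5)

    def test_matches_recount(self):
        rng = np.random.default_rng(0)
        correct = rng.integers(0, 2, size=400)
        acc = window_accuracy(make_log(correct), width=25)
        brute = [correct[i : i + 25].mean() for i in range(0, 400, 25)]
        assert np.allclose(acc, brute)

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError):
            window_accuracy(make_log([1] * 30), width=20)


class TestClassifyLearner:
    def test_immediate(self):
        a = classify_learner([0.85] * 20)
        assert a.status == "Immediate" and a.learning_point == 1

    def test_learner_at_block_eight(self):
        acc = [0.5] * 7 + [0.9] * 13
        a = classify_learner(acc)
        assert a.status == "Learner" and a.learning_point == 141

    def test_borderline_oscillation(self):
        a = classify_learner([0.85, 0.70] * 10)
        assert a.status == "Borderline" and a.learning_point is None

    def test_nonlearner_at_chance(self):
        a = classify_learner([0.5] * 20)
        assert a.status == "NonLearner"

    def test_late_run_shorter_than_minimum_is_borderline(self):
        # sustained only over the last 2 windows = 40 trials < 60 required
        acc = [0.5] * 18 + [0.9, 0.9]
        assert classify_learner(acc).status == "Borderline"

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            classify_learner([])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sampled_from([0.0, 0.5, 0.75, 0.80, 0.85, 1.0]), min_size=1, max_size=25
        )
    )
    def test_agrees_with_exhaustive_oracle(self, acc):
        a = classify_learner(acc)
        status, lp = oracle_classify(acc)
        assert (a.status, a.learning_point) == (status, lp)


class TestBlockSummaries:
    def test_constant_rt(self):
        out = block_summaries(make_log([1] * 400, rt=np.full(400, 1.0)))
        assert np.allclose(out["mean_rt"], 1.0)
        assert np.allclose(out["accuracy"], 1.0)
        assert len(out) == 4

    def test_matches_slicing(self):
        rng = np.random.default_rng(1)
        correct = rng.integers(0, 2, size=400)
        rt = rng.uniform(0.3, 2.0, size=400)
        out = block_summaries(make_log(correct, rt=rt))
        for b in range(4):
            sl = slice(100 * b, 100 * (b + 1))
            assert out["accuracy"].iloc[b] == pytest.approx(correct[sl].mean())
            assert out["mean_rt"].iloc[b] == pytest.approx(rt[sl].mean())


def make_ratings(pre_w, pre_b, post_w, post_b, n_pairs=20):
    rows = []
    for i in range(n_pairs):
        rows += [
            {"pair": i, "pair_type": "within", "phase": "pre", "rating": pre_w},
            {"pair": i, "pair_type": "within", "phase": "post", "rating": post_w},
            {"pair": i, "pair_type": "between", "phase": "pre", "rating": pre_b},
            {"pair": i, "pair_type": "between", "phase": "post", "rating": post_b},
        ]
    return RatingTable(subject_id="s", ratings=pd.DataFrame(rows))


class TestCPStats:
    def test_identical_phases_give_zero_changes(self):
        s = cp_stats(make_ratings(4, 5, 4, 5))
        assert s.diff_w == 0 and s.diff_b == 0 and s.global_cp == 0

    def test_simple_separation_and_compression(self):
        s = cp_stats(make_ratings(pre_w=4, pre_b=5, post_w=3, post_b=7))
        assert s.diff_w == -1 and s.diff_b == 2 and s.global_cp == 3

    def test_global_cp_identity_on_observed_nonlearner_means(self):
        # diffB = 0.776 and diffW = 0.376 compose to a global CP of 0.400
        s = CPStats(subject_id="grp", w_pre=4.55, w_post=4.926, b_pre=4.87, b_post=5.646)
        assert s.diff_b == pytest.approx(0.776)
        assert s.diff_w == pytest.approx(0.376)
        assert s.global_cp == pytest.approx(0.400)

    def test_missing_phase_rejected(self):
        t = make_ratings(4, 5, 4, 5)
        half = RatingTable("s", t.ratings[t.ratings.phase == "pre"])
        with pytest.raises(ValueError):
            cp_stats(half)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_global_cp_identity_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.integers(1, 10, size=4)
        s = cp_stats(make_ratings(*r))
        assert s.global_cp == pytest.approx(s.diff_b - s.diff_w)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "t,df,expected",
        [(6.453, 17, 1.521), (3.560, 24, 0.712), (0.0, 10, 0.0)],
    )
    def test_paired_d_from_t(self, t, df, expected):
        assert cohens_d_from_t(t, df).d == pytest.approx(expected, abs=5e-4)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            cohens_d_from_t(1.0, 0)

    def test_raw_and_t_paths_agree(self):
        # mean(diff)/sd(diff) must equal t/sqrt(n) from the same samples
        rng = np.random.default_rng(4)
        x = rng.normal(5, 1, 30)
        y = x + rng.normal(0.4, 0.8, 30)
        raw = paired_cohens_d(y, x)
        from_t = cohens_d_from_t(raw.t, raw.df)
        assert raw.d == pytest.approx(from_t.d, rel=1e-12)


class TestSpearmanFisher:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_fisher(x, x**3).rho == pytest.approx(1.0)
        assert spearman_fisher(x, -x).rho == pytest.approx(-1.0)

    def test_matches_rank_formula_without_ties(self):
        rng = np.random.default_rng(5)
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        r = spearman_fisher(x, y)
        dx = np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))
        brute = 1 - 6 * (dx**2).sum() / (10 * (100 - 1))
        assert r.rho == pytest.approx(brute)

    def test_ci_contains_rho(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r = spearman_fisher(x, y)
        assert r.ci95[0] <= r.rho <= r.ci95[1]
        assert r.fisher_z == pytest.approx(np.arctanh(r.rho))

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            spearman_fisher(np.ones(10), np.arange(10.0))


class TestSplitTrials:
    def test_learner_split(self):
        from cplearn.behavior import LearningAssessment

        a = LearningAssessment("s", "Learner", 141, ())
        before, after = split_trials(a, 400)
        assert len(before) == 140 and len(after) == 260
        assert before[-1] == 140 and after[0] == 141

    def test_nonlearner_halves(self):
        from cplearn.behavior import LearningAssessment

        a = LearningAssessment("s", "NonLearner", None, ())
        before, after = split_trials(a, 400)
        assert len(before) == len(after) == 200

    def test_partition_property(self):
        from cplearn.behavior import LearningAssessment

        for lp in (21, 141, 381):
            a = LearningAssessment("s", "Learner", lp, ())
            before, after = split_trials(a, 400)
            assert np.intersect1d(before, after).size == 0
            assert np.array_equal(np.union1d(before, after), np.arange(1, 401))

    def test_immediate_flagged(self):
        from cplearn.behavior import LearningAssessment

        a = LearningAssessment("s", "Immediate", 1, ())
        with pytest.raises(ValueError):
            split_trials(a, 400)
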