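"""Metrics, the label-permutation test and its exact oracles, ΔAccuracy,
and cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riskcast as rc
from riskcast import evaluate


class TestScoreSubject:
    def test_perfect_prediction(self):
        e = rc.score_subject([1, 0], [1, 0], [0.9, 0.1])
        assert (e.accuracy, e.f1, e.auroc) == (1.0, 1.0, 1.0)
        assert (e.tp, e.fp, e.fn, e.tn) == (1, 0, 0, 1)

    def test_hand_enumerated_confusion_table(self):
        e = rc.score_subject([1, 1, 0, 0], [1, 0, 1, 0])
        assert (e.tp, e.fp, e.fn, e.tn) == (1, 1, 1, 1)
        assert e.accuracy == 0.5
        assert e.f1 == 0.5

    def test_single_class_auroc_undefined(self):
        e = rc.score_subject([0, 0], [0, 1], [0.2, 0.8])
        assert e.auroc is None
        assert e.auprc is None  # no positives either

    def test_no_positives_auprc_undefined_but_auroc_defined(self):
        e = rc.score_subject([0, 1], [0, 0], [0.2, 0.1])
        assert e.auroc is not None
        assert e.auprc is not None
        e = rc.score_subject([0, 0, 1], [0, 0, 0], None)
        assert e.auroc is None and e.auprc is None

    def test_identity_sums(self):
        e = rc.score_subject([1, 0, 1, 1, 0], [0, 0, 1, 1, 1], [0.3, 0.2, 0.8, 0.9, 0.6])
        assert e.tp + e.fp + e.fn + e.tn == e.n_test
        assert e.accuracy == (e.tp + e.tn) / e.n_test

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rc.score_subject([1, 2], [1, 0])
        with pytest.raises(ValueError):
            rc.score_subject([1, 0], [1])


class TestPermutationTest:
    def test_worked_example_perfect_prediction(self):
        # y = yhat = (1,1,0,0): over the C(4,2) = 6 distinct arrangements the
        # null accuracies are {1, .5, .5, .5, .5, 0}, so Pr(A > 1) = 0,
        # null mean = 0.5 and ΔAccuracy = 0.5
        out = rc.permutation_test([1, 1, 0, 0], [1, 1, 0, 0], method="enumerate")
        assert out.p_value == 0.0
        assert out.null_mean == 0.5
        assert out.delta_accuracy == 0.5
        assert out.reject

    def test_worked_example_anti_prediction(self):
        # y exactly disagrees with yhat: a = 0 and 5 of the 6 arrangements
        # beat it
        out = rc.permutation_test([0, 1, 0, 1], [1, 0, 1, 0], method="enumerate")
        assert out.observed_accuracy == 0.0
        assert out.p_value == pytest.approx(5 / 6)
        assert not out.reject

    def test_constant_labels_degenerate_null(self):
        out = rc.permutation_test([1, 1, 1], [1, 0, 1], method="enumerate")
        assert out.null_sd == 0.0
        assert out.p_value == 0.0
        assert out.delta_accuracy == 0.0

    def test_sampled_matches_enumeration_within_mc_error(self):
        rng = np.random.default_rng(0)
        m = 2000
        for trial in range(25):
            n = int(rng.integers(2, 9))
            y = rng.integers(0, 2, n)
            yhat = rng.integers(0, 2, n)
            exact = rc.permutation_test(y, yhat, method="enumerate")
            sampled = rc.permutation_test(y, yhat, m=m, seed=trial)
            se = np.sqrt(exact.p_value * (1 - exact.p_value) / m)
            assert abs(sampled.p_value - exact.p_value) <= 4 * se

    def test_smoothed_p_value_never_zero(self):
        out = rc.permutation_test([1, 1, 0, 0], [1, 1, 0, 0], m=100, seed=0,
                                  smoothed=True)
        assert out.p_value == pytest.approx(1 / 101)

    def test_permutation_preserves_label_multiset(self):
        # null mean equals the closed form q*p + (1-q)*(1-p) exactly under
        # enumeration — a consequence of multiset preservation
        y = [1, 1, 1, 0, 0, 0, 0, 0]
        yhat = [1, 0, 1, 0, 0, 1, 0, 0]
        out = rc.permutation_test(y, yhat, method="enumerate")
        q, p = np.mean(yhat), np.mean(y)
        assert out.null_mean == pytest.approx(rc.expected_null_accuracy(q, p))


class TestExpectedNullAccuracy:
    @pytest.mark.parametrize("q,p,expected", [(0.5, 0.5, 0.5), (1, 1, 1.0), (0, 1, 0.0)])
    def test_closed_form_values(self, q, p, expected):
        assert rc.expected_null_accuracy(q, p) == expected

    def test_range_validation(self):
        with pytest.raises(ValueError):
            rc.expected_null_accuracy(1.2, 0.5)

    def test_agrees_with_sampled_null_mean(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            n = 60
            y = (rng.random(n) < 0.4).astype(int)
            yhat = (rng.random(n) < 0.3).astype(int)
            out = rc.permutation_test(y, yhat, m=3000, seed=100 + trial)
            se = out.null_sd / np.sqrt(out.m)
            expected = rc.expected_null_accuracy(yhat.mean(), y.mean())
            assert abs(out.null_mean - expected) <= 3 * max(se, 1e-12)


class TestRejectionOracle:
    def test_matches_enumeration(self):
        # dual route: the hypergeometric closed form against brute-force
        # enumeration of every label arrangement
        rng = np.random.default_rng(9)
        for trial in range(20):
            n = int(rng.integers(2, 9))
            n_pos = int(rng.integers(0, n + 1))
            yhat = rng.integers(0, 2, n)
            y = np.zeros(n, dtype=int)
            y[:n_pos] = 1
            exact = evaluate.expected_rejection_rate(n, n_pos, int(yhat.sum()), 0.05)
            # enumeration: P over arrangements that Pr(A > a) < alpha
            from itertools import combinations
            accs = []
            for pos in combinations(range(n), n_pos):
                perm = np.zeros(n, dtype=int)
                perm[list(pos)] = 1
                accs.append(np.sum(perm == yhat))
            accs = np.array(accs)
            rejects = [(np.mean(accs > a) < 0.05) for a in accs]
            assert exact == pytest.approx(np.mean(rejects))

    def test_degenerate_null_always_rejects(self):
        # constant predictions: the null distribution collapses, p = 0
        assert evaluate.expected_rejection_rate(10, 4, 0, 0.05) == 1.0
        assert evaluate.expected_rejection_rate(10, 4, 10, 0.05) == 1.0

    def test_poisson_binomial_interval_matches_binomial(self):
        from scipy import stats
        probs = [0.3] * 20
        lo, hi = rc.rejection_count_interval(probs, 0.99)
        assert lo == stats.binom.ppf(0.005, 20, 0.3)
        assert hi == stats.binom.ppf(0.995, 20, 0.3)


class TestCohortSummary:
    def make(self, accs, rejects=None, groups=None):
        evals = [
            rc.score_subject([1, 0], [1, 0] if a == 1.0 else [0, 1],
                             subject_id=f"S{i}")
            for i, a in enumerate(accs)
        ]
        # overwrite with the requested accuracies via synthetic counts
        for e, a in zip(evals, accs):
            e.tp, e.fn, e.fp, e.tn = 0, 0, 0, 0
            e.n_test = 10
            e.tp = int(round(a * 10)); e.tn = 0
            e.fp = 10 - e.tp; e.fn = 0
            e.accuracy = a
        outs = [
            rc.permutation_test([1, 0], [1, 0], m=10, seed=i)
            for i in range(len(accs))
        ]
        if rejects is not None:
            for o, r in zip(outs, rejects):
                o.reject = r
        return evals, outs

    def test_macro_mean_and_sample_sd(self):
        evals, outs = self.make([0.8, 0.6])
        s = rc.summarize_cohort(evals, outs)
        assert s.macro["accuracy"].mean == pytest.approx(0.7)
        assert s.macro["accuracy"].sd == pytest.approx(0.1414, abs=1e-4)

    def test_zero_spread_and_single_subject(self):
        evals, outs = self.make([0.8, 0.8])
        assert rc.summarize_cohort(evals, outs).macro["accuracy"].sd == 0.0
        evals, outs = self.make([0.8])
        assert rc.summarize_cohort(evals, outs).macro["accuracy"].sd is None

    def test_micro_counts_pool(self):
        evals, outs = self.make([1.0, 1.0])
        evals[0].tp, evals[0].fp, evals[0].fn, evals[0].tn = 1, 0, 0, 1
        evals[1].tp, evals[1].fp, evals[1].fn, evals[1].tn = 2, 0, 0, 2
        s = rc.summarize_cohort(evals, outs)
        assert s.micro_confusion == (3, 0, 0, 3)
        assert s.micro_accuracy == 1.0

    def test_micro_accuracy_is_sample_weighted_macro(self):
        evals, outs = self.make([0.8, 0.6, 1.0])
        s = rc.summarize_cohort(evals, outs)
        weighted = np.average(
            [e.accuracy for e in evals], weights=[e.n_test for e in evals]
        )
        assert s.micro_accuracy == pytest.approx(weighted)

    def test_significance_count_and_groups(self):
        evals, outs = self.make([0.8, 0.6, 0.9], rejects=[True, False, True])
        groups = {"S0": "female", "S1": "male", "S2": "male"}
        s = rc.summarize_cohort(evals, outs, groups)
        assert s.significant == 2
        assert set(s.by_group) == {"female", "male"}
        assert s.by_group["male"].n_subjects == 2
        assert s.by_group["female"].significant == 1

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            rc.summarize_cohort([], [])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    data=st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=8)
)
def test_permutation_p_value_properties(data):
    """p is a proportion in [0,1]; ΔAccuracy = a − null mean; reject ⇔ p < α."""
    y = np.array([int(a) for a, _ in data])
    yhat = np.array([int(b) for _, b in data])
    out = rc.permutation_test(y, yhat, method="enumerate", alpha=0.05)
    assert 0.0 <= out.p_value <= 1.0
    assert out.reject == (out.p_value < 0.05)
    assert out.delta_accuracy == pytest.approx(out.observed_accuracy - out.null_mean)
    # strict inequality: with fully concordant or fully tied nulls p can be 0,
    # never negative, and the observed accuracy itself is never counted
    assert out.p_value <= 1.0 - 1.0 / out.m or out.m == 1
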