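"""Per-subject metrics, the label-permutation significance test, ΔAccuracy,
and cohort summaries.

The significance test asks whether a subject's classifier beats
prevalence-aware guessing: holding the predictions fixed, the test labels are
shuffled m times (multiset preserved), each shuffle's accuracy forms the null
distribution A, and

    p = Pr(A > a) = |{b in A : b > a}| / m          (strict, as defined)
    ΔAccuracy = a - mean(A)

Because accuracy under a uniform label permutation depends only on the
overlap between predicted and true positives, the null is exactly
hypergeometric; this module exposes that closed form both as an enumeration
oracle for small n and as an exact rejection-probability calculator.  The
strict ">" convention makes the test anti-conservative where the null has
ties (in the extreme, a constant classifier yields a degenerate null and
p = 0), so calibration checks should compare against the exact oracle rather
than the nominal level; see :func:`expected_rejection_rate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

__all__ = [
    "SubjectEvaluation",
    "PermutationOutcome",
    "CohortSummary",
    "MetricSummary",
    "score_subject",
    "permutation_test",
    "expected_null_accuracy",
    "expected_rejection_rate",
    "rejection_count_interval",
    "summarize_cohort",
]


@dataclass
class SubjectEvaluation:
    """Test-set metrics for one subject x target x window."""

    subject_id: str
    target: str
    window: int
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    f1: float
    auroc: float | None  # None when the test set has a single class
    auprc: float | None  # None when the test set has no positives
    n_test: int


@dataclass
class PermutationOutcome:
    """Result of the label-permutation significance test for one subject."""

    observed_accuracy: float
    m: int
    null_mean: float
    null_sd: float
    p_value: float
    delta_accuracy: float
    reject: bool
    alpha: float


def _check_binary(y: np.ndarray, name: str) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return y.astype(int)


def score_subject(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Sequence[float] | None = None,
    subject_id: str = "",
    target: str = "",
    window: int = 0,
) -> SubjectEvaluation:
    """Confusion counts, accuracy, positive-class F1, AUROC, AUPRC.

    AUROC is undefined (``None``) when the test labels are single-class;
    AUPRC is undefined when there are no positive labels.  F1 with an empty
    positive class on both sides is reported as 0.
    """
    y = _check_binary(y_true, "y_true")
    yhat = _check_binary(y_pred, "y_pred")
    if len(y) != len(yhat) or len(y) == 0:
        raise ValueError("y_true and y_pred must have equal nonzero length")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    acc = (tp + tn) / len(y)
    f1 = float(f1_score(y, yhat, zero_division=0))
    auroc = auprc = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if len(scores) != len(y):
            raise ValueError("scores length mismatch")
        if y.min() != y.max():
            auroc = float(roc_auc_score(y, scores))
        if y.any():
            auprc = float(average_precision_score(y, scores))
    return SubjectEvaluation(
        subject_id=subject_id, target=target, window=window,
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=acc, f1=f1, auroc=auroc, auprc=auprc, n_test=len(y),
    )


def permutation_test(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    m: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "sample",
    smoothed: bool = False,
) -> PermutationOutcome:
    """Label-permutation significance test against prevalence-aware guessing.

    Parameters
    ----------
    method:
        ``"sample"`` draws ``m`` uniform permutations of ``y_true`` (the
        prediction vector stays fixed) and recomputes accuracy for each;
        ``"enumerate"`` averages over *all* distinct label arrangements,
        weighting each equally (exact for small n), in which case ``m`` is
        ignored.
    smoothed:
        If true, report the add-one p-value ``(count + 1) / (m + 1)`` instead
        of the plain ``count / m``.  Off by default: the published formula
        has no smoothing term (so p = 0 is reportable).

    Match counts are compared as integers, so ties in the null distribution
    are exact, never float artifacts.
    """
    y = _check_binary(y_true, "y_true")
    yhat = _check_binary(y_pred, "y_pred")
    if len(y) != len(yhat) or len(y) == 0:
        raise ValueError("y_true and y_pred must have equal nonzero length")
    n = len(y)
    a_matches = int(np.sum(y == yhat))

    if method == "enumerate":
        n1 = int(y.sum())
        arrangements = list(combinations(range(n), n1))
        match_counts = np.empty(len(arrangements), dtype=int)
        for i, pos in enumerate(arrangements):
            perm = np.zeros(n, dtype=int)
            perm[list(pos)] = 1
            match_counts[i] = int(np.sum(perm == yhat))
        m_eff = len(arrangements)
    elif method == "sample":
        if m < 1:
            raise ValueError("m must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
        perms = rng.permuted(np.tile(y, (m, 1)), axis=1)
        match_counts = (perms == yhat).sum(axis=1)
        m_eff = m
    else:
        raise ValueError(f"unknown method {method!r}")

    null_acc = match_counts / n
    exceed = int(np.sum(match_counts > a_matches))
    p = (exceed + 1) / (m_eff + 1) if smoothed else exceed / m_eff
    a = a_matches / n
    null_mean = float(null_acc.mean())
    return PermutationOutcome(
        observed_accuracy=a,
        m=m_eff,
        null_mean=null_mean,
        null_sd=float(null_acc.std(ddof=0)),
        p_value=float(p),
        delta_accuracy=a - null_mean,
        reject=bool(p < alpha),
        alpha=alpha,
    )


def expected_null_accuracy(q: float, p: float) -> float:
    """Closed-form mean accuracy of prevalence-aware guessing: a predictor
    positive with rate ``q`` against labels with prevalence ``p`` agrees with
    probability ``q*p + (1-q)*(1-p)``.  Analytic oracle for ``null_mean``."""
    if not (0.0 <= q <= 1.0 and 0.0 <= p <= 1.0):
        raise ValueError("q and p must be in [0, 1]")
    return q * p + (1.0 - q) * (1.0 - p)


def _null_match_distribution(n: int, n_pos: int, n_pred_pos: int):
    """Exact permutation-null distribution of the match count.

    Under a uniform permutation of labels, the overlap k between true and
    predicted positives is Hypergeometric(n, n_pos, n_pred_pos) and the
    number of matching entries is n - n_pos - n_pred_pos + 2k.
    """
    k_min = max(0, n_pos + n_pred_pos - n)
    k_max = min(n_pos, n_pred_pos)
    ks = np.arange(k_min, k_max + 1)
    probs = stats.hypergeom.pmf(ks, n, n_pos, n_pred_pos)
    matches = n - n_pos - n_pred_pos + 2 * ks
    return matches, probs / probs.sum()


def expected_rejection_rate(
    n: int, n_pos: int, n_pred_pos: int, alpha: float = 0.05
) -> float:
    """Exact probability that the strict-inequality permutation test rejects
    when the labels truly carry no information about the predictions.

    Under the null the observed accuracy is itself a draw from the
    permutation distribution, so Pr(reject) = Pr_a(Pr(A > a) < alpha),
    computable in closed form from the hypergeometric null.  With heavy tie
    mass this exceeds alpha (a degenerate null rejects with probability 1) —
    the reference value calibration checks should use instead of alpha.
    """
    matches, probs = _null_match_distribution(n, n_pos, n_pred_pos)
    # survival at each support point: Pr(A > a)
    order = np.argsort(matches)
    matches, probs = matches[order], probs[order]
    cdf = np.cumsum(probs)
    survival = 1.0 - cdf  # Pr(matches > matches[i])
    return float(np.sum(probs[survival < alpha]))


def rejection_count_interval(
    probs: Sequence[float], coverage: float = 0.99
) -> tuple[int, int]:
    """Central ``coverage`` interval for the number of rejections across
    independent subjects with per-subject rejection probabilities ``probs``
    (Poisson-binomial, exact by dynamic programming)."""
    probs = np.asarray(probs, dtype=float)
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    cdf = np.cumsum(pmf)
    tail = (1.0 - coverage) / 2.0
    lo = int(np.searchsorted(cdf, tail))
    hi = int(np.searchsorted(cdf, 1.0 - tail))
    return lo, hi


# ---------------------------------------------------------------------------
# Cohort summaries


@dataclass
class MetricSummary:
    mean: float
    sd: float | None  # sample SD (n-1); None when n == 1
    n: int


@dataclass
class CohortSummary:
    """Macro (across-subject) and micro (pooled) cohort summaries.

    ``macro`` maps metric name -> MetricSummary (undefined per-subject values
    excluded, with the count of subjects that contributed).  ``micro`` pools
    the confusion counts over subjects.  ``significant``/``n_subjects`` is
    the "k from n" significance count.  ``by_group`` holds per-group
    sub-summaries when a stratification is given.
    """

    n_subjects: int
    macro: dict[str, MetricSummary]
    micro_confusion: tuple[int, int, int, int]  # (tp, fp, fn, tn)
    micro_accuracy: float
    micro_f1: float
    significant: int
    by_group: dict[str, "CohortSummary"] | None = None


def _summarize(values: list[float]) -> MetricSummary | None:
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return MetricSummary(mean=float(arr.mean()), sd=sd, n=len(arr))


def summarize_cohort(
    evals: Sequence[SubjectEvaluation],
    outcomes: Sequence[PermutationOutcome],
    groups: Mapping[str, str] | None = None,
) -> CohortSummary:
    """Macro mean ± sample SD per metric, pooled micro confusion matrix and
    micro accuracy/F1, the significance count, and optional per-group
    stratification (e.g. by sex)."""
    if len(evals) == 0:
        raise ValueError("cannot summarize an empty cohort")
    if len(evals) != len(outcomes):
        raise ValueError("evals and outcomes must be parallel")

    def build(e_sub, o_sub):
        macro = {}
        for name, getter in [
            ("accuracy", lambda e: e.accuracy),
            ("f1", lambda e: e.f1),
            ("auroc", lambda e: e.auroc),
            ("auprc", lambda e: e.auprc),
        ]:
            s = _summarize([getter(e) for e in e_sub if getter(e) is not None])
            if s is not None:
                macro[name] = s
        s = _summarize([o.delta_accuracy for o in o_sub])
        if s is not None:
            macro["delta_accuracy"] = s
        tp = sum(e.tp for e in e_sub)
        fp = sum(e.fp for e in e_sub)
        fn = sum(e.fn for e in e_sub)
        tn = sum(e.tn for e in e_sub)
        total = tp + fp + fn + tn
        micro_acc = (tp + tn) / total
        micro_f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        return CohortSummary(
            n_subjects=len(e_sub),
            macro=macro,
            micro_confusion=(tp, fp, fn, tn),
            micro_accuracy=micro_acc,
            micro_f1=micro_f1,
            significant=sum(o.reject for o in o_sub),
        )

    summary = build(evals, outcomes)
    if groups is not None:
        by_group = {}
        labels = sorted({groups[e.subject_id] for e in evals if e.subject_id in groups})
        for label in labels:
            idx = [i for i, e in enumerate(evals) if groups.get(e.subject_id) == label]
            if idx:
                by_group[label] = build([evals[i] for i in idx], [outcomes[i] for i in idx])
        summary.by_group = by_group
    return summary
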