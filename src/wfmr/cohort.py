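"""Population comparison: Welch t-test, box-plot summaries, LOSO classification.

Each subject contributes up to five per-epoch feature values (typically the
WFMR).  The clinical/non-clinical contrast is assessed three ways: a one-sided
Welch t-test (alternative: the clinical mean is higher), a five-number
box-plot summary per population, and leave-one-subject-out (LOSO) binary
classification with naive Bayes, logistic regression and a decision tree —
all epochs of the held-out subject form the test fold, so no subject leaks
between training and test.  Accuracy is reported at epoch level (correct
epochs / total epochs); a subject counts as misclassified when a majority of
its epochs are (ties count as misclassified).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, InputError

CLINICAL, NONCLINICAL = "clinical", "nonclinical"
CLASSIFIERS = ("naive_bayes", "logistic_regression", "decision_tree")


@dataclasses.dataclass
class SubjectFeatures:
    """One subject's per-epoch feature vectors and population label."""

    subject_id: str
    population: str
    values: np.ndarray     # (n_epochs,) or (n_epochs, n_features)

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.population not in (CLINICAL, NONCLINICAL):
            raise InputError(f"unknown population {self.population!r}")
        if not 1 <= self.values.shape[0] <= 5:
            raise InputError(
                f"{self.subject_id}: expected 1–5 epochs, got {self.values.shape[0]}")


# ---------------------------------------------------------------------------
# Welch t-test


def welch_onesided(clinical: np.ndarray, nonclinical: np.ndarray
                   ) -> tuple[float, float, float]:
    """One-sided Welch t-test of H1: mean(clinical) > mean(nonclinical).

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom.
    """
    a = np.asarray(clinical, dtype=float)
    b = np.asarray(nonclinical, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("welch_onesided needs >= 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        df = float(a.size + b.size - 2)
    else:
        df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


# ---------------------------------------------------------------------------
# box plots


@dataclasses.dataclass
class BoxSummary:
    """Five-number summary with 1.5*IQR whiskers and the flagged outliers."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def boxplot_summary(values: np.ndarray) -> BoxSummary:
    """Five-number summary (linear-interpolation quartiles), Tukey whiskers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("boxplot_summary needs >= 1 value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxSummary(minimum=float(v.min()), q1=float(q1), median=float(med),
                      q3=float(q3), maximum=float(v.max()),
                      whisker_low=float(inside.min()),
                      whisker_high=float(inside.max()),
                      outliers=np.sort(outliers))


# ---------------------------------------------------------------------------
# LOSO classification


def _make_classifier(name: str, max_splits: int | None, seed: int):
    if name == "naive_bayes":
        return GaussianNB()
    if name == "logistic_regression":
        # C = inf disables the ridge penalty: plain maximum-likelihood fit
        return LogisticRegression(C=np.inf, max_iter=1000)
    if name == "decision_tree":
        # "maximum splits" caps the number of internal split nodes; a tree
        # with k splits has k + 1 leaves
        leaves = (max_splits or 7) + 1
        return DecisionTreeClassifier(max_leaf_nodes=leaves, random_state=seed)
    raise ConfigurationError(
        f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


@dataclasses.dataclass
class LosoResult:
    """Epoch-level LOSO outcome for one classifier."""

    classifier: str
    accuracy_pct: float
    n_epochs: int
    subject_correct: dict[str, bool]       # majority-of-epochs rule
    misclassified_subjects: list[str]
    max_splits: int | None = None
    split_sweep: dict[int, float] | None = None  # max-splits -> accuracy %


def loso_classify(subjects: list[SubjectFeatures], classifier: str,
                  max_splits: int | None = None, seed: int = 0) -> LosoResult:
    """Leave-one-subject-out binary classification at epoch level."""
    pops = {s.population for s in subjects}
    for pop in (CLINICAL, NONCLINICAL):
        if sum(s.population == pop for s in subjects) < 2:
            raise InputError(f"need >= 2 subjects in population {pop!r}")
    assert pops <= {CLINICAL, NONCLINICAL}

    y_all = np.concatenate([[s.population == CLINICAL] * len(s.values)
                            for s in subjects]).astype(int)
    x_all = np.vstack([s.values for s in subjects])
    owner = np.concatenate([[i] * len(s.values) for i, s in enumerate(subjects)])

    n_correct = 0
    subject_correct: dict[str, bool] = {}
    for i, subj in enumerate(subjects):
        test = owner == i
        train = ~test
        assert not np.any(test & train)
        if len(set(y_all[train])) < 2:
            raise InputError(f"training fold for {subj.subject_id} is single-class")
        clf = _make_classifier(classifier, max_splits, seed)
        clf.fit(x_all[train], y_all[train])
        pred = clf.predict(x_all[test])
        correct = pred == y_all[test]
        n_correct += int(correct.sum())
        subject_correct[subj.subject_id] = bool(correct.sum() * 2 > correct.size)
    acc = 100.0 * n_correct / len(y_all)
    return LosoResult(classifier=classifier, accuracy_pct=acc, n_epochs=len(y_all),
                      subject_correct=subject_correct,
                      misclassified_subjects=[k for k, v in subject_correct.items()
                                              if not v],
                      max_splits=max_splits)


def loso_tree_sweep(subjects: list[SubjectFeatures],
                    split_range: tuple[int, int] = (5, 30),
                    seed: int = 0) -> LosoResult:
    """Decision-tree LOSO over a max-splits sweep; returns the argmax run."""
    lo, hi = split_range
    sweep: dict[int, float] = {}
    best: LosoResult | None = None
    for k in range(lo, hi + 1):
        res = loso_classify(subjects, "decision_tree", max_splits=k, seed=seed)
        sweep[k] = res.accuracy_pct
        if best is None or res.accuracy_pct > best.accuracy_pct:
            best = res
    assert best is not None
    best.split_sweep = sweep
    return best


@dataclasses.dataclass
class CohortResult:
    """Everything the population comparison produces."""

    t_stat: float
    df: float
    p_one_sided: float
    box_clinical: BoxSummary
    box_nonclinical: BoxSummary
    loso: dict[str, LosoResult]


def compare_populations(subjects: list[SubjectFeatures],
                        split_range: tuple[int, int] = (5, 30),
                        seed: int = 0) -> CohortResult:
    """Welch test + box summaries + LOSO with all three classifiers."""
    clin = np.concatenate([s.values[:, 0] for s in subjects
                           if s.population == CLINICAL])
    nonc = np.concatenate([s.values[:, 0] for s in subjects
                           if s.population == NONCLINICAL])
    t, df, p = welch_onesided(clin, nonc)
    loso = {
        "naive_bayes": loso_classify(subjects, "naive_bayes", seed=seed),
        "logistic_regression": loso_classify(subjects, "logistic_regression",
                                             seed=seed),
        "decision_tree": loso_tree_sweep(subjects, split_range, seed=seed),
    }
    return CohortResult(t_stat=t, df=df, p_one_sided=p,
                        box_clinical=boxplot_summary(clin),
                        box_nonclinical=boxplot_summary(nonc),
                        loso=loso)
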