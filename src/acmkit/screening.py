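"""One-decision threshold screening with ROC evaluation.

Re-implements a C4.5-style decision stump: among all candidate cut-offs
(midpoints between consecutive distinct sorted values of one variable) the
rule maximizing Shannon information gain is selected — a single decision,
no compound rules.  The stump is evaluated by confusion metrics
(sensitivity, specificity, PPV, NPV, agreement rate) and the ROC curve /
AUC of the underlying variable, and validated by the repeated-split
protocol: 100 iterations of a random 66% train / 34% test partition,
keeping the iteration with the best test agreement.

Class orientation is always explicit: every report carries its
``positive_class`` / ``negative_class`` labels, so either clinical
orientation (e.g. "positive = patient" or "positive = treated") can be
reproduced exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ThresholdRule:
    """A single-variable, single-cut-off decision rule.

    ``direction`` is ``"gt"`` if values strictly above ``cutoff`` predict
    the positive class, ``"le"`` if values at or below it do.
    """

    variable: str
    cutoff: float
    direction: str
    positive_class: str
    negative_class: str

    def __post_init__(self) -> None:
        if self.direction not in ("gt", "le"):
            raise ValueError("direction must be 'gt' or 'le'")

    def predict(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        above = values > self.cutoff
        pos = above if self.direction == "gt" else ~above
        return np.where(pos, self.positive_class, self.negative_class)

    def scores(self, values) -> np.ndarray:
        """Monotone score: higher means more positive under this rule."""
        values = np.asarray(values, dtype=float)
        return values if self.direction == "gt" else -values

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ClassificationReport:
    """Confusion counts, derived fractions and the ROC of one rule."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str
    negative_class: str
    roc: np.ndarray | None = None  # (n, 2) array of (fpr, tpr)
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def ppv(self) -> float:
        """Proportion of positive calls that are true positives."""
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else math.nan

    @property
    def agreement(self) -> float:
        """Fraction of correctly classified subjects, (TP + TN) / N."""
        return (self.tp + self.tn) / self.n if self.n else math.nan

    def swapped(self) -> "ClassificationReport":
        """The same evaluation with the class orientation reversed."""
        return ClassificationReport(
            tp=self.tn,
            fp=self.fn,
            tn=self.tp,
            fn=self.fp,
            positive_class=self.negative_class,
            negative_class=self.positive_class,
        )

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "positive_class": self.positive_class,
            "negative_class": self.negative_class,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "agreement": self.agreement,
            "auc": self.auc,
        }


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _check_two_classes(labels: np.ndarray, positive_class: str | None) -> tuple[str, str]:
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if positive_class is None:
        positive_class = str(classes[-1])
    if positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not among labels")
    negative_class = str(classes[classes != positive_class][0])
    return str(positive_class), negative_class


def best_threshold(
    values,
    labels,
    variable: str = "value",
    positive_class: str | None = None,
) -> ThresholdRule:
    """Fit the information-gain-optimal decision stump.

    Candidate cut-offs are midpoints between consecutive distinct sorted
    values.  The cut-off maximizing the information gain of the induced
    partition is chosen; ties are broken by higher training agreement, then
    by the lower cut-off.  The direction is then set to maximize agreement.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(str)
    if values.size != labels.size or values.size == 0:
        raise ValueError("values and labels must be equal-length and non-empty")
    pos, neg = _check_two_classes(labels, positive_class)
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("no valid cut-off: all values identical")
    cutoffs = (distinct[:-1] + distinct[1:]) / 2.0

    y = labels == pos
    n = values.size
    parent = _entropy(np.array([y.sum(), n - y.sum()]))

    best: tuple[float, float, float] | None = None  # (gain, agreement, -cutoff) to maximize
    best_rule: ThresholdRule | None = None
    for c in cutoffs:
        above = values > c
        n_above = int(above.sum())
        pos_above = int((y & above).sum())
        pos_below = int(y.sum()) - pos_above
        child = (
            n_above * _entropy(np.array([pos_above, n_above - pos_above]))
            + (n - n_above) * _entropy(np.array([pos_below, (n - n_above) - pos_below]))
        ) / n
        gain = parent - child
        # direction maximizing agreement at this cut-off
        agree_gt = (pos_above + ((n - n_above) - pos_below)) / n
        agree_le = (pos_below + (n_above - pos_above)) / n
        direction = "gt" if agree_gt >= agree_le else "le"
        agreement = max(agree_gt, agree_le)
        key = (gain, agreement, -c)
        if best is None or key > best:
            best = key
            best_rule = ThresholdRule(variable, float(c), direction, pos, neg)
    assert best_rule is not None
    return best_rule


def roc_auc(values, labels, positive_class: str | None = None) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC with higher values scoring positive.

    The AUC equals the two-sample rank statistic ``U / (n1 * n2)`` with
    ties counted as one half.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(str)
    pos, _ = _check_two_classes(labels, positive_class)
    fpr, tpr, _ = _sk_roc_curve(labels == pos, values, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def evaluate_rule(rule: ThresholdRule, values, labels) -> ClassificationReport:
    """Confusion metrics and ROC/AUC of a fitted rule on labelled data."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(str)
    if values.size == 0:
        raise ValueError("empty input")
    pred = rule.predict(values)
    is_pos = labels == rule.positive_class
    pred_pos = pred == rule.positive_class
    tp = int((is_pos & pred_pos).sum())
    fp = int((~is_pos & pred_pos).sum())
    tn = int((~is_pos & ~pred_pos).sum())
    fn = int((is_pos & ~pred_pos).sum())
    report = ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        positive_class=rule.positive_class, negative_class=rule.negative_class,
    )
    if np.unique(labels).size == 2:
        roc, auc_ = roc_auc(rule.scores(values), labels, rule.positive_class)
        report.roc, report.auc = roc, auc_
    return report


@dataclass
class SplitProtocolResult:
    """Outcome of the repeated random-split protocol."""

    best_rule: ThresholdRule
    best_iteration: int
    best_report: ClassificationReport
    refit_rule: ThresholdRule
    per_iteration: list[dict] = field(default_factory=list)
    selection_criterion: str = "test_agreement"
    seed: int | None = None

    @property
    def test_agreements(self) -> np.ndarray:
        return np.array([r["test_agreement"] for r in self.per_iteration])

    @property
    def test_aucs(self) -> np.ndarray:
        return np.array([r["test_auc"] for r in self.per_iteration])


def split_protocol(
    values,
    labels,
    n_iter: int = 100,
    train_frac: float = 0.66,
    seed: int = 0,
    variable: str = "value",
    positive_class: str | None = None,
    stratified: bool = True,
) -> SplitProtocolResult:
    """Best-of-``n_iter`` random 66/34 split evaluation of the stump.

    Each iteration draws a random ``train_frac`` training subset
    (stratified by class by default, so both classes appear on both
    sides), fits :func:`best_threshold` on it, and evaluates on the
    complement.  The best iteration has the highest test agreement, ties
    broken by higher test AUC then lower iteration index.  ``refit_rule``
    is the stump fitted on the full data set.  Fully reproducible from
    ``seed``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(str)
    pos, neg = _check_two_classes(labels, positive_class)
    if train_frac > 1.0 or train_frac <= 0.0:
        raise ValueError("train_frac must lie in (0, 1]")
    for cls in (pos, neg):
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls!r} too small to split")
    rng = np.random.default_rng(seed)
    n = values.size
    per_iteration: list[dict] = []
    refit_rule = best_threshold(values, labels, variable, pos)
    for it in range(n_iter):
        if train_frac == 1.0:
            train_idx = np.arange(n)
            test_idx = np.arange(n)
        elif stratified:
            train_parts, test_parts = [], []
            for cls in (neg, pos):
                idx = np.flatnonzero(labels == cls)
                perm = rng.permutation(idx)
                k = int(round(train_frac * idx.size))
                k = min(max(k, 1), idx.size - 1)
                train_parts.append(perm[:k])
                test_parts.append(perm[k:])
            train_idx = np.sort(np.concatenate(train_parts))
            test_idx = np.sort(np.concatenate(test_parts))
        else:
            perm = rng.permutation(n)
            k = min(max(int(round(train_frac * n)), 1), n - 1)
            train_idx, test_idx = np.sort(perm[:k]), np.sort(perm[k:])
        try:
            rule = best_threshold(values[train_idx], labels[train_idx], variable, pos)
        except ValueError:
            per_iteration.append(
                {"iteration": it, "test_agreement": math.nan, "test_auc": math.nan,
                 "rule": None, "train_idx": train_idx.tolist()}
            )
            continue
        rep = evaluate_rule(rule, values[test_idx], labels[test_idx])
        per_iteration.append(
            {
                "iteration": it,
                "test_agreement": rep.agreement,
                "test_auc": rep.auc if rep.auc is not None else math.nan,
                "rule": rule,
                "train_idx": train_idx.tolist(),
            }
        )
    scored = [
        (r["test_agreement"], np.nan_to_num(r["test_auc"]), -r["iteration"])
        for r in per_iteration
        if r["rule"] is not None and not math.isnan(r["test_agreement"])
    ]
    if not scored:
        raise ValueError("no iteration produced a valid rule")
    best_key = max(scored)
    best_it = -int(best_key[2])
    best_rec = per_iteration[best_it]
    best_rule = best_rec["rule"]
    test_idx_best = np.setdiff1d(np.arange(n), np.array(best_rec["train_idx"], dtype=int))
    if train_frac == 1.0:
        test_idx_best = np.arange(n)
    best_report = evaluate_rule(best_rule, values[test_idx_best], labels[test_idx_best])
    return SplitProtocolResult(
        best_rule=best_rule,
        best_iteration=best_it,
        best_report=best_report,
        refit_rule=refit_rule,
        per_iteration=per_iteration,
        seed=seed,
    )


@dataclass
class PairedComparison:
    """Wilcoxon signed-rank comparison of two per-iteration metric sequences."""

    p_value: float
    statistic: float
    n_nonzero: int
    degenerate: bool


def compare_variables(metric_a, metric_b) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired per-iteration metrics.

    Pairs with zero difference are dropped; if every pair is zero the
    comparison is degenerate and ``p = 1`` is reported with a flag.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.size != b.size or a.size == 0:
        raise ValueError("sequences must be equal-length and non-empty")
    diffs = b - a
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return PairedComparison(p_value=1.0, statistic=0.0, n_nonzero=0, degenerate=True)
    res = stats.wilcoxon(nonzero, alternative="two-sided")
    return PairedComparison(
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        n_nonzero=int(nonzero.size),
        degenerate=False,
    )
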