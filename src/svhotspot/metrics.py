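"""Imbalance-aware evaluation statistics for hotspot models.

ROC AUC is the Mann–Whitney probability that a random positive outscores a
random negative (ties count 1/2). Because hotspot classes are tiny, the
mean test AUC over the 45 CV folds gets two confidence intervals:

* a t-interval, ``mean ± t_{1-a/2, n-1} * s / sqrt(n)`` over the fold AUCs;
* a normal interval from the Hanley–McNeil standard error of the Wilcoxon
  statistic, ``SE(W) = sqrt((Q(1-Q) + (n1-1)(Q1-Q^2) + (n0-1)(Q2-Q^2)) /
  (n0 n1))`` with ``Q1 = Q/(2-Q)`` and ``Q2 = 2Q^2/(1+Q)``, evaluated at
  Q = mean test AUC and the average test-fold class sizes.

A model "has power" when both intervals exclude 0.5.

Recall is measured at top-fraction thresholds: the fraction f of test
observations with the highest predicted probability is called positive
(f in 0.05..0.50, the complements of the probability quantiles
0.95..0.50), and the lift of recall is median recall / f, so 1 marks
random-equivalent ranking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .model import CVEvaluation, predict_proba, zscore_apply

log = logging.getLogger(__name__)

#: top fractions at which recall is evaluated (complements of the
#: predicted-probability quantiles 0.95, 0.90, ..., 0.50)
TOP_FRACTIONS = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


def auc(labels, scores) -> float:
    """Mann–Whitney ROC AUC: P(score+ > score-) + 0.5 * P(tie)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def recall_at_top_fraction(labels, scores, fraction: float) -> float:
    """Recall when the top ``fraction`` of observations by score is called positive.

    ``m = round(fraction * n)`` observations are selected; ties at the score
    cut are broken by stable input order.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("recall undefined without positives")
    n = len(labels)
    m = int(np.floor(fraction * n + 0.5))  # round half up, deterministically
    if m == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    return float(labels[order[:m]].sum() / n_pos)


def lift_of_recall(median_recall: float, fraction: float) -> float:
    """Ratio of the median recall to the selected top fraction (1 = random)."""
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    return median_recall / fraction


def t_interval(values, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided t confidence interval for the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("t-interval needs at least 2 values")
    mean = values.mean()
    s = values.std(ddof=1)
    half = stats.t.ppf(1 - alpha / 2, df=n - 1) * s / np.sqrt(n)
    return float(mean - half), float(mean + half)


def hanley_mcneil_se(Q: float, n0: float, n1: float) -> float:
    """Hanley–McNeil standard error of the AUC (Wilcoxon statistic).

    ``Q`` is the AUC estimate, ``n0``/``n1`` the negative/positive class
    sizes (fractional sizes from averaging over folds are accepted).
    """
    if not (0 <= Q <= 1):
        raise ValueError("Q must be in [0, 1]")
    if n0 < 1 or n1 < 1:
        raise ValueError("class sizes must be >= 1")
    q1 = Q / (2 - Q)
    q2 = 2 * Q * Q / (1 + Q)
    var = (Q * (1 - Q) + (n1 - 1) * (q1 - Q * Q) + (n0 - 1) * (q2 - Q * Q)) / (n0 * n1)
    return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class AUCConfidence:
    """Mean test AUC with its two confidence intervals."""
    mean_auc: float
    t_lower: float
    t_upper: float
    se_lower: float
    se_upper: float
    alpha: float
    n: int
    s: float
    n0: float
    n1: float
    se_w: float

    @property
    def has_power(self) -> bool:
        """Both intervals exclude 0.5 (the no-discrimination AUC)."""
        return not (self.t_lower <= 0.5 <= self.t_upper) and \
            not (self.se_lower <= 0.5 <= self.se_upper)


def auc_confidence(test_aucs, n0: float, n1: float,
                   alpha: float = 0.05) -> AUCConfidence:
    """Both confidence intervals for the mean of the per-fold test AUCs."""
    values = np.asarray(test_aucs, dtype=float)
    mean = float(values.mean())
    t_lo, t_hi = t_interval(values, alpha)
    se = hanley_mcneil_se(mean, n0, n1)
    z = stats.norm.ppf(1 - alpha / 2)
    return AUCConfidence(mean_auc=mean, t_lower=t_lo, t_upper=t_hi,
                         se_lower=mean - z * se, se_upper=mean + z * se,
                         alpha=alpha, n=len(values),
                         s=float(values.std(ddof=1)), n0=n0, n1=n1, se_w=se)


@dataclass(frozen=True, eq=False)
class RecallCurve:
    """Median recall, Q3 recall and lift over the top-fraction grid."""
    top_fractions: tuple
    median_recall: np.ndarray
    recall_q3: np.ndarray
    lift: np.ndarray

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.lift))

    @property
    def best_fraction(self) -> float:
        return float(self.top_fractions[self.best_index])

    @property
    def best_lift(self) -> float:
        return float(self.lift[self.best_index])


def recall_curve(fold_labels, fold_scores,
                 fractions=TOP_FRACTIONS) -> RecallCurve:
    """Per-fraction recall distribution over folds, with lift of the median."""
    med, q3, lift = [], [], []
    for f in fractions:
        recalls = [recall_at_top_fraction(y, s, f)
                   for y, s in zip(fold_labels, fold_scores)]
        m = float(np.median(recalls))
        med.append(m)
        q3.append(float(np.percentile(recalls, 75)))
        lift.append(lift_of_recall(m, f))
    return RecallCurve(top_fractions=tuple(fractions),
                       median_recall=np.array(med), recall_q3=np.array(q3),
                       lift=np.array(lift))


@dataclass(frozen=True, eq=False)
class EvaluationSummary:
    """Headline statistics of one repeated-CV evaluation."""
    cancer_type: str
    aggregation_level: int
    labeling_percent: float
    predictor_set: tuple
    median_train_auc: float
    median_test_auc: float
    test_auc_sd: float
    confidence: AUCConfidence
    recall: RecallCurve
    median_coefficients: dict[str, float]
    median_intercept: float

    @property
    def best_fraction(self) -> float:
        return self.recall.best_fraction

    @property
    def best_lift(self) -> float:
        return self.recall.best_lift

    @property
    def has_power(self) -> bool:
        return self.confidence.has_power

    def to_json(self, path=None) -> str:
        d = {
            "cancer_type": self.cancer_type,
            "aggregation_level": self.aggregation_level,
            "labeling_percent": self.labeling_percent,
            "predictor_set": list(self.predictor_set),
            "median_train_auc": self.median_train_auc,
            "median_test_auc": self.median_test_auc,
            "test_auc_sd": self.test_auc_sd,
            "confidence": asdict(self.confidence),
            "has_power": self.has_power,
            "top_fractions": list(self.recall.top_fractions),
            "median_recall": self.recall.median_recall.tolist(),
            "recall_q3": self.recall.recall_q3.tolist(),
            "lift": self.recall.lift.tolist(),
            "best_fraction": self.best_fraction,
            "best_lift": self.best_lift,
            "median_coefficients": self.median_coefficients,
            "median_intercept": self.median_intercept,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def summarize(cv: CVEvaluation, alpha: float = 0.05,
              fractions=TOP_FRACTIONS) -> EvaluationSummary:
    """Reduce a repeated-CV run to its summary statistics."""
    if len(cv.fold_results) < 2:
        raise ValueError("summary needs at least 2 fold results")
    test_aucs = cv.test_aucs
    n0 = float(np.mean([f.n_test_neg for f in cv.fold_results]))
    n1 = float(np.mean([f.n_test_pos for f in cv.fold_results]))
    conf = auc_confidence(test_aucs, n0=n0, n1=n1, alpha=alpha)
    curve = recall_curve([f.test_labels for f in cv.fold_results],
                         [f.test_scores for f in cv.fold_results], fractions)
    names = cv.dataset.predictor_names
    med_coefs = {k: float(np.median([f.coefficients[k] for f in cv.fold_results]))
                 for k in names}
    return EvaluationSummary(
        cancer_type=cv.dataset.cancer_type,
        aggregation_level=cv.dataset.aggregation_level,
        labeling_percent=cv.dataset.labeling_percent,
        predictor_set=names,
        median_train_auc=float(np.median(cv.train_aucs)),
        median_test_auc=float(np.median(test_aucs)),
        test_auc_sd=float(test_aucs.std(ddof=1)),
        confidence=conf, recall=curve, median_coefficients=med_coefs,
        median_intercept=float(np.median([f.intercept for f in cv.fold_results])))


def select_best_models(summaries: list[EvaluationSummary]) -> dict[str, EvaluationSummary]:
    """Best summary per cancer type by maximum lift of recall.

    Ties go to the higher median test AUC, then the smaller aggregation
    level. Empty groups are skipped with a warning.
    """
    groups: dict[str, list[EvaluationSummary]] = {}
    for s in summaries:
        groups.setdefault(s.cancer_type, []).append(s)
    best = {}
    for cancer, group in groups.items():
        if not group:
            log.warning("no summaries for cancer %r; skipped", cancer)
            continue
        best[cancer] = max(
            group, key=lambda s: (s.best_lift, s.median_test_auc,
                                  -s.aggregation_level))
    return best


def compare_predictor_sets(summaries: list[EvaluationSummary]) -> pd.DataFrame:
    """Median performance per (cancer, predictor set), with the winner flagged.

    For each cancer and predictor set the median over that cancer's datasets
    of the median test AUC and of the best lift is reported; the set with
    the higher median best-lift per cancer is the winner (ties reported as
    such).
    """
    rows = []
    by_key: dict[tuple, list[EvaluationSummary]] = {}
    for s in summaries:
        by_key.setdefault((s.cancer_type, s.predictor_set), []).append(s)
    for (cancer, pset), group in by_key.items():
        rows.append({
            "cancer_type": cancer,
            "predictor_set": "+".join(pset),
            "n_datasets": len(group),
            "median_test_auc": float(np.median([s.median_test_auc for s in group])),
            "median_best_lift": float(np.median([s.best_lift for s in group])),
        })
    out = pd.DataFrame(rows)
    out["winner"] = False
    out["tie"] = False
    for cancer, grp in out.groupby("cancer_type"):
        top = grp["median_best_lift"].max()
        hits = grp.index[grp["median_best_lift"] == top]
        if len(hits) > 1:
            out.loc[hits, "tie"] = True
        else:
            out.loc[hits, "winner"] = True
    return out


@dataclass(frozen=True, eq=False)
class FrozenModel:
    """Coefficients plus scaler of one fitted fold, for cross-cancer transfer."""
    predictor_names: tuple
    coefficients: np.ndarray
    intercept: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray


def freeze_median_model(cv: CVEvaluation) -> FrozenModel:
    """Median coefficients and scaler over all folds, as a transferable model."""
    names = cv.dataset.predictor_names
    coefs = np.array([[f.coefficients[k] for k in names] for f in cv.fold_results])
    means = np.array([f.scaler_mean for f in cv.fold_results])
    sds = np.array([f.scaler_sd for f in cv.fold_results])
    intercepts = np.array([f.intercept for f in cv.fold_results])
    return FrozenModel(predictor_names=names,
                       coefficients=np.median(coefs, axis=0),
                       intercept=float(np.median(intercepts)),
                       scaler_mean=np.median(means, axis=0),
                       scaler_sd=np.median(sds, axis=0))


def transfer_evaluate(model: FrozenModel, dataset,
                      fractions=TOP_FRACTIONS) -> RecallCurve:
    """Apply a frozen model unchanged to another cancer's dataset.

    The source scaler and coefficients are reused as-is; recall and lift are
    computed on the target labels over the top-fraction grid (a single pass
    over the whole target dataset, so median recall = the recall).
    """
    if tuple(dataset.predictor_names) != tuple(model.predictor_names):
        raise ValueError(
            f"predictor mismatch: model has {model.predictor_names}, "
            f"dataset has {dataset.predictor_names}")
    Z = zscore_apply(dataset.X, model.scaler_mean, model.scaler_sd)
    scores = predict_proba(model.coefficients, model.intercept, Z)
    y = np.asarray(dataset.target)
    return recall_curve([y], [scores], fractions)
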