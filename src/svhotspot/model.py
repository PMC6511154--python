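"""Hotspot prediction datasets and the repeated-CV logistic evaluation scheme.

Hotspot labelings are extremely imbalanced (down to 0.01% positives), so a
single train/test split gives an unstable performance estimate. The scheme
used here is 15x repeated stratified 3-fold cross-validation: in each of the
45 folds the training folds are oversampled to exact class balance by
duplicating minority (hotspot) windows, predictors are z-scored with
statistics fitted on the oversampled training data only, a logistic
regression is fitted, and train/test ROC AUC, coefficients and test-set
predicted probabilities are recorded. All randomness derives from a single
root seed through a counter-based expansion, so runs are fully reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

#: default predictor sets; medium stem-loops are computed but excluded from
#: the defaults because they are ~94% correlated with short stem-loops.
PREDICTOR_SETS = {
    "stemloop": ("SL_short", "SL_long"),
    "quadruplex": ("G4",),
    "joint": ("SL_short", "SL_long", "G4"),
}

DEFAULT_REPEATS = 15
DEFAULT_K = 3
DEFAULT_MIN_POSITIVES = 10


@dataclass(frozen=True, eq=False)
class ModelDataset:
    """Aligned (target, predictors) vectors over windows for one labeling."""
    cancer_type: str
    aggregation_level: int
    labeling_percent: float
    target: np.ndarray                      # binary, one per window
    predictors: dict[str, np.ndarray]       # name -> vector per window

    @property
    def n(self) -> int:
        return len(self.target)

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(self.predictors)

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([self.predictors[k] for k in self.predictors])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"window": np.arange(self.n), "target": self.target.astype(int)})
        for name, vals in self.predictors.items():
            out[name] = vals
        return out


def assemble_dataset(labeling, coverage_tracks, predictor_set="joint",
                     min_positives: int = DEFAULT_MIN_POSITIVES) -> ModelDataset:
    """Join a hotspot labeling with coverage tracks into a model dataset.

    ``predictor_set`` is a key of :data:`PREDICTOR_SETS` or an explicit tuple
    of structure-class names; ``coverage_tracks`` maps class name ->
    CoverageTrack (or plain vector). Constant predictors are rejected: they
    carry no information and break z-scoring.
    """
    names = PREDICTOR_SETS.get(predictor_set, tuple(predictor_set))
    target = np.asarray(labeling.labels, dtype=np.int8)
    n_pos = int(target.sum())
    if n_pos < min_positives:
        raise ValueError(
            f"labeling has {n_pos} positives; at least {min_positives} required")
    predictors: dict[str, np.ndarray] = {}
    for name in names:
        if name not in coverage_tracks:
            raise ValueError(f"missing coverage track for predictor {name!r}")
        track = coverage_tracks[name]
        vals = np.asarray(getattr(track, "coverage", track), dtype=float)
        if hasattr(track, "windows") and not track.windows.same_grid(labeling.windows):
            raise ValueError(f"track {name!r} is on a different window grid")
        if len(vals) != len(target):
            raise ValueError(f"track {name!r} length mismatch")
        if np.ptp(vals) == 0:
            raise ValueError(f"predictor {name!r} is constant")
        predictors[name] = vals
    return ModelDataset(cancer_type=labeling.cancer_type,
                        aggregation_level=labeling.aggregation_level,
                        labeling_percent=labeling.labeling_percent,
                        target=target, predictors=predictors)


def zscore_fit(train_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and sample (ddof=1) standard deviations of the train fold."""
    X = np.atleast_2d(np.asarray(train_values, dtype=float))
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero train-fold variance; cannot z-score")
    return mean, sd


def zscore_apply(values: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (np.asarray(values, dtype=float) - mean) / sd


def stratified_kfold_indices(target: np.ndarray, k: int = DEFAULT_K,
                             seed: int = 0) -> list[np.ndarray]:
    """Seeded stratified partition of indices into k folds.

    Per class, fold sizes differ by at most one. The returned arrays are the
    *test* index sets; they partition ``arange(len(target))``.
    """
    target = np.asarray(target)
    counts = np.bincount(target.astype(int))
    if (counts[counts > 0] < k).any():
        raise ValueError(f"every class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32))
    return [test for _, test in skf.split(np.zeros(len(target)), target)]


def oversample_minority(indices: np.ndarray, target: np.ndarray,
                        seed: int = 0) -> np.ndarray:
    """Duplicate minority-class indices until class counts are exactly equal.

    Every minority index is repeated the same whole number of times; the
    non-divisible remainder is drawn without replacement (seeded) from the
    minority indices. Majority indices are untouched.
    """
    indices = np.asarray(indices)
    y = np.asarray(target)[indices]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling needs both classes present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return indices.copy()
    minority_idx = indices[y == minority]
    reps, rem = divmod(n_maj, n_min)
    extra = np.tile(minority_idx, reps - 1)
    if rem:
        rng = np.random.default_rng(seed)
        extra = np.concatenate(
            [extra, rng.choice(minority_idx, size=rem, replace=False)])
    return np.concatenate([indices, extra])


def fit_logistic(X: np.ndarray, y: np.ndarray,
                 ridge_alpha: float = 1e-6) -> tuple[np.ndarray, float]:
    """Maximum-likelihood logistic fit with a tiny-ridge separation fallback.

    Returns ``(coefficients, intercept)``. The unpenalized fit is attempted
    first; if it fails to converge or yields non-finite coefficients (as it
    will under quasi-complete separation, which small hotspot folds can
    produce), the model is refitted with an L2 penalty of ``ridge_alpha``,
    negligible at reporting precision.
    """
    import warnings

    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to fit")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            m = LogisticRegression(C=np.inf, solver="lbfgs",
                                   max_iter=1000, tol=1e-10).fit(X, y)
            if np.all(np.isfinite(m.coef_)) and np.all(np.abs(m.coef_) < 1e6):
                return m.coef_.ravel().copy(), float(m.intercept_[0])
        except ConvergenceWarning:
            pass
    m = LogisticRegression(C=1.0 / (ridge_alpha * len(y)),
                           solver="lbfgs", max_iter=5000).fit(X, y)
    if not np.all(np.isfinite(m.coef_)):
        raise RuntimeError("logistic fit failed even with ridge fallback")
    return m.coef_.ravel().copy(), float(m.intercept_[0])


def predict_proba(coef: np.ndarray, intercept: float, X: np.ndarray) -> np.ndarray:
    """Inverse-logit of the linear score."""
    score = np.atleast_2d(np.asarray(X, dtype=float)) @ np.asarray(coef) + intercept
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-score))


@dataclass
class FoldResult:
    """One fold of one repeat of the cross-validation."""
    repeat_index: int
    fold_index: int
    train_auc: float
    test_auc: float
    coefficients: dict[str, float]
    intercept: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    test_labels: np.ndarray
    test_scores: np.ndarray

    @property
    def n_test_pos(self) -> int:
        return int(self.test_labels.sum())

    @property
    def n_test_neg(self) -> int:
        return int(len(self.test_labels) - self.test_labels.sum())


@dataclass
class CVEvaluation:
    """All fold results of one repeated-CV run for one dataset."""
    dataset: ModelDataset
    repeats: int
    k: int
    seed: int
    fold_results: list[FoldResult] = field(default_factory=list)

    @property
    def test_aucs(self) -> np.ndarray:
        return np.array([f.test_auc for f in self.fold_results])

    @property
    def train_aucs(self) -> np.ndarray:
        return np.array([f.train_auc for f in self.fold_results])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fold_results:
            row = {"repeat": f.repeat_index, "fold": f.fold_index,
                   "train_auc": f.train_auc, "test_auc": f.test_auc,
                   "intercept": f.intercept}
            row.update({f"coef_{k}": v for k, v in f.coefficients.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _fold_seed(root_seed: int, repeat: int, fold: int) -> int:
    """Counter-based expansion of the root seed, stable across platforms."""
    ss = np.random.SeedSequence([int(root_seed) % (2**31), repeat, fold])
    return int(ss.generate_state(1)[0] % (2**31))


def run_repeated_cv(dataset: ModelDataset, repeats: int = DEFAULT_REPEATS,
                    k: int = DEFAULT_K, seed: int = 0) -> CVEvaluation:
    """Run the repeated stratified k-fold evaluation on one dataset.

    Per fold: split -> oversample the training folds to class balance ->
    fit z-score statistics on the oversampled training data and apply to
    train and test -> fit the logistic model -> record train/test AUC,
    coefficients and test-set probabilities. Yields exactly ``repeats * k``
    fold results and is deterministic given ``seed``.
    """
    X_all = dataset.X
    y_all = np.asarray(dataset.target, dtype=int)
    out = CVEvaluation(dataset=dataset, repeats=repeats, k=k, seed=seed)
    for rep in range(1, repeats + 1):
        split_seed = _fold_seed(seed, rep, 0)
        folds = stratified_kfold_indices(y_all, k=k, seed=split_seed)
        all_idx = np.arange(dataset.n)
        for fold_no, test_idx in enumerate(folds, start=1):
            try:
                train_idx = np.setdiff1d(all_idx, test_idx)
                os_idx = oversample_minority(train_idx, y_all,
                                             seed=_fold_seed(seed, rep, fold_no))
                X_tr, y_tr = X_all[os_idx], y_all[os_idx]
                mean, sd = zscore_fit(X_tr)
                Z_tr = zscore_apply(X_tr, mean, sd)
                Z_te = zscore_apply(X_all[test_idx], mean, sd)
                coef, intercept = fit_logistic(Z_tr, y_tr)
                p_tr = predict_proba(coef, intercept, Z_tr)
                p_te = predict_proba(coef, intercept, Z_te)
                out.fold_results.append(FoldResult(
                    repeat_index=rep, fold_index=fold_no,
                    train_auc=float(roc_auc_score(y_tr, p_tr)),
                    test_auc=float(roc_auc_score(y_all[test_idx], p_te)),
                    coefficients=dict(zip(dataset.predictor_names, coef)),
                    intercept=intercept, scaler_mean=mean, scaler_sd=sd,
                    test_labels=y_all[test_idx].copy(), test_scores=p_te))
            except Exception as exc:
                raise RuntimeError(
                    f"repeated CV failed at repeat {rep}, fold {fold_no}: {exc}"
                ) from exc
    return out
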