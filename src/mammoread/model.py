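"""Difficulty prediction from radiomic features: nested-CV random forest.

The classifier maps an area's radiomic feature vector to its
easy/difficult label. The evaluation protocol is a nested
cross-validation: a leave-one-out outer loop for unbiased performance
estimation and a repeated (x3) 3-fold stratified inner loop selecting
the forest size from a grid. Inside every inner training fold the
minority class is oversampled with SMOTE, features with
(pre-standardization) variance <= 1 are dropped, and the survivors are
standardized; statistics never touch validation or test rows.
Out-of-fold scores are aggregated into an AUC with a 2000-replicate
stratified-bootstrap 95% CI and an accuracy at threshold 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Nested-CV protocol constants; defaults follow the study design."""

    tree_grid: tuple = (100, 250, 500, 1000)
    inner_folds: int = 3
    inner_repeats: int = 3
    variance_threshold: float = 1.0
    smote_neighbours: int = 5
    bootstrap_reps: int = 2000
    ci_level: float = 0.95
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tree_grid:
            raise ValueError("tree grid must be non-empty")
        if self.inner_folds < 2 or self.inner_repeats < 1:
            raise ValueError("need >=2 inner folds and >=1 repeat")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")


@dataclass
class ModelResult:
    """Aggregated nested-CV outcome for one (error type, view) pipeline."""

    scores: np.ndarray  # out-of-fold probability of "difficult"
    y: np.ndarray
    auc: float
    auc_ci: tuple
    accuracy: float
    chosen_trees: list
    top_features: list  # per outer fold: list of top-10 feature names
    feature_names: list
    bootstrap_aucs: np.ndarray = field(repr=False, default=None)
    error_type: Optional[str] = None
    view: Optional[str] = None
    cohort: Optional[str] = None


# ---------------------------------------------------------------------------
# building blocks

def smote_oversample(X: np.ndarray, y: np.ndarray, k: int = 5,
                     seed: int = 0):
    """Synthetic minority oversampling to a balanced class ratio.

    Synthetic rows are convex combinations of a minority sample and one
    of its k nearest minority neighbours; originals are preserved. When
    the minority class has fewer than k+1 members, k shrinks (warned);
    a singleton minority falls back to duplication with small jitter.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    Xm = X[y == minority]
    if n_min < 2:
        warnings.warn("singleton minority class: duplicating with jitter")
        scale = 1e-6 * (np.abs(Xm).mean() + 1.0)
        X_new = Xm[np.zeros(n_new, dtype=int)] + \
            rng.normal(0.0, scale, size=(n_new, X.shape[1]))
    else:
        if n_min < k + 1:
            warnings.warn(f"minority class of {n_min}: reducing SMOTE "
                          f"neighbours from {k} to {n_min - 1}")
            k = n_min - 1
        d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nbrs = np.argsort(d2, axis=1)[:, :k]
        base = rng.integers(0, n_min, size=n_new)
        pick = nbrs[base, rng.integers(0, k, size=n_new)]
        lam = rng.random(size=(n_new, 1))
        X_new = Xm[base] + lam * (Xm[pick] - Xm[base])
    X_out = np.vstack([X, X_new])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def variance_filter(X_train: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Indices of features with training variance strictly above threshold.

    Computed on raw (pre-standardization) training values; the same
    index set must be applied to validation/test rows. An empty
    selection falls back to all features (warned).
    """
    variances = np.nanvar(np.asarray(X_train, dtype=float), axis=0)
    keep = np.flatnonzero(variances > threshold)
    if keep.size == 0:
        warnings.warn("variance filter removed every feature; keeping all")
        keep = np.arange(X_train.shape[1])
    return keep


@dataclass
class Standardizer:
    """Per-feature (x - train mean)/train SD; zero-SD features map to 0."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X_train: np.ndarray) -> "Standardizer":
        X = np.asarray(X_train, dtype=float)
        return cls(mean=X.mean(axis=0), sd=X.std(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        sd = np.where(self.sd < 1e-12, 1.0, self.sd)
        out = (np.asarray(X, dtype=float) - self.mean) / sd
        out[:, self.sd < 1e-12] = 0.0
        return out

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd + self.mean


def standardize(train: np.ndarray, apply_to: np.ndarray):
    """Fit on train, transform both; returns (train_z, apply_z, scaler)."""
    scaler = Standardizer.fit(train)
    return scaler.transform(train), scaler.transform(apply_to), scaler


def accuracy_at_threshold(y, scores, threshold: float = 0.5) -> float:
    y = np.asarray(y)
    pred = (np.asarray(scores) >= threshold).astype(int)
    return float((pred == y).mean())


def bootstrap_auc_ci(y, scores, reps: int = 2000, seed: int = 0,
                     ci_level: float = 0.95):
    """Stratified-bootstrap percentile CI of the AUC.

    Cases are resampled within each class so every replicate keeps both
    classes. Returns ``(auc, low, high, replicate_aucs)``.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    auc = float(roc_auc_score(y, scores))
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    boots = np.empty(reps)
    for b in range(reps):
        s0 = rng.choice(idx0, size=idx0.size, replace=True)
        s1 = rng.choice(idx1, size=idx1.size, replace=True)
        sel = np.concatenate([s0, s1])
        boots[b] = roc_auc_score(y[sel], scores[sel])
    alpha = 1.0 - ci_level
    low, high = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return auc, float(low), float(high), boots


def compare_aucs(result_a: ModelResult, result_b: ModelResult):
    """Two-tailed z-test on an AUC difference using bootstrap SEs."""
    if result_a.bootstrap_aucs is None or result_b.bootstrap_aucs is None:
        raise ValueError("both results need bootstrap distributions")
    se_a = float(np.std(result_a.bootstrap_aucs))
    se_b = float(np.std(result_b.bootstrap_aucs))
    denom = np.sqrt(se_a ** 2 + se_b ** 2)
    if denom < 1e-12:
        return 0.0, 1.0
    z = (result_a.auc - result_b.auc) / denom
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# nested cross-validation

def _inner_stratified_splits(y, folds, repeats, rng):
    """Repeated stratified K-fold index pairs; redraws folds missing a
    class in either half (possible at tiny class counts)."""
    splits = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(0, 2**31 - 1)))
        try:
            for tr, va in skf.split(np.zeros(len(y)), y):
                if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                    raise ValueError
                splits.append((tr, va))
        except ValueError:
            warnings.warn("inner split missing a class; repeat skipped")
    return splits


def _fit_transform_train(X_tr, y_tr, config, seed, do_smote=True):
    """SMOTE -> variance filter -> standardize on training rows only."""
    if do_smote:
        X_tr, y_tr = smote_oversample(X_tr, y_tr, k=config.smote_neighbours,
                                      seed=seed)
    keep = variance_filter(X_tr, config.variance_threshold)
    scaler = Standardizer.fit(X_tr[:, keep])
    return X_tr, y_tr, keep, scaler


def nested_cv(X, y, config: ModelConfig | None = None,
              feature_names: Optional[Sequence[str]] = None,
              error_type: Optional[str] = None, view: Optional[str] = None,
              cohort: Optional[str] = None) -> ModelResult:
    """Leave-one-out outer loop with repeated stratified inner tuning.

    Per outer iteration the inner loop scores every tree-grid value by
    mean inner-validation AUC (SMOTE, variance filter and
    standardization all refit inside each inner training fold); the
    winner is refit on the full outer-training set and scores the
    held-out sample. Out-of-fold scores are aggregated into AUC (with
    stratified-bootstrap CI), accuracy, per-fold chosen tree counts and
    per-fold top-10 importance rankings.
    """
    config = config or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    feature_names = list(feature_names)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need two classes with >= 2 samples each")
    master = np.random.default_rng(config.seed)
    scores = np.empty(len(y))
    chosen, top_feats = [], []
    for outer_i, (tr_idx, te_idx) in enumerate(
            LeaveOneOut().split(X)):
        fold_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7919, outer_i]))
        X_tr, y_tr = X[tr_idx], y[tr_idx]
        splits = _inner_stratified_splits(
            y_tr, config.inner_folds, config.inner_repeats, fold_rng)
        grid_scores = {n: [] for n in config.tree_grid}
        for si, (itr, iva) in enumerate(splits):
            seed_i = int(fold_rng.integers(0, 2**31 - 1))
            Xi, yi, keep, scaler = _fit_transform_train(
                X_tr[itr], y_tr[itr], config, seed_i)
            Zi = scaler.transform(Xi[:, keep])
            Zv = scaler.transform(X_tr[iva][:, keep])
            for n_trees in config.tree_grid:
                rf = RandomForestClassifier(
                    n_estimators=n_trees, max_features="sqrt",
                    random_state=seed_i, n_jobs=1)
                rf.fit(Zi, yi)
                prob = rf.predict_proba(Zv)[:, list(rf.classes_).index(1)]
                grid_scores[n_trees].append(roc_auc_score(y_tr[iva], prob))
        mean_auc = {n: (np.mean(v) if v else -np.inf)
                    for n, v in grid_scores.items()}
        best = max(config.tree_grid, key=lambda n: (mean_auc[n], -n))
        chosen.append(best)
        # refit on the full outer-training set (no SMOTE outside the
        # inner loop) and score the held-out sample
        seed_o = int(fold_rng.integers(0, 2**31 - 1))
        keep = variance_filter(X_tr, config.variance_threshold)
        scaler = Standardizer.fit(X_tr[:, keep])
        Z_tr = scaler.transform(X_tr[:, keep])
        Z_te = scaler.transform(X[te_idx][:, keep])
        rf = RandomForestClassifier(n_estimators=best, max_features="sqrt",
                                    random_state=seed_o, n_jobs=1)
        rf.fit(Z_tr, y_tr)
        scores[te_idx] = rf.predict_proba(Z_te)[:, list(rf.classes_).index(1)]
        order = np.argsort(rf.feature_importances_)[::-1][:10]
        top_feats.append([feature_names[keep[i]] for i in order])
    auc, lo, hi, boots = bootstrap_auc_ci(
        y, scores, reps=config.bootstrap_reps,
        seed=int(master.integers(0, 2**31 - 1)), ci_level=config.ci_level)
    acc = accuracy_at_threshold(y, scores, config.decision_threshold)
    return ModelResult(scores=scores, y=y, auc=auc, auc_ci=(lo, hi),
                       accuracy=acc, chosen_trees=chosen,
                       top_features=top_feats, feature_names=feature_names,
                       bootstrap_aucs=boots, error_type=error_type,
                       view=view, cohort=cohort)


def result_table(results: Sequence[ModelResult]) -> pd.DataFrame:
    """Summary table shaped like an error-type x view performance report."""
    rows = []
    for r in results:
        rows.append({"error_type": r.error_type, "cohort": r.cohort,
                     "view": r.view, "auc": r.auc,
                     "auc_ci_low": r.auc_ci[0], "auc_ci_high": r.auc_ci[1],
                     "accuracy": r.accuracy,
                     "n_areas": len(r.y)})
    return pd.DataFrame(rows)
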