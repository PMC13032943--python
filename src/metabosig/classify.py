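"""Cross-validated random-forest classification with negative controls.

The central object is :class:`RandomForestCV`: a model built from a
sample-by-feature matrix, binary labels and a subject-grouped fold
assignment. ``fit()`` trains one forest per fold (mtry = floor(sqrt(p)),
the convention for classification forests) and pools each fold's held-out
scores into a single score vector, from which summary ROC and
precision-recall areas are computed. A matched negative control refits the
same folds after permuting class labels across subjects.

Supporting statistics: rank-based AUROC (ties counted half), step-wise
AUPRC, the paired DeLong test for comparing correlated ROC curves
(one-sided, "experimental beats control"), the star coding used for
reporting p-values, and a bootstrap test comparing a clinical subgroup's
AUROC against matched-size random subsets of the pooled scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score

__all__ = [
    "ModelEvaluation",
    "RocComparison",
    "BootstrapTest",
    "RandomForestCV",
    "train_rf_cv",
    "permuted_label_control",
    "permute_labels_by_subject",
    "auroc",
    "auprc",
    "delong_compare",
    "star_code",
    "bootstrap_subset_test",
    "FoldError",
]


class FoldError(ValueError):
    """A cross-validation fold cannot be trained (e.g. single-class)."""


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank statistic (Mann-Whitney),
    tied scores counted half. Requires both classes present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: only one class present")
    r = stats.rankdata(scores)
    return (r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve by step-wise integration
    (average precision). Requires both classes present."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("AUPRC undefined: only one class present")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class ModelEvaluation:
    """Pooled cross-validation results of a :class:`RandomForestCV` fit."""

    scores: pd.DataFrame  # sample_id index; columns y_true, score, fold
    auroc: float
    auprc: float
    models: dict[int, Any] = field(default_factory=dict, repr=False)
    control: "ModelEvaluation | None" = None
    label: str = "class"

    def compare_to_control(self) -> "RocComparison":
        """DeLong test of this model's AUROC exceeding its permuted-label
        control's, on the shared pooled test samples."""
        if self.control is None:
            raise ValueError("no control evaluation attached")
        ctrl = self.control.scores.reindex(self.scores.index)
        return delong_compare(self.scores["score"].to_numpy(),
                              ctrl["score"].to_numpy(),
                              self.scores["y_true"].to_numpy())

    def summary(self) -> str:
        lines = [
            "Cross-validated random forest",
            "=" * 45,
            f"label:            {self.label}",
            f"pooled samples:   {len(self.scores)}",
            f"cases:            {int(self.scores['y_true'].sum())}",
            f"folds:            {self.scores['fold'].nunique()}",
            f"AUROC:            {self.auroc:.3f}",
            f"AUPRC:            {self.auprc:.3f}",
        ]
        if self.control is not None:
            cmp = self.compare_to_control()
            lines += [
                f"control AUROC:    {self.control.auroc:.3f}",
                f"DeLong p (1-sided): {cmp.p_value:.4g} {star_code(cmp.p_value)}",
            ]
        return "\n".join(lines)


class RandomForestCV:
    """Random-forest classifier evaluated by subject-grouped cross-validation.

    Parameters
    ----------
    matrix : DataFrame
        Samples x features (preprocessed intensities), indexed by sample_id.
    labels : Series
        Binary class per sample_id.
    folds : Series
        Fold index per sample_id (from :mod:`metabosig.splits`).
    n_trees : int
        Forest size; mtry is fixed at floor(sqrt(n_features)).
    seed : int
        Seeds tree construction per fold.
    """

    def __init__(self, matrix: pd.DataFrame, labels: pd.Series, folds: pd.Series,
                 n_trees: int = 500, seed: int = 0):
        common = matrix.index.intersection(folds.index)
        if len(common) != len(folds):
            missing = folds.index.difference(matrix.index).tolist()[:5]
            raise ValueError(f"fold plan references samples absent from the matrix: {missing}")
        self.matrix = matrix.loc[folds.index]
        self.labels = labels.reindex(folds.index).astype(int)
        if self.labels.isna().any():
            raise ValueError("labels missing for some planned samples")
        self.folds = folds
        self.n_trees = int(n_trees)
        self.seed = int(seed)

    @property
    def mtry(self) -> int:
        return max(1, int(np.floor(np.sqrt(self.matrix.shape[1]))))

    @classmethod
    def from_dataframe(cls, matrix: pd.DataFrame, meta: pd.DataFrame, label: str,
                       folds: pd.Series, **kwargs) -> "RandomForestCV":
        per_sample = meta.drop_duplicates("sample_id").set_index("sample_id")[label]
        return cls(matrix, per_sample, folds, **kwargs)

    def fit(self, label_name: str = "class") -> ModelEvaluation:
        X = self.matrix.to_numpy(dtype=float)
        y = self.labels.to_numpy()
        fold_ids = sorted(self.folds.unique())
        ss = np.random.SeedSequence([self.seed, 0xF01D])
        fold_seeds = {f: int(s.generate_state(1)[0] % (2**31)) for f, s in
                      zip(fold_ids, ss.spawn(len(fold_ids)))}

        parts, models = [], {}
        for f in fold_ids:
            test = (self.folds == f).to_numpy()
            train = ~test
            if np.unique(y[train]).size < 2:
                raise FoldError(f"training data for fold {f} contains a single class")
            rf = RandomForestClassifier(n_estimators=self.n_trees,
                                        max_features=self.mtry,
                                        random_state=fold_seeds[f], n_jobs=1)
            rf.fit(X[train], y[train])
            pos_col = int(np.flatnonzero(rf.classes_ == 1)[0])
            s = rf.predict_proba(X[test])[:, pos_col]
            parts.append(pd.DataFrame({
                "y_true": y[test], "score": s, "fold": f,
            }, index=self.folds.index[test]))
            models[f] = rf
        pooled = pd.concat(parts).loc[self.folds.index]
        pooled.index.name = "sample_id"
        return ModelEvaluation(
            scores=pooled,
            auroc=auroc(pooled["score"], pooled["y_true"]),
            auprc=auprc(pooled["score"], pooled["y_true"]),
            models=models,
            label=label_name,
        )


def train_rf_cv(matrix: pd.DataFrame, labels: pd.Series, folds: pd.Series,
                n_trees: int = 500, seed: int = 0) -> ModelEvaluation:
    """Functional wrapper: fit :class:`RandomForestCV` and return the pooled
    evaluation."""
    return RandomForestCV(matrix, labels, folds, n_trees=n_trees, seed=seed).fit()


def permute_labels_by_subject(labels: pd.Series, subjects: pd.Series,
                              seed: int = 0) -> pd.Series:
    """Permute class labels across subjects: every subject receives another
    subject's label, all of a subject's samples stay concordant, and the
    subject-level class counts are preserved exactly."""
    subjects = subjects.reindex(labels.index)
    per_subject = labels.groupby(subjects).first()
    rng = np.random.default_rng(seed)
    permuted = pd.Series(rng.permutation(per_subject.to_numpy()),
                         index=per_subject.index)
    return subjects.map(permuted).astype(labels.dtype)


def permuted_label_control(matrix: pd.DataFrame, labels: pd.Series, folds: pd.Series,
                           subjects: pd.Series, n_trees: int = 500,
                           seed: int = 0) -> ModelEvaluation:
    """Negative control: same matrix and fold plan, labels permuted at
    subject level."""
    shuffled = permute_labels_by_subject(labels.reindex(folds.index),
                                         subjects.reindex(folds.index), seed)
    ev = RandomForestCV(matrix, shuffled, folds, n_trees=n_trees, seed=seed).fit()
    ev.label = "permuted-label control"
    return ev


@dataclass
class RocComparison:
    """Result of a paired one-sided DeLong comparison of two ROC curves."""

    auc_experimental: float
    auc_control: float
    statistic: float
    p_value: float
    sidedness: str = "greater"
    degenerate: bool = False

    def __str__(self) -> str:
        return (f"AUC {self.auc_experimental:.3f} vs {self.auc_control:.3f}: "
                f"z = {self.statistic:.3f}, one-sided p = {self.p_value:.4g} "
                f"{star_code(self.p_value)}")


def _delong_auc_cov(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and covariance matrix of k paired score vectors (DeLong)."""
    pos = scores[:, labels == 1]
    neg = scores[:, labels == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = stats.rankdata(pos[r])
        ty = stats.rankdata(neg[r])
        tz = stats.rankdata(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    return aucs, np.atleast_2d(s01) / m + np.atleast_2d(s10) / n


def delong_compare(scores_a, scores_b, labels) -> RocComparison:
    """Paired DeLong test that ROC area of ``scores_a`` exceeds that of
    ``scores_b`` on the same samples (one-sided).

    A zero-variance difference (e.g. identical score vectors) is flagged
    degenerate and returns statistic 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    aucs, cov = _delong_auc_cov(np.vstack([a, b]), y)
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0 or not np.isfinite(var_diff):
        return RocComparison(aucs[0], aucs[1], 0.0, 1.0, degenerate=True)
    z = (aucs[0] - aucs[1]) / np.sqrt(var_diff)
    return RocComparison(aucs[0], aucs[1], float(z), float(stats.norm.sf(z)))


def star_code(p: float) -> str:
    """Star coding for p-values: (0.01, 0.05] -> '*', (0.001, 0.01] -> '***',
    <= 0.001 -> '****', otherwise ''."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p <= 0.001:
        return "****"
    if p <= 0.01:
        return "***"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class BootstrapTest:
    """Subgroup AUROC versus matched-size bootstrap subsets of the pooled
    cross-validation scores."""

    observed_auc: float
    bootstrap_aucs: np.ndarray
    subset_size: int
    p_value: float

    def summary(self) -> str:
        lo, hi = np.percentile(self.bootstrap_aucs, [2.5, 97.5])
        return (f"subset AUROC {self.observed_auc:.3f} vs {len(self.bootstrap_aucs)} "
                f"matched-size draws (mean {self.bootstrap_aucs.mean():.3f}, "
                f"95% [{lo:.3f}, {hi:.3f}]): t-test p = {self.p_value:.4g} "
                f"{star_code(min(self.p_value, 1.0))}")


def bootstrap_subset_test(evaluation: ModelEvaluation, subset_ids,
                          n_boot: int = 10_000, seed: int = 0,
                          replace: bool = False) -> BootstrapTest:
    """Test whether a subgroup's AUROC differs from matched-size random
    subsets of the pooled test scores.

    Draws ``n_boot`` subsets of ``len(subset_ids)`` samples from the pooled
    scores (without replacement by default), computes each draw's AUROC
    (single-class draws are redrawn), and applies a one-sample t-test of the
    bootstrap distribution against the observed subgroup AUROC (two-sided).
    """
    pooled = evaluation.scores
    subset = pooled.loc[pooled.index.intersection(pd.Index(subset_ids))]
    if subset.empty:
        raise ValueError("subset is empty or disjoint from the pooled scores")
    y_sub = subset["y_true"].to_numpy()
    if np.unique(y_sub).size < 2:
        raise ValueError("subset contains a single class; AUROC undefined")
    observed = auroc(subset["score"], y_sub)

    s = pooled["score"].to_numpy()
    y = pooled["y_true"].to_numpy()
    size = len(subset)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        while True:
            idx = rng.choice(len(s), size=size, replace=replace)
            yi = y[idx]
            if 0 < yi.sum() < size:
                break
        boot[i] = auroc(s[idx], yi)
    if np.ptp(boot) == 0.0:
        # all draws identical (e.g. a saturated classifier): the t statistic
        # is undefined; report the trivially degenerate answer
        p = 1.0 if observed == boot[0] else 0.0
    else:
        _, p = stats.ttest_1samp(boot, observed)
    return BootstrapTest(observed_auc=float(observed), bootstrap_aucs=boot,
                         subset_size=size, p_value=float(p))
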