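"""Signature-size determination by stepwise permutation of ranked features.

Starting from a baseline cross-validated forest, the abundances of the
top-k ranked m/z features (per fold, using that fold's own training-data
ranking) are permuted across samples, the per-fold forests are retrained and
their pooled AUROC recorded; k grows by a fixed step until all features are
permuted or the ranked arm reaches the noise floor. Two negative controls
run on the same grid: permuting k *random* features (accumulating, so the
permuted count matches the grid), and refitting with subject-permuted class
labels. Where the ranked arm has fallen to the controls' level, the
remaining features carry little unique signal; the signature size is the
"flattest point" of the smoothed ranked-arm curve — the grid point where
the absolute first derivative of a local-linear (tricube/lowess) fit is
minimal, located by discrete descent from multiple starts with ties broken
toward smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier

from .classify import RandomForestCV, auroc, permute_labels_by_subject
from .rank import RankedFeatures, rank_by_v

__all__ = [
    "EliminationCurve",
    "SignatureThreshold",
    "permute_topk_and_eval",
    "build_elimination_curves",
    "elbow_threshold",
    "SignatureAnalysis",
]


@dataclass
class EliminationCurve:
    """Pooled AUROC as a function of the number of permuted features, for
    the ranked arm and its two negative controls."""

    table: pd.DataFrame  # columns: k, auroc_ranked, auroc_random, auroc_shuffled
    step: int
    smoothing_span: float = 0.75

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SignatureThreshold:
    """Chosen signature size plus elbow diagnostics."""

    n_signature: int
    curve: EliminationCurve
    derivative_at_elbow: float
    no_signal: bool = False
    smoothed: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Signature threshold (permutation elimination)",
            "=" * 45,
            f"grid step:           {self.curve.step}",
            f"grid points:         {len(self.curve.table)}",
            f"baseline AUROC:      {self.curve.table['auroc_ranked'].iloc[0]:.3f}",
            f"final ranked AUROC:  {self.curve.table['auroc_ranked'].iloc[-1]:.3f}",
            f"signature size:      {self.n_signature}",
            f"|dAUROC/dk| at elbow: {self.derivative_at_elbow:.3g}",
        ]
        if self.no_signal:
            lines.append("WARNING: curve shows no decline; no-signal flag set")
        return "\n".join(lines)


def _fold_topk_permutation(matrix: pd.DataFrame, ranking: RankedFeatures, k: int,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Copy of ``matrix`` with the ranking's top-k features independently
    permuted across rows."""
    out = matrix.copy()
    if k <= 0:
        return out
    feats = ranking.top(k)["mz"].map(lambda v: f"{v:.6f}")
    cols = [c for c in matrix.columns if c in set(feats)]
    if len(cols) != len(feats):  # columns formatted differently: match by float
        colmap = {float(c): c for c in matrix.columns}
        cols = [colmap[v] for v in ranking.top(k)["mz"]]
    for c in cols:
        out[c] = rng.permutation(out[c].to_numpy())
    return out


def _permute_columns(matrix: pd.DataFrame, cols, rng: np.random.Generator) -> pd.DataFrame:
    out = matrix.copy()
    for c in cols:
        out[c] = rng.permutation(out[c].to_numpy())
    return out


def permute_topk_and_eval(matrix: pd.DataFrame, labels: pd.Series, folds: pd.Series,
                          fold_rankings: dict[int, RankedFeatures], k: int,
                          seed: int = 0, n_trees: int = 500) -> float:
    """Pooled AUROC after permuting each fold's top-k ranked features.

    Within each fold the top-k features of *that fold's* ranking are
    permuted across all ML samples (destroying their label association),
    the fold's forest is retrained and its held-out samples scored; scores
    are pooled over folds. The input matrix is never mutated.
    """
    n_features = matrix.shape[1]
    if k > n_features:
        import warnings
        warnings.warn(f"k={k} exceeds feature count {n_features}; clipping", stacklevel=2)
        k = n_features
    sub = matrix.loc[folds.index]
    fold_ids = sorted(folds.unique())
    ss = np.random.SeedSequence([seed, 0x7049])
    rngs = {f: np.random.default_rng(s) for f, s in zip(fold_ids, ss.spawn(len(fold_ids)))}
    mtry = max(1, int(np.floor(np.sqrt(n_features))))
    y = labels.reindex(folds.index).astype(int).to_numpy()

    pooled_scores, pooled_y = [], []
    for f in fold_ids:
        perm = _fold_topk_permutation(sub, fold_rankings[f], k, rngs[f])
        X = perm.to_numpy(dtype=float)
        test = (folds == f).to_numpy()
        rf = RandomForestClassifier(n_estimators=n_trees, max_features=mtry,
                                    random_state=int(rngs[f].integers(2**31)), n_jobs=1)
        rf.fit(X[~test], y[~test])
        pos_col = int(np.flatnonzero(rf.classes_ == 1)[0])
        pooled_scores.append(rf.predict_proba(X[test])[:, pos_col])
        pooled_y.append(y[test])
    return auroc(np.concatenate(pooled_scores), np.concatenate(pooled_y))


def build_elimination_curves(matrix: pd.DataFrame, labels: pd.Series, folds: pd.Series,
                             fold_rankings: dict[int, RankedFeatures],
                             subjects: pd.Series, step: int = 50, seed: int = 0,
                             n_trees: int = 500, early_stop_eps: float = 0.05,
                             max_k: int | None = None) -> EliminationCurve:
    """Evaluate ranked / random / label-shuffled arms over the permutation grid.

    The grid is 0, step, 2*step, ... up to the feature count (or ``max_k``).
    The random arm accumulates its permuted set so exactly k features are
    permuted at grid point k; the shuffled arm applies the ranked-arm
    permutation to subject-permuted labels. Early stop: once the ranked arm
    sits within ``early_stop_eps`` of the shuffled arm for 3 consecutive
    grid points the remaining grid is skipped.
    """
    n_features = matrix.shape[1]
    top = n_features if max_k is None else min(max_k, n_features)
    grid = list(range(0, top + 1, step))

    sub = matrix.loc[folds.index]
    y = labels.reindex(folds.index).astype(int)
    y_shuf = permute_labels_by_subject(y, subjects.reindex(folds.index), seed=seed + 1)

    rng_random = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    random_order = rng_random.permutation(np.asarray(matrix.columns))

    rows = []
    close_streak = 0
    for k in grid:
        a_ranked = permute_topk_and_eval(sub, y, folds, fold_rankings, k,
                                         seed=seed, n_trees=n_trees)
        rand_cols = random_order[:k]
        perm_rand = _permute_columns(sub, rand_cols,
                                     np.random.default_rng(np.random.SeedSequence([seed, 0xB22, k])))
        a_random = RandomForestCV(perm_rand, y, folds, n_trees=n_trees, seed=seed).fit().auroc
        a_shuffled = permute_topk_and_eval(sub, y_shuf, folds, fold_rankings, k,
                                           seed=seed, n_trees=n_trees)
        rows.append({"k": k, "auroc_ranked": a_ranked, "auroc_random": a_random,
                     "auroc_shuffled": a_shuffled})
        close_streak = close_streak + 1 if abs(a_ranked - a_shuffled) <= early_stop_eps else 0
        if close_streak >= 3 and len(rows) >= 5:  # keep enough points for the elbow
            break
    return EliminationCurve(table=pd.DataFrame(rows), step=step)


def _lowess_smooth(k: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Local linear regression with tricube weights at the grid points."""
    if span <= 0:
        return y.copy()
    return sm.nonparametric.lowess(y, k, frac=min(span, 1.0), it=0,
                                   return_sorted=False)


def elbow_threshold(curve: EliminationCurve, smoothing_span: float | None = None,
                    flat_tol: float = 0.02) -> SignatureThreshold:
    """Locate the signature size at the flattest point of the ranked arm.

    The ranked-arm AUROC series is smoothed by local linear regression
    (tricube weights, span default 0.75); |first derivative| (central
    differences on the grid) is minimised over the grid interior (k past the
    first step, so a flat start cannot win) by discrete descent from
    multiple starts; near-ties resolve toward smaller k. A curve whose
    smoothed decline is below ``flat_tol`` yields the no-signal flag and
    size 0.
    """
    tab = curve.table
    if len(tab) < 5:
        raise ValueError("need at least 5 grid points for elbow detection")
    span = curve.smoothing_span if smoothing_span is None else smoothing_span
    k = tab["k"].to_numpy(dtype=float)
    yr = tab["auroc_ranked"].to_numpy(dtype=float)
    smooth = _lowess_smooth(k, yr, span)

    decline = smooth[0] - smooth.min()
    if decline < flat_tol:
        return SignatureThreshold(n_signature=0, curve=curve, derivative_at_elbow=0.0,
                                  no_signal=True,
                                  smoothed=pd.DataFrame({"k": k, "smoothed": smooth}))

    deriv = np.gradient(smooth, k)
    absd = np.abs(deriv)
    interior = np.arange(1, len(k))  # exclude k = 0 only

    # discrete descent from multiple starts; ties stop movement
    candidates = set()
    starts = np.unique(np.linspace(0, len(interior) - 1, num=min(10, len(interior)), dtype=int))
    for s in starts:
        i = interior[s]
        while True:
            neighbors = [j for j in (i - 1, i + 1) if j in interior]
            better = [j for j in neighbors if absd[j] < absd[i] - 1e-15]
            if not better:
                break
            i = min(better, key=lambda j: absd[j])
        candidates.add(i)
    best_val = min(absd[i] for i in candidates)
    near = [i for i in interior if absd[i] <= best_val + 1e-9]
    i_star = min(near)  # ties toward smaller k
    return SignatureThreshold(n_signature=int(k[i_star]), curve=curve,
                              derivative_at_elbow=float(absd[i_star]),
                              smoothed=pd.DataFrame({"k": k, "smoothed": smooth}))


class SignatureAnalysis:
    """Model object for signature-size determination.

    Wraps the per-fold rankings, elimination curves and elbow detection into
    a statsmodels-style fit: construct from the processed matrices, labels
    and fold plan; ``fit()`` returns a :class:`SignatureThreshold`.
    """

    def __init__(self, matrix: pd.DataFrame, fc_matrix: pd.DataFrame,
                 labels: pd.Series, folds: pd.Series, subjects: pd.Series,
                 step: int = 50, n_trees: int = 500, seed: int = 0,
                 smoothing_span: float = 0.75, max_k: int | None = None):
        self.matrix = matrix
        self.fc_matrix = fc_matrix
        self.labels = labels
        self.folds = folds
        self.subjects = subjects
        self.step = step
        self.n_trees = n_trees
        self.seed = seed
        self.smoothing_span = smoothing_span
        self.max_k = max_k

    def fold_rankings(self) -> dict[int, RankedFeatures]:
        """V-score ranking per fold, computed on that fold's training samples."""
        out = {}
        for f in sorted(self.folds.unique()):
            train_ids = self.folds.index[(self.folds != f).to_numpy()]
            out[f] = rank_by_v(self.fc_matrix.loc[train_ids],
                               self.matrix.loc[train_ids],
                               self.labels.loc[train_ids])
        return out

    def fit(self) -> SignatureThreshold:
        rankings = self.fold_rankings()
        curve = build_elimination_curves(self.matrix, self.labels, self.folds,
                                         rankings, self.subjects, step=self.step,
                                         seed=self.seed, n_trees=self.n_trees,
                                         max_k=self.max_k)
        curve.smoothing_span = self.smoothing_span
        return elbow_threshold(curve)
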