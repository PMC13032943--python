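"""Univariate feature ranking: the combined V-score and logistic-Wald z.

The V-score fuses a two-sample test and a fold change into one signed
criterion per m/z feature:

    V = -log10(p) * log2(FC)

where p is a Welch t-test p-value computed on the fully processed
(autoscaled) matrix and FC is the case/control ratio of means on the
positive-intensity (pre-autoscaling) matrix. Features are ranked by |V|
descending, so large changes in either direction rank equally high. The
alternative criterion fits one logistic regression per feature and ranks by
the absolute Wald statistic |Z| = |coefficient / SE|. Agreement between two
rankings (e.g. computed for different phenotypes) is quantified by Spearman
correlation of the per-feature |criterion| values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedFeatures",
    "RankAgreement",
    "vscore",
    "rank_by_v",
    "rank_by_logistic",
    "spearman_rank_agreement",
]

_TINY_P = np.finfo(float).tiny


@dataclass
class RankedFeatures:
    """Per-feature statistics and the derived ordering (rank 1 = strongest)."""

    table: pd.DataFrame  # columns: mz, p_value, fold_change, V, wald_z, rank
    rank_by: str  # "abs_V" or "abs_Z"
    flagged: list[str]  # features with degenerate statistics

    def top(self, n: int) -> pd.DataFrame:
        """The n strongest features in rank order."""
        return self.table.sort_values("rank").head(n)

    def criterion(self) -> pd.Series:
        """|criterion| per feature (the quantity rankings are built from)."""
        col = "V" if self.rank_by == "abs_V" else "wald_z"
        return self.table.set_index("mz")[col].abs()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class RankAgreement:
    rho: float
    p_value: float


def vscore(p_value: float, fold_change: float) -> float:
    """Combined V-score, ``-log10(p) * log2(FC)``.

    p = 0 is clipped to the smallest positive float (with a warning); a
    non-positive fold change is an error because its log-ratio is undefined.
    """
    if fold_change <= 0 or not np.isfinite(fold_change):
        raise ValueError(f"fold_change must be positive and finite, got {fold_change}")
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p_value must be in [0, 1], got {p_value}")
    if p_value == 0.0:
        warnings.warn("p-value of 0 clipped to the smallest positive float", stacklevel=2)
        p_value = _TINY_P
    return float(-np.log10(p_value) * np.log2(fold_change))


def _order_and_rank(table: pd.DataFrame, criterion_col: str) -> pd.DataFrame:
    """Rank by |criterion| descending; ties broken by smaller p, then lower m/z."""
    key = table[criterion_col].abs()
    order = np.lexsort((table["mz"].to_numpy(dtype=float),
                        table["p_value"].to_numpy(),
                        -key.to_numpy()))
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    out = table.copy()
    out["rank"] = ranks
    return out


def rank_by_v(matrix_for_fc: pd.DataFrame, matrix_for_test: pd.DataFrame,
              labels: pd.Series) -> RankedFeatures:
    """Rank features by |V| from Welch t-tests and case/control fold changes.

    ``matrix_for_test`` (typically the autoscaled matrix) feeds the t-test;
    ``matrix_for_fc`` (positive intensities, imputed) feeds the ratio of
    means. Zero-variance features get p = 1, V = 0 and a flag.
    """
    y = labels.reindex(matrix_for_test.index).astype(int).to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    Xt = matrix_for_test.to_numpy(dtype=float)
    Xf = matrix_for_fc.reindex(matrix_for_test.index).to_numpy(dtype=float)

    case, ctrl = Xt[y == 1], Xt[y == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(case, ctrl, equal_var=False, nan_policy="omit")
        p = np.asarray(p)
        fc = np.nanmean(Xf[y == 1], axis=0) / np.nanmean(Xf[y == 0], axis=0)

    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    p_clipped = np.clip(p, _TINY_P, 1.0)
    bad_fc = ~np.isfinite(fc) | (fc <= 0)
    v = np.where(bad_fc | degenerate, 0.0,
                 -np.log10(p_clipped) * np.log2(np.where(bad_fc, 1.0, fc)))

    table = pd.DataFrame({
        "mz": matrix_for_test.columns.astype(float),
        "p_value": p,
        "fold_change": fc,
        "V": v,
        "wald_z": np.nan,
    })
    table = _order_and_rank(table, "V")
    flagged = matrix_for_test.columns[degenerate | bad_fc].tolist()
    return RankedFeatures(table=table, rank_by="abs_V", flagged=flagged)


def _logistic_wald_z(x: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                     max_iter: int = 50) -> tuple[float, bool]:
    """Wald z of the slope in logit(P(y=1)) = b0 + b1 x, by Newton-IRLS.

    With ``ridge`` > 0 a small L2 penalty on the slope stabilises separated
    fits. Returns (z, converged)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * np.array([0.0, beta[1]])
        hess = (X * w[:, None]).T @ X + np.diag([0.0, ridge])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    hess = (X * w[:, None]).T @ X + np.diag([0.0, ridge])
    cov = np.linalg.inv(hess)
    se = np.sqrt(cov[1, 1])
    z = beta[1] / se if se > 0 else 0.0
    return float(z), converged


def rank_by_logistic(matrix: pd.DataFrame, labels: pd.Series) -> RankedFeatures:
    """Rank features by |Z| from single-feature logistic regressions.

    Each feature predicts the class alone (plus intercept), fitted by
    maximum likelihood. Separated or non-converging fits are refitted with a
    tiny ridge penalty (1e-6) and flagged.
    """
    y = labels.reindex(matrix.index).astype(int).to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    X = matrix.to_numpy(dtype=float)

    zs = np.empty(X.shape[1])
    flagged = []
    for j in range(X.shape[1]):
        x = X[:, j]
        if np.nanstd(x) == 0:
            zs[j] = 0.0
            flagged.append(str(matrix.columns[j]))
            continue
        z, ok = _logistic_wald_z(x, y.astype(float))
        if not ok or not np.isfinite(z) or abs(z) > 1e3:
            z, _ = _logistic_wald_z(x, y.astype(float), ridge=1e-6)
            flagged.append(str(matrix.columns[j]))
        zs[j] = z

    # two-sided normal p for reference; ranking uses |Z| itself
    p = 2.0 * stats.norm.sf(np.abs(zs))
    table = pd.DataFrame({
        "mz": matrix.columns.astype(float),
        "p_value": p,
        "fold_change": np.nan,
        "V": np.nan,
        "wald_z": zs,
    })
    table = _order_and_rank(table, "wald_z")
    return RankedFeatures(table=table, rank_by="abs_Z", flagged=flagged)


def spearman_rank_agreement(criterion_a: pd.Series, criterion_b: pd.Series) -> RankAgreement:
    """Spearman correlation between two per-feature |criterion| vectors
    (tie-corrected), with the large-sample p-value."""
    b = criterion_b.reindex(criterion_a.index)
    if b.isna().any():
        raise ValueError("feature universes differ between the two rankings")
    a_v, b_v = criterion_a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    if np.std(a_v) == 0 or np.std(b_v) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(a_v, b_v)
    return RankAgreement(rho=float(rho), p_value=float(p))
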