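"""Peak-table preprocessing: missingness filtering, quantile normalisation,
autoscaling, batch centering, replicate averaging and floor imputation.

The default pipeline mirrors common DI-MS practice: features measured in too
few samples are dropped (a feature counts as present in a sample if at least
one technical replicate recorded a signal), every replicate spectrum is
quantile-normalised to a common intensity distribution, features are
autoscaled to zero mean / unit variance, day-of-run batch location shifts
are removed by per-batch median centering, and technical replicates are
averaged into one row per sample. Fold-change statistics downstream use a
parallel matrix that stops before autoscaling (log-ratios are undefined on
mean-zero data) with remaining missing cells imputed at half the feature
minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedMatrix",
    "filter_missing",
    "quantile_normalize",
    "autoscale",
    "batch_center",
    "average_replicates",
    "impute_half_min",
    "run_default_pipeline",
]


@dataclass
class NormalizedMatrix:
    """A processed intensity matrix plus provenance.

    ``data`` is samples x features. ``steps`` records the applied operations
    in order; ``constant_features`` flags features zeroed by autoscaling;
    ``removed_features`` records features dropped by the missingness filter.
    """

    data: pd.DataFrame
    steps: list[str] = field(default_factory=list)
    constant_features: list[str] = field(default_factory=list)
    removed_features: pd.DataFrame | None = None


def _sample_level_presence(table: pd.DataFrame) -> pd.DataFrame:
    """Sample x feature boolean presence: present if any replicate has a value."""
    return table.notna().groupby(level="sample_id", sort=False).any()


def filter_missing(table: pd.DataFrame, max_missing_fraction: float = 0.20
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop features whose sample-level missing fraction exceeds the threshold.

    A feature is removed iff the fraction of samples with no signal in any
    replicate is *strictly greater* than ``max_missing_fraction`` (a feature
    missing in exactly 20% of samples survives the default filter). Returns
    the retained table and a removal report (feature, missing_fraction).
    """
    if table.empty:
        raise ValueError("peak table is empty")
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    present = _sample_level_presence(table)
    missing_frac = 1.0 - present.mean(axis=0)
    removed = missing_frac[missing_frac > max_missing_fraction]
    report = pd.DataFrame({"feature": removed.index, "missing_fraction": removed.values})
    kept = table.loc[:, missing_frac[missing_frac <= max_missing_fraction].index]
    return kept, report


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise rows to a common distribution.

    Each row's sorted non-missing values are replaced by across-row means of
    the aligned order statistics; tied values receive the mean of their tied
    reference quantiles. Rows with fewer observed values than the reference
    length are mapped through interpolated quantiles of the reference, so
    complete rows end up with identical value multisets.
    """
    X = matrix.to_numpy(dtype=float)
    n_rows, n_cols = X.shape
    counts = np.sum(~np.isnan(X), axis=1)
    if n_rows == 0:
        return matrix.copy()

    full = counts.max()
    if full == 0:
        return matrix.copy()
    # reference distribution: mean of order statistics over rows, each row's
    # sorted values stretched onto a common grid of `full` quantiles
    grid = np.linspace(0.0, 1.0, full)
    ref_acc = np.zeros(full)
    n_used = 0
    for i in range(n_rows):
        vals = np.sort(X[i][~np.isnan(X[i])])
        if vals.size == 0:
            continue
        if vals.size == full:
            ref_acc += vals
        else:
            q = np.linspace(0.0, 1.0, vals.size)
            ref_acc += np.interp(grid, q, vals)
        n_used += 1
    ref = ref_acc / n_used

    out = X.copy()
    for i in range(n_rows):
        m = ~np.isnan(X[i])
        k = counts[i]
        if k == 0:
            continue
        vals = X[i, m]
        if k == full:
            ref_k = ref
        elif k == 1:
            ref_k = np.array([np.interp(0.5, grid, ref)])
        else:
            ref_k = np.interp(np.linspace(0.0, 1.0, k), grid, ref)
        order = np.argsort(vals, kind="mergesort")
        assigned = np.empty(k)
        assigned[order] = ref_k
        # ties receive the mean of their aligned reference quantiles
        uniq, inverse = np.unique(vals, return_inverse=True)
        if uniq.size < k:
            sums = np.bincount(inverse, weights=assigned)
            cnts = np.bincount(inverse)
            assigned = (sums / cnts)[inverse]
        out[i, m] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def autoscale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardise each feature to mean 0, SD 1 (ddof=1 denominator).

    Constant features (zero variance over non-missing entries) are set to
    all-zeros and returned in the flag list rather than producing NaNs.
    """
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    safe_sd = sd.replace(0.0, 1.0).fillna(1.0)
    out = (matrix - mean) / safe_sd
    if constant:
        out[constant] = out[constant].where(out[constant].isna(), 0.0)
    return out, constant


def batch_center(matrix: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Remove per-batch location shifts feature-wise.

    Per feature and batch, subtract the batch median and add back the global
    median, equalising day-of-run medians while preserving each feature's
    overall location. ``batch`` must label every row of ``matrix``.
    """
    aligned = batch.reindex(matrix.index)
    if aligned.isna().any():
        missing = matrix.index[aligned.isna()].tolist()[:5]
        raise ValueError(f"rows without a batch label: {missing}")
    global_med = matrix.median(axis=0)
    centered = matrix.copy()
    for b, idx in matrix.groupby(aligned.to_numpy()).groups.items():
        block = matrix.loc[idx]
        centered.loc[idx] = block - block.median(axis=0) + global_med
    return centered


def average_replicates(table: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate rows to one row per sample by the mean of
    non-missing replicate values (all replicates missing -> missing)."""
    known = pd.MultiIndex.from_frame(meta[["sample_id", "replicate_id"]].drop_duplicates())
    unknown = table.index.difference(known)
    if len(unknown) > 0:
        raise ValueError(f"replicates without metadata rows: {list(unknown[:5])}")
    return table.groupby(level="sample_id", sort=False).mean()


def impute_half_min(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells with half the feature's minimum observed value,
    the standard low-abundance floor convention in metabolomics."""
    floor = matrix.min(axis=0) * 0.5
    return matrix.fillna(floor)


def run_default_pipeline(table: pd.DataFrame, meta: pd.DataFrame,
                         max_missing_fraction: float = 0.20,
                         do_batch_center: bool = True
                         ) -> tuple[NormalizedMatrix, pd.DataFrame]:
    """Full preprocessing: filter -> quantile normalise -> autoscale ->
    batch centre -> average replicates.

    Returns ``(normalized, fold_change_matrix)``. The fold-change matrix
    follows the same path but stops before autoscaling and batch centering
    (log-ratios need positive intensities), with residual missing values
    imputed at half the feature minimum after averaging.
    """
    filtered, report = filter_missing(table, max_missing_fraction)
    qn = quantile_normalize(filtered)

    scaled, constant = autoscale(qn)
    steps = ["filter_missing", "quantile_normalize", "autoscale"]
    if do_batch_center:
        rep_batch = meta.set_index(["sample_id", "replicate_id"])["batch"]
        scaled = batch_center(scaled, rep_batch)
        steps.append("batch_center")
    averaged = average_replicates(scaled, meta)
    steps.append("average_replicates")
    # scaling happened at replicate level; averaging shrinks the variance, so
    # re-standardise at the sample level to restore the unit-variance contract
    averaged, constant2 = autoscale(averaged)
    steps.append("autoscale")
    norm = NormalizedMatrix(data=averaged, steps=steps,
                            constant_features=sorted(set(constant) | set(constant2)),
                            removed_features=report)

    fc = impute_half_min(average_replicates(qn, meta))
    return norm, fc
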