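"""Subject-grouped data splitting: enrichment holdout, grouped stratified
k-fold, and the dual-variable scheme for treatment-confounded phenotypes.

All assignment happens at subject level so that no subject's samples ever
span a train/test boundary (repeated visits from one person are strongly
correlated and would otherwise leak label information). Stratification uses
a greedy bin-packing heuristic: subjects are placed in decreasing
sample-count order into the currently least-filled compatible fold, which
matches optimal per-fold class balance on small instances.

The dual-variable scheme handles a phenotype whose cases are concentrated
in a treatment group (e.g. UDCA in PSC-IBD): control subjects are spread by
plain grouped k-fold, while case subjects are stratified on the treatment
variable, and the fold count is reduced so every fold receives at least one
subject of the rarest treatment category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SplitPlan",
    "holdout_split",
    "grouped_stratified_kfold",
    "dual_variable_folds",
    "make_plan",
    "assert_no_subject_leakage",
]

HOLDOUT = "holdout"


@dataclass
class SplitPlan:
    """Complete split of a cohort: per-sample assignment to the enrichment
    holdout or to one of K cross-validation folds within the ML fraction."""

    assignment: pd.DataFrame  # columns: sample_id, subject_id, assignment
    label: str
    secondary: str | None = None

    @property
    def n_folds(self) -> int:
        ml = self.assignment.loc[self.assignment["assignment"] != HOLDOUT, "assignment"]
        return int(ml.nunique())

    def fold_of(self) -> pd.Series:
        """Integer fold index per ML-set sample (holdout samples excluded)."""
        ml = self.assignment[self.assignment["assignment"] != HOLDOUT]
        return ml.set_index("sample_id")["assignment"].str.removeprefix("fold").astype(int)

    def ml_samples(self) -> pd.Index:
        return pd.Index(self.assignment.loc[self.assignment["assignment"] != HOLDOUT, "sample_id"])

    def holdout_samples(self) -> pd.Index:
        return pd.Index(self.assignment.loc[self.assignment["assignment"] == HOLDOUT, "sample_id"])

    def to_csv(self, path) -> None:
        self.assignment.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "", secondary: str | None = None) -> "SplitPlan":
        return cls(pd.read_csv(path, dtype=str), label=label, secondary=secondary)


def _subject_table(meta: pd.DataFrame, label: str, secondary: str | None = None) -> pd.DataFrame:
    """Collapse per-replicate metadata to one row per subject with its class,
    optional secondary category and unique-sample count."""
    agg = meta.groupby("subject_id").agg(
        cls=(label, "first"),
        n_samples=("sample_id", "nunique"),
        **({"sec": (secondary, "first")} if secondary else {}),
    ).reset_index()
    consistent = meta.groupby("subject_id")[label].nunique()
    if (consistent > 1).any():
        bad = consistent[consistent > 1].index.tolist()[:5]
        raise ValueError(f"subjects with inconsistent '{label}': {bad}")
    return agg


def _greedy_fill(subjects: pd.DataFrame, n_bins: int, rng: np.random.Generator,
                 stratify: bool) -> dict[str, int]:
    """Assign subjects to bins, largest first, each into the bin with the
    fewest samples of the subject's stratum (then fewest total samples)."""
    order = subjects.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
    order = order.sort_values("n_samples", ascending=False, kind="mergesort")
    totals = np.zeros(n_bins)
    strata = {s: np.zeros(n_bins) for s in order["stratum"].unique()}
    out: dict[str, int] = {}
    for _, row in order.iterrows():
        key = strata[row["stratum"]] if stratify else totals
        best = np.lexsort((np.arange(n_bins), totals, key))[0]
        out[row["subject_id"]] = int(best)
        totals[best] += row["n_samples"]
        strata[row["stratum"]][best] += row["n_samples"]
    return out


def holdout_split(meta: pd.DataFrame, label: str, ml_fraction: float = 0.80,
                  seed: int = 0, secondary: str | None = None
                  ) -> tuple[pd.Index, pd.Index]:
    """Split samples 80/20 into ML and enrichment sets at subject level.

    Subjects are stratified by class (and, when ``secondary`` is given, case
    subjects additionally by the secondary category, so rare untreated cases
    are spread over both fractions). Returns ``(ml_sample_ids,
    holdout_sample_ids)``.
    """
    if not 0.0 < ml_fraction < 1.0:
        raise ValueError("ml_fraction must be in (0, 1)")
    subjects = _subject_table(meta, label, secondary)
    class_counts = subjects.groupby("cls")["subject_id"].count()
    if (class_counts < 2).any() or len(class_counts) < 2:
        raise ValueError("need at least 2 subjects in each class to split")
    if secondary:
        subjects["stratum"] = np.where(subjects["cls"].astype(bool),
                                       "case:" + subjects["sec"].astype(str),
                                       "control")
    else:
        subjects["stratum"] = subjects["cls"].astype(str)

    rng = np.random.default_rng(seed)
    holdout_subjects: set[str] = set()
    for stratum, grp in subjects.groupby("stratum"):
        grp = grp.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
        target = (1.0 - ml_fraction) * grp["n_samples"].sum()
        acc = 0.0
        for _, row in grp.iterrows():
            if abs(acc + row["n_samples"] - target) <= abs(acc - target) and acc < target:
                holdout_subjects.add(row["subject_id"])
                acc += row["n_samples"]
    # guarantee both classes appear in both sets
    for cls, grp in subjects.groupby("cls"):
        in_hold = grp["subject_id"].isin(holdout_subjects)
        if not in_hold.any():
            holdout_subjects.add(grp.sort_values("n_samples")["subject_id"].iloc[0])
        elif in_hold.all():
            holdout_subjects.discard(grp.sort_values("n_samples")["subject_id"].iloc[-1])

    sample_subject = meta[["sample_id", "subject_id"]].drop_duplicates()
    is_hold = sample_subject["subject_id"].isin(holdout_subjects)
    return (pd.Index(sample_subject.loc[~is_hold, "sample_id"]),
            pd.Index(sample_subject.loc[is_hold, "sample_id"]))


def grouped_stratified_kfold(meta: pd.DataFrame, label: str, n_folds: int = 5,
                             seed: int = 0) -> pd.Series:
    """Assign samples to K folds, grouped by subject and stratified by class.

    Returns a Series mapping sample_id -> fold index (0..K-1). If a class
    has fewer subjects than folds the fold count is reduced with a warning.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    subjects = _subject_table(meta, label)
    min_class_subjects = subjects.groupby("cls")["subject_id"].count().min()
    k = min(n_folds, int(min_class_subjects))
    if k < n_folds:
        warnings.warn(f"reducing folds from {n_folds} to {k}: smallest class has "
                      f"{min_class_subjects} subjects", stacklevel=2)
    if k < 2:
        raise ValueError("smallest class has fewer than 2 subjects; cannot fold")
    subjects["stratum"] = subjects["cls"].astype(str)
    fold_of_subject = _greedy_fill(subjects, k, np.random.default_rng(seed), stratify=True)
    sample_subject = meta[["sample_id", "subject_id"]].drop_duplicates()
    return pd.Series(sample_subject["subject_id"].map(fold_of_subject).to_numpy(),
                     index=sample_subject["sample_id"], name="fold")


def dual_variable_folds(meta: pd.DataFrame, label: str, secondary: str,
                        n_folds: int = 5, seed: int = 0) -> pd.Series:
    """Fold assignment for a treatment-confounded phenotype.

    Control subjects are spread by grouped k-fold (sample-count balance
    only); case subjects are spread by grouped *stratified* k-fold on the
    secondary (treatment) variable. The fold count is
    ``min(n_folds, subjects in the rarest secondary category among cases)``
    so each fold receives at least one rare-category case. With no variation
    in the secondary variable among cases the scheme falls back to plain
    grouped stratified k-fold on the class label.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    subjects = _subject_table(meta, label, secondary)
    cases = subjects[subjects["cls"].astype(bool)].copy()
    controls = subjects[~subjects["cls"].astype(bool)].copy()
    sec_counts = cases.groupby("sec")["subject_id"].count()
    if len(sec_counts) < 2 or sec_counts.min() < 2:
        warnings.warn("secondary variable has fewer than 2 case subjects in some "
                      "category; falling back to grouped stratified k-fold on the "
                      "class label", stacklevel=2)
        return grouped_stratified_kfold(meta, label, n_folds, seed)
    k = min(n_folds, int(sec_counts.min()))
    if k < n_folds:
        warnings.warn(f"reducing folds from {n_folds} to {k}: rarest secondary "
                      f"category has {sec_counts.min()} case subjects", stacklevel=2)

    rng = np.random.default_rng(seed)
    controls["stratum"] = "control"
    fold_of_subject = _greedy_fill(controls, k, rng, stratify=False)
    cases["stratum"] = cases["sec"].astype(str)
    fold_of_subject.update(_greedy_fill(cases, k, rng, stratify=True))

    sample_subject = meta[["sample_id", "subject_id"]].drop_duplicates()
    return pd.Series(sample_subject["subject_id"].map(fold_of_subject).to_numpy(),
                     index=sample_subject["sample_id"], name="fold")


def make_plan(meta: pd.DataFrame, label: str, secondary: str | None = None,
              ml_fraction: float = 0.80, n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Build the full split plan for one classification question: the 80/20
    enrichment holdout followed by K folds within the ML fraction. Re-run
    with a different ``label`` (and seed) for each question."""
    ml_ids, hold_ids = holdout_split(meta, label, ml_fraction, seed, secondary)
    ml_meta = meta[meta["sample_id"].isin(ml_ids)]
    if secondary is not None:
        folds = dual_variable_folds(ml_meta, label, secondary, n_folds, seed + 1)
    else:
        folds = grouped_stratified_kfold(ml_meta, label, n_folds, seed + 1)
    sample_subject = meta[["sample_id", "subject_id"]].drop_duplicates()
    assignment = sample_subject.copy()
    fold_str = folds.map(lambda f: f"fold{f}")
    assignment["assignment"] = assignment["sample_id"].map(fold_str).fillna(HOLDOUT)
    return SplitPlan(assignment.reset_index(drop=True), label=label, secondary=secondary)


def assert_no_subject_leakage(folds: pd.Series, meta: pd.DataFrame) -> None:
    """Raise if any subject's samples land in more than one fold."""
    subj = meta[["sample_id", "subject_id"]].drop_duplicates().set_index("sample_id")["subject_id"]
    per_subject = folds.groupby(subj.reindex(folds.index)).nunique()
    if (per_subject > 1).any():
        bad = per_subject[per_subject > 1].index.tolist()[:5]
        raise AssertionError(f"subjects spanning folds: {bad}")
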