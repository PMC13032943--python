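"""Mummichog-style metabolite-set enrichment of an m/z signature.

Untargeted DI-MS features are m/z bins, not identified compounds. To test
whether a signature of top-ranked m/z values is enriched for a metabolite
set (a pathway, or the metabolites associated with a microbial taxon), each
candidate compound's neutral monoisotopic mass is expanded into the m/z
values of its plausible ESI adducts; a compound "matches" if any predicted
adduct m/z lies within a ppm tolerance of any signature m/z. Set-level
significance uses the EASE score: the one-sided hypergeometric tail with
the observed overlap reduced by one, a deliberately conservative variant of
Fisher's exact test. The universe is restricted to compounds matchable to
the full measured feature list, so enrichment conditions on detectability.

Also here: construction of a microbe-association metabolite-set database
from a taxon-compound correlation table (keep positive, significant,
formula-resolvable associations; one set per taxon), and the V-sign split
of a signature into increased and decreased halves.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass
from pyteomics.auxiliary import PyteomicsError
from scipy import stats

from .rank import RankedFeatures

__all__ = [
    "AdductRule",
    "MetaboliteSetDB",
    "EnrichmentResult",
    "formula_mass",
    "adduct_mz",
    "neutral_candidates",
    "match_signature",
    "ease_test",
    "run_enrichment",
    "split_by_sign",
    "build_microbe_db",
    "DEFAULT_ADDUCTS",
    "ESSENTIAL_AMINO_ACIDS",
]

ELECTRON = 0.000548579909  # Da

_SUPPORTED_ELEMENTS = {"C", "H", "N", "O", "P", "S", "Na", "K", "Cl", "F", "Br", "I", "Se"}
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _element_mass(el: str) -> float:
    return _pmass.nist_mass[el][0][0]


def formula_mass(formula: str) -> float:
    """Neutral monoisotopic mass (Da) of an element-count formula string.

    Supports C, H, N, O, P, S, Na, K, Cl, F, Br, I, Se. Malformed strings
    or unknown elements raise ``ValueError``.
    """
    if not formula or not isinstance(formula, str):
        raise ValueError(f"malformed formula: {formula!r}")
    pos = 0
    total = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"malformed formula: {formula!r}")
        pos = m.end()
        el, count = m.group(1), m.group(2)
        if el not in _SUPPORTED_ELEMENTS:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        total += _element_mass(el) * (int(count) if count else 1)
    if pos != len(formula):
        raise ValueError(f"malformed formula: {formula!r}")
    # cross-check against pyteomics' own parser (also catches odd edge cases)
    try:
        ref = _pmass.calculate_mass(formula=formula)
    except PyteomicsError as e:
        raise ValueError(f"malformed formula: {formula!r}") from e
    if abs(ref - total) > 1e-6:
        raise ValueError(f"inconsistent formula parse for {formula!r}")
    return total


@dataclass(frozen=True)
class AdductRule:
    """One ESI adduct: observed m/z = (multimer * M + mass_shift) / |charge|.

    ``mass_shift`` carries the full proton/electron bookkeeping for the ion.
    """

    name: str
    mass_shift: float
    charge: int
    multimer: int = 1
    mode: str = "positive"

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("charge must be non-zero")
        if self.multimer < 1:
            raise ValueError("multimer must be >= 1")


def _shift(composition: dict[str, int], charge: int) -> float:
    """Mass shift for adding the given atoms and removing `charge` electrons."""
    s = sum(_element_mass(el) * n for el, n in composition.items())
    return s - charge * ELECTRON


_H, _Na, _K, _N, _O, _C, _Cl, _Br = (_element_mass(e) for e in
                                     ("H", "Na", "K", "N", "O", "C", "Cl", "Br"))

DEFAULT_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("[M+H]+", _shift({"H": 1}, +1), +1),
    AdductRule("[M+Na]+", _shift({"Na": 1}, +1), +1),
    AdductRule("[M+K]+", _shift({"K": 1}, +1), +1),
    AdductRule("[M+NH4]+", _shift({"N": 1, "H": 4}, +1), +1),
    AdductRule("[M+2H]2+", _shift({"H": 2}, +2), +2),
    AdductRule("[2M+H]+", _shift({"H": 1}, +1), +1, multimer=2),
    AdductRule("[M+H-H2O]+", _shift({"H": -1, "O": -1}, +1), +1),
    AdductRule("[M+ACN+H]+", _shift({"C": 2, "H": 4, "N": 1}, +1), +1),
    AdductRule("[M+CH3OH+H]+", _shift({"C": 1, "H": 5, "O": 1}, +1), +1),
    AdductRule("[M-H]-", _shift({"H": -1}, -1), -1, mode="negative"),
    AdductRule("[M+Cl]-", _shift({"Cl": 1}, -1), -1, mode="negative"),
    AdductRule("[M+FA-H]-", _shift({"C": 1, "H": 1, "O": 2}, -1), -1, mode="negative"),
    AdductRule("[M-2H]2-", _shift({"H": -2}, -2), -2, mode="negative"),
    AdductRule("[2M-H]-", _shift({"H": -1}, -1), -1, multimer=2, mode="negative"),
    AdductRule("[M-H-H2O]-", _shift({"H": -3, "O": -1}, -1), -1, mode="negative"),
    AdductRule("[M+Na-2H]-", _shift({"Na": 1, "H": -2}, -1), -1, mode="negative"),
    AdductRule("[M+K-2H]-", _shift({"K": 1, "H": -2}, -1), -1, mode="negative"),
    AdductRule("[M+Br]-", _shift({"Br": 1}, -1), -1, mode="negative"),
    AdductRule("[M+HAc-H]-", _shift({"C": 2, "H": 3, "O": 2}, -1), -1, mode="negative"),
)

ESSENTIAL_AMINO_ACIDS = ("histidine", "isoleucine", "leucine", "lysine", "methionine",
                         "phenylalanine", "threonine", "tryptophan", "valine")


def adduct_mz(neutral_mass: float, rule: AdductRule) -> float:
    """Observed m/z of ``neutral_mass`` under one adduct rule."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return (rule.multimer * neutral_mass + rule.mass_shift) / abs(rule.charge)


def neutral_candidates(mz: float, rules) -> list[tuple[AdductRule, float]]:
    """Invert an observed m/z: candidate neutral masses per adduct rule
    (non-positive candidates dropped)."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    out = []
    for rule in rules:
        m = (abs(rule.charge) * mz - rule.mass_shift) / rule.multimer
        if m > 0:
            out.append((rule, m))
    return out


@dataclass
class MetaboliteSetDB:
    """Named sets of compounds (pathways or microbial taxa).

    ``sets`` maps a set name to member compound ids; ``compounds`` is a
    DataFrame indexed by compound id with columns ``formula`` and ``mass``.
    """

    sets: dict[str, list[str]]
    compounds: pd.DataFrame

    @property
    def universe(self) -> pd.Index:
        return self.compounds.index

    def write(self, gmt_path, compounds_path) -> None:
        with open(gmt_path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, ""] + list(members)) + "\n")
        self.compounds.to_csv(compounds_path, index_label="compound_id")

    @classmethod
    def read(cls, gmt_path, compounds_path) -> "MetaboliteSetDB":
        sets = {}
        with open(gmt_path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2:
                    sets[parts[0]] = [p for p in parts[2:] if p]
        compounds = pd.read_csv(compounds_path, index_col="compound_id")
        return cls(sets=sets, compounds=compounds)


@dataclass
class EnrichmentResult:
    """Per-set enrichment table plus the counts behind it."""

    table: pd.DataFrame  # set, k, m, n, N, ease_p, significant
    direction: str = "all"
    n_signature_mz: int = 0
    matched_compounds: set[str] = field(default_factory=set)

    def significant_sets(self) -> list[str]:
        return self.table.loc[self.table["significant"], "set"].tolist()

    def summary(self) -> str:
        sig = self.significant_sets()
        lines = [
            f"Metabolite-set enrichment ({self.direction})",
            "=" * 45,
            f"signature m/z:        {self.n_signature_mz}",
            f"matched compounds (n): {len(self.matched_compounds)}",
            f"sets tested:          {len(self.table)}",
            f"significant (EASE <= 0.05): {len(sig)}",
        ]
        for s in sig[:20]:
            row = self.table[self.table["set"] == s].iloc[0]
            lines.append(f"  {s}: k={int(row['k'])}/m={int(row['m'])}, p={row['ease_p']:.3g}")
        return "\n".join(lines)


def match_signature(signature_mz, db: MetaboliteSetDB, rules=DEFAULT_ADDUCTS,
                    tolerance_ppm: float = 5.0) -> tuple[set[str], pd.DataFrame]:
    """Annotate signature m/z values with candidate compounds.

    A compound matches if any adduct-predicted m/z lies within
    ``tolerance_ppm`` (relative to the predicted m/z) of any signature m/z.
    Returns the deduplicated matched-compound set and the full many-to-many
    match table.
    """
    rules = tuple(rules)
    if not rules:
        raise ValueError("adduct rule list is empty")
    if tolerance_ppm < 0:
        raise ValueError("tolerance_ppm must be >= 0")
    query = np.sort(np.asarray(list(signature_mz), dtype=float))
    rows = []
    matched: set[str] = set()
    if query.size == 0:
        return matched, pd.DataFrame(columns=["compound_id", "adduct", "predicted_mz",
                                              "query_mz", "ppm_error"])
    for cid, comp in db.compounds.iterrows():
        m = float(comp["mass"])
        for rule in rules:
            pred = adduct_mz(m, rule)
            tol = pred * tolerance_ppm * 1e-6
            lo = np.searchsorted(query, pred - tol, side="left")
            hi = np.searchsorted(query, pred + tol, side="right")
            for q in query[lo:hi]:
                rows.append({"compound_id": cid, "adduct": rule.name,
                             "predicted_mz": pred, "query_mz": q,
                             "ppm_error": (q - pred) / pred * 1e6})
                matched.add(cid)
    return matched, pd.DataFrame(rows)


def ease_test(k: int, m: int, n: int, N: int) -> float:
    """EASE score: hypergeometric tail P(X >= k - 1) with m marked in a
    universe of N, drawing n. Overlap k = 0 (or 1) gives p = 1."""
    if min(k, m, n, N) < 0 or k > min(m, n) or m > N or n > N:
        raise ValueError(f"inconsistent counts: k={k}, m={m}, n={n}, N={N}")
    if k <= 1:
        return 1.0
    return float(stats.hypergeom.sf(k - 2, N, m, n))


def _excluded_set(name: str) -> bool:
    low = name.lower()
    return "synthesis" in low and any(aa in low for aa in ESSENTIAL_AMINO_ACIDS)


def run_enrichment(ranked: RankedFeatures, n_signature: int, db: MetaboliteSetDB,
                   rules=DEFAULT_ADDUCTS, tolerance_ppm: float = 5.0,
                   direction: str = "all", alpha: float = 0.05,
                   exclude_essential_aa: bool = True) -> EnrichmentResult:
    """Set-level enrichment of the top-``n_signature`` features by |criterion|.

    The holdout-partition ranking supplies the signature; the universe size
    N is the number of database compounds matchable to the *full* measured
    feature list. ``direction`` selects all signature features or only those
    with positive / negative V. Sets named for biosynthesis of essential
    amino acids are excluded (humans cannot synthesise them, so their
    enrichment is uninterpretable in plasma); degradation sets stay.
    """
    import warnings
    n_feat = len(ranked.table)
    if n_signature > n_feat:
        warnings.warn(f"n_signature={n_signature} exceeds {n_feat} features; clipping",
                      stacklevel=2)
        n_signature = n_feat

    all_mz = ranked.table["mz"].to_numpy(dtype=float)
    universe_matched, _ = match_signature(all_mz, db, rules, tolerance_ppm)
    N = len(universe_matched)

    if direction == "all":
        sig_mz = ranked.top(n_signature)["mz"].to_numpy(dtype=float)
    elif direction in ("pos", "neg"):
        pos, neg, _ = split_by_sign(ranked, n_signature)
        sig_mz = np.asarray(pos if direction == "pos" else neg, dtype=float)
    else:
        raise ValueError("direction must be 'all', 'pos' or 'neg'")

    matched, match_table = match_signature(sig_mz, db, rules, tolerance_ppm)
    matched &= universe_matched
    n = len(matched)

    rows = []
    for name, members in db.sets.items():
        if exclude_essential_aa and _excluded_set(name):
            continue
        mem = set(members) & universe_matched
        m = len(mem)
        if m == 0 or N == 0:
            continue
        k = len(mem & matched)
        p = ease_test(k, m, n, N)
        rows.append({"set": name, "k": k, "m": m, "n": n, "N": N,
                     "ease_p": p, "significant": p <= alpha})
    table = pd.DataFrame(rows, columns=["set", "k", "m", "n", "N", "ease_p", "significant"])
    if len(table):
        table = table.sort_values("ease_p", kind="mergesort").reset_index(drop=True)
    return EnrichmentResult(table=table, direction=direction,
                            n_signature_mz=len(sig_mz), matched_compounds=matched)


def split_by_sign(ranked: RankedFeatures, n_signature: int
                  ) -> tuple[list[float], list[float], int]:
    """Partition the signature by the sign of V.

    Returns (m/z with V > 0, m/z with V < 0, count of V == 0 features,
    which belong to neither direction)."""
    top = ranked.top(n_signature)
    v = top["V"].to_numpy(dtype=float)
    mz = top["mz"].to_numpy(dtype=float)
    return mz[v > 0].tolist(), mz[v < 0].tolist(), int(np.sum(v == 0))


def build_microbe_db(assoc: pd.DataFrame, alpha: float = 0.05) -> MetaboliteSetDB:
    """Build a taxon-keyed metabolite-set database from an association table.

    Rows are kept iff ``p_adjusted < alpha`` (strict), ``rho > 0`` and both a
    compound id and a parseable molecular formula are present; kept
    compounds get a neutral monoisotopic mass; one set per taxon; empty
    sets are dropped.
    """
    required = {"taxon", "compound_id", "formula", "rho", "p_adjusted"}
    missing = required - set(assoc.columns)
    if missing:
        raise ValueError(f"association table lacks columns: {sorted(missing)}")

    has_id = assoc["compound_id"].astype(str).str.len() > 0
    has_id &= assoc["compound_id"].notna() & (assoc["compound_id"].astype(str) != "nan")
    keep = (assoc["p_adjusted"] < alpha) & (assoc["rho"] > 0) & has_id
    kept = assoc[keep].copy()

    compounds = {}
    sets: dict[str, list[str]] = {}
    for _, row in kept.iterrows():
        cid = str(row["compound_id"])
        formula = str(row["formula"])
        if cid not in compounds:
            try:
                compounds[cid] = (formula, formula_mass(formula))
            except ValueError:
                continue  # unresolvable formula: behaves like a missing id
        sets.setdefault(str(row["taxon"]), [])
        if cid not in sets[str(row["taxon"])] and cid in compounds:
            sets[str(row["taxon"])].append(cid)
    sets = {name: members for name, members in sets.items() if members}
    comp_df = pd.DataFrame(
        [(cid, f, m) for cid, (f, m) in compounds.items()],
        columns=["compound_id", "formula", "mass"],
    ).set_index("compound_id")
    return MetaboliteSetDB(sets=sets, compounds=comp_df)
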