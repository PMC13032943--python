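"""Synthetic cohort, peak-table and microbe-association generators.

The generator emulates the structure of a longitudinal IBD surveillance
cohort profiled by direct-infusion mass spectrometry (DI-MS): subjects with
repeated visits, a low-prevalence binary phenotype (PSC-like, ~8% of
subjects), a treatment confounder concentrated in cases (UDCA-like, ~82% of
cases treated), sex, technical triplicates per plasma sample, day-of-run
batch shifts on the log-intensity scale, and intensity-dependent missingness
(low-abundance censoring). A configurable subset of m/z features carries a
planted case/control effect so that feature ranking, signature thresholding
and enrichment can be validated against known ground truth.

Intensities are log-normal: a feature's log2 intensity is the sum of a
feature baseline, the planted class effect (cases only), a per-(batch,
feature) shift, a per-(sample, feature) biological term and per-replicate
technical noise. Cells go missing with probability that is a decreasing
logistic function of the latent log2 intensity, calibrated so the marginal
missing fraction matches ``missing_rate_base``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_peak_table",
    "generate_association_table",
    "planted_compound_annotations",
    "draw_mz_grid",
    "BUILTIN_FORMULAS",
]

# Molecular formulas of common small plasma/gut metabolites (amino acids,
# organic acids, sugars, bile acids, nucleosides, SCFAs, vitamins ...).
# Used to give synthetic association tables chemically real formulas so the
# adduct/annotation path downstream operates on plausible masses.
BUILTIN_FORMULAS: tuple[tuple[str, str], ...] = (
    ("SYN00001", "C3H7NO2"),     # alanine
    ("SYN00002", "C6H14N4O2"),   # arginine
    ("SYN00003", "C4H8N2O3"),    # asparagine
    ("SYN00004", "C4H7NO4"),     # aspartate
    ("SYN00005", "C3H7NO2S"),    # cysteine
    ("SYN00006", "C5H9NO4"),     # glutamate
    ("SYN00007", "C5H10N2O3"),   # glutamine
    ("SYN00008", "C2H5NO2"),     # glycine
    ("SYN00009", "C6H9N3O2"),    # histidine
    ("SYN00010", "C6H13NO2"),    # (iso)leucine
    ("SYN00011", "C6H14N2O2"),   # lysine
    ("SYN00012", "C5H11NO2S"),   # methionine
    ("SYN00013", "C9H11NO2"),    # phenylalanine
    ("SYN00014", "C5H9NO2"),     # proline
    ("SYN00015", "C3H7NO3"),     # serine
    ("SYN00016", "C4H9NO3"),     # threonine
    ("SYN00017", "C11H12N2O2"),  # tryptophan
    ("SYN00018", "C9H11NO3"),    # tyrosine
    ("SYN00019", "C5H11NO2"),    # valine
    ("SYN00020", "C6H12O6"),     # hexose
    ("SYN00021", "C12H22O11"),   # disaccharide
    ("SYN00022", "C5H10O5"),     # pentose
    ("SYN00023", "C6H12O7"),     # gluconate
    ("SYN00024", "C3H6O3"),      # lactate
    ("SYN00025", "C3H4O3"),      # pyruvate
    ("SYN00026", "C4H6O4"),      # succinate
    ("SYN00027", "C4H4O4"),      # fumarate
    ("SYN00028", "C4H6O5"),      # malate
    ("SYN00029", "C6H8O7"),      # citrate
    ("SYN00030", "C2H4O2"),      # acetate
    ("SYN00031", "C3H6O2"),      # propionate
    ("SYN00032", "C4H8O2"),      # butyrate
    ("SYN00033", "C5H10O2"),     # valerate
    ("SYN00034", "C2H2O4"),      # oxalate
    ("SYN00035", "C5H4N4O3"),    # urate
    ("SYN00036", "CH4N2O"),      # urea
    ("SYN00037", "C4H9N3O2"),    # creatine
    ("SYN00038", "C4H7N3O"),     # creatinine
    ("SYN00039", "C9H8O3"),      # hydroxyphenyl-propenoate
    ("SYN00040", "C8H8O3"),      # hydroxyphenyl-acetate / vanillin
    ("SYN00041", "C9H10O3"),     # hydroxyphenyl-lactate
    ("SYN00042", "C7H6O2"),      # benzoate
    ("SYN00043", "C9H9NO2"),     # phenylacetylglycine core
    ("SYN00044", "C8H7N"),       # indole-ish
    ("SYN00045", "C10H9NO2"),    # indole-acetate
    ("SYN00046", "C11H11NO3"),   # indole-lactate
    ("SYN00047", "C8H5NO2"),     # indole-dione
    ("SYN00048", "C24H40O4"),    # deoxycholate / chenodeoxycholate / UDCA
    ("SYN00049", "C24H40O5"),    # cholate
    ("SYN00050", "C26H43NO5"),   # glycconjugated bile acid
    ("SYN00051", "C26H45NO6S"),  # tauroconjugated bile acid
    ("SYN00052", "C24H40O3"),    # lithocholate
    ("SYN00053", "C27H46O"),     # cholesterol
    ("SYN00054", "C16H32O2"),    # palmitate
    ("SYN00055", "C18H36O2"),    # stearate
    ("SYN00056", "C18H34O2"),    # oleate
    ("SYN00057", "C18H32O2"),    # linoleate
    ("SYN00058", "C20H32O2"),    # arachidonate
    ("SYN00059", "C22H32O2"),    # docosahexaenoate
    ("SYN00060", "C3H8O3"),      # glycerol
    ("SYN00061", "C5H14NO"),     # choline (neutral form)
    ("SYN00062", "C7H15NO3"),    # carnitine
    ("SYN00063", "C9H17NO4"),    # acetylcarnitine
    ("SYN00064", "C5H11NO2Se"),  # selenomethionine
    ("SYN00065", "C10H13N5O4"),  # adenosine
    ("SYN00066", "C10H13N5O5"),  # guanosine
    ("SYN00067", "C9H13N3O5"),   # cytidine
    ("SYN00068", "C9H12N2O6"),   # uridine
    ("SYN00069", "C10H14N2O5"),  # thymidine
    ("SYN00070", "C5H5N5"),      # adenine
    ("SYN00071", "C5H5N5O"),     # guanine
    ("SYN00072", "C4H4N2O2"),    # uracil
    ("SYN00073", "C5H4N4O"),     # hypoxanthine
    ("SYN00074", "C5H4N4O2"),    # xanthine
    ("SYN00075", "C6H8O6"),      # ascorbate
    ("SYN00076", "C6H5NO2"),     # nicotinate
    ("SYN00077", "C6H6N2O"),     # nicotinamide
    ("SYN00078", "C12H17N4OS"),  # thiamine (cation core)
    ("SYN00079", "C17H20N4O6"),  # riboflavin
    ("SYN00080", "C8H11NO3"),    # pyridoxine
    ("SYN00081", "C19H19N7O6"),  # folate
    ("SYN00082", "C9H17NO5"),    # pantothenate
    ("SYN00083", "C10H16N2O3S"), # biotin
    ("SYN00084", "C2H7NO3S"),    # taurine
    ("SYN00085", "C6H13NO5"),    # glucosamine
    ("SYN00086", "C8H15NO6"),    # N-acetylglucosamine
    ("SYN00087", "C11H19NO9"),   # N-acetylneuraminate
    ("SYN00088", "C6H10O5"),     # levoglucosan-ish
    ("SYN00089", "C7H12O6"),     # quinate
    ("SYN00090", "C7H6O5"),      # gallate
    ("SYN00091", "C4H6N2O2"),    # dihydrouracil-ish
    ("SYN00092", "C3H9O6P"),     # glycerophosphate
    ("SYN00093", "C6H13O9P"),    # hexose phosphate
    ("SYN00094", "C10H12N5O7P"), # AMP (minus H variant)
    ("SYN00095", "C3H8NO6P"),    # phosphoserine
    ("SYN00096", "C2H8NO4P"),    # phosphoethanolamine
    ("SYN00097", "C6H15O3N"),    # triethanolamine-ish
    ("SYN00098", "C4H11NO"),     # dimethylaminoethanol-ish
    ("SYN00099", "C7H7ClN2O2S"), # chlorinated sulfonamide-ish xenobiotic
    ("SYN00100", "C9H8BrNO2"),   # brominated xenobiotic
    ("SYN00101", "C7H5F3O"),     # fluorinated xenobiotic
    ("SYN00102", "C7H7IO2"),     # iodinated xenobiotic
    ("SYN00103", "C10H14N5O8P"), # nucleotide-ish
    ("SYN00104", "C5H9NO3S"),    # N-acetylcysteine
    ("SYN00105", "C6H12N2O4S2"), # cystine
    ("SYN00106", "C10H17N3O6S"), # glutathione
    ("SYN00107", "C5H7NO3"),     # pyroglutamate
    ("SYN00108", "C4H9NO2"),     # GABA / aminoisobutyrate
    ("SYN00109", "C7H11N3O2"),   # methylhistidine
    ("SYN00110", "C6H11NO2"),    # pipecolate
    ("SYN00111", "C5H12N2O2"),   # ornithine
    ("SYN00112", "C6H13N3O3"),   # citrulline
    ("SYN00113", "C8H16N2O4S"),  # cystathionine-ish
    ("SYN00114", "C14H20N6O5S"), # S-adenosylhomocysteine-ish
    ("SYN00115", "C5H9NO2S"),    # thioproline-ish
    ("SYN00116", "C9H12O4"),     # dihydroxyphenyl-propanoate
    ("SYN00117", "C8H10O4"),     # homovanillate-ish
    ("SYN00118", "C10H12O5"),    # sinapoyl-ish
    ("SYN00119", "C13H16N2O2"),  # melatonin core
    ("SYN00120", "C10H12N2O"),   # serotonin
)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort and its peak table.

    Defaults match the cohort structure of a typical IBD surveillance study
    with a rare cholestatic comorbidity: ~8% case prevalence at subject
    level, ~82% of cases on a case-concentrated treatment, roughly equal
    sexes, one-to-three visits per subject, technical triplicates, and
    moderate day-of-run batch shifts.
    """

    n_subjects: int = 200
    visits_per_subject: tuple[int, int] = (1, 3)
    case_prevalence: float = 0.08
    confounder_rate_in_cases: float = 0.82
    confounder_rate_in_controls: float = 0.0
    sex_ratio: float = 0.5
    n_features: int = 1000
    n_planted: int = 50
    planted_log2fc: float = 1.0
    planted_frac_up: float = 1.0
    planted_compound_frac: float = 0.0
    background_compound_features: int = 0
    batch_count: int = 5
    batch_shift_sd: float = 0.3
    replicate_count: int = 3
    replicate_noise_sd: float = 0.2
    biological_sd: float = 0.8
    missing_rate_base: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "case_prevalence": self.case_prevalence,
            "confounder_rate_in_cases": self.confounder_rate_in_cases,
            "confounder_rate_in_controls": self.confounder_rate_in_controls,
            "sex_ratio": self.sex_ratio,
            "missing_rate_base": self.missing_rate_base,
            "planted_frac_up": self.planted_frac_up,
            "planted_compound_frac": self.planted_compound_frac,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if self.n_planted > self.n_features:
            raise ValueError("n_planted cannot exceed n_features")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if self.batch_count < 1:
            raise ValueError("batch_count must be >= 1")
        lo, hi = self.visits_per_subject
        if lo < 1 or hi < lo:
            raise ValueError("visits_per_subject must be a (lo, hi) range with 1 <= lo <= hi")


def draw_mz_grid(n_features: int, rng: np.random.Generator,
                 mz_range: tuple[float, float] = (70.0, 1000.0),
                 min_spacing_ppm: float = 2.0) -> np.ndarray:
    """Draw ``n_features`` synthetic m/z values uniform on ``mz_range``.

    Values are sorted and thinned to respect a minimum relative spacing
    (default 2 ppm, the bin width of high-resolution DI-MS peak tables);
    rejected values are redrawn until the grid is full.
    """
    lo, hi = mz_range
    mz = np.sort(rng.uniform(lo, hi, size=n_features))
    for _ in range(1000):
        rel_gap = np.diff(mz) / mz[:-1]
        bad = np.flatnonzero(rel_gap < min_spacing_ppm * 1e-6)
        if bad.size == 0:
            return mz
        keep = np.delete(mz, bad + 1)
        extra = rng.uniform(lo, hi, size=n_features - keep.size)
        mz = np.sort(np.concatenate([keep, extra]))
    raise RuntimeError("could not construct an m/z grid with the requested spacing")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate per-replicate cohort metadata.

    Returns a DataFrame with one row per (sample, replicate):
    ``sample_id, subject_id, replicate_id, batch, injection_order,
    class_label, sex, treatment``. Class, sex and treatment are assigned at
    subject level; batch is a day-of-run label shared by all replicates of a
    sample; injection order is the global run sequence.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_subjects
    case = rng.random(n) < spec.case_prevalence
    sex = rng.random(n) < spec.sex_ratio
    treat_p = np.where(case, spec.confounder_rate_in_cases, spec.confounder_rate_in_controls)
    treatment = rng.random(n) < treat_p
    lo, hi = spec.visits_per_subject
    visits = rng.integers(lo, hi + 1, size=n)

    samples = []
    for i in range(n):
        for v in range(visits[i]):
            samples.append((f"S{i:04d}", f"S{i:04d}_V{v + 1}", int(case[i]), int(sex[i]), int(treatment[i])))
    # run order is randomised, then chunked into day-of-run batches
    order = rng.permutation(len(samples))
    batch_edges = np.array_split(np.arange(len(samples)), spec.batch_count)
    batch_of_pos = np.empty(len(samples), dtype=int)
    for b, idx in enumerate(batch_edges):
        batch_of_pos[idx] = b

    rows = []
    injection = 0
    for pos, si in enumerate(order):
        subject_id, sample_id, cls, sx, tr = samples[si]
        batch = f"B{batch_of_pos[pos] + 1:02d}"
        for r in range(1, spec.replicate_count + 1):
            injection += 1
            rows.append({
                "sample_id": sample_id,
                "subject_id": subject_id,
                "replicate_id": f"R{r}",
                "batch": batch,
                "injection_order": injection,
                "class_label": cls,
                "sex": sx,
                "treatment": tr,
            })
    meta = pd.DataFrame(rows)
    meta = meta.sort_values("injection_order", kind="mergesort").reset_index(drop=True)
    return meta


def _calibrate_missing_threshold(latent: np.ndarray, target: float, scale: float) -> float:
    """Bisect a logistic location so mean missing probability hits ``target``."""
    lo, hi = latent.min() - 10 * scale, latent.max() + 10 * scale
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp(-(mid - latent) / scale))
        if p.mean() > target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def generate_peak_table(meta: pd.DataFrame, spec: CohortSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a replicate-level peak table for a cohort.

    Returns ``(table, planted_idx)``: a DataFrame indexed by
    ``(sample_id, replicate_id)`` whose columns are m/z values formatted as
    strings, cells holding intensities (NaN = missing), and the integer
    column indices of the planted differential features.

    Log2 intensity = feature baseline + planted effect (cases only)
    + batch shift + biological sample term + replicate technical noise;
    intensity = 2**log2. Missingness is intensity-dependent (logistic in the
    latent log2 value) with the marginal rate calibrated to
    ``missing_rate_base``.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))

    mz = draw_mz_grid(spec.n_features, rng)
    planted_idx = np.sort(rng.choice(spec.n_features, size=spec.n_planted, replace=False))
    if spec.planted_compound_frac > 0 or spec.background_compound_features > 0:
        # anchor part of the planted set (and optionally some null features)
        # at real compound [M+H]+ m/z values so the enrichment path
        # downstream has recoverable annotations with a detectable universe
        ann = planted_compound_annotations(spec)
        for i, row in ann.iterrows():
            mz[planted_idx[i]] = row["mz"]
        n_bg = min(spec.background_compound_features,
                   len(BUILTIN_FORMULAS) - len(ann),
                   spec.n_features - spec.n_planted)
        if n_bg > 0:
            from .enrich import DEFAULT_ADDUCTS, adduct_mz, formula_mass
            non_planted = np.setdiff1d(np.arange(spec.n_features), planted_idx)
            bg_feats = rng.choice(non_planted, size=n_bg, replace=False)
            for j in range(n_bg):
                _, formula = BUILTIN_FORMULAS[len(ann) + j]
                mz[bg_feats[j]] = adduct_mz(formula_mass(formula), DEFAULT_ADDUCTS[0])
    n_up = int(round(spec.planted_frac_up * spec.n_planted))
    sign = np.zeros(spec.n_features)
    up = rng.permutation(spec.n_planted) < n_up
    sign[planted_idx[up]] = 1.0
    sign[planted_idx[~up]] = -1.0

    baseline = rng.uniform(10.0, 20.0, size=spec.n_features)

    samples = meta[["sample_id", "subject_id", "batch", "class_label"]].drop_duplicates("sample_id")
    batches = sorted(samples["batch"].unique())
    batch_shift = {b: rng.normal(0.0, spec.batch_shift_sd, size=spec.n_features) for b in batches}

    n_samples = len(samples)
    cls = samples["class_label"].to_numpy()
    bio = rng.normal(0.0, spec.biological_sd, size=(n_samples, spec.n_features))
    effect = np.outer(cls, sign * spec.planted_log2fc)
    shift = np.stack([batch_shift[b] for b in samples["batch"]])
    sample_log2 = baseline[None, :] + effect + shift + bio

    rep_ids = sorted(meta["replicate_id"].unique())
    index = pd.MultiIndex.from_product(
        [samples["sample_id"], rep_ids], names=["sample_id", "replicate_id"]
    )
    n_rep = len(rep_ids)
    noise = rng.normal(0.0, spec.replicate_noise_sd, size=(n_samples * n_rep, spec.n_features))
    latent = np.repeat(sample_log2, n_rep, axis=0) + noise

    intensities = np.exp2(latent)
    if spec.missing_rate_base > 0:
        scale = 1.0
        thr = _calibrate_missing_threshold(latent, spec.missing_rate_base, scale)
        p_miss = 1.0 / (1.0 + np.exp(-(thr - latent) / scale))
        intensities[rng.random(latent.shape) < p_miss] = np.nan

    cols = [f"{v:.6f}" for v in mz]
    table = pd.DataFrame(intensities, index=index, columns=cols)
    # keep only (sample, replicate) combinations that exist in the metadata
    valid = pd.MultiIndex.from_frame(meta[["sample_id", "replicate_id"]])
    table = table.loc[table.index.isin(valid)]
    return table, planted_idx


def planted_compound_annotations(spec: CohortSpec) -> pd.DataFrame:
    """Compound identities of the compound-anchored planted features.

    The first ``round(planted_compound_frac * n_planted)`` planted features
    (in planted-index order) are assigned built-in compounds in catalogue
    order, observed as their [M+H]+ adduct. Returns a DataFrame with columns
    ``compound_id, formula, mz``, row i describing planted feature i.
    """
    from .enrich import DEFAULT_ADDUCTS, adduct_mz, formula_mass

    k = int(round(spec.planted_compound_frac * spec.n_planted))
    k = min(k, len(BUILTIN_FORMULAS))
    rows = []
    for i in range(k):
        cid, formula = BUILTIN_FORMULAS[i]
        rows.append({"compound_id": cid, "formula": formula,
                     "mz": adduct_mz(formula_mass(formula), DEFAULT_ADDUCTS[0])})
    return pd.DataFrame(rows, columns=["compound_id", "formula", "mz"])


def generate_association_table(n_taxa: int, n_compounds: int, frac_significant: float,
                               seed: int, compounds_per_taxon: int = 10,
                               frac_missing_id: float = 0.0,
                               planted_taxon_compounds=None) -> pd.DataFrame:
    """Generate a synthetic taxon-metabolite association table.

    Emulates the shape of gut microbiome-plasma metabolite correlation
    atlases: one row per (taxon, compound) with a molecular formula drawn
    from a built-in list of real small-molecule formulas, a correlation
    ``rho`` in (-1, 1) and an adjusted p-value. A ``frac_significant``
    fraction of rows is constructed to pass the downstream inclusion filter
    (``p_adjusted < 0.05`` and ``rho > 0``); the rest are constructed to
    fail it, so database-builder recovery is exactly testable.

    ``planted_taxon_compounds`` optionally appends a taxon named
    ``Taxon_planted`` whose rows are exactly the given compound ids (looked
    up in the built-in catalogue), all passing the inclusion filter — the
    ground-truth positive for enrichment recovery.
    """
    if n_taxa < 1 or n_compounds < 1:
        raise ValueError("n_taxa and n_compounds must be positive")
    if not 0.0 <= frac_significant <= 1.0:
        raise ValueError("frac_significant must be in [0, 1]")
    rng = np.random.default_rng(seed)

    ids = [BUILTIN_FORMULAS[i % len(BUILTIN_FORMULAS)] for i in range(n_compounds)]
    # disambiguate repeated formulas with a suffix so compound ids stay unique
    pool = [(f"{cid}.{i // len(BUILTIN_FORMULAS)}" if i >= len(BUILTIN_FORMULAS) else cid, formula)
            for i, (cid, formula) in enumerate(ids)]

    rows = []
    for t in range(n_taxa):
        taxon = f"Taxon_{t + 1:03d}"
        k = min(compounds_per_taxon, n_compounds)
        chosen = rng.choice(n_compounds, size=k, replace=False)
        for ci in chosen:
            cid, formula = pool[ci]
            significant = rng.random() < frac_significant
            if significant:
                rho = rng.uniform(0.05, 0.95)
                p_adj = rng.uniform(0.0, 0.0499)
            else:
                if rng.random() < 0.5:
                    rho = rng.uniform(-0.95, -0.05)
                    p_adj = rng.uniform(0.0, 1.0)
                else:
                    rho = rng.uniform(0.05, 0.95)
                    p_adj = rng.uniform(0.05, 1.0)
            if rng.random() < frac_missing_id:
                cid_out, formula_out = "", ""
            else:
                cid_out, formula_out = cid, formula
            rows.append({
                "taxon": taxon,
                "compound_id": cid_out,
                "formula": formula_out,
                "rho": rho,
                "p_adjusted": p_adj,
                "significant": significant,
            })
    if planted_taxon_compounds:
        catalogue = dict(BUILTIN_FORMULAS)
        for cid in planted_taxon_compounds:
            if cid not in catalogue:
                raise ValueError(f"unknown built-in compound id: {cid}")
            rows.append({
                "taxon": "Taxon_planted",
                "compound_id": cid,
                "formula": catalogue[cid],
                "rho": float(rng.uniform(0.3, 0.9)),
                "p_adjusted": float(rng.uniform(0.0, 0.01)),
                "significant": True,
            })
    return pd.DataFrame(rows)


def write_peak_table(table: pd.DataFrame, path) -> None:
    """Write a peak table as TSV: sample_id, replicate_id, then m/z columns."""
    out = table.reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> pd.DataFrame:
    """Read a peak table written by :func:`write_peak_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate_id": str})
    return df.set_index(["sample_id", "replicate_id"])
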