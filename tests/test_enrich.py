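"""Enrichment primitives: formula masses, adducts, EASE, matching, the
essential-amino-acid exclusion and the microbe DB builder."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from metabosig import enrich, rank, simcohort
from metabosig.enrich import (DEFAULT_ADDUCTS, AdductRule, MetaboliteSetDB,
                              adduct_mz, build_microbe_db, ease_test,
                              formula_mass, match_signature, neutral_candidates,
                              run_enrichment, split_by_sign)

PROTON = 1.007276466


class TestFormulaMass:
    @pytest.mark.parametrize("formula,expected", [
        ("H2O", 18.010565),
        ("C6H12O6", 180.063388),
        ("C3H7NO2", 89.047678),      # alanine
        ("C24H40O4", 392.292660),    # UDCA-type bile acid
        ("C7H7ClN2O2S", 217.991676),
    ])
    def test_monoisotopic_values(self, formula, expected):
        assert formula_mass(formula) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("bad", ["", "X5", "h2o", "C6H12O6)", "12C", None])
    def test_malformed_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            formula_mass(bad)


class TestAdducts:
    def test_default_rule_count_and_modes(self):
        assert len(DEFAULT_ADDUCTS) == 19
        assert {r.mode for r in DEFAULT_ADDUCTS} == {"positive", "negative"}

    @pytest.mark.parametrize("name,expected", [
        ("[M+H]+", 101.007276),
        ("[M-H]-", 98.992724),
        ("[2M+H]+", 201.007276),
        ("[M+2H]2+", 51.007276),
        ("[M+Na]+", 122.989221),
    ])
    def test_proton_bookkeeping_at_mass_100(self, name, expected):
        rule = next(r for r in DEFAULT_ADDUCTS if r.name == name)
        assert adduct_mz(100.0, rule) == pytest.approx(expected, abs=1e-5)

    def test_round_trip_all_rules(self):
        rng = np.random.default_rng(0)
        masses = rng.uniform(50, 1500, 100)
        for rule in DEFAULT_ADDUCTS:
            for m in masses:
                cands = dict((r.name, v) for r, v in
                             neutral_candidates(adduct_mz(m, rule), DEFAULT_ADDUCTS))
                assert abs(cands[rule.name] - m) / m < 1e-9

    def test_invalid_rules_and_masses(self):
        with pytest.raises(ValueError):
            AdductRule("bad", 1.0, 0)
        with pytest.raises(ValueError):
            adduct_mz(-5.0, DEFAULT_ADDUCTS[0])
        with pytest.raises(ValueError):
            neutral_candidates(-1.0, DEFAULT_ADDUCTS)


def exact_hypergeom_tail(j, N, m, n):
    """P(X >= j) for hypergeometric(N, m, n) by exact enumeration."""
    total = Fraction(0)
    for x in range(max(j, 0), min(m, n) + 1):
        total += Fraction(math.comb(m, x) * math.comb(N - m, n - x), math.comb(N, n))
    return float(min(total, Fraction(1)))


class TestEase:
    def test_small_overlaps_give_one(self):
        assert ease_test(0, 10, 20, 100) == 1.0
        assert ease_test(1, 10, 20, 100) == 1.0

    def test_matches_enumeration_oracle(self):
        assert ease_test(5, 10, 100, 1000) == pytest.approx(
            exact_hypergeom_tail(4, 1000, 10, 100), abs=1e-12)

    def test_exhaustive_grid_small_universe(self):
        for N in (5, 9, 14):
            for m in range(0, N + 1, 2):
                for n in range(0, N + 1, 3):
                    for k in range(0, min(m, n) + 1):
                        assert ease_test(k, m, n, N) == pytest.approx(
                            exact_hypergeom_tail(k - 1, N, m, n), abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ease_test(5, 3, 10, 100)
        with pytest.raises(ValueError):
            ease_test(1, 10, 200, 100)


def _db(compounds, sets):
    comp = pd.DataFrame(
        [(cid, f, formula_mass(f)) for cid, f in compounds],
        columns=["compound_id", "formula", "mass"]).set_index("compound_id")
    return MetaboliteSetDB(sets=sets, compounds=comp)


class TestMatchSignature:
    def setup_method(self):
        self.db = _db([("c1", "C6H12O6"), ("c2", "C3H7NO2")],
                      {"S": ["c1", "c2"]})

    def test_exact_adduct_mz_matches(self):
        mz = adduct_mz(formula_mass("C6H12O6"), DEFAULT_ADDUCTS[0])
        matched, table = match_signature([mz], self.db)
        assert matched == {"c1"}
        assert (table["compound_id"] == "c1").all()

    def test_ppm_boundary(self):
        pred = adduct_mz(formula_mass("C6H12O6"), DEFAULT_ADDUCTS[0])
        just_out = pred * (1 + 5.5e-6)
        matched, _ = match_signature([just_out], self.db, tolerance_ppm=5.0)
        assert matched == set()
        just_in = pred * (1 + 4.5e-6)
        matched, _ = match_signature([just_in], self.db, tolerance_ppm=5.0)
        assert matched == {"c1"}

    def test_zero_tolerance_exact_only(self):
        pred = adduct_mz(formula_mass("C3H7NO2"), DEFAULT_ADDUCTS[1])
        matched, _ = match_signature([pred], self.db, tolerance_ppm=0.0)
        assert matched == {"c2"}
        matched, _ = match_signature([pred + 1e-6], self.db, tolerance_ppm=0.0)
        assert matched == set()

    def test_overlap_monotone_in_tolerance(self):
        rng = np.random.default_rng(1)
        query = rng.uniform(80, 600, 300)
        sizes = []
        for ppm in (0.5, 5, 50, 500):
            matched, _ = match_signature(query, self.db, tolerance_ppm=ppm)
            sizes.append(len(matched))
        assert sizes == sorted(sizes)

    def test_empty_rules_rejected(self):
        with pytest.raises(ValueError):
            match_signature([100.0], self.db, rules=[])


def _ranked_from(mz, v):
    n = len(mz)
    table = pd.DataFrame({
        "mz": np.asarray(mz, dtype=float),
        "p_value": np.full(n, 1e-4),
        "fold_change": np.exp2(np.sign(v)),
        "V": np.asarray(v, dtype=float),
        "wald_z": np.nan,
    })
    order = np.argsort(-np.abs(table["V"].to_numpy()), kind="mergesort")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    table["rank"] = ranks
    return rank.RankedFeatures(table=table, rank_by="abs_V", flagged=[])


class TestRunEnrichment:
    def _planted_setup(self, seed=0, n_null_sets=10):
        rng = np.random.default_rng(seed)
        compounds = list(simcohort.BUILTIN_FORMULAS[:60])
        planted_ids = [cid for cid, _ in compounds[:8]]
        null_pool = [cid for cid, _ in compounds[8:]]
        sets = {"Planted": planted_ids}
        for i in range(n_null_sets):
            sets[f"Null_{i}"] = list(rng.choice(null_pool, size=8, replace=False))
        db = _db(compounds, sets)
        # signature: the planted compounds' [M+H]+ m/z; universe adds all others
        sig_mz = [adduct_mz(db.compounds.loc[c, "mass"], DEFAULT_ADDUCTS[0])
                  for c in planted_ids]
        other_mz = [adduct_mz(db.compounds.loc[c, "mass"], DEFAULT_ADDUCTS[0])
                    for c in null_pool]
        all_mz = np.array(sig_mz + other_mz)
        v = np.concatenate([np.full(len(sig_mz), 9.0),
                            rng.uniform(-0.5, 0.5, len(other_mz))])
        return _ranked_from(all_mz, v), db

    def test_planted_set_flagged_nulls_not(self):
        ranked, db = self._planted_setup()
        res = run_enrichment(ranked, 8, db)
        assert "Planted" in res.significant_sets()
        null_flags = res.table[res.table["set"] != "Planted"]["significant"]
        assert null_flags.mean() <= 0.1

    def test_empty_signature_all_p_one(self):
        ranked, db = self._planted_setup()
        res = run_enrichment(ranked, 0, db)
        assert (res.table["ease_p"] == 1.0).all()

    def test_oversized_signature_clipped(self):
        ranked, db = self._planted_setup()
        with pytest.warns(UserWarning, match="clip"):
            run_enrichment(ranked, 10_000, db)

    def test_essential_aa_biosynthesis_excluded(self):
        ranked, db = self._planted_setup()
        db.sets["Lysine biosynthesis"] = db.sets["Planted"][:4]
        db.sets["Lysine degradation"] = db.sets["Planted"][:4]
        db.sets["Valine, leucine and isoleucine biosynthesis"] = db.sets["Planted"][:4]
        db.sets["De novo fatty acid biosynthesis"] = db.sets["Planted"][:4]
        res = run_enrichment(ranked, 8, db)
        names = set(res.table["set"])
        assert "Lysine biosynthesis" not in names
        assert "Valine, leucine and isoleucine biosynthesis" not in names
        assert "Lysine degradation" in names
        assert "De novo fatty acid biosynthesis" in names


class TestSplitBySign:
    def test_partition_and_directions(self):
        mz = [100.0, 200.0, 300.0, 400.0, 500.0]
        v = [5.0, -4.0, 3.0, 0.0, -1.0]
        ranked = _ranked_from(mz, v)
        pos, neg, zeros = split_by_sign(ranked, 5)
        assert set(pos) == {100.0, 300.0}
        assert set(neg) == {200.0, 500.0}
        assert zeros == 1
        assert len(pos) + len(neg) + zeros == 5

    def test_all_positive(self):
        ranked = _ranked_from([10.0, 20.0], [1.0, 2.0])
        pos, neg, zeros = split_by_sign(ranked, 2)
        assert neg == [] and zeros == 0 and len(pos) == 2


class TestBuildMicrobeDb:
    def test_filters_applied_strictly(self):
        assoc = pd.DataFrame({
            "taxon": ["T1"] * 5,
            "compound_id": ["a", "b", "c", "d", ""],
            "formula": ["C6H12O6", "H2O", "C2H4O2", "C3H6O3", "C5H5N5"],
            "rho": [0.4, -0.3, 0.4, 0.2, 0.9],
            "p_adjusted": [0.04, 0.001, 0.05, 0.01, 0.001],
        })
        db = build_microbe_db(assoc)
        # b: negative rho; c: p == 0.05 not < 0.05; missing id dropped
        assert db.sets == {"T1": ["a", "d"]}
        assert db.compounds.loc["a", "mass"] == pytest.approx(180.063388, abs=1e-5)

    def test_empty_sets_dropped_and_missing_columns(self):
        assoc = pd.DataFrame({
            "taxon": ["T1", "T2"],
            "compound_id": ["a", "b"],
            "formula": ["H2O", "H2O"],
            "rho": [-0.5, 0.5],
            "p_adjusted": [0.01, 0.01],
        })
        db = build_microbe_db(assoc)
        assert list(db.sets) == ["T2"]
        with pytest.raises(ValueError, match="lacks columns"):
            build_microbe_db(assoc.drop(columns=["rho"]))

    def test_recovery_from_generator(self):
        assoc = simcohort.generate_association_table(15, 60, 0.5, seed=12)
        db = build_microbe_db(assoc)
        expected = assoc[assoc["significant"]].groupby("taxon")["compound_id"].nunique()
        for taxon, n in expected.items():
            assert len(db.sets[taxon]) == n

    def test_roundtrip_serialisation(self, tmp_path):
        assoc = simcohort.generate_association_table(5, 30, 0.7, seed=13)
        db = build_microbe_db(assoc)
        db.write(tmp_path / "db.gmt", tmp_path / "db.csv")
        back = MetaboliteSetDB.read(tmp_path / "db.gmt", tmp_path / "db.csv")
        assert back.sets == db.sets
        pd.testing.assert_frame_equal(back.compounds, db.compounds)
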