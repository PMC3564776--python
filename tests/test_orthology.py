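import itertools

import numpy as np
import pytest

from thermocomp.errors import ParameterError, UntrimmableAlignmentError
from thermocomp.io_formats import HitRecord
from thermocomp.orthology import (
    best_hits,
    build_ortholog_sets,
    mutual_best_pairs,
    trim_alignment,
)


def hit(q, s, qsp, ssp, bitscore, evalue=1e-10):
    return HitRecord(
        query_id=q,
        subject_id=s,
        query_species=qsp,
        subject_species=ssp,
        bitscore=bitscore,
        evalue=evalue,
    )


class TestBestHits:
    def test_max_bitscore_wins(self):
        best = best_hits(
            [hit("q1", "s1", "A", "B", 200), hit("q1", "s2", "A", "B", 150)]
        )
        assert best[("q1", "B")] == "s1"

    def test_evalue_breaks_bitscore_tie(self):
        best = best_hits(
            [
                hit("q1", "s2", "A", "B", 200, evalue=1e-40),
                hit("q1", "s1", "A", "B", 200, evalue=1e-50),
            ]
        )
        assert best[("q1", "B")] == "s1"

    def test_lexicographic_final_tie_break(self):
        best = best_hits(
            [
                hit("q1", "s2", "A", "B", 200, evalue=1e-50),
                hit("q1", "s1", "A", "B", 200, evalue=1e-50),
            ]
        )
        assert best[("q1", "B")] == "s1"

    def test_same_species_hits_ignored(self):
        assert best_hits([hit("q1", "q2", "A", "A", 500)]) == {}


def brute_force_sets(best, species, id_to_species):
    """Independent oracle: enumerate every one-per-species tuple and keep
    those where all directed best hits stay inside the tuple."""
    per_species = {
        sp: sorted(pid for pid, s in id_to_species.items() if s == sp)
        for sp in species
    }
    found = []
    for combo in itertools.product(*(per_species[sp] for sp in species)):
        members = dict(zip(species, combo))
        ok = all(
            best.get((members[a], b)) == members[b]
            for a in species
            for b in species
            if a != b
        )
        if ok:
            found.append(members)
    return found


class TestBuildOrthologSets:
    def make_ids(self, species, n):
        ids = {}
        for sp in species:
            for i in range(n):
                ids[f"{sp}{i}"] = sp
        return ids

    def perfect_clique_best(self, species, n):
        best = {}
        for a in species:
            for b in species:
                if a != b:
                    for i in range(n):
                        best[(f"{a}{i}", b)] = f"{b}{i}"
        return best

    def test_perfect_clique_three_species(self):
        species = ["A", "B", "C"]
        best = self.perfect_clique_best(species, 1)
        sets = build_ortholog_sets(best, species, self.make_ids(species, 1))
        assert len(sets) == 1
        assert sets[0].members == {"A": "A0", "B": "B0", "C": "C0"}

    def test_one_broken_direction_kills_the_set(self):
        species = ["A", "B", "C"]
        best = self.perfect_clique_best(species, 2)
        best[("C0", "A")] = "A1"  # C0's best in A points elsewhere
        sets = build_ortholog_sets(best, species, self.make_ids(species, 2))
        assert all(s.members["C"] != "C0" for s in sets)
        assert len(sets) == 1

    def test_two_reciprocal_pairs(self):
        species = ["A", "B"]
        best = {
            ("A0", "B"): "B0",
            ("B0", "A"): "A0",
            ("A1", "B"): "B1",
            ("B1", "A"): "A1",
        }
        ids = self.make_ids(species, 2)
        sets = build_ortholog_sets(best, species, ids)
        assert len(sets) == 2
        assert sets == sorted(sets, key=lambda s: s.members["A"])

    def test_reciprocity_invariant_on_emitted_sets(self):
        species = ["A", "B", "C"]
        best = self.perfect_clique_best(species, 3)
        sets = build_ortholog_sets(best, species, self.make_ids(species, 3))
        for s in sets:
            for a in species:
                for b in species:
                    if a != b:
                        assert best[(s.members[a], b)] == s.members[b]

    def test_duplicate_species_rejected(self):
        with pytest.raises(ParameterError):
            build_ortholog_sets({}, ["A", "A"], {})

    @pytest.mark.parametrize("n_species,n_proteins,seed", [
        (2, 4, 0), (3, 5, 1), (3, 6, 2), (4, 4, 3), (4, 6, 4), (2, 6, 5),
    ])
    def test_matches_brute_force_enumeration(self, n_species, n_proteins, seed):
        rng = np.random.default_rng(seed)
        species = [chr(ord("A") + i) for i in range(n_species)]
        id_to_species = self.make_ids(species, n_proteins)
        best = {}
        for pid, sp in id_to_species.items():
            for target in species:
                if target == sp:
                    continue
                if rng.random() < 0.9:  # some queries have no hit
                    best[(pid, target)] = f"{target}{rng.integers(n_proteins)}"
        expected = brute_force_sets(best, species, id_to_species)
        got = build_ortholog_sets(best, species, id_to_species)
        assert len(got) == len(expected)
        assert [s.members for s in got] == sorted(
            expected, key=lambda m: m[species[0]]
        )


class TestMutualBestPairs:
    def test_only_reciprocal_pairs_kept(self):
        best = {
            ("A0", "B"): "B0",
            ("B0", "A"): "A0",  # reciprocal
            ("A1", "B"): "B1",
            ("B1", "A"): "A0",  # one-sided
        }
        ids = {"A0": "A", "A1": "A", "B0": "B", "B1": "B"}
        assert mutual_best_pairs(best, ids) == {frozenset(("A0", "B0"))}


class TestTrimAlignment:
    def test_hand_trace(self):
        span, frags = trim_alignment({"a": "--KDE-R", "b": "MAKDEFR"})
        assert span == (3, 7)
        assert frags == {"a": "KDER", "b": "KDEFR"}

    def test_gap_free_alignment_is_identity(self):
        rows = {"a": "MKR", "b": "MKV"}
        span, frags = trim_alignment(rows)
        assert span == (1, 3)
        assert frags == rows

    def test_no_gap_free_column_is_error(self):
        with pytest.raises(UntrimmableAlignmentError):
            trim_alignment({"a": "-A-", "b": "A-A"})

    def test_anchor_columns_gap_free_and_idempotent(self, rng):
        for _ in range(20):
            width = int(rng.integers(5, 25))
            rows = {}
            for rid in ("a", "b", "c"):
                chars = [
                    "-" if rng.random() < 0.25 else "ACDEF"[int(rng.integers(5))]
                    for _ in range(width)
                ]
                rows[rid] = "".join(chars)
            try:
                (first, last), _ = trim_alignment(rows)
            except UntrimmableAlignmentError:
                continue
            for row in rows.values():
                assert row[first - 1] != "-" and row[last - 1] != "-"
            retrimmed = {rid: row[first - 1 : last] for rid, row in rows.items()}
            (f2, l2), _ = trim_alignment(retrimmed)
            assert (f2, l2) == (1, last - first + 1)
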