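import numpy as np
import pytest
from Bio.Seq import Seq

from thermocomp.errors import ParameterError, ValidationError
from thermocomp.io_formats import ProteinRecord
from thermocomp.measures import cvp_bias, gc_by_codon_position
from thermocomp.orthology import best_hits, build_ortholog_sets
from thermocomp.survey import roc_auc
from thermocomp.synthetic_data import (
    BASE_RESIDUE_FREQS,
    SpeciesProfile,
    gen_coding_sequences,
    gen_melt_curve,
    gen_ortholog_sets,
    gen_pair_dataset,
    make_profiles,
)


class TestSpeciesProfile:
    def test_probs_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            SpeciesProfile(species="x", residue_probs=np.full(20, 0.06))

    def test_shift_bounds(self):
        with pytest.raises(ParameterError):
            SpeciesProfile(species="x", thermo_shift=0.3)

    def test_shifted_profile_remains_probability_vector(self):
        p = SpeciesProfile(species="x", thermo_shift=0.1).shifted_probs()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 0).all()

    def test_shift_moves_mass_polar_to_charged(self):
        prof = SpeciesProfile(species="x", thermo_shift=0.05)
        base, shifted = BASE_RESIDUE_FREQS, prof.shifted_probs()
        idx = {aa: i for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        charged = sum(shifted[idx[a]] - base[idx[a]] for a in "EDKR")
        polar = sum(shifted[idx[a]] - base[idx[a]] for a in "STNQ")
        assert charged == pytest.approx(0.05, abs=1e-12)
        assert polar == pytest.approx(-0.05, abs=1e-12)


class TestMakeProfiles:
    def test_gc_coupling_tilts_garp_but_preserves_cvp(self):
        profiles = make_profiles(
            ["low", "high"],
            gc3_targets={"low": 0.2, "high": 0.8},
            jitter=0.0,
            gc_coupling=0.5,
        )
        idx = {aa: i for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        low, high = (p.residue_probs for p in profiles)
        garp = lambda p: sum(p[idx[a]] for a in "GARP")
        fymink = lambda p: sum(p[idx[a]] for a in "FYMINK")
        cvp_mass = lambda p: sum(p[idx[a]] for a in "EDKR") - sum(
            p[idx[a]] for a in "STNQ"
        )
        assert garp(high) > garp(low)
        assert fymink(high) < fymink(low)
        assert cvp_mass(high) == pytest.approx(cvp_mass(low), abs=1e-12)
        for p in (low, high):
            assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestGenOrthologSets:
    def test_seed_determinism(self):
        profiles = make_profiles(["A", "B"], seed=3)
        d1 = gen_ortholog_sets(profiles, n_sets=5, seed=7)
        d2 = gen_ortholog_sets(profiles, n_sets=5, seed=7)
        assert [r.residues for r in d1.proteomes["A"]] == [
            r.residues for r in d2.proteomes["A"]
        ]
        assert d1.hits == d2.hits

    def test_planted_sets_recovered_without_indels(self):
        profiles = make_profiles(["A", "B", "C"], thermo_shifts={"A": 0.05}, seed=1)
        data = gen_ortholog_sets(profiles, n_sets=10, indel_rate=0.0, seed=2)
        sets = build_ortholog_sets(
            best_hits(data.hits), ["A", "B", "C"], data.id_to_species
        )
        assert len(sets) == 10
        recovered = {frozenset(s.members.values()) for s in sets}
        planted = {frozenset(ids) for ids in data.set_ids}
        assert recovered == planted

    def test_alignments_consistent_with_sequences(self):
        profiles = make_profiles(["A", "B"], seed=5)
        data = gen_ortholog_sets(profiles, n_sets=3, indel_rate=0.1, seed=6)
        for i, aln in enumerate(data.alignments):
            widths = {len(row) for row in aln.values()}
            assert len(widths) == 1
            for sp, row in aln.items():
                assert row.replace("-", "") == data.proteomes[sp][i].residues

    def test_symmetric_profiles_give_equal_expected_cvp(self):
        profiles = make_profiles(["A", "B", "C"], jitter=0.0, seed=0)
        data = gen_ortholog_sets(profiles, n_sets=200, seed=4)
        means = {
            sp: np.mean([cvp_bias(r.residues) for r in recs])
            for sp, recs in data.proteomes.items()
        }
        spread = max(means.values()) - min(means.values())
        assert spread == pytest.approx(0.0, abs=1e-9)  # identical profiles couple exactly

    def test_planted_shift_raises_mean_cvp_by_200_delta(self):
        delta = 0.1
        profiles = make_profiles(
            ["hot", "cold"], thermo_shifts={"hot": delta}, jitter=0.0, seed=0
        )
        data = gen_ortholog_sets(profiles, n_sets=200, seed=8)
        hot = np.mean([cvp_bias(r.residues) for r in data.proteomes["hot"]])
        cold = np.mean([cvp_bias(r.residues) for r in data.proteomes["cold"]])
        assert hot - cold == pytest.approx(200 * delta, abs=1.0)

    def test_parameter_validation(self):
        profiles = make_profiles(["A", "B"])
        with pytest.raises(ParameterError):
            gen_ortholog_sets(profiles, n_sets=0)
        with pytest.raises(ParameterError):
            gen_ortholog_sets(profiles[:1], n_sets=5)


class TestGenPairDataset:
    @staticmethod
    def auc(pairs):
        scores = [(cvp_bias(t.residues), "thermophile") for t, _ in pairs]
        scores += [(cvp_bias(m.residues), "mesophile") for _, m in pairs]
        return roc_auc(scores).auc

    def test_null_case_auc_near_half(self):
        assert self.auc(gen_pair_dataset(500, 0.0, seed=1)) == pytest.approx(0.5, abs=0.05)

    def test_strong_shift_auc_high(self):
        assert self.auc(gen_pair_dataset(500, 0.08, seed=1)) > 0.95

    def test_auc_monotone_in_shift(self):
        aucs = [
            self.auc(gen_pair_dataset(300, d, seed=2))
            for d in (0.0, 0.02, 0.04, 0.06, 0.08, 0.1)
        ]
        assert aucs == sorted(aucs)

    def test_invalid_n_pairs(self):
        with pytest.raises(ParameterError):
            gen_pair_dataset(0, 0.05)


class TestGenCodingSequences:
    @pytest.fixture
    def records(self):
        rng = np.random.default_rng(0)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        return [
            ProteinRecord(
                id=f"p{i}", species="sp", residues="".join(rng.choice(alphabet, 200))
            )
            for i in range(5)
        ]

    def test_round_trip_translation(self, records):
        for rec in gen_coding_sequences(records, gc3_target=0.5, seed=1):
            assert str(Seq(rec.coding_seq).translate()) == rec.residues

    def test_gc3_limit_high(self, records):
        # every residue has at least one G/C-ending codon, so the limit is exact
        coded = gen_coding_sequences(records, gc3_target=1.0, seed=1)
        for rec in coded:
            assert gc_by_codon_position(rec.coding_seq).gc3 == 100.0

    def test_gc3_midpoint_within_band(self, records):
        coded = gen_coding_sequences(records, gc3_target=0.5, seed=1)
        gc3 = np.mean([gc_by_codon_position(r.coding_seq).gc3 for r in coded])
        # the achievable midpoint is pulled up slightly by M (ATG) and W (TGG)
        assert abs(gc3 - 50.0) < 5.0

    def test_unknown_residue_rejected(self):
        rec = ProteinRecord(id="p", species="s", residues="MKX")
        with pytest.raises(ValidationError):
            gen_coding_sequences([rec], gc3_target=0.5)

    def test_determinism(self, records):
        a = gen_coding_sequences(records, gc3_target=0.4, seed=9)
        b = gen_coding_sequences(records, gc3_target=0.4, seed=9)
        assert [r.coding_seq for r in a] == [r.coding_seq for r in b]


class TestGenMeltCurve:
    def test_grid_shape(self):
        curve = gen_melt_curve(45.0)
        assert len(curve) == 301
        assert curve.temperatures[0] == 20.0
        assert curve.temperatures[-1] == pytest.approx(80.0)

    def test_same_seed_identical(self):
        a = gen_melt_curve(45.0, noise_sd=2.0, seed=5)
        b = gen_melt_curve(45.0, noise_sd=2.0, seed=5)
        np.testing.assert_array_equal(a.fluorescence, b.fluorescence)

    def test_tm_outside_grid_rejected(self):
        with pytest.raises(ParameterError):
            gen_melt_curve(85.0)
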