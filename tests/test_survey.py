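import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from thermocomp.errors import UndefinedRocError
from thermocomp.io_formats import ProteinRecord
from thermocomp.measures import evaluate_measures
from thermocomp.survey import (
    cumulative_ranks,
    paired_concordance,
    rank_set,
    roc_auc,
    trapezoid_area,
)


class TestRankSet:
    def test_direction_positive(self):
        assert rank_set({"A": 10, "B": 5, "C": 1}, +1) == {"A": 1, "B": 2, "C": 3}

    def test_average_rank_ties(self):
        assert rank_set({"A": 5, "B": 5, "C": 1}, +1) == {"A": 1.5, "B": 1.5, "C": 3}

    def test_direction_flip(self):
        assert rank_set({"A": 10, "B": 5, "C": 1}, -1) == {"A": 3, "B": 2, "C": 1}

    def test_missing_value_skips_set(self):
        assert rank_set({"A": 1.0, "B": None, "C": 2.0}, +1) is None
        assert rank_set({"A": 1.0, "B": float("nan"), "C": 2.0}, +1) is None

    def test_all_missing_is_skip_not_error(self):
        assert rank_set({"A": None, "B": None}, +1) is None

    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=10, unique=True)
    )
    def test_rank_sum_conservation(self, values):
        species = [f"s{i}" for i in range(len(values))]
        ranks = rank_set(dict(zip(species, values)), +1)
        n = len(values)
        assert sum(ranks.values()) == pytest.approx(n * (n + 1) / 2)


def make_set_table(values_by_species):
    records = [
        ProteinRecord(id=f"{sp}_p", species=sp, residues=seq)
        for sp, seq in values_by_species.items()
    ]
    return evaluate_measures(records)


class TestCumulativeRanks:
    def test_identical_ordering_across_sets(self):
        # species A has the highest CvP in both sets
        tables = [
            make_set_table({"A": "EDKREDKR", "B": "EDKRSTNQ", "C": "STNQSTNQ"}),
            make_set_table({"A": "EDKREDKR", "B": "EDKRSTNQ", "C": "STNQSTNQ"}),
        ]
        summaries = {s.measure_name: s for s in cumulative_ranks(tables)}
        cvp = summaries["cvp_bias"]
        assert cvp.n_sets_used == 2
        assert cvp.cumulative_rank["A"] == 2.0  # rank 1 in each of 2 sets

    def test_rank_sum_conservation_over_sets(self, rng):
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        tables = []
        for _ in range(10):
            values = {
                sp: "".join(rng.choice(alphabet, size=30)) for sp in "ABCDE"
            }
            tables.append(make_set_table(values))
        for summ in cumulative_ranks(tables):
            if summ.n_sets_used == 0:
                continue
            total = sum(summ.cumulative_rank.values())
            expected = summ.n_sets_used * 5 * 6 / 2
            assert total == pytest.approx(expected)

    def test_sets_missing_a_value_excluded_for_that_measure(self):
        # EEKK makes (E+K)/(Q+H) undefined -> the set is skipped for that
        # measure but still counted for the others
        tables = [
            make_set_table({"A": "EEKK", "B": "EKQH", "C": "EKKQ"}),
            make_set_table({"A": "EKQH", "B": "EKQH", "C": "EKKQ"}),
        ]
        summaries = {s.measure_name: s for s in cumulative_ranks(tables)}
        assert summaries["ek_qh_ratio"].n_sets_used == 1
        assert summaries["cvp_bias"].n_sets_used == 2


def brute_force_auc(pos, neg):
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [(2, "t"), (3, "t"), (0, "m"), (1, "m")]
        assert roc_auc(scores, positive="t").auc == 1.0

    def test_all_ties(self):
        scores = [(1, "t"), (1, "t"), (1, "m")]
        assert roc_auc(scores, positive="t").auc == 0.5

    def test_pair_counting_hand_case(self):
        scores = [(3, "t"), (1, "t"), (2, "m"), (0, "m")]
        assert roc_auc(scores, positive="t").auc == 0.75

    def test_single_class_is_error(self):
        with pytest.raises(UndefinedRocError):
            roc_auc([(1, "t"), (2, "t")], positive="t")

    def test_curve_endpoints_and_monotonicity(self):
        scores = [(3, "t"), (1, "t"), (2, "m"), (0, "m"), (2, "t")]
        result = roc_auc(scores, positive="t")
        assert result.roc_points[0] == (0.0, 0.0)
        assert result.roc_points[-1] == (1.0, 1.0)
        xs, ys = zip(*result.roc_points)
        assert all(a <= b for a, b in zip(xs, xs[1:]))
        assert all(a <= b for a, b in zip(ys, ys[1:]))

    @given(
        st.lists(
            st.tuples(st.integers(-3, 3), st.sampled_from(["t", "m"])),
            min_size=2,
            max_size=8,
        )
    )
    def test_equals_brute_force_pair_counting(self, scores):
        labels = {lab for _, lab in scores}
        if labels != {"t", "m"}:
            return
        result = roc_auc(scores, positive="t")
        pos = [v for v, lab in scores if lab == "t"]
        neg = [v for v, lab in scores if lab == "m"]
        assert result.auc == pytest.approx(brute_force_auc(pos, neg))
        # and the trapezoidal area under the returned curve agrees
        assert trapezoid_area(result.roc_points) == pytest.approx(result.auc)

    @given(
        st.lists(
            st.tuples(
                st.integers(-50, 50).map(lambda v: v / 10),
                st.sampled_from(["t", "m"]),
            ),
            min_size=4,
            max_size=20,
        )
    )
    def test_label_swap_symmetry_and_monotone_invariance(self, scores):
        labels = {lab for _, lab in scores}
        if labels != {"t", "m"}:
            return
        auc = roc_auc(scores, positive="t").auc
        swapped = roc_auc(scores, positive="m").auc
        assert auc + swapped == pytest.approx(1.0)
        transformed = [(np.exp(v / 2) + v, lab) for v, lab in scores]
        assert roc_auc(transformed, positive="t").auc == pytest.approx(auc)

    def test_agrees_with_reference_implementation(self, rng):
        values = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = [
            (float(v), "t" if lab else "m") for v, lab in zip(values, labels)
        ]
        expected = roc_auc_score(labels, values)
        assert roc_auc(scores, positive="t").auc == pytest.approx(expected)

    def test_direction_flip(self):
        scores = [(0, "t"), (1, "t"), (2, "m"), (3, "m")]
        assert roc_auc(scores, positive="t", direction=-1).auc == 1.0


class TestPairedConcordance:
    def test_all_concordant(self):
        assert paired_concordance([(2, 1), (3, 0)]) == 1.0

    def test_tie_counts_half(self):
        assert paired_concordance([(1, 1)]) == 0.5

    def test_mixed(self):
        assert paired_concordance([(2, 1), (0, 3)]) == 0.5

    def test_direction_oriented(self):
        assert paired_concordance([(1, 2)], direction=-1) == 1.0

    def test_empty_is_error(self):
        with pytest.raises(UndefinedRocError):
            paired_concordance([])
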