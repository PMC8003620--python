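"""Swallowability index, rank bands, matrix assembly and ordering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swallowmetrics.study_tables import (
    SI_COMPLEXITY_ORDER,
    SI_MATRIX,
    SI_PERFORMANCE_ORDER,
)
from swallowmetrics.swallowability import (
    Rank,
    SwallowabilityRecord,
    build_matrix,
    classify_si,
    rank_formulations,
    swallowability_index,
)

positive = st.floats(min_value=1e-3, max_value=1e3)


def reference_records():
    return [
        SwallowabilityRecord(formulation_id=fid, time_s=t, si=si)
        for fid in SI_COMPLEXITY_ORDER
        for t, si in SI_MATRIX[fid].items()
    ]


class TestIndexFormula:
    def test_no_swelling_forces_zero_index(self):
        assert swallowability_index(0.0, 90.0, 2.0, 0.3, 1.5) == 0.0

    def test_hand_evaluated_value(self):
        assert swallowability_index(1.0, 100.0, 1.0, 0.1, 1.0) == pytest.approx(10.0)

    def test_homogeneity_in_each_factor(self):
        base = swallowability_index(0.5, 80.0, 2.0, 0.3, 1.5)
        assert swallowability_index(1.0, 80.0, 2.0, 0.3, 1.5) == pytest.approx(2 * base)
        assert swallowability_index(0.5, 160.0, 2.0, 0.3, 1.5) == pytest.approx(base / 2)
        assert swallowability_index(0.5, 80.0, 4.0, 0.3, 1.5) == pytest.approx(base / 2)
        assert swallowability_index(0.5, 80.0, 2.0, 0.6, 1.5) == pytest.approx(base / 2)
        assert swallowability_index(0.5, 80.0, 2.0, 0.3, 3.0) == pytest.approx(base / 2)

    @pytest.mark.parametrize("factor", ["CA", "Wa", "F", "CoF"])
    def test_non_positive_denominator_factor_rejected(self, factor):
        kwargs = dict(GL=1.0, CA=90.0, Wa=2.0, F=0.3, CoF=1.5)
        kwargs[factor] = 0.0
        with pytest.raises(ValueError):
            swallowability_index(**kwargs)

    def test_negative_gel_layer_change_rejected(self):
        with pytest.raises(ValueError):
            swallowability_index(-0.1, 90.0, 2.0, 0.3, 1.5)

    @given(GL=positive, CA=positive, Wa=positive, F=positive, CoF=positive)
    @settings(max_examples=80, derandomize=True)
    def test_monotone_in_every_factor(self, GL, CA, Wa, F, CoF):
        si = swallowability_index(GL, CA, Wa, F, CoF)
        assert swallowability_index(GL * 1.1, CA, Wa, F, CoF) > si
        assert swallowability_index(GL, CA * 1.1, Wa, F, CoF) < si
        assert swallowability_index(GL, CA, Wa * 1.1, F, CoF) < si
        assert swallowability_index(GL, CA, Wa, F * 1.1, CoF) < si
        assert swallowability_index(GL, CA, Wa, F, CoF * 1.1) < si


class TestRankBands:
    @pytest.mark.parametrize(
        "si, rank",
        [
            (0.0, Rank.POOR),
            (0.5, Rank.PASS),
            (1.0, Rank.GOOD),  # half-open band convention
            (1.86, Rank.GOOD),
            (2.0, Rank.VERY_GOOD),
            (3.99, Rank.VERY_GOOD),
            (4.0, Rank.EXCELLENT),
            (7.99, Rank.EXCELLENT),
        ],
    )
    def test_band_assignment(self, si, rank):
        assert classify_si(si) is rank

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            classify_si(-0.01)

    @given(a=st.floats(0, 20), b=st.floats(0, 20))
    @settings(max_examples=80, derandomize=True)
    def test_total_and_monotone_over_nonnegative_indices(self, a, b):
        ra, rb = classify_si(a), classify_si(b)
        assert isinstance(ra, Rank)
        if a <= b:
            assert ra <= rb

    def test_every_reference_cell_gets_exactly_one_band(self):
        ranks = [classify_si(si) for fid in SI_MATRIX for si in SI_MATRIX[fid].values()]
        assert len(ranks) == 55
        assert set(classify_si(si) for si in SI_MATRIX["Unc"].values()) == {Rank.POOR}
        assert classify_si(SI_MATRIX["OEZ"][20]) is Rank.EXCELLENT
        assert classify_si(SI_MATRIX["HPMC"][20]) is Rank.GOOD


class TestMatrix:
    def test_reference_matrix_round_trips_bit_identically(self):
        matrix = build_matrix(reference_records())
        again = type(matrix).from_csv(matrix.to_csv())
        assert matrix.values.equals(again.values)
        assert (matrix.ranks.values == again.ranks.values).all()

    def test_duplicate_cells_rejected(self):
        rec = SwallowabilityRecord(formulation_id="A", time_s=4, si=1.0)
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix([rec, SwallowabilityRecord(formulation_id="A", time_s=4, si=2.0)])

    def test_empty_and_singleton_matrices(self):
        assert build_matrix([]).values.empty
        single = build_matrix([SwallowabilityRecord(formulation_id="A", time_s=4, si=1.5)])
        assert single.values.shape == (1, 1)
        assert single.ranks.iloc[0, 0] is Rank.GOOD

    def test_missing_cells_flagged(self):
        recs = [
            SwallowabilityRecord(formulation_id="A", time_s=4, si=1.0),
            SwallowabilityRecord(formulation_id="A", time_s=8),  # no factors -> missing
        ]
        matrix = build_matrix(recs)
        assert matrix.missing_cells() == [("A", 8.0)]

    def test_html_rendering_carries_band_colors(self):
        html = build_matrix(reference_records()).to_html()
        for color in ("red", "orange", "yellow", "limegreen", "darkgreen"):
            assert color in html


class TestRecordAssembly:
    def test_record_computes_index_and_rank_from_factors(self):
        rec = SwallowabilityRecord(
            formulation_id="X", time_s=20, GL=1.0, CA=100.0, Wa=1.0, F=0.1, CoF=1.0
        )
        assert rec.si == pytest.approx(10.0)
        assert rec.rank is Rank.EXCELLENT

    def test_zero_swelling_short_circuits_missing_factors(self):
        rec = SwallowabilityRecord(formulation_id="Unc", time_s=4, GL=0.0)
        assert rec.si == 0.0
        assert rec.rank is Rank.POOR

    def test_missing_factor_leaves_index_unset(self):
        rec = SwallowabilityRecord(formulation_id="X", time_s=4, GL=1.0, CA=90.0)
        assert rec.si is None


class TestOrdering:
    def test_twenty_second_column_orders_commercial_coats(self):
        matrix = build_matrix(reference_records())
        order = rank_formulations(matrix, time_s=20)
        assert order[:4] == ["Unc", "PVA", "KIR", "HPMC"]

    def test_overall_mean_ordering_reproduces_performance_ranking(self):
        matrix = build_matrix(reference_records())
        assert rank_formulations(matrix) == list(SI_PERFORMANCE_ORDER)

    def test_ties_break_alphabetically(self):
        recs = [
            SwallowabilityRecord(formulation_id=f, time_s=4, si=1.0) for f in "CAB"
        ]
        assert rank_formulations(build_matrix(recs), time_s=4) == ["A", "B", "C"]

    def test_unknown_column_rejected(self):
        matrix = build_matrix(reference_records())
        with pytest.raises(KeyError):
            rank_formulations(matrix, time_s=99)

    def test_single_row_orders_to_itself(self):
        matrix = build_matrix([SwallowabilityRecord(formulation_id="A", time_s=4, si=1.0)])
        assert rank_formulations(matrix, time_s=4) == ["A"]
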