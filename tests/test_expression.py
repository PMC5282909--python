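import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyfam import expression_analysis as ea
from polyfam.models import (
    ExpressionMatrix,
    FamilyAssignment,
    HomoeologPair,
    StressCall,
    ValidationError,
)

TISSUES = ["root", "stem", "leaf", "ovule_0dpa", "fiber_10dpa"]


def matrix(rows):
    return ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=TISSUES))


def calls_from_log2fc(log2fc, calls=None, gene="g", stress="cold"):
    times = (1, 3, 6, 12, 24)
    if calls is None:
        calls = ["up" if fc >= 1 else ("down" if fc <= -1 else "unchanged") for fc in log2fc]
    return [StressCall(gene, stress, t, c, fc) for t, c, fc in zip(times, calls, log2fc)]


class TestCallExpressed:
    @pytest.mark.parametrize("fpkm,expected", [(0.0, False), (1.0, False), (5.3, True)])
    def test_strictly_greater_than_one(self, fpkm, expected):
        assert ea.call_expressed(fpkm) is expected

    def test_negative_is_error(self):
        with pytest.raises(ValidationError):
            ea.call_expressed(-0.1)


class TestPairHomoeologs:
    def test_matching_and_unpaired(self):
        pairs, unpaired = ea.pair_homoeologs(["X1A", "X1D", "X2A"])
        assert len(pairs) == 1
        assert (pairs[0].base_id, pairs[0].a_gene, pairs[0].d_gene) == ("X1", "X1A", "X1D")
        assert unpaired == ["X2A"]

    def test_empty_input(self):
        assert ea.pair_homoeologs([]) == ([], [])

    def test_order_invariant(self):
        a = ea.pair_homoeologs(["X1D", "X1A"])[0]
        b = ea.pair_homoeologs(["X1A", "X1D"])[0]
        assert a == b

    def test_named_assignments_accepted(self):
        assigns = [
            FamilyAssignment("gene1", "DREB", name="GhDREB5A"),
            FamilyAssignment("gene2", "DREB", name="GhDREB5D"),
        ]
        (pair,), _ = ea.pair_homoeologs(assigns)
        assert (pair.a_gene, pair.d_gene) == ("gene1", "gene2")

    def test_duplicate_subgenome_name_is_error(self):
        with pytest.raises(ValidationError):
            ea.pair_homoeologs(["X1A", "X1A"])


class TestClassifyBias:
    def pair(self):
        return HomoeologPair("X1", "X1A", "X1D")

    @pytest.mark.parametrize(
        "a,d,expected",
        [
            (10.0, 10.0, "balanced"),
            (8.0, 0.5, "A"),  # log2(8.1/0.6) = 3.75 >= 1
            (0.5, 8.0, "D"),
            (0.2, 0.3, "silent"),
        ],
    )
    def test_bias_rules(self, a, d, expected):
        m = matrix({"X1A": [a] * 5, "X1D": [d] * 5})
        assert ea.classify_bias(self.pair(), m, "root") == expected

    def test_missing_gene_row_is_error(self):
        m = matrix({"X1A": [1.0] * 5})
        with pytest.raises(ValidationError, match="X1D"):
            ea.classify_bias(self.pair(), m, "root")


class TestCallStressResponse:
    def test_twofold_boundary_inclusive_without_pseudocount(self):
        call, log2fc, _ = ea.call_stress_response(2.0, 4.0, pseudocount=0.0)
        assert call == "up"
        assert log2fc == pytest.approx(1.0)

    def test_equal_values_unchanged(self):
        assert ea.call_stress_response(4.0, 4.0)[0] == "unchanged"

    def test_down_call(self):
        call, log2fc, _ = ea.call_stress_response(4.0, 1.9)
        assert call == "down"
        assert log2fc == pytest.approx(math.log2(2.0 / 4.1))

    def test_unexpressed_in_both_is_untestable(self):
        call, _, testable = ea.call_stress_response(0.5, 0.9)
        assert call == "unchanged"
        assert testable is False

    def test_negative_is_error(self):
        with pytest.raises(ValidationError):
            ea.call_stress_response(-1.0, 2.0)

    @given(
        c=st.floats(1.5, 1e4),
        t=st.floats(1.5, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_swapping_control_and_treatment_maps_up_to_down(self, c, t):
        # with pseudocount 0 the thresholds 2 and 1/2 are exact reciprocals
        fwd = ea.call_stress_response(c, t, pseudocount=0.0)[0]
        rev = ea.call_stress_response(t, c, pseudocount=0.0)[0]
        mapping = {"up": "down", "down": "up", "unchanged": "unchanged"}
        # boundary r exactly 2: up is inclusive, down (r = 1/2) is exclusive
        if t != 2 * c and c != 2 * t:
            assert rev == mapping[fwd]

    @given(scale=st.floats(0.01, 100.0), c=st.floats(0.0, 50.0), t=st.floats(0.0, 50.0))
    @settings(max_examples=200, deadline=None)
    def test_call_invariant_under_uniform_scaling_with_scaled_pseudocount(self, scale, c, t):
        base = ea.call_stress_response(c, t, pseudocount=0.1)
        scaled = ea.call_stress_response(c * scale, t * scale, pseudocount=0.1 * scale)
        assert base[1] == pytest.approx(scaled[1], abs=1e-9)


class TestTemporalPattern:
    def test_early_peak(self):
        tp = ea.classify_temporal_pattern(
            calls_from_log2fc([2.5, 2.0, 1.0, 0.5, 0.2], ["up", "up", "up", "unchanged", "unchanged"])
        )
        assert tp.pattern == "early_peak"

    def test_unresponsive(self):
        tp = ea.classify_temporal_pattern(
            calls_from_log2fc([0, 0, 0, 0, 0], ["unchanged"] * 5)
        )
        assert tp.pattern == "unresponsive"

    def test_biphasic_two_maxima_with_dip(self):
        tp = ea.classify_temporal_pattern(calls_from_log2fc([2.0, 0.5, 0.4, 1.8, 2.2]))
        assert tp.pattern == "biphasic"

    def test_late_peak(self):
        tp = ea.classify_temporal_pattern(calls_from_log2fc([0.1, 0.3, 0.8, 1.6, 2.4]))
        assert tp.pattern == "late_peak"

    def test_constitutive_all_up(self):
        tp = ea.classify_temporal_pattern(calls_from_log2fc([1.5, 1.5, 1.5, 1.5, 1.5], ["up"] * 5))
        assert tp.pattern == "constitutive"

    def test_missing_timepoint_is_error(self):
        with pytest.raises(ValidationError, match="24"):
            ea.classify_temporal_pattern(calls_from_log2fc([1, 1, 1, 1, 1])[:4])


class TestSummarizeStress:
    def test_single_stress_gene(self):
        calls = [StressCall("g1", "cold", 1, "up", 2.0),
                 StressCall("g1", "heat", 1, "unchanged", 0.0),
                 StressCall("g1", "drought", 1, "unchanged", 0.0)]
        assert ea.summarize_stress(calls) == {"cold": 1, "drought": 0, "heat": 0, "union": 1}

    def test_union_semantics(self):
        calls = [StressCall("g1", "cold", 1, "up", 2.0), StressCall("g1", "heat", 3, "up", 2.0)]
        s = ea.summarize_stress(calls)
        assert (s["cold"], s["heat"], s["union"]) == (1, 1, 1)

    def test_tally_matches_brute_force_set_union(self):
        calls = [
            StressCall("g1", "cold", 1, "up", 2.0),
            StressCall("g2", "heat", 1, "up", 2.0),
            StressCall("g3", "cold", 1, "up", 2.0),
            StressCall("g3", "drought", 6, "up", 2.0),
        ]
        s = ea.summarize_stress(calls)
        assert s == {"cold": 2, "drought": 1, "heat": 1, "union": 3}
        oracle = len({c.gene_id for c in calls if c.call == "up"})
        assert s["union"] == oracle


class TestClassifyFate:
    def fate(self, a_row, d_row, stress_calls=()):
        m = matrix({"X1A": a_row, "X1D": d_row})
        return ea.classify_fate(HomoeologPair("X1", "X1A", "X1D"), m, stress_calls)

    def test_silenced_member_is_non_functionalization(self):
        assert self.fate([10] * 5, [0] * 5) == "non_functionalization"

    def test_single_member_induction_is_neo_functionalization(self):
        calls = [StressCall("X1A", "cold", 1, "up", 2.5)]
        assert self.fate([10] * 5, [10] * 5, calls) == "neo_functionalization"

    def test_class_switched_bias_is_dominance(self):
        # A-biased in vegetative tissues, D-biased in reproductive ones
        a = [20, 20, 20, 2, 2]
        d = [2, 2, 2, 20, 20]
        assert self.fate(a, d) == "dominance"

    def test_complementary_occupancy_is_sub_functionalization(self):
        a = [10, 10, 10, 0, 0]
        d = [0, 0, 0, 10, 10]
        assert self.fate(a, d) == "sub_functionalization"

    def test_uniform_pair_is_conserved(self):
        assert self.fate([10] * 5, [10] * 5) == "conserved"

    def test_every_pair_gets_exactly_one_label(self, rng):
        for _ in range(100):
            a = list(rng.uniform(0, 20, 5).round(2))
            d = list(rng.uniform(0, 20, 5).round(2))
            assert self.fate(a, d) in (
                "conserved",
                "non_functionalization",
                "sub_functionalization",
                "dominance",
                "neo_functionalization",
            )

    def test_missing_tissue_class_is_error(self):
        m = ExpressionMatrix(
            pd.DataFrame({"petal": [10.0, 10.0]}, index=["X1A", "X1D"])
        )
        with pytest.raises(ValidationError, match="vegetative"):
            ea.classify_fate(HomoeologPair("X1", "X1A", "X1D"), m, ())
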