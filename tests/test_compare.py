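"""Cross-condition occupancy quantities, specificity labels, qPCR arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gefcall import (
    CallerConfig,
    Component,
    Fragment,
    build_occupancy_table,
    chap_yield,
    classify_specificity,
    copy_ratio,
    count_overlapping,
    display_scale,
    normalized_reads,
    rank_components,
)
from gefcall.compare import (
    DEFAULT_CONDITIONS,
    LABEL_CONSTITUTIVE,
    LABEL_PRE,
    LABEL_SPORADIC,
    LABEL_TRANSIENT,
    OccupancyTable,
    to_long_format,
)

from oracles import brute_force_overlap_count


def frag(s, e):
    return Fragment("genome", s, e)


class TestCountOverlapping:
    def test_disjoint_fragments_do_not_count(self):
        assert count_overlapping((100, 200), [frag(50, 99), frag(250, 300)]) == 0

    def test_partial_overlap_counts(self):
        assert count_overlapping((100, 200), [frag(150, 220)]) == 1

    def test_abutting_half_open_does_not_count(self):
        assert count_overlapping((100, 200), [frag(20, 100), frag(200, 280)]) == 0

    @given(st.data())
    def test_matches_pairwise_brute_force(self, data):
        frags = [
            frag(s, s + data.draw(st.integers(1, 120)))
            for s in data.draw(st.lists(st.integers(0, 900), min_size=0, max_size=60))
        ]
        start = data.draw(st.integers(0, 900))
        end = start + data.draw(st.integers(1, 150))
        assert count_overlapping((start, end), frags) == brute_force_overlap_count((start, end), frags)


class TestNormalizedReads:
    def test_arithmetic(self):
        assert normalized_reads(0, 10**6) == 0
        assert normalized_reads(500, 10**6) == 5e-4

    def test_scale_invariance_under_duplication(self):
        assert normalized_reads(500, 10**6) == normalized_reads(1_000, 2 * 10**6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalized_reads(1, 0)
        with pytest.raises(ValueError):
            normalized_reads(5, 3)


class TestClassifySpecificity:
    @pytest.mark.parametrize(
        "flags,label",
        [
            ((True, False, False, False), LABEL_PRE),
            ((False, True, False, False), LABEL_TRANSIENT),
            ((True, True, True, True), LABEL_CONSTITUTIVE),
            ((False, False, False, False), LABEL_SPORADIC),
            ((True, False, True, False), LABEL_SPORADIC),
            ((False, False, False, True), LABEL_SPORADIC),
        ],
    )
    def test_flag_patterns(self, flags, label):
        assert classify_specificity(dict(zip(DEFAULT_CONDITIONS, flags))) == label

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_specificity({"0min": True})

    @given(flags=st.tuples(*[st.booleans()] * 4))
    def test_stable_under_appending_condition_flagged_like_random(self, flags):
        base = dict(zip(DEFAULT_CONDITIONS, flags))
        extended = {**base, "extra": base["random"]}
        assert classify_specificity(extended, conditions=DEFAULT_CONDITIONS + ("extra",)) == classify_specificity(base)


def make_table(rows, conditions=DEFAULT_CONDITIONS):
    df = pd.DataFrame(rows)
    return OccupancyTable(df=df, conditions=tuple(conditions), thresholds={c: 1 for c in conditions})


class TestRankComponents:
    def row(self, start, depth, norm=0.0):
        r = {"start": start, "end": start + 90}
        for c in DEFAULT_CONDITIONS:
            r[f"avg_depth_{c}"] = depth
            r[f"normalized_{c}"] = norm
            r[f"above_{c}"] = True
        return r

    def test_highest_depth_ranked_first(self):
        table = make_table([self.row(16_519, 16_341.3), self.row(3_925_748, 30_601.5)])
        ranked = rank_components(table, "0min")
        assert ranked.iloc[0]["start"] == 3_925_748 and ranked.iloc[0]["rank"] == 1

    def test_single_component_is_rank_one(self):
        ranked = rank_components(make_table([self.row(10, 5.0)]), "10min")
        assert list(ranked["rank"]) == [1]

    def test_input_order_invariance(self):
        rows = [self.row(100 * k, float(d)) for k, d in enumerate([5, 9, 2, 9, 7])]
        r1 = rank_components(make_table(rows), "0min")
        r2 = rank_components(make_table(rows[::-1]), "0min")
        assert list(r1["start"]) == list(r2["start"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            rank_components(make_table([]), "0min")


class TestDisplayScale:
    def test_identity(self):
        assert round(display_scale(123, 123), 2) == 1.00

    def test_full_precision_quotient(self):
        assert display_scale(4, 6) == 1.5

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            display_scale(0, 10)


class TestQpcrArithmetic:
    def test_chap_yield_percent(self):
        assert chap_yield(0.05, 1.0) == pytest.approx(5.0)
        assert chap_yield(3.3, 3.3) == pytest.approx(100.0)

    def test_chap_yield_table_matches_hand_computation(self):
        inputs = {"0min": 2.0, "10min": 1.6, "20min": 1.8, "random": 2.2}
        purified = {"0min": 0.11, "10min": 0.02, "20min": 0.018, "random": 0.044}
        expected = {"0min": 5.5, "10min": 1.25, "20min": 1.0, "random": 2.0}
        for t in inputs:
            assert chap_yield(purified[t], inputs[t]) == pytest.approx(expected[t])

    def test_chap_yield_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            chap_yield(1.0, 0.0)

    def test_copy_ratio_reference_is_exactly_one(self):
        a = {"0min": 1.7, "10min": 2.9, "20min": 4.1, "random": 3.3}
        b = {"0min": 0.9, "10min": 1.0, "20min": 1.1, "random": 1.2}
        ratios = copy_ratio(a, b, "0min")
        assert ratios["0min"] == 1.0

    def test_copy_ratio_linearity(self):
        a = {"r": 1.0, "t": 2.0}
        b = {"r": 1.0, "t": 1.0}
        doubled = {"r": 1.0, "t": 4.0}
        assert copy_ratio(doubled, b, "r")["t"] == pytest.approx(2 * copy_ratio(a, b, "r")["t"])

    def test_copy_ratio_four_timepoint_hand_computation(self):
        a = {"0min": 2.0, "10min": 3.0, "20min": 4.0, "random": 1.0}
        b = {"0min": 1.0, "10min": 1.0, "20min": 2.0, "random": 0.5}
        ratios = copy_ratio(a, b, "0min")
        assert ratios == pytest.approx({"0min": 1.0, "10min": 1.5, "20min": 1.0, "random": 1.0})

    def test_copy_ratio_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            copy_ratio({"a": 1.0}, {"a": 1.0}, "b")


class TestOccupancyTable:
    def build(self):
        rng = np.random.default_rng(99)
        glen = 5_000
        conditions = ("0min", "10min")
        # one shared site with fragments in both conditions, one 10min-only site
        fragments = {
            "0min": [frag(1_000 + int(o), 1_090 + int(o)) for o in rng.integers(-10, 10, 120)],
            "10min": [frag(1_000 + int(o), 1_090 + int(o)) for o in rng.integers(-10, 10, 110)]
            + [frag(3_000 + int(o), 3_085 + int(o)) for o in rng.integers(-10, 10, 100)],
        }
        components = {
            "0min": [Component("genome", 995, 1_095, avg_depth=110.0)],
            "10min": [
                Component("genome", 1_000, 1_092, avg_depth=100.0),
                Component("genome", 2_995, 3_090, avg_depth=95.0),
            ],
        }
        totals = {c: len(fragments[c]) for c in conditions}
        thresholds = {"0min": 50, "10min": 50}
        return build_occupancy_table(
            components, fragments, totals, thresholds,
            conditions=conditions, caller_cfg=CallerConfig(), genome_length=glen,
        )

    def test_reciprocal_overlap_merges_rows_across_conditions(self):
        table = self.build()
        assert len(table.df) == 2
        shared = table.row_containing(1_050)
        assert shared is not None
        assert table.flags(shared) == {"0min": True, "10min": True}

    def test_condition_without_called_component_scores_below_threshold(self):
        table = self.build()
        only10 = table.row_containing(3_040)
        assert table.flags(only10) == {"0min": False, "10min": True}

    def test_normalized_reads_are_proportions(self):
        table = self.build()
        for c in table.conditions:
            col = table.df[f"normalized_{c}"]
            assert ((0 <= col) & (col <= 1)).all()

    def test_flags_recomputable_from_avg_depth_and_threshold(self):
        table = self.build()
        for c in table.conditions:
            expected = table.df[f"avg_depth_{c}"] >= table.thresholds[c]
            assert (table.df[f"above_{c}"] == expected).all()

    def test_long_format_has_row_per_component_condition(self):
        table = self.build()
        long = to_long_format(table)
        assert len(long) == len(table.df) * len(table.conditions)

    def test_tsv_documents_overlap_rule(self, tmp_path):
        table = self.build()
        table.to_tsv(tmp_path / "occ.tsv")
        text = (tmp_path / "occ.tsv").read_text()
        assert ">=1 bp" in text.splitlines()[0]
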