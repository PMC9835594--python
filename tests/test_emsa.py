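"""EMSA quantification, important-base calling and variant designers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xselex import (
    ImportanceModel,
    call_important,
    relative_binding,
    shifted_fraction,
    transition_variants,
    ub_substitution_variants,
)


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "gel_id",
            "variant_id",
            "position",
            "variant_class",
            "complex_density",
            "free_density",
        ],
    )


SIMPLE = make_table(
    [
        ("g1", "orig", None, "original", 60.0, 40.0),
        ("g1", "v5", 5, "transition", 30.0, 70.0),
        ("g2", "orig", None, "original", 30.0, 20.0),
        ("g2", "v6", 6, "transition", 48.0, 32.0),
    ]
)


class TestShiftedFraction:
    @pytest.mark.parametrize(
        "c,f,expected", [(50, 50, 0.5), (0, 80, 0.0), (80, 0, 1.0)]
    )
    def test_values(self, c, f, expected):
        assert shifted_fraction(c, f) == expected

    def test_empty_lane(self):
        with pytest.raises(ValueError, match="empty lane"):
            shifted_fraction(0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shifted_fraction(-1.0, 5.0)


class TestRelativeBinding:
    def test_within_gel_normalization(self):
        rel = relative_binding(SIMPLE)
        by_id = rel.set_index("variant_id")["relative_binding"]
        assert by_id["v5"] == pytest.approx(50.0)  # 0.30 / 0.60
        assert by_id["v6"] == pytest.approx(100.0)  # 0.60 / 0.60 on its own gel
        assert by_id["orig"].tolist() == pytest.approx([100.0, 100.0])

    @given(c=st.floats(0.1, 100.0))
    @settings(max_examples=30, derandomize=True)
    def test_scale_invariance(self, c):
        scaled = SIMPLE.copy()
        mask = scaled["gel_id"] == "g1"
        scaled.loc[mask, ["complex_density", "free_density"]] *= c
        a = relative_binding(SIMPLE)["relative_binding"]
        b = relative_binding(scaled)["relative_binding"]
        assert np.allclose(a, b)

    def test_missing_original_names_gel(self):
        bad = SIMPLE[SIMPLE["variant_id"] != "orig"].copy()
        with pytest.raises(ValueError, match="g1"):
            relative_binding(bad)

    def test_zero_original_fraction(self):
        bad = SIMPLE.copy()
        bad.loc[bad["variant_id"] == "orig", "complex_density"] = 0.0
        with pytest.raises(ValueError, match="zero"):
            relative_binding(bad)

    def test_multiple_original_lanes_use_mean(self):
        table = make_table(
            [
                ("g1", "o1", None, "original", 40.0, 60.0),
                ("g1", "o2", None, "original", 60.0, 40.0),
                ("g1", "v1", 1, "transition", 50.0, 50.0),
            ]
        )
        rel = relative_binding(table)
        v = rel.set_index("variant_id")["relative_binding"]
        assert v["v1"] == pytest.approx(100.0)  # 0.5 / mean(0.4, 0.6)


class TestCallImportant:
    def test_no_important_when_all_full_binding(self):
        rel = relative_binding(SIMPLE)
        rel["relative_binding"] = 100.0
        calls = call_important(rel)
        assert calls.important_positions() == frozenset()

    def test_threshold_on_position_mean(self):
        """Variants at 40% and 60% average to 50% < 65% -> flagged."""
        table = make_table(
            [
                ("g1", "orig", None, "original", 50.0, 50.0),
                ("g1", "v3a", 3, "transition", 20.0, 80.0),  # 40%
                ("g1", "v3b", 3, "transition", 30.0, 70.0),  # 60%
                ("g1", "v4", 4, "transition", 35.0, 65.0),  # 70%
            ]
        )
        calls = call_important(relative_binding(table))
        assert calls.important_positions() == frozenset({3})

    def test_monotone_in_threshold(self):
        rel = relative_binding(SIMPLE)
        lo = call_important(rel, threshold=40.0).important_positions()
        hi = call_important(rel, threshold=80.0).important_positions()
        assert lo <= hi

    def test_untested_positions_reported(self):
        calls = call_important(
            relative_binding(SIMPLE), positions_universe=(5, 6, 9)
        )
        assert calls.untested == (9,)

    def test_classes_called_separately(self):
        table = make_table(
            [
                ("g1", "orig", None, "original", 50.0, 50.0),
                ("g1", "t10", 10, "transition", 10.0, 90.0),
                ("g1", "d10", 10, "ub_sub", 45.0, 55.0),
            ]
        )
        calls = call_important(relative_binding(table))
        assert calls.important_positions("transition") == frozenset({10})
        assert calls.important_positions("ub_sub") == frozenset()

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            call_important(relative_binding(SIMPLE), threshold=0.0)


class TestImportanceModel:
    def test_fit_and_summary(self):
        results = ImportanceModel(SIMPLE).fit()
        assert results.important_positions() == frozenset({5})
        text = results.summary()
        assert "tau" in text and "transition" in text

    def test_median_option(self):
        results = ImportanceModel(SIMPLE, stat="median").fit()
        assert results.calls.stat == "median"

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            ImportanceModel(pd.DataFrame({"gel_id": ["g1"]}))

    def test_plot_returns_axis(self):
        import matplotlib

        matplotlib.use("Agg")
        ax = ImportanceModel(SIMPLE).fit().plot_binding()
        assert len(ax.patches) == 2  # one bar per tested position


class TestVariantDesigners:
    def test_transition_rule(self):
        assert transition_variants("AT", {0, 1}) == {0: "GT", 1: "AC"}

    def test_ds_position_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="unnatural"):
            out = transition_variants("ADG", {0, 1, 2})
        assert out == {0: "GDG", 2: "ADA"}

    def test_empty_set(self):
        assert transition_variants("ACGT", set()) == {}

    def test_frozen_flank_error(self):
        with pytest.raises(ValueError, match="constant flank"):
            transition_variants("ACGT", {0}, frozen={0})

    def test_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            transition_variants("ACGT", {9})

    def test_arc1172_ds_substitution_set(self):
        """Ten single-stranded positions of the 41-mer anti-vWF DNA
        aptamer each get one Ds-substituted variant."""
        arc1172 = "G" * 41  # only positions matter for the designer
        positions = {7, 8, 10, 21, 22, 27, 28, 29, 30, 31}
        out = ub_substitution_variants(arc1172, positions, one_based=True)
        assert len(out) == 10
        for pos, var in out.items():
            assert len(var) == 41
            assert var[pos - 1] == "D"
            assert sum(a != b for a, b in zip(arc1172, var)) == 1

    def test_single_position_single_variant(self):
        out = ub_substitution_variants("ACGT", {2})
        assert out == {2: "ACDT"}
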