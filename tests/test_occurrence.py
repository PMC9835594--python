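"""Required numbers, placements, hit sublibraries and occurrences."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xselex import (
    DPLibrarySet,
    DPSublibrary,
    DRLibrary,
    NaturalRandomLibrary,
    OccurrenceModel,
    hit_sublibraries,
    match_probability,
    motif_from_counts,
    occurrence_dp,
    occurrence_dr,
    occurrence_natural,
    placements,
    required_complexity,
    required_number,
    round_sig,
)


class TestRequiredNumber:
    def test_anti_vegf(self):
        """21 important naturals + 8 any-pair stem bp, Ds predetermined: 4^29."""
        motif = motif_from_counts(21, 2, 8)
        R = required_number(motif, "dp")
        assert R == 4**29
        assert round_sig(float(R), 2) == 2.9e17

    def test_anti_den3_tentative(self):
        motif = motif_from_counts(28, 2, 6)
        assert round_sig(float(required_number(motif, "dp")), 2) == 3.0e20

    def test_anti_vwf_five_letter(self):
        """13 important bases incl. two Ds, counted in the five letters."""
        motif = motif_from_counts(11, 2, 6)
        R = required_number(motif, "dr")
        assert R == 5**19
        assert round_sig(float(R), 2) == 1.9e13

    def test_unconstrained_motif(self):
        # an all-wildcard motif stands in for "no constraints"
        from xselex import parse_motif

        motif = parse_motif("length: 5")
        assert required_number(motif, "natural") == 1
        assert required_number(motif, "dr") == 1

    def test_strict_equals_paper_for_four_letters(self):
        motif = motif_from_counts(3, 0, 2)
        assert required_number(motif, "natural", "strict") == pytest.approx(4**5)

    def test_strict_vs_paper_stem_factor_five_letters(self):
        """Per-bp pair probability in a doped pool is 4x0.225^2 = 0.2025,
        not the 1/5 the printed exponents assume."""
        motif = motif_from_counts(0, 0, 1)
        R_paper = required_number(motif, "dr", "paper")
        R_strict = required_number(motif, "dr", "strict")
        assert R_paper == 5
        assert 1 / R_strict == pytest.approx(0.2025)

    def test_natural_library_cannot_hold_ub(self):
        motif = motif_from_counts(1, 1, 0)
        assert required_number(motif, "natural", "strict") == math.inf


class TestPlacements:
    def test_core_19_in_n30(self):
        motif = motif_from_counts(19, 0, 4)
        assert motif.essential_core_span == 19
        assert placements(motif, 30) == 12

    def test_core_equals_region(self):
        motif = motif_from_counts(8, 0, 0)
        assert placements(motif, 8) == 1

    def test_anchored(self):
        motif = motif_from_counts(19, 0, 4)
        assert placements(motif, 30, anchored=True) == 1

    def test_core_too_long_warns_and_zero(self):
        motif = motif_from_counts(12, 0, 0)
        with pytest.warns(UserWarning, match="exceeds"):
            assert placements(motif, 10) == 0


def _dp_grid(region_len=20, gaps=(3, 5, 7), offsets=(0, 2, 4, 6)):
    subs = [
        DPSublibrary(region_len, (o, o + g))
        for g in gaps
        for o in offsets
        if o + g < region_len
    ]
    return DPLibrarySet(sublibraries=tuple(subs), total_molecules=1e6)


class TestHitSublibraries:
    def test_two_ds_interval_match(self):
        """Only sublibraries reproducing the -Ds-N_n-Ds- spacing hit."""
        dp = _dp_grid()
        motif = motif_from_counts(4, 2, 0, ub_offsets=(0, 5))  # gap 5 within 6-nt core
        assert motif.essential_core_span == 6
        # gap-5 sublibraries at any offset keeping the core inside: all 4 offsets
        assert hit_sublibraries(motif, dp) == 4

    def test_offset_feasibility(self):
        dp = DPLibrarySet(
            sublibraries=(
                DPSublibrary(6, (0, 3)),
                DPSublibrary(6, (2, 5)),
            ),
            total_molecules=1.0,
        )
        # core of 6 nt with UBs at in-core offsets 1 and 4: needs the pair at (1, 4)
        motif = motif_from_counts(4, 2, 0, ub_offsets=(1, 4))
        assert hit_sublibraries(motif, dp) == 0
        dp2 = DPLibrarySet(
            sublibraries=(DPSublibrary(6, (1, 4)),), total_molecules=1.0
        )
        assert hit_sublibraries(motif, dp2) == 1

    def test_single_ub_motif_hits_every_sublibrary(self):
        """One essential Ds is realisable in every sublibrary carrying Ds."""
        dp = _dp_grid()
        motif = motif_from_counts(3, 1, 0, ub_offsets=(1,))
        assert hit_sublibraries(motif, dp) == dp.n_sublibraries

    def test_empty_set_impossible(self):
        with pytest.raises(ValueError):
            DPLibrarySet(sublibraries=(), total_molecules=1.0)


class TestOccurrence:
    def test_anti_den4(self, fixtures):
        r = fixtures["anti-DEN4-NS1"].evaluate()
        assert r.required_number == 4**22
        assert (r.hit_sublibraries, r.total_sublibraries) == (2, 74)
        assert round_sig(r.occurrence_reported, 2) == 9.0
        assert r.occurrence == pytest.approx(6.0e15 / 4**22 * 2 / 74)

    def test_zero_hits_zero_occurrence(self):
        motif = motif_from_counts(4, 2, 0, ub_offsets=(0, 5))
        r = occurrence_dp(motif, molecules=1e15, hits=0, total=10)
        assert r.occurrence == 0.0
        assert r.p_at_least_one == 0.0

    def test_toy_dp_matches_arithmetic(self):
        motif = motif_from_counts(3, 0, 1)
        r = occurrence_dp(motif, molecules=float(4**5), hits=1, total=1)
        assert r.occurrence == pytest.approx(4.0)

    def test_pegaptanib_precursor(self, fixtures):
        r = fixtures["pegaptanib-precursor"].evaluate()
        assert r.placements == 12
        assert round(r.occurrence) == 103

    def test_molecules_equal_required_number(self):
        motif = motif_from_counts(5, 0, 0)
        lib = NaturalRandomLibrary(random_len=5, molecules=float(4**5))
        r = occurrence_natural(motif, lib)
        assert r.placements == 1
        assert r.occurrence == pytest.approx(1.0)

    def test_anti_vwf_paper_mode_quotient(self, fixtures):
        r = fixtures["anti-vWF"].evaluate()
        assert r.occurrence == pytest.approx(1.1e15 / 5**19)
        assert round(r.occurrence) == 58
        assert set(r.extras) == {"occurrence_paper_mode", "occurrence_strict_mode"}

    def test_dr_unconstrained_motif_gives_molecules(self):
        from xselex import parse_motif

        motif = parse_motif("length: 4")
        lib = DRLibrary(random_len=4, molecules=1e6)
        r = occurrence_dr(motif, lib, mode="strict")
        assert r.occurrence == pytest.approx(1e6)

    def test_summary_mentions_key_quantities(self, fixtures):
        text = fixtures["anti-DEN4-NS1"].evaluate().summary()
        assert "required number" in text and "hit sublibraries" in text

    def test_model_dispatch(self, fixtures):
        fx = fixtures["anti-vWF"]
        r = OccurrenceModel(fx.motif, fx.library, anchored=True).evaluate()
        assert r.library_kind == "dr"


class TestRequiredComplexity:
    @given(
        n_ess=st.integers(0, 6),
        n_stem=st.integers(0, 4),
        h=st.integers(1, 10),
        extra=st.integers(0, 10),
        target=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=80, derandomize=True)
    def test_round_trip_identity(self, n_ess, n_stem, h, extra, target):
        motif = motif_from_counts(n_ess, 0, n_stem) if n_ess + n_stem else None
        if motif is None:
            return
        S = h + extra
        M = required_complexity(motif, target_occurrence=target, hits=h, total=S)
        r = occurrence_dp(motif, molecules=M, hits=h, total=S)
        assert r.occurrence == pytest.approx(target, rel=1e-9)

    def test_toy_value(self):
        motif = motif_from_counts(3, 0, 1)  # R = 4^4
        assert required_complexity(motif, target_occurrence=1.0, hits=1, total=2) == 512

    def test_zero_target(self):
        motif = motif_from_counts(3, 0, 1)
        assert required_complexity(motif, target_occurrence=0.0, hits=1, total=2) == 0

    def test_no_hit_sublibrary_error(self):
        motif = motif_from_counts(3, 0, 1)
        with pytest.raises(ValueError, match="no hit sublibrary"):
            required_complexity(motif, target_occurrence=1.0, hits=0, total=2)


class TestMonotonicity:
    @given(
        n_ess=st.integers(0, 8), n_stem=st.integers(0, 4)
    )
    @settings(max_examples=40, derandomize=True)
    def test_occurrence_strictly_decreasing_in_exponent(self, n_ess, n_stem):
        def occ(ne, ns):
            m = motif_from_counts(ne, 0, ns) if ne + ns else None
            if m is None:
                return 1e9
            return occurrence_dp(m, molecules=1e15, hits=1, total=1).occurrence

        base = occ(n_ess, n_stem)
        assert occ(n_ess + 1, n_stem) < base or base == 1e9
        assert occ(n_ess, n_stem + 1) < base or base == 1e9

    def test_strict_prob_consistent_with_paper_four_letter(self):
        motif = motif_from_counts(4, 0, 2)
        assert match_probability(motif, "natural") == pytest.approx(4.0**-6)
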