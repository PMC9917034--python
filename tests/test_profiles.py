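"""Degradome summaries: TIC normalization, cleavage profiles, terminal
matrices, candidate filtering and catalytic-phenotype signatures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degradomics.errors import ConfigError, StateError
from degradomics.io_tables import SubstrateRecord
from degradomics.profiles import (
    CleavageProfile,
    activity_signature,
    bond_class_availability,
    cleavage_profile,
    filter_mhc1_candidates,
    terminal_matrix,
    tic_normalize,
)
from conftest import make_located

ABSTRACT_CORE_PEPTIDES = ["LPRHRDTGIL", "SLPQKSHGR", "QDENPVVHFF",
                          "KGRGLSLSRF", "GYGGRASDY"]


class TestTicNormalize:
    def test_single_peptide_is_100(self, toy_substrate):
        (lp,) = tic_normalize([make_located(toy_substrate, 1, 3, intensity=7.0)])
        assert lp.relative_abundance == 100.0

    def test_hand_arithmetic(self, toy_substrate):
        located = [make_located(toy_substrate, 1, 3, intensity=v)
                   for v in (2.0, 3.0, 5.0)]
        rels = [lp.relative_abundance for lp in tic_normalize(located)]
        assert rels == [20.0, 30.0, 50.0]

    def test_count_mode_equal_shares(self, toy_substrate):
        located = [make_located(toy_substrate, s, s + 2) for s in (1, 2, 3, 4)]
        rels = [lp.relative_abundance for lp in tic_normalize(located)]
        assert rels == [25.0] * 4

    def test_empty_is_empty(self):
        assert tic_normalize([]) == []

    def test_conservation_per_sample(self, toy_substrate):
        located = [make_located(toy_substrate, 1, 3, sample=s, intensity=v)
                   for s, v in [("a", 1.0), ("a", 9.0), ("b", 4.0)]]
        normed = tic_normalize(located)
        for sample in ("a", "b"):
            total = sum(lp.relative_abundance for lp in normed
                        if lp.sample_id == sample)
            assert total == pytest.approx(100.0, abs=1e-6)

    def test_scale_invariance(self, toy_substrate):
        located = [make_located(toy_substrate, 1, 3, intensity=v)
                   for v in (2.0, 3.0, 5.0)]
        doubled = [make_located(toy_substrate, 1, 3, intensity=2 * v)
                   for v in (2.0, 3.0, 5.0)]
        assert [lp.relative_abundance for lp in tic_normalize(located)] == \
               [lp.relative_abundance for lp in tic_normalize(doubled)]


class TestCleavageProfile:
    def test_full_span_peptide_has_no_events(self, toy_substrate):
        prof = cleavage_profile([make_located(toy_substrate, 1, 6)], toy_substrate)
        assert prof.total == 0
        assert prof.frequencies.sum() == 0  # undefined-empty renders as zeros

    def test_adjacent_fragments_share_one_bond(self, toy_substrate):
        located = [make_located(toy_substrate, 1, 3),
                   make_located(toy_substrate, 4, 6)]
        prof = cleavage_profile(located, toy_substrate)
        assert prof.counts[2] == 2  # bond 3, cut seen from both sides
        assert prof.total == 2
        assert prof.frequencies[2] == 1.0

    def test_internal_peptide_two_events(self, toy_substrate):
        prof = cleavage_profile([make_located(toy_substrate, 2, 4)], toy_substrate)
        assert prof.counts[0] == 1 and prof.counts[3] == 1
        assert prof.frequencies[0] == prof.frequencies[3] == 0.5

    def test_tic_weighting_requires_normalize(self, toy_substrate):
        with pytest.raises(StateError):
            cleavage_profile([make_located(toy_substrate, 2, 4)],
                             toy_substrate, weighting="tic")

    def test_frequencies_sum_to_one(self, toy_substrate):
        located = [make_located(toy_substrate, s, e)
                   for s, e in [(1, 3), (2, 4), (4, 6), (2, 5)]]
        prof = cleavage_profile(located, toy_substrate)
        assert prof.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(1, 12), st.integers(1, 12)).map(sorted),
        min_size=1, max_size=20,
    ))
    def test_count_mode_matches_brute_force_recount(self, intervals):
        """Profile equals a naive recount over every peptide boundary."""
        sub = SubstrateRecord("s", "AAKFAAQWERTY")  # L = 12
        located = [make_located(sub, s, e) for s, e in intervals]
        prof = cleavage_profile(located, sub)
        expected = np.zeros(sub.L - 1)
        for s, e in intervals:
            if s > 1:
                expected[s - 2] += 1
            if e < sub.L:
                expected[e - 1] += 1
        assert np.array_equal(prof.counts, expected)


class TestTerminalMatrix:
    def test_counting_and_normalization(self, toy_substrate):
        located = [make_located(toy_substrate, 1, 2),   # AA
                   make_located(toy_substrate, 1, 2),   # AA
                   make_located(toy_substrate, 4, 6)]   # FAA
        tm = terminal_matrix(located)
        frame = tm.to_frame()
        assert frame.loc["A", "A"] == 2
        assert frame.loc["F", "A"] == 1
        normed = tm.to_frame(normalized=True)
        assert normed.loc["A", "A"] == pytest.approx(2 / 3)
        assert normed.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_input(self):
        tm = terminal_matrix([])
        assert tm.counts.sum() == 0 and tm.normalized.sum() == 0

    def test_single_peptide(self, toy_substrate):
        tm = terminal_matrix([make_located(toy_substrate, 3, 4)])  # KF
        assert tm.to_frame(normalized=True).loc["K", "F"] == 1.0

    def test_uses_observed_deamidated_residues(self, mbp):
        # QDENPVVHFF observed as EDENPVVHFF: first residue counted as E
        lp = make_located(mbp, 81, 90, deamidation_sites=(81,))
        assert lp.observed_sequence == "EDENPVVHFF"
        tm = terminal_matrix([lp])
        assert tm.to_frame().loc["E", "F"] == 1


class TestCandidateFilter:
    def test_abstract_core_peptides_retained(self, mbp):
        located = []
        for pep in ABSTRACT_CORE_PEPTIDES:
            start = mbp.sequence.find(pep) + 1
            assert start > 0
            located.append(make_located(mbp, start, start + len(pep) - 1))
        kept = filter_mhc1_candidates(located)
        assert [lp.germline_sequence for lp in kept] == ABSTRACT_CORE_PEPTIDES

    def test_short_peptide_removed(self, toy_substrate):
        assert filter_mhc1_candidates([make_located(toy_substrate, 1, 2)]) == []

    def test_empty_input(self):
        assert filter_mhc1_candidates([]) == []

    def test_inverted_range_rejected(self, toy_substrate):
        with pytest.raises(ConfigError):
            filter_mhc1_candidates([], length_range=(10, 9))


class TestActivitySignature:
    def test_all_tryptic(self):
        sub = SubstrateRecord("s", "AKAKAKAK")
        located = [make_located(sub, 1, 2), make_located(sub, 3, 4)]
        prof = cleavage_profile(located, sub)
        sig = activity_signature(prof, sub)
        assert sig.event_fractions["tryptic"] == 1.0

    def test_closed_form_with_equal_availability(self):
        # 16 bonds whose P1 residues cycle F,K,D,G: each class holds 1/4
        sub = SubstrateRecord("s", "FKDG" * 4 + "A")
        avail = bond_class_availability(sub)
        assert all(v == pytest.approx(0.25) for v in avail.values())
        counts = np.zeros(sub.L - 1)
        counts[0] = 50   # bond 1, P1=F  (chymotryptic)
        counts[1] = 25   # bond 2, P1=K  (tryptic)
        counts[2] = 25   # bond 3, P1=D  (caspase)
        prof = CleavageProfile(sub.id, counts, "count")
        sig = activity_signature(prof, sub)
        assert sig.weights == pytest.approx(
            {"chymotryptic": 0.5, "tryptic": 0.25, "caspase": 0.25, "other": 0.0})

    def test_fractions_and_weights_sum_to_one(self, mbp):
        located = [make_located(mbp, s, s + 8) for s in (2, 20, 50, 90, 140)]
        sig = activity_signature(cleavage_profile(located, mbp), mbp)
        assert sum(sig.event_fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(sig.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(w >= 0 for w in sig.weights.values())

    def test_zero_events_is_state_error(self, toy_substrate):
        prof = cleavage_profile([make_located(toy_substrate, 1, 6)], toy_substrate)
        with pytest.raises(StateError):
            activity_signature(prof, toy_substrate)

    def test_tic_scale_invariance(self, mbp):
        located = [make_located(mbp, s, s + 8, intensity=v)
                   for s, v in [(2, 5.0), (20, 1.0), (50, 3.0)]]
        doubled = [make_located(mbp, s, s + 8, intensity=2 * v)
                   for s, v in [(2, 5.0), (20, 1.0), (50, 3.0)]]
        sig1 = activity_signature(
            cleavage_profile(tic_normalize(located), mbp, "tic"), mbp)
        sig2 = activity_signature(
            cleavage_profile(tic_normalize(doubled), mbp, "tic"), mbp)
        assert sig1.weights == pytest.approx(sig2.weights)
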