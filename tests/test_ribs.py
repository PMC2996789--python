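import numpy as np
import pytest

from retromorf.align import PairwiseAlignment, percent_identity, smith_waterman
from retromorf.disorder import DisorderProfile, call_disordered_segments, get_scale
from retromorf.ribs import (
    ContextParams,
    DisorderContext,
    ResidueClassMap,
    RibsParams,
    classify_ribs,
    disorder_context,
    find_ppii_motifs,
    hydrophobic_moment,
    pattern_similarity,
)
from retromorf.sequence_io import ProteinSequence, reverse_sequence

from conftest import random_protein


def ungapped(q, t):
    return PairwiseAlignment("q", "t", q, t, 1.0, 0, len(q), 0, len(t))


class TestPatternSimilarity:
    def test_identical_sequences(self):
        assert pattern_similarity(ungapped("MKVLA", "MKVLA")) == 1.0

    def test_same_class_substitutions(self):
        # K/R both positive, L/V both hydrophobic
        assert pattern_similarity(ungapped("KL", "RV")) == 1.0

    def test_cross_class_columns(self):
        # K (positive) vs D (negative); L (hydrophobic) vs E (negative)
        assert pattern_similarity(ungapped("KL", "DE")) == 0.0

    def test_gap_columns_count_as_mismatch(self):
        aln = PairwiseAlignment("q", "t", "KL-A", "RVSA", 1.0, 0, 3, 0, 4)
        assert pattern_similarity(aln) == pytest.approx(3 / 4)

    def test_identity_match_implies_class_match(self, rng):
        # identical residues are always same-class, so pattern similarity is
        # bounded below by fractional identity on any alignment
        for _ in range(200):
            a = random_protein(rng, int(rng.integers(5, 30)))
            b = random_protein(rng, int(rng.integers(5, 30)))
            aln = smith_waterman(a, b)
            if aln.is_empty:
                continue
            assert pattern_similarity(aln) >= percent_identity(aln) / 100 - 1e-12

    def test_custom_partition_must_cover_alphabet(self):
        with pytest.raises(ValueError):
            ResidueClassMap({"hydrophobic": frozenset("ACFILMVW")})


class TestHydrophobicMoment:
    def test_homopolymer_18mer_cancels_on_alpha_helix(self):
        # 18 unit vectors at 100 deg spacing complete 5 full turns: sum = 0
        assert hydrophobic_moment("L" * 18, 100.0) == pytest.approx(0.0, abs=1e-9)

    def test_two_residue_window_at_180_degrees(self):
        kd = get_scale("hydropathy")
        h1, h2 = kd.raw["I"], kd.raw["D"]
        assert hydrophobic_moment("ID", 180.0) == pytest.approx(abs(h1 - h2) / 2)

    def test_reversal_invariance(self, rng):
        # reversing the window conjugates the helical-wheel vector sum, so
        # the amphipathic signal survives reading the sequence backwards
        for _ in range(500):
            w = random_protein(rng, int(rng.integers(2, 30)))
            assert hydrophobic_moment(w) == pytest.approx(
                hydrophobic_moment(reverse_sequence(w)), abs=1e-9
            )

    def test_perfect_amphipathic_helix_exceeds_scrambled(self):
        # hydrophobic face every ~3.6 residues vs the same residues scrambled
        amphipathic = "LSSLLSSLSSLLSSLSSL"
        scrambled = "SLSLSLSLSLSLSLSLLL"
        assert hydrophobic_moment(amphipathic) > hydrophobic_moment(scrambled)

    def test_window_too_short(self):
        with pytest.raises(ValueError):
            hydrophobic_moment("L")


class TestPpiiMotifs:
    def test_class_one_hit(self):
        hits = find_ppii_motifs("ARTTPQAPG")
        assert [(h.motif_class, h.start, h.end, h.sequence) for h in hits] == [
            ("I", 2, 8, "RTTPQAP")
        ]

    def test_class_two_hit(self):
        hits = find_ppii_motifs("GPATPLRG")
        assert [(h.motif_class, h.start, h.end, h.sequence) for h in hits] == [
            ("II", 2, 7, "PATPLR")
        ]

    def test_proline_free_sequence_empty(self):
        assert find_ppii_motifs("ARNDEGHIKLMQSTVWY") == []

    def test_overlapping_hits_all_reported(self):
        # two class I occurrences shifted by one residue share their prolines
        seq = "RRTPPTPP"
        classes = [(h.motif_class, h.start) for h in find_ppii_motifs(seq)]
        assert ("I", 1) in classes and ("I", 2) in classes

    def test_motif_spanning_both_classes(self):
        # PxxPxR immediately followed by more prolines can satisfy class I too
        seq = "APTTPLRTTPTTPA"
        hits = find_ppii_motifs(seq)
        assert {h.motif_class for h in hits} == {"I", "II"}


def profile_of(scores, threshold=0.5, window=1):
    return DisorderProfile("t", np.asarray(scores, float), window, "top_idp", threshold)


class TestDisorderContext:
    def ctx(self, span, scores, **kw):
        prof = profile_of(scores)
        segs = call_disordered_segments(prof, min_len=4)
        return disorder_context(span, prof, segs, ContextParams(**kw))

    def test_span_inside_long_disordered_run(self):
        assert self.ctx((40, 55), [0.8] * 100) is DisorderContext.FLANKED_BY_DISORDER

    def test_short_linker_between_ordered_domains(self):
        # a ~25-residue disordered run bridging two ordered domains is a
        # linker, not a binding region
        scores = [0.2] * 60 + [0.8] * 25 + [0.2] * 60
        assert self.ctx((68, 78), scores) is DisorderContext.SHORT_LINKER

    def test_terminal_disordered_run_is_tail(self):
        scores = [0.9] * 60 + [0.2] * 100
        assert self.ctx((20, 35), scores) is DisorderContext.DISORDERED_TAIL

    def test_span_in_ordered_interior(self):
        scores = [0.2] * 200
        assert self.ctx((80, 95), scores) is DisorderContext.ORDERED

    def test_dip_bordered_by_two_disordered_runs(self):
        scores = [0.8] * 50 + [0.2] * 12 + [0.8] * 50
        assert self.ctx((50, 62), scores) is DisorderContext.FLANKED_BY_DISORDER

    def test_terminal_dip_next_to_disordered_run_is_tail(self):
        scores = [0.2] * 12 + [0.9] * 60
        assert self.ctx((0, 12), scores) is DisorderContext.DISORDERED_TAIL

    def test_span_outside_profile_errors(self):
        with pytest.raises(ValueError):
            self.ctx((90, 120), [0.5] * 100)


class TestClassifyRibs:
    def test_all_criteria_met_reversed(self):
        v = classify_ribs(65.0, 0.8, DisorderContext.FLANKED_BY_DISORDER)
        assert (v.criterion1, v.criterion2, v.criterion3) == (True, True, True)
        assert v.label == "retro_morf_candidate"
        assert v.is_positive and v.reasons == ()

    def test_all_criteria_met_normal_orientation(self):
        v = classify_ribs(65.0, 0.8, DisorderContext.DISORDERED_TAIL, orientation="normal")
        assert v.label == "morf_match"

    def test_identity_exactly_sixty_rejected(self):
        # the identity gate is strict: exactly 60% fails, just above passes
        v = classify_ribs(60.0, 0.9, DisorderContext.FLANKED_BY_DISORDER)
        assert not v.criterion1 and v.label == "rejected"
        assert any("criterion1" in r for r in v.reasons)
        v2 = classify_ribs(60.0 + 1e-9, 0.9, DisorderContext.FLANKED_BY_DISORDER)
        assert v2.criterion1 and v2.is_positive

    def test_ordered_context_rejected(self):
        v = classify_ribs(90.0, 0.9, DisorderContext.ORDERED)
        assert not v.criterion3 and v.label == "rejected"
        assert any("criterion3" in r for r in v.reasons)

    def test_short_linker_rejected(self):
        v = classify_ribs(90.0, 0.9, DisorderContext.SHORT_LINKER)
        assert not v.criterion3 and v.label == "rejected"

    def test_monotonicity_in_identity_and_pattern(self, rng):
        # raising identity or pattern similarity never flips a positive
        # verdict to rejected
        contexts = list(DisorderContext)
        for _ in range(100):
            ident = float(rng.uniform(0, 100))
            pat = float(rng.uniform(0, 1))
            ctx = contexts[int(rng.integers(len(contexts)))]
            v = classify_ribs(ident, pat, ctx)
            if v.is_positive:
                up = classify_ribs(
                    min(100.0, ident + 5), min(1.0, pat + 0.1), ctx
                )
                assert up.is_positive

    def test_label_recomputable_from_criteria(self, rng):
        contexts = list(DisorderContext)
        for _ in range(50):
            v = classify_ribs(
                float(rng.uniform(0, 100)),
                float(rng.uniform(0, 1)),
                contexts[int(rng.integers(len(contexts)))],
            )
            assert v.is_positive == (v.criterion1 and v.criterion2 and v.criterion3)
            assert v.is_positive or v.reasons
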