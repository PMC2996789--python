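from functools import lru_cache

import numpy as np
import pytest
from Bio import Align

from retromorf.align import (
    AlignmentError,
    EvalueEstimate,
    PairwiseAlignment,
    empirical_evalue,
    load_matrix,
    local_score,
    percent_identity,
    smith_waterman,
)

from conftest import random_protein


def bruteforce_local_score(a, b, score_fn, gap_open, gap_extend):
    """Independent oracle: top-down recursion over alignment extensions.

    Explores, from every start pair, all ways of extending an alignment by a
    substitution, a gap in one sequence, or stopping; affine costs are
    tracked through an explicit gap-state argument.
    """
    open_cost = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def extend(i, j, state):
        options = [0.0]  # stopping is always allowed in a local alignment
        if i < len(a) and j < len(b):
            options.append(score_fn(a[i], b[j]) + extend(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "A" else open_cost
            options.append(-cost + extend(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if state == "B" else open_cost
            options.append(-cost + extend(i, j + 1, "B"))
        return max(options)

    best = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, score_fn(a[i], b[j]) + extend(i + 1, j + 1, "M"))
    return best


class TestSmithWaterman:
    def test_identical_leucine_tetramer_blosum62(self):
        # four L/L columns at +4 each under BLOSUM62
        aln = smith_waterman("LLLL", "LLLL")
        assert aln.score == 16.0
        assert percent_identity(aln) == 100.0

    def test_no_positive_pair_gives_empty_alignment(self):
        aln = smith_waterman("GGGG", "WWWW")
        assert aln.score == 0.0
        assert aln.is_empty

    def test_exact_substring_found_with_coordinates(self):
        aln = smith_waterman("MKVLAWF", "GGGMKVLAWFGGG")
        assert aln.aligned_query == "MKVLAWF"
        assert (aln.q_start, aln.q_end) == (0, 7)
        assert (aln.t_start, aln.t_end) == (3, 10)

    def test_alignment_strings_reproduce_subsequences(self, rng):
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(10, 40)))
            b = random_protein(rng, int(rng.integers(10, 40)))
            aln = smith_waterman(a, b)
            if aln.is_empty:
                continue
            assert aln.aligned_query.replace("-", "") == a.residues[aln.q_start : aln.q_end]
            assert aln.aligned_target.replace("-", "") == b.residues[aln.t_start : aln.t_end]
            assert not any(
                q == t == "-" for q, t in zip(aln.aligned_query, aln.aligned_target)
            )

    def test_matches_bruteforce_oracle_on_small_pairs(self, rng):
        # reduced 4-letter alphabet so mismatches are common
        matrix = load_matrix()
        letters = list("LKGD")
        score_fn = lambda x, y: matrix.scores[matrix.index(x), matrix.index(y)]
        for _ in range(200):
            a = "".join(rng.choice(letters, size=int(rng.integers(1, 9))))
            b = "".join(rng.choice(letters, size=int(rng.integers(1, 9))))
            expected = bruteforce_local_score(a, b, score_fn, 11.0, 1.0)
            assert smith_waterman(a, b).score == pytest.approx(expected)

    def test_matches_biopython_aligner_on_longer_pairs(self, rng):
        aligner = Align.PairwiseAligner(
            mode="local",
            substitution_matrix=Align.substitution_matrices.load("BLOSUM62"),
            open_gap_score=-12.0,  # first gap residue: open 11 + extend 1
            extend_gap_score=-1.0,
        )
        for _ in range(30):
            a = random_protein(rng, int(rng.integers(20, 70))).residues
            b = random_protein(rng, int(rng.integers(20, 70))).residues
            expected = max(aligner.score(a, b), 0.0)
            assert smith_waterman(a, b).score == pytest.approx(expected)

    def test_score_symmetry(self, rng):
        for _ in range(30):
            a = random_protein(rng, 25).residues
            b = random_protein(rng, 40).residues
            assert local_score(a, b) == pytest.approx(local_score(b, a))

    def test_appending_residues_never_decreases_score(self, rng):
        for _ in range(30):
            a = random_protein(rng, 15).residues
            b = random_protein(rng, 30).residues
            base = local_score(a, b)
            assert local_score(a + "W", b) >= base - 1e-9
            assert local_score(a, b + "W") >= base - 1e-9

    def test_deterministic_traceback(self, rng):
        a = random_protein(rng, 30)
        b = random_protein(rng, 50)
        first = smith_waterman(a, b)
        again = smith_waterman(a, b)
        assert first == again

    def test_unknown_residue_errors_unless_permissive(self):
        with pytest.raises(AlignmentError, match="absent"):
            smith_waterman("MKULA", "MKVLA")
        aln = smith_waterman("MKULA", "MKVLA", permissive=True)
        assert aln.score > 0


class TestPercentIdentity:
    def make(self, q, t):
        return PairwiseAlignment("q", "t", q, t, 1.0, 0, len(q.replace("-", "")), 0, len(t.replace("-", "")))

    def test_identical_ungapped(self):
        assert percent_identity(self.make("MKVLAMKVLA", "MKVLAMKVLA")) == 100.0

    def test_six_of_ten_matches(self):
        assert percent_identity(self.make("MKVLAMKVLA", "MKVLAMWWWW")) == 60.0

    def test_gap_column_counts_in_denominator(self):
        aln = self.make("MKVLAMKVL-", "MKVLAMKVLW")
        assert percent_identity(aln) == 90.0

    def test_empty_alignment_signalled(self):
        empty = PairwiseAlignment("q", "t", "", "", 0.0, 0, 0, 0, 0)
        with pytest.raises(AlignmentError, match="undefined"):
            percent_identity(empty)


class TestEmpiricalEvalue:
    def test_score_above_all_shuffles(self, rng):
        q = random_protein(rng, 15).residues
        t = random_protein(rng, 100).residues
        est = empirical_evalue(q, t, score=1e6, n_shuffles=999, db_size=1, seed=3)
        assert est.p_emp == pytest.approx(1 / 1000)
        assert est.evalue == pytest.approx(1 / 1000)

    def test_score_below_all_shuffles_caps_at_one(self, rng):
        q = random_protein(rng, 15).residues
        t = random_protein(rng, 100).residues
        est = empirical_evalue(q, t, score=0.0, n_shuffles=99, seed=3)
        assert est.p_emp == 1.0

    def test_deterministic_for_fixed_seed(self, rng):
        q = random_protein(rng, 12).residues
        t = random_protein(rng, 80).residues
        s = local_score(q, t)
        a = empirical_evalue(q, t, s, n_shuffles=99, seed=11)
        b = empirical_evalue(q, t, s, n_shuffles=99, seed=11)
        assert a == b

    def test_p_emp_never_zero_and_evalue_scales(self, rng):
        q = random_protein(rng, 10).residues
        t = random_protein(rng, 50).residues
        est = empirical_evalue(q, t, score=1e9, n_shuffles=99, db_size=500, seed=1)
        assert est.p_emp > 0.0
        assert est.evalue == pytest.approx(est.p_emp * 500)

    def test_too_few_shuffles_rejected(self, rng):
        with pytest.raises(ValueError):
            empirical_evalue("MKVLA", "MKVLA", 1.0, n_shuffles=10)
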