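"""Pairwise local alignment with percent identity and empirical E-values.

This is the database-prescan machinery: every candidate fragment (in normal
or reversed orientation) is aligned locally against each database sequence
with Smith–Waterman under affine gaps (BLOSUM62, gap open 11 / extend 1 —
the classic protein-BLAST parameterisation), and the alignment score is
turned into an empirical significance estimate by re-scoring shuffled
copies of the query.  The add-one estimator

    p_emp = (1 + #{shuffle scores >= observed}) / (n_shuffles + 1)

is never zero, so log-transforms are safe, and under the null hypothesis of
an unrelated query it is (sub)uniform by exchangeability.  The E-value is
p_emp scaled by the database size.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.Align import substitution_matrices

from . import _sw
from .sequence_io import ProteinSequence

GAP_CHAR = "-"
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A residue substitution matrix with its alphabet and code lookup."""

    name: str
    alphabet: str
    scores: np.ndarray  # (len(alphabet), len(alphabet)) float64

    def index(self, residue: str, *, permissive: bool = False) -> int:
        i = self.alphabet.find(residue)
        if i < 0:
            if permissive and "X" in self.alphabet:
                return self.alphabet.find("X")
            raise AlignmentError(f"residue {residue!r} absent from matrix {self.name}")
        return i

    def encode(self, residues: str, *, permissive: bool = False) -> np.ndarray:
        return np.array(
            [self.index(r, permissive=permissive) for r in residues], dtype=np.int64
        )


@lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a named substitution matrix (via Biopython's bundled tables)."""
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    return SubstitutionMatrix(name, alphabet, np.array(mat, dtype=np.float64))


@dataclass(frozen=True)
class PairwiseAlignment:
    """One local alignment of a (possibly reversed) query against a target.

    Coordinates are 0-based half-open on the un-gapped sequences; gapped
    aligned strings have equal length and no gap–gap column.  An empty
    alignment (no positively scoring pair anywhere) has score 0 and empty
    aligned strings.
    """

    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    orientation: str = "normal"

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise AlignmentError("aligned strings must have equal length")
        if self.score < 0:
            raise AlignmentError("local alignment score cannot be negative")
        if self.orientation not in ("normal", "reversed"):
            raise AlignmentError(f"bad orientation {self.orientation!r}")

    @property
    def is_empty(self) -> bool:
        return len(self.aligned_query) == 0

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    @property
    def identity_pct(self) -> float:
        return percent_identity(self)


def percent_identity(aln: PairwiseAlignment) -> float:
    """Percent of alignment columns with identical residues.

    Gapped columns count in the denominator (the conservative convention),
    so identity over a gappy alignment cannot exceed identity over its
    matched columns alone.
    """
    if aln.is_empty:
        raise AlignmentError("percent identity undefined for an empty alignment")
    matches = sum(
        q == t and q != GAP_CHAR
        for q, t in zip(aln.aligned_query, aln.aligned_target)
    )
    return 100.0 * matches / aln.n_columns


def _as_residues(seq: str | ProteinSequence) -> tuple[str, str]:
    if isinstance(seq, ProteinSequence):
        return seq.residues, seq.id
    return seq, ""


_EPS = 1e-9


def smith_waterman(
    a: str | ProteinSequence,
    b: str | ProteinSequence,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    *,
    orientation: str = "normal",
    permissive: bool = False,
) -> PairwiseAlignment:
    """Optimal local alignment of ``a`` (query) against ``b`` (target).

    Affine gap penalties: a gap of length L costs gap_open + L*gap_extend.
    Ties are broken deterministically: the alignment ends at the first
    (row-major) maximum of the score matrix and the traceback prefers
    diagonal over up (gap in target) over left (gap in query), so repeated
    runs yield byte-identical alignments.
    """
    a_res, a_id = _as_residues(a)
    b_res, b_id = _as_residues(b)
    if not a_res or not b_res:
        raise AlignmentError("both sequences must be non-empty")
    if gap_open < 0 or gap_extend <= 0:
        raise AlignmentError("gap penalties must be positive")
    matrix = matrix or load_matrix()
    ac = matrix.encode(a_res, permissive=permissive)
    bc = matrix.encode(b_res, permissive=permissive)
    H, E, F = _sw.sw_matrices(ac, bc, matrix.scores, float(gap_open), float(gap_extend))

    flat = int(np.argmax(H))  # first occurrence, row-major: smallest (i, j)
    i, j = divmod(flat, H.shape[1])
    best = float(H[i, j])
    if best <= 0.0:
        return PairwiseAlignment(a_id, b_id, "", "", 0.0, 0, 0, 0, 0, orientation)

    open_cost = gap_open + gap_extend
    cols_q: list[str] = []
    cols_t: list[str] = []
    q_end, t_end = i, j
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if h <= _EPS:
                break
            s = matrix.scores[ac[i - 1], bc[j - 1]]
            if abs(h - (H[i - 1, j - 1] + s)) <= _EPS:
                cols_q.append(a_res[i - 1])
                cols_t.append(b_res[j - 1])
                i -= 1
                j -= 1
            elif abs(h - F[i, j]) <= _EPS:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in target: consume query residue
            cols_q.append(a_res[i - 1])
            cols_t.append(GAP_CHAR)
            came_open = abs(F[i, j] - (H[i - 1, j] - open_cost)) <= _EPS
            i -= 1
            state = "H" if came_open else "F"
        else:  # state "E": gap in query: consume target residue
            cols_q.append(GAP_CHAR)
            cols_t.append(b_res[j - 1])
            came_open = abs(E[i, j] - (H[i, j - 1] - open_cost)) <= _EPS
            j -= 1
            state = "H" if came_open else "E"

    return PairwiseAlignment(
        query_id=a_id,
        target_id=b_id,
        aligned_query="".join(reversed(cols_q)),
        aligned_target="".join(reversed(cols_t)),
        score=best,
        q_start=i,
        q_end=q_end,
        t_start=j,
        t_end=t_end,
        orientation=orientation,
    )


def local_score(
    a: str | np.ndarray,
    b: str | np.ndarray,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    *,
    permissive: bool = False,
) -> float:
    """Score-only Smith–Waterman (fast path, no traceback)."""
    matrix = matrix or load_matrix()
    ac = a if isinstance(a, np.ndarray) else matrix.encode(a, permissive=permissive)
    bc = b if isinstance(b, np.ndarray) else matrix.encode(b, permissive=permissive)
    return float(_sw.sw_score(ac, bc, matrix.scores, float(gap_open), float(gap_extend)))


@dataclass(frozen=True)
class EvalueEstimate:
    """Shuffle-based significance of an alignment score.

    ``n_ge`` counts shuffled-query scores at least as high as the observed
    score; ``p_emp`` is the add-one empirical p-value and ``evalue`` its
    database-size multiple.
    """

    score: float
    n_shuffles: int
    n_ge: int
    db_size: int
    seed: int

    @property
    def p_emp(self) -> float:
        return (self.n_ge + 1) / (self.n_shuffles + 1)

    @property
    def evalue(self) -> float:
        return self.p_emp * self.db_size


def empirical_evalue(
    query: str | ProteinSequence,
    target: str | ProteinSequence,
    score: float,
    n_shuffles: int = 199,
    db_size: int = 1,
    seed: int = 0,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    *,
    permissive: bool = False,
) -> EvalueEstimate:
    """Estimate alignment-score significance by shuffling the query.

    The query is permuted ``n_shuffles`` times (composition preserved) and
    each permutation is re-scored against the target; deterministic for a
    fixed seed.
    """
    if n_shuffles < 99:
        raise ValueError("n_shuffles must be at least 99 for usable resolution")
    if db_size < 1:
        raise ValueError("db_size must be >= 1")
    matrix = matrix or load_matrix()
    q_res, _ = _as_residues(query)
    t_res, _ = _as_residues(target)
    qc = matrix.encode(q_res, permissive=permissive)
    tc = matrix.encode(t_res, permissive=permissive)
    rng = np.random.default_rng(seed)
    shuffles = rng.permuted(np.tile(qc, (n_shuffles, 1)), axis=1)
    decoy_scores = _sw.sw_score_batch(
        shuffles, tc, matrix.scores, float(gap_open), float(gap_extend)
    )
    n_ge = int(np.sum(decoy_scores >= score - _EPS))
    return EvalueEstimate(score, n_shuffles, n_ge, db_size, seed)


HIT_TSV_HEADER = (
    "query_id\ttarget_id\torientation\tscore\tidentity_pct\t"
    "q_start\tq_end\tt_start\tt_end\tp_emp\tevalue\n"
)


def alignments_to_tsv(
    rows: Iterable[tuple[PairwiseAlignment, EvalueEstimate]], path: str | Path
) -> None:
    """Tabular hit export (1-based inclusive coordinates, BLAST-outfmt-like)."""
    with Path(path).open("w") as fh:
        fh.write(HIT_TSV_HEADER)
        for aln, est in rows:
            ident = f"{percent_identity(aln):.2f}" if not aln.is_empty else "NA"
            fh.write(
                f"{aln.query_id}\t{aln.target_id}\t{aln.orientation}\t{aln.score:.1f}\t"
                f"{ident}\t{aln.q_start + 1}\t{aln.q_end}\t{aln.t_start + 1}\t{aln.t_end}\t"
                f"{est.p_emp:.6g}\t{est.evalue:.6g}\n"
            )
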