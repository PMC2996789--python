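"""The retro-MoRF decision core: three-criterion classification of hits.

A fragment F that binds a partner through a MoRF, and a database segment rF
whose sequence reads as the reverse of F, are judged likely to share
binding capability when

1. the local-alignment sequence identity between them exceeds 60%
   (strictly — identity of exactly 60% fails);
2. the aligned segment shows a similar hydrophobic/charge pattern,
   operationalised here as the fraction of alignment columns whose
   residues fall in the same physicochemical class;
3. the aligned segment sits in a disorder-favourable context: inside or
   flanked by substantial disordered regions, or in a disordered tail.
   Short disordered runs bridging two ordered domains are treated as
   linkers, not binding regions, and fail this criterion.

Amphipathicity (helical-wheel hydrophobic moment) and polyproline-II
SH3-ligand motifs are computed as supporting annotations, not hard gates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .align import GAP_CHAR, PairwiseAlignment
from .disorder import DisorderProfile, DisorderSegment, ResidueScale, get_scale
from .sequence_io import AMINO_ACIDS, ProteinSequence

DEFAULT_IDENTITY_THRESHOLD = 60.0
DEFAULT_PATTERN_THRESHOLD = 0.6
DEFAULT_MIN_BINDING_REGION_LEN = 50


@dataclass(frozen=True)
class ResidueClassMap:
    """Partition of the 20 residues into physicochemical classes."""

    classes: dict[str, frozenset[str]] = field(
        default_factory=lambda: {
            "hydrophobic": frozenset("ACFILMVW"),
            "polar": frozenset("GNQSTYP"),
            "positive": frozenset("KRH"),
            "negative": frozenset("DE"),
        }
    )

    def __post_init__(self) -> None:
        covered: set[str] = set()
        for members in self.classes.values():
            if covered & members:
                raise ValueError("residue classes must be disjoint")
            covered |= members
        if covered != set(AMINO_ACIDS):
            raise ValueError("residue classes must cover exactly the 20 residues")

    def class_of(self, residue: str) -> str:
        for name, members in self.classes.items():
            if residue in members:
                return name
        return "special"  # ambiguity codes


DEFAULT_CLASSES = ResidueClassMap()


class DisorderContext(str, Enum):
    """Disorder environment of an aligned span on the target sequence."""

    FLANKED_BY_DISORDER = "flanked_by_disorder"
    DISORDERED_TAIL = "disordered_tail"
    SHORT_LINKER = "short_linker"
    ORDERED = "ordered"


@dataclass(frozen=True)
class ContextParams:
    """Parameters for classifying the disorder context of a span.

    min_binding_region_len separates genuine disordered binding regions
    from short inter-domain linkers; adjacency_tol is the largest gap
    allowed between the span and a bordering disordered segment (None
    derives half the profile window, the most the windowed smoothing can
    displace a threshold crossing away from a composition boundary).
    """

    min_binding_region_len: int = DEFAULT_MIN_BINDING_REGION_LEN
    adjacency_tol: int | None = None


def pattern_similarity(
    aln: PairwiseAlignment, classes: ResidueClassMap = DEFAULT_CLASSES
) -> float:
    """Fraction of alignment columns whose residues share a residue class.

    Gap columns count as mismatches; range [0, 1].  Because identical
    residues are necessarily same-class, this is never below the
    (fractional) identity of the same alignment.
    """
    if aln.is_empty:
        raise ValueError("pattern similarity undefined for an empty alignment")
    same = 0
    for q, t in zip(aln.aligned_query, aln.aligned_target):
        if q == GAP_CHAR or t == GAP_CHAR:
            continue
        if classes.class_of(q) == classes.class_of(t):
            same += 1
    return same / aln.n_columns


def hydrophobic_moment(
    window: str | ProteinSequence,
    delta_deg: float = 100.0,
    hydropathy: ResidueScale | None = None,
) -> float:
    """Helical-wheel hydrophobic moment of a residue window.

    mu_H = |sum_k H_k (cos k*delta, sin k*delta)| / n with delta = 100 deg
    for an alpha-helix (3.6 residues/turn); H_k are raw hydropathy values.
    Reversal-invariant: reading the window backwards conjugates the vector
    sum and leaves its magnitude unchanged, which is why amphipathic
    patterns survive sequence reversal.
    """
    if isinstance(window, ProteinSequence):
        window = window.residues
    if len(window) < 2:
        raise ValueError("hydrophobic moment needs a window of length >= 2")
    hydropathy = hydropathy or get_scale("hydropathy")
    h = np.array([hydropathy.raw_value(r) for r in window])
    angles = np.deg2rad(delta_deg) * np.arange(len(window))
    return float(np.hypot(h @ np.cos(angles), h @ np.sin(angles)) / len(window))


@dataclass(frozen=True)
class PpiiMotif:
    """One SH3-ligand polyproline-II motif occurrence (1-based inclusive)."""

    motif_class: str  # "I" (RxxPxxP) or "II" (PxxPxR)
    start: int
    end: int
    sequence: str


_PPII_PATTERNS = (
    ("I", re.compile(r"(?=(R..P..P))")),
    ("II", re.compile(r"(?=(P..P.R))")),
)


def find_ppii_motifs(seq: str | ProteinSequence) -> list[PpiiMotif]:
    """All class I (RxxPxxP) and class II (PxxPxR) SH3-ligand motifs.

    PPII helices have three residues per turn and near-threefold symmetry,
    so these proline-core motifs can engage SH3 domains in either chain
    direction — class I and class II ligands bind in opposite orientations.
    Overlapping occurrences are all reported.
    """
    if isinstance(seq, ProteinSequence):
        seq = seq.residues
    hits = [
        PpiiMotif(cls, m.start() + 1, m.start() + len(m.group(1)), m.group(1))
        for cls, pat in _PPII_PATTERNS
        for m in pat.finditer(seq)
    ]
    return sorted(hits, key=lambda h: (h.start, h.motif_class))


def disorder_context(
    span: tuple[int, int],
    profile: DisorderProfile,
    segments: list[DisorderSegment],
    params: ContextParams | None = None,
) -> DisorderContext:
    """Classify the disorder environment of a span (0-based half-open).

    ordered            span and both local flanks score below threshold
    disordered_tail    the disordered run containing/bordering the span
                       touches a sequence terminus
    short_linker       the span lies in a disordered run shorter than
                       min_binding_region_len bridging two ordered regions
    flanked_by_disorder  otherwise: inside, or bordered on both sides by,
                       qualifying disordered runs
    """
    params = params or ContextParams()
    start, end = span
    n = len(profile)
    if not 0 <= start < end <= n:
        raise ValueError(f"span [{start}, {end}) outside profile of length {n}")
    tol = params.adjacency_tol if params.adjacency_tol is not None else profile.window // 2

    containing = next(
        (s for s in segments if s.start <= start and end <= s.end), None
    )
    if containing is not None:
        n_termini = int(containing.start == 0) + int(containing.end == n)
        if n_termini == 1:
            return DisorderContext.DISORDERED_TAIL
        # n_termini == 2 means the whole sequence is disordered: the span is
        # surrounded by disorder on both sides, not in a tail
        if n_termini == 0 and containing.length < params.min_binding_region_len:
            return DisorderContext.SHORT_LINKER
        return DisorderContext.FLANKED_BY_DISORDER

    left_seg = next(
        (s for s in reversed(segments) if s.end >= start - tol and s.start < start), None
    )
    right_seg = next(
        (s for s in segments if s.start <= end + tol and s.end > end), None
    )
    if left_seg is not None and right_seg is not None:
        return DisorderContext.FLANKED_BY_DISORDER
    if right_seg is not None and start <= tol:
        return DisorderContext.DISORDERED_TAIL
    if left_seg is not None and end >= n - tol:
        return DisorderContext.DISORDERED_TAIL
    if left_seg is not None or right_seg is not None:
        return DisorderContext.FLANKED_BY_DISORDER

    # no qualifying disordered run contains or borders the span: the span
    # and its local flanks sit below threshold (up to the min-length filter)
    return DisorderContext.ORDERED


@dataclass(frozen=True)
class RibsParams:
    """Thresholds for the three-criterion verdict."""

    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD  # strict >
    pattern_threshold: float = DEFAULT_PATTERN_THRESHOLD  # >=


@dataclass(frozen=True)
class RibsVerdict:
    """Per-hit evaluation of the three criteria plus the final label."""

    identity_pct: float
    pattern_similarity: float
    context: DisorderContext
    criterion1: bool
    criterion2: bool
    criterion3: bool
    label: str  # retro_morf_candidate | morf_match | rejected
    reasons: tuple[str, ...]

    @property
    def is_positive(self) -> bool:
        return self.label != "rejected"


def classify_ribs(
    identity_pct: float,
    pattern_sim: float,
    context: DisorderContext,
    params: RibsParams | None = None,
    orientation: str = "reversed",
) -> RibsVerdict:
    """Combine the three criteria into a verdict.

    Criterion 1 is a strict inequality: identity of exactly the threshold
    (60%) is rejected.  A positive verdict on a reversed-orientation hit is
    labelled retro_morf_candidate; on a normal-orientation hit, morf_match.
    """
    params = params or RibsParams()
    c1 = identity_pct > params.identity_threshold
    c2 = pattern_sim >= params.pattern_threshold
    c3 = context in (DisorderContext.FLANKED_BY_DISORDER, DisorderContext.DISORDERED_TAIL)
    reasons: list[str] = []
    if not c1:
        reasons.append(
            f"criterion1: identity {identity_pct:.1f}% not above {params.identity_threshold:.0f}%"
        )
    if not c2:
        reasons.append(
            f"criterion2: pattern similarity {pattern_sim:.2f} below {params.pattern_threshold:.2f}"
        )
    if not c3:
        reasons.append(f"criterion3: disorder context is {context.value}")
    if c1 and c2 and c3:
        label = "retro_morf_candidate" if orientation == "reversed" else "morf_match"
    else:
        label = "rejected"
    return RibsVerdict(
        identity_pct=identity_pct,
        pattern_similarity=pattern_sim,
        context=context,
        criterion1=c1,
        criterion2=c2,
        criterion3=c3,
        label=label,
        reasons=tuple(reasons),
    )
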