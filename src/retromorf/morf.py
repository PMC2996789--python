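"""Dip detection: MoRF candidates inside predicted disordered regions.

A molecular recognition feature (MoRF) is a short segment that sits inside
an intrinsically disordered region but is itself structure-prone, typically
because it is enriched in hydrophobic residues relative to its disordered
surroundings.  On a disorder-score track such a segment appears as a *dip*:
a short run of sub-threshold scores bordered by long high-scoring runs.
This module finds those dips and annotates their hydrophobic enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .disorder import DisorderProfile
from .sequence_io import ProteinSequence

#: standard apolar residue set used for enrichment annotation.
HYDROPHOBIC_SET = frozenset("ACFILMVW")


@dataclass(frozen=True)
class DipParams:
    """Tunable bounds on what counts as a MoRF-candidate dip.

    threshold        order/disorder boundary on the profile scores
    min_dip_len /
    max_dip_len      admissible dip lengths, in residues (MoRFs are short)
    min_flank_len    minimum length of each adjacent disordered run
    min_depth        minimum (flank mean − dip mean) score contrast
    allow_tail       admit single-flank dips that touch a sequence terminus
    """

    threshold: float = 0.5
    min_dip_len: int = 5
    max_dip_len: int = 30
    min_flank_len: int = 10
    min_depth: float = 0.2
    allow_tail: bool = True


@dataclass(frozen=True)
class MorfCandidate:
    """One dip interval (0-based half-open) with its flank statistics."""

    seq_id: str
    start: int
    end: int
    dip_mean: float
    left_flank_len: int
    right_flank_len: int
    flank_mean: float
    is_tail: bool = False
    hydro_enrichment: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def depth(self) -> float:
        return self.flank_mean - self.dip_mean

    def satisfies(self, params: DipParams) -> bool:
        """Self-audit: re-validate this candidate against a parameter set."""
        if not params.min_dip_len <= self.length <= params.max_dip_len:
            return False
        if self.depth < params.min_depth:
            return False
        flanks = [l for l in (self.left_flank_len, self.right_flank_len) if l > 0]
        if self.is_tail:
            if not params.allow_tail or len(flanks) != 1:
                return False
        elif len(flanks) != 2:
            return False
        return all(l >= params.min_flank_len for l in flanks)


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of a boolean mask as (start, end, value) triples."""
    runs = []
    start = 0
    for i in range(1, mask.size + 1):
        if i == mask.size or mask[i] != mask[start]:
            runs.append((start, i, bool(mask[start])))
            start = i
    return runs


def detect_dips(profile: DisorderProfile, params: DipParams | None = None) -> list[MorfCandidate]:
    """Find all dips in a disorder profile that satisfy the parameter bounds.

    A dip is a maximal run of scores below the threshold bordered on both
    sides (or on one side, for dips touching a terminus when ``allow_tail``
    is set) by disordered runs of at least ``min_flank_len`` residues.
    Candidates are non-overlapping and sorted by start position.
    """
    params = params or DipParams()
    scores = profile.scores
    runs = _runs(scores >= params.threshold)
    candidates: list[MorfCandidate] = []
    for k, (start, end, disordered) in enumerate(runs):
        if disordered:
            continue
        left = runs[k - 1] if k > 0 else None
        right = runs[k + 1] if k + 1 < len(runs) else None
        left_len = (left[1] - left[0]) if left else 0
        right_len = (right[1] - right[0]) if right else 0
        left_ok = left is not None and left_len >= params.min_flank_len
        right_ok = right is not None and right_len >= params.min_flank_len
        is_tail = False
        if left_ok and right_ok:
            flank_idx = np.r_[left[0]:left[1], right[0]:right[1]]
        elif params.allow_tail and start == 0 and right_ok:
            flank_idx = np.arange(right[0], right[1])
            left_len, is_tail = 0, True
        elif params.allow_tail and end == scores.size and left_ok:
            flank_idx = np.arange(left[0], left[1])
            right_len, is_tail = 0, True
        else:
            continue
        cand = MorfCandidate(
            seq_id=profile.seq_id,
            start=start,
            end=end,
            dip_mean=float(scores[start:end].mean()),
            left_flank_len=left_len,
            right_flank_len=right_len,
            flank_mean=float(scores[flank_idx].mean()),
            is_tail=is_tail,
        )
        if cand.satisfies(params):
            candidates.append(cand)
    return candidates


def hydrophobic_enrichment(
    seq: ProteinSequence,
    cand: MorfCandidate,
    hydro_set: frozenset[str] = HYDROPHOBIC_SET,
) -> float:
    """Hydrophobic-content contrast between a dip and its disordered flanks.

    Returns the fraction of hydrophobic residues inside the dip minus the
    fraction over the adjacent disordered runs; range [-1, 1].  A difference
    rather than a ratio, so hydrophobe-free flanks are well defined.
    """
    if not 0 <= cand.start < cand.end <= len(seq):
        raise ValueError(f"candidate interval [{cand.start}, {cand.end}) outside sequence")
    if not cand.is_tail and (cand.left_flank_len == 0 or cand.right_flank_len == 0):
        raise ValueError("non-tail candidate with a zero-length flank")
    dip = seq.residues[cand.start : cand.end]
    flank = (
        seq.residues[cand.start - cand.left_flank_len : cand.start]
        + seq.residues[cand.end : cand.end + cand.right_flank_len]
    )
    frac_dip = sum(r in hydro_set for r in dip) / len(dip)
    frac_flank = sum(r in hydro_set for r in flank) / len(flank) if flank else 0.0
    return frac_dip - frac_flank


def annotate_candidates(
    seq: ProteinSequence,
    profile: DisorderProfile,
    params: DipParams | None = None,
    hydro_set: frozenset[str] = HYDROPHOBIC_SET,
) -> list[MorfCandidate]:
    """Detect dips and attach hydrophobic-enrichment annotation."""
    cands = detect_dips(profile, params)
    return [
        replace(c, hydro_enrichment=hydrophobic_enrichment(seq, c, hydro_set))
        for c in cands
    ]


def rank_candidates(cands: list[MorfCandidate]) -> list[MorfCandidate]:
    """Order candidates for screening: deepest dip first, then most enriched."""
    return sorted(
        cands,
        key=lambda c: (-c.depth, -(c.hydro_enrichment if c.hydro_enrichment is not None else -2.0), c.start),
    )


def extract_fragment(seq: ProteinSequence, cand: MorfCandidate) -> ProteinSequence:
    """Cut the dip interval out of its parent sequence as a query fragment.

    The fragment id records the parent id and the 1-based inclusive span.
    """
    return ProteinSequence(
        id=f"{seq.id}:{cand.start + 1}-{cand.end}",
        residues=seq.residues[cand.start : cand.end],
        description=f"MoRF candidate from {seq.id}",
        ambiguous=seq.ambiguous,
    )


def candidates_to_bed(cands: list[MorfCandidate], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for c in cands:
            name = "morf_tail" if c.is_tail else "morf_dip"
            fh.write(f"{c.seq_id}\t{c.start}\t{c.end}\t{name}\t{c.depth:.4f}\n")


def candidates_to_tsv(cands: list[MorfCandidate], path: str | Path) -> None:
    """Full-field TSV export (1-based inclusive coordinates)."""
    cols = (
        "seq_id\tstart\tend\tlength\tdip_mean\tflank_mean\tdepth\t"
        "left_flank_len\tright_flank_len\thydro_enrichment\tis_tail\n"
    )
    with Path(path).open("w") as fh:
        fh.write(cols)
        for c in cands:
            enr = "" if c.hydro_enrichment is None else f"{c.hydro_enrichment:.4f}"
            fh.write(
                f"{c.seq_id}\t{c.start + 1}\t{c.end}\t{c.length}\t{c.dip_mean:.4f}\t"
                f"{c.flank_mean:.4f}\t{c.depth:.4f}\t{c.left_flank_len}\t"
                f"{c.right_flank_len}\t{enr}\t{c.is_tail}\n"
            )
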