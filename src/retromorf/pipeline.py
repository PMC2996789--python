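"""End-to-end orchestration: profile, detect, scan, classify, report.

The scan aligns every query fragment — and, when requested, its reversed
copy — against every database sequence, gates each pair on an empirical
shuffle p-value (the prescan, standing in for a fast database search with
an analytic E-value cut-off), and then evaluates the three retro-MoRF
criteria on the survivors using a disorder profile of the *target*
sequence around the matched span.  All randomness is derived from one run
seed, so identical inputs produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .align import (
    EvalueEstimate,
    PairwiseAlignment,
    alignments_to_tsv,
    empirical_evalue,
    load_matrix,
    percent_identity,
    smith_waterman,
)
from .disorder import (
    DisorderProfile,
    DisorderSegment,
    call_disordered_segments,
    disorder_profile,
)
from .morf import DipParams, annotate_candidates, extract_fragment
from .ribs import (
    ContextParams,
    RibsParams,
    RibsVerdict,
    classify_ribs,
    disorder_context,
    pattern_similarity,
)
from .sequence_io import ProteinSequence, reverse_sequence

#: smallest empirical p attainable with n shuffles is 1/(n+1); the default
#: prescan keeps a pair only when the observed score beats every decoy.
DEFAULT_PRESCAN_SHUFFLES = 199
DEFAULT_REPORT_SHUFFLES = 999
DEFAULT_PRESCAN_MAX_P = 1.0 / (DEFAULT_PRESCAN_SHUFFLES + 1)


@dataclass(frozen=True)
class ScanParams:
    """Every knob of the scan, in one place (YAML-overridable via the CLI)."""

    orientation: str = "both"  # normal | reversed | both
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    prescan_shuffles: int = DEFAULT_PRESCAN_SHUFFLES
    report_shuffles: int = DEFAULT_REPORT_SHUFFLES
    prescan_max_p: float = DEFAULT_PRESCAN_MAX_P
    max_evalue: float | None = None
    window: int = 21
    scale: str = "top_idp"
    disorder_threshold: float = 0.5
    min_segment_len: int = 4
    dip: DipParams = field(default_factory=DipParams)
    context: ContextParams = field(default_factory=ContextParams)
    ribs: RibsParams = field(default_factory=RibsParams)
    permissive: bool = False


@dataclass(frozen=True)
class ScanHit:
    """One prescan-surviving alignment with its E-value and verdict."""

    query_id: str  # id of the un-reversed query fragment
    orientation: str
    target_id: str
    alignment: PairwiseAlignment
    evalue: EvalueEstimate
    verdict: RibsVerdict


def _orientations(mode: str) -> list[str]:
    if mode not in ("normal", "reversed", "both"):
        raise ValueError(f"bad orientation mode {mode!r}")
    return ["normal", "reversed"] if mode == "both" else [mode]


def _target_profile(
    cache: dict[str, tuple[DisorderProfile, list[DisorderSegment]]],
    target: ProteinSequence,
    params: ScanParams,
) -> tuple[DisorderProfile, list[DisorderSegment]]:
    if target.id not in cache:
        prof = disorder_profile(
            target, params.scale, params.window, params.disorder_threshold
        )
        segs = call_disordered_segments(prof, min_len=params.min_segment_len)
        cache[target.id] = (prof, segs)
    return cache[target.id]


def scan_database(
    queries: list[ProteinSequence],
    db: list[ProteinSequence],
    orientation: str = "both",
    params: ScanParams | None = None,
    seed: int = 0,
) -> list[ScanHit]:
    """Scan query fragments against a database in the requested orientations.

    Per query x target x orientation: local alignment, prescan shuffle
    p-value (query shuffles, composition preserved); survivors get a
    higher-resolution E-value, target-side disorder context and the
    three-criterion verdict.  Hits are sorted by E-value then score.
    """
    if not queries or not db:
        raise ValueError("queries and database must be non-empty")
    params = params or ScanParams()
    matrix = load_matrix(params.matrix_name)
    cache: dict[str, tuple[DisorderProfile, list[DisorderSegment]]] = {}
    hits: list[ScanHit] = []
    counter = 0
    for query in queries:
        for orient in _orientations(orientation):
            q = query if orient == "normal" else reverse_sequence(query)
            for target in db:
                pair_seed = (seed * 1_000_003 + counter) % (2**31)
                counter += 2
                aln = smith_waterman(
                    q, target, matrix, params.gap_open, params.gap_extend,
                    orientation=orient, permissive=params.permissive,
                )
                if aln.score <= 0.0:
                    continue
                prescan = empirical_evalue(
                    q.residues, target.residues, aln.score,
                    n_shuffles=params.prescan_shuffles, db_size=len(db),
                    seed=pair_seed, matrix=matrix,
                    gap_open=params.gap_open, gap_extend=params.gap_extend,
                    permissive=params.permissive,
                )
                if prescan.p_emp > params.prescan_max_p:
                    continue
                est = empirical_evalue(
                    q.residues, target.residues, aln.score,
                    n_shuffles=params.report_shuffles, db_size=len(db),
                    seed=(pair_seed + 1) % (2**31), matrix=matrix,
                    gap_open=params.gap_open, gap_extend=params.gap_extend,
                    permissive=params.permissive,
                )
                if params.max_evalue is not None and est.evalue > params.max_evalue:
                    continue
                profile, segments = _target_profile(cache, target, params)
                context = disorder_context(
                    (aln.t_start, aln.t_end), profile, segments, params.context
                )
                verdict = classify_ribs(
                    percent_identity(aln),
                    pattern_similarity(aln),
                    context,
                    params.ribs,
                    orientation=orient,
                )
                hits.append(
                    ScanHit(query.id, orient, target.id, aln, est, verdict)
                )
    hits.sort(
        key=lambda h: (h.evalue.evalue, -h.alignment.score, h.query_id, h.target_id)
    )
    return hits


def run_scan(
    query_protein: ProteinSequence,
    db: list[ProteinSequence],
    orientation: str = "both",
    params: ScanParams | None = None,
    seed: int = 0,
) -> tuple[list[ScanHit], list[ProteinSequence]]:
    """Full protocol from a whole query protein.

    Profiles the query, extracts MoRF-candidate dips as fragments, and
    scans them against the database.  Returns the hits and the fragments.
    """
    params = params or ScanParams()
    profile = disorder_profile(
        query_protein, params.scale, params.window, params.disorder_threshold
    )
    cands = annotate_candidates(query_protein, profile, params.dip)
    fragments = [extract_fragment(query_protein, c) for c in cands]
    if not fragments:
        return [], []
    return scan_database(fragments, db, orientation, params, seed), fragments


@dataclass(frozen=True)
class RunSummary:
    """Bookkeeping over one scan: hit and positive counts, overall, per
    orientation and per query."""

    n_hits: int
    n_positive: int
    by_orientation: dict[str, dict[str, int]]
    per_query: dict[str, dict[str, int]]

    def to_dict(self) -> dict:
        return {
            "n_hits": self.n_hits,
            "n_positive": self.n_positive,
            "by_orientation": self.by_orientation,
            "per_query": self.per_query,
        }


def summarize_run(hits: list[ScanHit]) -> RunSummary:
    """Count hits and positive verdicts overall, per orientation, per query."""
    by_orient: dict[str, dict[str, int]] = {}
    per_query: dict[str, dict[str, int]] = {}
    for h in hits:
        for bucket, key in ((by_orient, h.orientation), (per_query, h.query_id)):
            row = bucket.setdefault(key, {"hits": 0, "positives": 0})
            row["hits"] += 1
            row["positives"] += int(h.verdict.is_positive)
    return RunSummary(
        n_hits=len(hits),
        n_positive=sum(int(h.verdict.is_positive) for h in hits),
        by_orientation=by_orient,
        per_query=per_query,
    )


def hits_to_tsv(hits: list[ScanHit], path: str | Path) -> None:
    alignments_to_tsv([(h.alignment, h.evalue) for h in hits], path)


def verdicts_to_json(hits: list[ScanHit], path: str | Path) -> None:
    rows = []
    for h in hits:
        rows.append(
            {
                "query_id": h.query_id,
                "target_id": h.target_id,
                "orientation": h.orientation,
                "score": h.alignment.score,
                "identity_pct": h.verdict.identity_pct,
                "pattern_similarity": h.verdict.pattern_similarity,
                "context": h.verdict.context.value,
                "p_emp": h.evalue.p_emp,
                "evalue": h.evalue.evalue,
                "criterion1": h.verdict.criterion1,
                "criterion2": h.verdict.criterion2,
                "criterion3": h.verdict.criterion3,
                "label": h.verdict.label,
                "reasons": list(h.verdict.reasons),
                "q_span": [h.alignment.q_start + 1, h.alignment.q_end],
                "t_span": [h.alignment.t_start + 1, h.alignment.t_end],
            }
        )
    with Path(path).open("w") as fh:
        json.dump(rows, fh, indent=2)


def summary_to_json(summary: RunSummary, path: str | Path, **extra) -> None:
    payload = summary.to_dict()
    payload.update(extra)
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=2)
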