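"""FASTA I/O and the sequence primitives the rest of the package builds on.

Sequences are plain upper-case strings over the 20-letter amino-acid
alphabet.  A permissive mode additionally admits the common ambiguity
codes (X, B, Z, U); records containing them are flagged so downstream
scoring can treat them neutrally.

Coordinates are 0-based half-open everywhere inside the package; any
user-facing report converts to 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_CODES = "XBZU"

#: marker appended to (or stripped from) a record id on reversal, so every
#: hit stays traceable to the orientation of the query actually aligned.
REVERSAL_MARKER = "|rev"


class SequenceError(ValueError):
    """Raised for malformed FASTA records or illegal residues."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence record.

    Parameters
    ----------
    id:
        Record identifier; must be unique within a loaded database.
    residues:
        Upper-case amino-acid string (non-empty).
    description:
        Optional free text from the FASTA header.
    ambiguous:
        True when the record contains ambiguity codes (permissive mode only).
    """

    id: str
    residues: str
    description: str = ""
    ambiguous: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


def validate_residues(residues: str, record_id: str, *, permissive: bool = False) -> bool:
    """Check every character against the amino-acid alphabet.

    Returns True when the sequence contains ambiguity codes (only possible
    in permissive mode); raises :class:`SequenceError` naming the record and
    the 1-based position of the first offending character otherwise.
    """
    allowed = set(AMINO_ACIDS) | (set(AMBIGUITY_CODES) if permissive else set())
    ambiguous = False
    for pos, ch in enumerate(residues, start=1):
        if ch not in allowed:
            raise SequenceError(
                f"record {record_id!r}: illegal residue {ch!r} at position {pos}"
            )
        if ch in AMBIGUITY_CODES:
            ambiguous = True
    return ambiguous


def make_sequence(
    record_id: str, residues: str, description: str = "", *, permissive: bool = False
) -> ProteinSequence:
    """Normalise (upper-case, strip whitespace) and validate a sequence."""
    cleaned = "".join(residues.split()).upper()
    if not cleaned:
        raise SequenceError(f"record {record_id!r}: empty sequence")
    ambiguous = validate_residues(cleaned, record_id, permissive=permissive)
    return ProteinSequence(record_id, cleaned, description, ambiguous)


def read_fasta(path: str | Path, *, permissive: bool = False) -> list[ProteinSequence]:
    """Read a multi-record FASTA file into validated records.

    Residues are upper-cased with whitespace removed; record order is
    preserved. Duplicate ids raise. An empty file yields an empty list with
    a warning.
    """
    path = Path(path)
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SequenceError(f"{path}: record {len(records) + 1} has an empty header")
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(make_sequence(rec.id, str(rec.seq), desc, permissive=permissive))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(
    records: Iterable[ProteinSequence], path: str | Path, width: int = 60
) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width`` columns.

    Round-trips losslessly with :func:`read_fasta` for ids and residues.
    """
    if width < 1:
        raise ValueError("width must be a positive integer")
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def reverse_sequence(seq: ProteinSequence) -> ProteinSequence:
    """Return the retro-sequence: residues read backwards.

    Length and amino-acid composition are unchanged; only the reading
    direction flips. The id gains a reversal marker (or loses it again, so
    reversal is an involution on ids as well as residues).
    """
    if seq.id.endswith(REVERSAL_MARKER):
        new_id = seq.id[: -len(REVERSAL_MARKER)]
    else:
        new_id = seq.id + REVERSAL_MARKER
    return replace(seq, id=new_id, residues=seq.residues[::-1])


def shuffle_sequence(seq: ProteinSequence, seed: int) -> ProteinSequence:
    """Uniform random permutation of the residues; deterministic per seed.

    Composition (and therefore any composition-level statistic) is
    preserved exactly; used to build decoys for empirical E-values.
    """
    rng = np.random.default_rng(seed)
    shuffled = "".join(rng.permutation(list(seq.residues)))
    return replace(seq, id=f"{seq.id}|shuf{seed}", residues=shuffled)


def composition(residues: str | ProteinSequence) -> dict[str, int]:
    """Residue multiset as a letter -> count map."""
    if isinstance(residues, ProteinSequence):
        residues = residues.residues
    counts: dict[str, int] = {}
    for ch in residues:
        counts[ch] = counts.get(ch, 0) + 1
    return counts
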