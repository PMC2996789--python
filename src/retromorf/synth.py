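"""Seeded synthetic proteins with planted MoRFs / retro-MoRFs and truth tables.

The generator emulates the screening situation the package is built for:
long intrinsically disordered proteins (i.i.d. residues drawn from a
disorder-promoting composition) into which short hydrophobic-rich motifs
are planted, in normal or reversed orientation, optionally with point
mutations.  Hydrophobic-rich motifs in a disorder-promoting background
produce exactly the dip-in-a-disordered-region signature the detector
looks for, so every pipeline stage is testable end to end without any
external database.

It does not attempt realistic evolution: no indels, no substitution-model
divergence, no domain architecture — composition-level realism only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .disorder import get_scale
from .morf import HYDROPHOBIC_SET
from .sequence_io import AMINO_ACIDS, ProteinSequence

#: margin kept free of plants at each target terminus so both flanks of a
#: planted motif are substantial disordered runs.
PLANT_MARGIN = 50


def default_background_composition(top_k: int = 8, top_mass: float = 0.9) -> dict[str, float]:
    """Disorder-promoting residue frequencies.

    The ``top_k`` most disorder-promoting residues of the default scale
    (P, E, K, S, Q, H, D, R for the shipped TOP-IDP ordering) share
    ``top_mass`` uniformly; the remaining residues share the rest.
    """
    scale = get_scale("top_idp")
    ranked = sorted(AMINO_ACIDS, key=lambda r: -scale.values[r])
    top = ranked[:top_k]
    rest = ranked[top_k:]
    comp = {r: top_mass / len(top) for r in top}
    comp.update({r: (1.0 - top_mass) / len(rest) for r in rest})
    return comp


def generate_background(
    length: int, composition: dict[str, float] | None = None, seed: int = 0
) -> ProteinSequence:
    """I.i.d. residues from a frequency map; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be positive")
    composition = composition or default_background_composition()
    letters = sorted(composition)
    freqs = np.array([composition[r] for r in letters])
    if freqs.min() < 0 or abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError("composition frequencies must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list(letters), size=length, p=freqs / freqs.sum()))
    return ProteinSequence(f"bg_{seed}", residues, "synthetic disordered background")


def random_motif(length: int, seed: int, alphabet: frozenset[str] = HYDROPHOBIC_SET) -> ProteinSequence:
    """A hydrophobic-rich motif, so a plant carves a dip into the profile."""
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(sorted(alphabet), size=length))
    return ProteinSequence(f"motif_{seed}", residues, "synthetic planted motif")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted motif (0-based half-open span)."""

    target_id: str
    start: int
    end: int
    orientation: str  # normal | reversed
    motif_id: str
    n_mutations: int


def plant_motif(
    target: ProteinSequence,
    motif: str | ProteinSequence,
    position: int,
    reversed_: bool = False,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> tuple[ProteinSequence, TruthRecord]:
    """Overwrite a span of the target with a (possibly reversed) motif copy.

    Each planted position is mutated independently with probability
    ``mutation_rate`` to a uniformly chosen different residue.  The mutation
    coin flips and replacement letters are drawn from the seed independently
    of the rate, so sweeps over rates with a shared seed produce nested
    mutation sets (higher rate = superset of mutated positions).
    """
    motif_res = motif.residues if isinstance(motif, ProteinSequence) else motif
    motif_id = motif.id if isinstance(motif, ProteinSequence) else "motif"
    if not 0.0 <= mutation_rate < 1.0:
        raise ValueError("mutation_rate must lie in [0, 1)")
    if position < 0 or position + len(motif_res) > len(target):
        raise ValueError(
            f"motif of length {len(motif_res)} does not fit at position {position} "
            f"in target of length {len(target)}"
        )
    planted = motif_res[::-1] if reversed_ else motif_res
    rng = np.random.default_rng(seed)
    coins = rng.random(len(planted))
    # replacement pre-drawn per position: uniform over the 19 other residues
    repl_idx = rng.integers(0, 19, size=len(planted))
    mutated = []
    n_mut = 0
    for k, ch in enumerate(planted):
        if coins[k] < mutation_rate:
            others = AMINO_ACIDS.replace(ch, "")
            mutated.append(others[repl_idx[k]])
            n_mut += 1
        else:
            mutated.append(ch)
    new_res = target.residues[:position] + "".join(mutated) + target.residues[position + len(planted):]
    new_target = ProteinSequence(target.id, new_res, target.description, target.ambiguous)
    truth = TruthRecord(
        target_id=target.id,
        start=position,
        end=position + len(planted),
        orientation="reversed" if reversed_ else "normal",
        motif_id=motif_id,
        n_mutations=n_mut,
    )
    return new_target, truth


@dataclass(frozen=True)
class BenchmarkSpec:
    """Conditions of a planted-motif screening benchmark.

    Defaults describe the standard study setting: 50 disordered targets of
    300–600 residues, 10 planted exact reversed 15-mers, no normal-
    orientation plants, no mutations.
    """

    n_targets: int = 50
    target_length_range: tuple[int, int] = (300, 600)
    composition: dict[str, float] | None = None
    n_planted_normal: int = 0
    n_planted_reversed: int = 10
    motif_length_range: tuple[int, int] = (15, 15)
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_normal < 0 or self.n_planted_reversed < 0:
            raise ValueError("plant counts must be non-negative")
        if self.n_planted_normal + self.n_planted_reversed > self.n_targets:
            raise ValueError("more plants than targets")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must lie in [0, 1)")
        if self.motif_length_range[0] > self.motif_length_range[1]:
            raise ValueError("bad motif length range")
        max_motif = self.motif_length_range[1]
        if self.target_length_range[0] < max_motif + 2 * PLANT_MARGIN:
            raise ValueError("targets too short to host a motif with disordered flanks")


@dataclass(frozen=True)
class Benchmark:
    """Generated database plus ground truth and the source motifs."""

    spec: BenchmarkSpec
    targets: list[ProteinSequence]
    truth: list[TruthRecord]
    motifs: list[ProteinSequence]


def generate_benchmark(spec: BenchmarkSpec | None = None) -> Benchmark:
    """Build a fully seeded benchmark database with planted motifs.

    One motif is planted per chosen target (normal-orientation plants
    first); the remaining targets are pure background decoys.  Identical
    specs yield identical benchmarks.
    """
    spec = spec or BenchmarkSpec()
    rng = np.random.default_rng(spec.seed)
    comp = spec.composition or default_background_composition()
    n_plants = spec.n_planted_normal + spec.n_planted_reversed

    lengths = rng.integers(
        spec.target_length_range[0], spec.target_length_range[1] + 1, size=spec.n_targets
    )
    targets = []
    for i, L in enumerate(lengths):
        bg = generate_background(int(L), comp, seed=int(rng.integers(2**31)))
        targets.append(ProteinSequence(f"T{i:04d}", bg.residues, "synthetic target"))

    motifs = []
    for i in range(n_plants):
        mlen = int(rng.integers(spec.motif_length_range[0], spec.motif_length_range[1] + 1))
        m = random_motif(mlen, seed=int(rng.integers(2**31)))
        motifs.append(ProteinSequence(f"M{i:03d}", m.residues, m.description))

    planted_idx = rng.choice(spec.n_targets, size=n_plants, replace=False)
    truth: list[TruthRecord] = []
    for k, (ti, motif) in enumerate(zip(planted_idx, motifs)):
        reversed_ = k >= spec.n_planted_normal
        tgt = targets[ti]
        pos = int(rng.integers(PLANT_MARGIN, len(tgt) - PLANT_MARGIN - len(motif) + 1))
        new_tgt, rec = plant_motif(
            tgt, motif, pos, reversed_=reversed_,
            mutation_rate=spec.mutation_rate, seed=int(rng.integers(2**31)),
        )
        targets[ti] = new_tgt
        truth.append(rec)
    return Benchmark(spec, targets, truth, motifs)


def truth_to_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("target_id\tstart\tend\torientation\tmotif_id\tn_mutations\n")
        for r in truth:
            fh.write(
                f"{r.target_id}\t{r.start + 1}\t{r.end}\t{r.orientation}\t"
                f"{r.motif_id}\t{r.n_mutations}\n"
            )


def spec_to_json(spec: BenchmarkSpec, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(asdict(spec), fh, indent=2, default=list)
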