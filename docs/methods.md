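# Methods

## Disorder profiling

The per-residue disorder score is the mean, over a centred window, of a
published propensity scale min–max normalised to [0, 1] with 1 the most
disorder-promoting residue. Shipped scales: the TOP-IDP disorder-propensity
ordering (default) and Kyte–Doolittle hydropathy (sign-flipped before
normalisation so that, like every scale here, higher means more
disorder-promoting; the raw values are kept for the hydrophobic moment).
This profiler is intentionally **not** a trained disorder predictor — no
learned weights, no meta-prediction. The downstream logic needs only a
[0, 1] disorder track with the conventional 0.5 order/disorder boundary,
and a transparent composition profiler provides one with two properties a
trained model cannot guarantee: exact mirror symmetry under sequence
reversal, and full reproducibility from a 20-number table. Consequently the
profile reflects composition only, not local sequence patterns, and its
absolute values should not be compared with any particular predictor's.

Windows are **clipped** (shrunk) at the termini, not padded: padding would
break the reversal mirror symmetry that the whole retro-sequence argument
rests on. Defaults: window 21 (odd; smooth enough that single residues do
not flip order/disorder calls), threshold 0.5, minimum disordered-segment
length 4 (suppresses single-position flickers).

## Dip detection (MoRF candidates)

A dip is a maximal run of sub-threshold scores bordered on both sides by
disordered runs of ≥ `min_flank_len` residues; with `allow_tail` a run
touching a sequence terminus qualifies with a single flank. Defaults:
dip length 5–30 (MoRFs are short; ~20-residue windows are the norm in the
MoRF literature), `min_flank_len` 10, `min_depth` 0.2 (flank mean − dip
mean; separates sharp dips from noise). Hydrophobic enrichment is the
*difference* between the hydrophobic fraction inside the dip and over its
flanking disordered runs (a ratio would be undefined on hydrophobe-free
flanks); the hydrophobic set is the standard apolar {A, C, F, I, L, M, V, W}.
When a ranking is needed, candidates are ordered by depth, then enrichment —
a package convention, since no principled ordering is established.

## Alignment and empirical significance

Local alignment is Smith–Waterman with affine gaps (Gotoh), BLOSUM62
(loaded from Biopython's tables), gap open 11 / extend 1 — the classic
protein-BLAST parameterisation. Tie-breaking is fixed: the traceback starts
at the first (row-major) maximum of the score matrix and prefers diagonal
over up (gap in target) over left (gap in query), so runs are byte-for-byte
reproducible. Percent identity counts matching columns over **all** columns
including gapped ones — the conservative reading, stated explicitly because
the 60% identity gate depends on it. Identity is measured over the aligned
span, not the whole fragment.

Significance is empirical rather than analytic: the query is permuted
`n_shuffles` times (composition preserved) and re-scored, and
p_emp = (1 + #{decoy ≥ observed})/(n_shuffles + 1). The add-one form keeps
p_emp > 0 and makes it sub-uniform under the null by exchangeability (score
ties make it conservative). E-value = p_emp × database size. An add-one
estimate is bounded below by 1/(n_shuffles + 1), so analytic-style cut-offs
such as 10⁻³ or 10⁻⁴ are not reachable at practical shuffle counts; the
prescan therefore gates on **p_emp ≤ 1/(prescan_shuffles + 1)** — i.e. the
observed score must beat every decoy — which is the most stringent gate the
resolution allows. Defaults: 199 shuffles for the prescan (gate 0.005),
999 shuffles for the E-values attached to reported hits; an optional
`max_evalue` report filter is exposed for users who raise the shuffle count
and database size to where analytic-style thresholds become meaningful.

## The three-criterion verdict

1. **Identity strictly above 60%** on the aligned span. The boundary is
   strict: exactly 60.0% is rejected.
2. **Pattern similarity ≥ 0.6**: fraction of alignment columns whose
   residues share a physicochemical class (hydrophobic {A,C,F,I,L,M,V,W},
   polar {G,N,Q,S,T,Y,P}, positive {K,R,H}, negative {D,E}; gap columns
   count as mismatches). The class-match fraction is this package's
   operationalisation of "similar hydrophobic/charge pattern"; the 0.6
   default mirrors the stringency of the identity criterion. Because
   identical residues are same-class, pattern similarity ≥ identity/100 on
   any alignment.
3. **Disorder context** of the matched span on the *target* sequence
   (profiled once per target and cached): positive when the span lies
   inside, or is bordered by, called disordered segments
   (`flanked_by_disorder`), or when the containing/bordering disordered run
   touches exactly one terminus (`disordered_tail`). A span inside an
   interior disordered run shorter than `min_binding_region_len` (default
   50 — disordered runs of ~25–40 residues bridging ordered domains behave
   as linkers, not binding regions) is a `short_linker`; anything else is
   `ordered`. Both of the latter fail the criterion. The adjacency
   tolerance between a span and a bordering segment defaults to half the
   profile window — the most the windowed smoothing can displace a
   threshold crossing away from a composition boundary (a fixed small
   tolerance misses genuine dip flanks, which was observed directly on
   planted benchmarks).

A positive verdict on a reversed-orientation hit is labelled
`retro_morf_candidate`; on a normal-orientation hit, `morf_match`.
Amphipathicity (hydrophobic moment, δ = 100° for an α-helix, raw
Kyte–Doolittle values) and PPII motif hits are reported as supporting
annotations only — they never gate the verdict.

## Synthetic benchmark

The generator emulates the screening situation the tool targets: long
disordered proteins containing short structure-prone motifs in normal or
reversed orientation. Background residues are i.i.d. from a
disorder-promoting composition — the top 8 residues of the default scale
(P, E, K, S, Q, H, D, R) share 90% of the mass, the other 12 share 10% —
which yields an expected profile score of ≈ 0.68, comfortably disordered.
Planted motifs are drawn uniformly from the hydrophobic set so they carve
genuine dips into the profile. Standard conditions: 50 targets of 300–600
residues, 10 planted exact reversed 15-mers, one per target, ≥ 50 residues
from either terminus, mutation rate 0.

Point mutations on planted copies use per-position coin flips and
replacement letters drawn independently of the rate, so sweeping rates with
a shared seed produces *nested* mutation sets — a variance-reduction
coupling that makes recovery-vs-rate curves monotone without averaging over
many replicates.

What passing the benchmark does **not** show: the generator has no indels,
no evolutionary divergence, no domain architecture and no realistic
database redundancy, so recovery rates here say nothing about sensitivity
on real proteomes; they verify the machinery (orientation bookkeeping,
gating, context classification), not biological discovery rates.

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open; all text reports are 1-based
  inclusive.
- Score-equality comparisons in the traceback use an absolute tolerance of
  1e-9 (exact for integer matrices and integer gap penalties).
- An alignment with no positively scoring pair is returned empty with score
  0; percent identity and pattern similarity on an empty alignment raise
  rather than return a sentinel.
- Ambiguity codes (X/B/Z/U) are rejected by default; in permissive mode the
  record is flagged, scales score them 0.5 (neutral), hydropathy 0, and
  alignment maps them to the matrix's X column.
- Reversal toggles a `|rev` id suffix, so double reversal restores the id
  and every hit is traceable to the orientation actually aligned.
- All randomness (shuffles, generators) flows from explicit integer seeds;
  scan-internal per-pair seeds are derived deterministically from the run
  seed, so identical inputs give byte-identical reports.

## Problem sizes

The shipped test-suite and acceptance runs use the standard benchmark (50
targets, 10 plants, 199 prescan shuffles) and a 1,000-trial null
calibration; a full run of both completes in about a minute on one CPU,
scaling linearly in queries × targets × shuffles × alignment area.

## Known limitations

- The prescan is a linear scan; no heuristic seeding or indexing, so very
  large databases are slow.
- One optimal alignment per pair is reported; co-optimal alignments are
  not enumerated (determinism was preferred).
- The disorder profiler's composition basis means highly patterned but
  compositionally disordered sequences (e.g. strict repeats) are scored by
  composition alone.
- Binding partners themselves are never modelled; the verdict transfers an
  annotation hypothesis, it does not predict an interaction.
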