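# Methods

## Motif model

The LIR (LC3-interacting region) is a short linear motif of the form
Θ-x-x-Γ, with an aromatic residue (W/F/Y) docking into the first
hydrophobic pocket of the Atg8 fold and an aliphatic residue (I/L/V) into
the second. Two consensus definitions are implemented as position-class
patterns over the 20-letter alphabet:

* `xLIR` (6 positions):
  `(ADEFGLPRSK)(DEGMSTV)(WFY)(DEILQTV)(ADEFHIKLMPSTV)(ILV)`. Positions 3
  and 6 are the core residues.
* `WxxL` (4 positions): `(WFY)(any)(any)(ILV)`.

Scanning considers every overlapping window and keeps all matches —
no greedy consumption, since a protein can carry several candidate LIRs
(batch runs on real proteomes show more motifs than motif-containing
proteins). Coordinates are 0-based half-open internally and converted to
1-based inclusive at the reporting boundary, in one place. Windows
containing any non-canonical letter (X, B, Z, U, O, J) never match:
class membership is undefined for ambiguity codes, and the same rule
applies to scoring.

## PSSM

Published descriptions of the LIR predictor report a PSSM score per xLIR
hit but not the matrix construction, so the model here is the standard
log-odds estimator with additive smoothing:

    weight(p, a) = log2[(count(p, a) + c) / (n + 20 c)] − log2(b_a)

with pseudocount `c = 1.0` (default, any positive value keeps weights
finite), background `b` uniform at 0.05 (override with empirical
frequencies where available), and log base 2. Scores from this matrix
are therefore *not* numerically comparable to scores from the original
hosted predictor, whose matrix was never printed; the model is
serializable as a 6 × 20 TSV so that an externally obtained matrix can
be loaded in its place. Uniform training counts against a uniform
background give an all-zero matrix — a useful identity check.

Similarity to known LIRs is defined (no published definition exists) as:
exact identity at the core positions 3 and 6, at most `max_mismatches`
(default 2) differences over the four remaining positions.

## Disorder filter

A protein is called a LIRCP when at least one xLIR hit overlaps an
intrinsically disordered segment. Defaults:

* per-residue scores are thresholded at 0.5 (the conventional
  IUPred/ANCHOR operating point) and run-length encoded into segments;
* `min_overlap = 1` residue counts as overlapping — the published
  criterion says "within" a disordered region without stating a
  fraction, and any-overlap is the weaker reading; `min_overlap = 6`
  gives strict containment of the 6-mer;
* proteins with no disorder data are not called LIRCPs under the default
  `strict` policy; the `permissive` policy treats all their hits as
  anchored and flags the record `no-disorder-data`.

Reimplementing a disorder predictor is out of scope. The built-in
heuristic (windowed Kyte–Doolittle hydropathy combined with mean net
charge, window 21, squashed to [0, 1]) exists so the pipeline can run
without external tracks; it is a coarse folding-index-style rule, labeled
`source='builtin'`, and not equivalent to IUPred/ANCHOR output.

## Enrichment

GO annotations are projected onto a GO-slim with the map2slim
min-ancestor rule: an annotation term maps to the slim terms reachable
by an upward `is_a` path passing through no other slim term (naive
ancestor closure is available via `rule='closure'`). `part_of` edges are
ignored by default — the generic slim is `is_a`-dominated — and can be
included with a flag. Obsolete terms are parsed but never map; unknown
annotation terms are skipped with a log message unless strict mode is on.

Each slim category is tested with the exact hypergeometric upper tail
P(X ≥ x) for x LIRCPs among the n category members drawn from a universe
of N containing k LIRCPs. Only the pmf formula is published; the upper
tail is the standard over-representation convention and is adopted here.
The universe N defaults to the number of proteins with at least one GO
annotation (the published definition of "total proteins" is ambiguous)
and can be overridden with the full proteome size. Evaluation is
delegated to a log-space implementation, so proteome-scale N is exact to
floating-point precision.

BH adjustment runs within each namespace (MF/BP/CC) separately —
mirroring one distribution file per top-level hierarchy — followed by the
four-tier classification with inclusive boundaries at 0.01, 0.05 and 0.1.

Triage drops not-significant entries, keeps those sharing ≥ 1 GO term
with the packaged reference set (the printed terms associated with
experimentally validated LIRCPs; extensible by the caller), and
partitions by a user-supplied curation label map into groups A
(validated LIR), B (known Atg8 interactor), C (autophagy-linked), D
(no known link). The original grouping was manual literature curation,
so the labels are necessarily an input, not a computation.

## Synthetic fixtures

The generator emulates the quantities the pipeline consumes, with a
single seed fixing every draw:

* proteins of length 80–300 drawn from a uniform residue background;
  `round(n_proteins × plant_rate)` proteins (default rate 0.06,
  matching the observed 4–7 % LIRCP fraction per organism) receive one
  xLIR drawn uniformly from the consensus class product;
* `round(n_plants × anchored_fraction)` plants (default 0.5) are covered
  by a disordered segment; the rest are decoys guaranteed clear of
  disorder; unplanted proteins get a decoy segment half the time;
* in strict mode (the test default) background residues are
  rejection-resampled until no xLIR exists outside a planted site, which
  supports exact-count assertions; loose mode keeps the natural
  background rate (≈ 9 × 10⁻⁴ per window under uniform frequencies);
* the annotation generator emits a miniature ontology (three namespace
  roots, slim terms, a few non-slim leaves to exercise upward mapping)
  and assigns one term to pseudo-LIRCPs at `enriched_multiplier` (default
  10) times the 8 % background rate, recording realized counts.

What the fixtures do *not* emulate: real amino-acid composition and
domain architecture, correlated GO annotations, the true distribution of
disorder, or predictor noise in disorder calls. Passing the fixture
tests therefore demonstrates algorithmic correctness (exact recovery of
known plants, calibrated statistics), not predictive accuracy on real
proteomes — absolute LIRCP counts for real organisms depend on the 2014
proteome snapshots, the original disorder predictor and the original
PSSM, none of which are reproducible at desk scale, and only the
arithmetic relations among the published counts are asserted.

## Numerical choices

* Displayed percentages and ratios are rounded half-up to 2 decimals
  (`decimal.Decimal`), matching the published presentation; the ratio is
  undefined (None/empty) when there are no LIRCPs.
* Tie-break in result ordering: namespace, then adjusted p, then
  descending x, then term ID.
* Hypergeometric bounds (0 ≤ x ≤ min(n, k) ≤ N) and p ∈ [0, 1] are
  validated; violations raise rather than clamp.
* Problem sizes in the test and acceptance runs — 1,000 random sequences
  for the scanner oracle, universes N ≤ 15 for exhaustive enumeration,
  120–200-protein fixtures and 200 enrichment draws — were chosen as the
  smallest sizes at which the checked properties are non-trivial while
  the whole suite stays interactive.

## Known limitations

* Non-canonical LIRs (e.g. the CALCOCO2/NDP52 motif binding LC3C) are
  not predicted.
* PSSM scores differ numerically from the original hosted predictor
  (matrix never published).
* The built-in disorder heuristic is a rough folding-index rule; use
  real predictor output for serious work.
* Batch WxxL scanning reports relaxed-pattern hits but never uses them
  for the LIRCP call, which rests on xLIR only.
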