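# lirscan

Proteome-wide prediction of **LIR-motif-containing proteins (LIRCPs)** —
proteins that bind Atg8-family proteins (LC3/GABARAP) through a short
linear LC3-interacting region (LIR/AIM/LRS) — together with GO-slim
functional profiling of the predictions.

It is written for autophagy researchers and bioinformaticians who want to
screen a proteome (or a single sequence) for candidate Atg8 interactors
and ask which functional categories the candidates concentrate in.

## What it computes

**Motif scanning.** Two consensus patterns are matched at every position
of each protein:

- `xLIR`: `(ADEFGLPRSK)(DEGMSTV)(WFY)(DEILQTV)(ADEFHIKLMPSTV)(ILV)` — the
  extended six-position LIR consensus; positions 3 (aromatic) and 6
  (aliphatic) are the core residues that occupy the two hydrophobic
  pockets of the Atg8 fold.
- `WxxL`: `(WFY)xx(ILV)` — the relaxed classical pattern.

Each 6-mer hit can be scored with an additive log-odds PSSM built from
validated LIR instances,

    weight(p, a) = log2[(count(p, a) + c) / (n + 20c)] − log2(background(a)),

with pseudocount `c` (default 1) and a background of residue frequencies
(default uniform 0.05); the hit score is the sum of the six positional
weights. Hits are also annotated with similar experimentally
characterized LIR motifs (exact match at the core positions 3 and 6, at
most two mismatches elsewhere).

**LIRCP criterion.** A protein is predicted to be a LIRCP when at least
one xLIR hit overlaps an intrinsically disordered ("anchor") segment.
Disorder comes from external per-residue predictor output (IUPred/ANCHOR
style), interval lists, or a clearly labeled built-in hydropathy/charge
heuristic.

**GO-slim enrichment.** Protein GO annotations are projected onto a
GO-slim with the map2slim min-ancestor rule and each slim category is
tested for over-representation among the LIRCPs with the exact
hypergeometric tail

    P(X ≥ x), where h(x; N, n, k) = C(k, x) C(N−k, n−x) / C(N, n)

(`N` universe size, `n` proteins in the category, `k` LIRCPs, `x` LIRCPs
in the category). Benjamini–Hochberg FDR control is applied per GO
namespace and each category is placed in one of four tiers: highly
significant (p-adj ≤ 0.01), significant (≤ 0.05), low significance
(≤ 0.1), not significant (> 0.1). Candidate triage keeps significant
LIRCPs sharing at least one GO term with a reference set derived from
experimentally validated LIRCPs and partitions them into curation groups
A–D.

## Worked example

```python
from lirscan import (XLIR, build_pssm, scan_pattern, score_window,
                     DisorderTrack, classify_lircp, summarize)

hits = scan_pattern("MDDWTHLAAEDYVIL", XLIR, protein_id="DEMO")
print([(h.start, h.end, h.window) for h in hits])
# [(2, 7, 'DDWTHL'), (10, 15, 'EDYVIL')]

model = build_pssm(["DDWTHL", "EDYVIL", "DSWTVV"])   # validated instances
print(round(score_window("DDWTHL", model), 3))
# 7.715

track = DisorderTrack("DEMO", 15, segments=[(1, 8)])
result = classify_lircp(hits, track)
print(result.lircp, [(h.start, h.end) for h in result.hits_anchored])
# True [(2, 7)]

stats = summarize(n_orfs=88479, n_lircps=5204, n_lir_motifs=6087)
print(stats.pct_lircps, stats.ratio_lirs_per_lircp)
# 5.88 1.17
```

The first call finds both xLIR windows in the toy sequence; the PSSM
score is the summed log-odds of `DDWTHL` under the three-instance model;
the disorder filter keeps only the hit overlapping the disordered segment
(residues 1–8), so the protein is called a LIRCP; `summarize` turns
human-proteome-scale batch counts into the displayed percentage of LIRCPs
and the LIR-per-LIRCP ratio.

The same pipeline runs from the shell:

```bash
lirscan fixtures --seed 3 -o fix/                 # synthetic demo inputs
lirscan scan fix/proteome.fasta --disorder fix/disorder -o entries.tsv
lirscan enrich entries.tsv --obo fix/mini_go.obo --slim fix/mini_go.obo \
        --annot fix/annotations.tsv -o enrich.tsv
lirscan summarize --orfs 88479 --lircps 5204 --motifs 6087
```

## Scope notes

Non-canonical LIR motifs (such as the CALCOCO2/NDP52–LC3C interaction
motif) are out of scope, as are web serving, hosted BLAST searches and
reimplementation of ANCHOR/IUPred disorder energetics.
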