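# bedesign

Design and evaluation of sgRNAs for CRISPR **base editing** in model
organisms (built around medaka and zebrafish workflows, but genome-agnostic).

Base editors are Cas9-nickase–deaminase fusions that convert single bases
without double-strand breaks: cytosine base editors (CBEs) install C→T,
adenine base editors (ABEs) install A→G, inside a position window of the
20-nt protospacer 5′ of an NGG PAM. Picking a good guide means finding a
protospacer that (1) places the target base in the editing window, (2) sits
in a favourable dinucleotide context, (3) produces the intended codon change
with tolerable bystander edits, and (4) has no base-editable off-target
sites. `bedesign` automates all four steps, and additionally classifies
pathogenic human SNVs by whether a base editor can install them at an
orthologous fish position.

## The rank score

Each editable base in a protospacer is scored

```
S = E − DP − WP
```

where `E` is the editor's efficiency starting value (5 for BE4-Gam, 10 for
the second-generation editors ancBE4max, evoBE4max and ABE8e), `DP = E ×
PF(preceding base)` penalises disfavoured dinucleotide contexts (e.g.
rat-APOBEC1 CBEs dislike GC; evoBE4max dislikes AC; ABE8e is
context-insensitive), and `WP = E × 0.8` is charged when the base lies in
the observed window but outside the peak window. A guide is ranked by its
best-scoring editable base; scores can be negative.

| editor | E | DP T/C/A/G | window observed (peak) | WP |
|---|---|---|---|---|
| BE4-Gam | 5 | 0 / 2 / 3 / 4 | 3–10 (4–8) | 4 |
| ancBE4max | 10 | 0 / 2 / 2 / 8 | 3–9 (4–7) | 8 |
| evoBE4max | 10 | 0 / 2 / 8 / 2 | 1–11 (4–8) | 8 |
| ABE8e | 10 | 0 / 0 / 0 / 0 | 3–11 (4–8) | 8 |

Off-target candidates are genomic near-matches with ≤ 4 mismatches over the
spacer and ≤ 2 in the 12 nt adjacent to the PAM, kept only when a substrate
base lies in the editing window, and sorted by a position-weighted threat
score (PAM-distal mismatches are better tolerated by Cas9, hence more
threatening).

## Worked example

Scoring one base by hand: BE4-Gam, protospacer position 5, preceded by C →
`S = 5 − 2 − 0 = 3`:

```console
$ bedesign score --editor BE4-Gam --pos 5 --context C
3
```

Designing guides on the start of the medaka *oca2* exon carrying Q333
(frame F1, evoBE4max):

```console
$ bedesign design --query GAAACCCAGGTGGCCATTGCAGGTGGCC --editor evoBE4max --frame F1
protospacer           pam  strand  start  end  editable_positions  best_score  best_position  combined_consequence
GAAACCCAGGTGGCCATTGC  AGG  +       1      20   5,6,7               8.0         6              nonsense
ACCCAGGTGGCCATTGCAGG  TGG  +       4      23   2,3,4,11            8.0         4              nonsense
GCCACCTGCAATGGCCACCT  GGG  -       8      27   2,3,5,6,9           8.0         6              missense
GGCCACCTGCAATGGCCACC  TGG  -       9      28   3,4,6,7,10          8.0         4              missense
```

The top guide is the *oca2*-Q333 protospacer: cytosines at
positions 5–7 are editable; converting C7 turns the CAG codon into TAG, a
premature stop (`combined_consequence = nonsense`). The best score is 8
(E = 10, DP = 2 for the CC context at position 6, no window penalty).
Per-base consequences, HGVS-like protein notation and ready-to-anneal
cloning oligos (5′ bases G-substituted for T7 transcription when needed)
are in the full TSV (`--out`).

Other subcommands: `bedesign offtarget` (genome-wide editable off-target
search), `bedesign modelability` (SNV-by-SNV CBE/ABE classification with
stringent vs bystander-permissive status), `bedesign fixtures`
(deterministic synthetic genomes/genes/variant tables).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time: the mismatch limits actually enforced
by the off-target search (measured by planting decoy sites beyond both
limits into a seeded random genome) and the editable-position/stop-codon
predictions for five printed worked-example protospacers. Results are
written as JSON, one entry per quantity.
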