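# Methods

This note documents the models and procedures implemented in `bedesign`,
the defaults and why they were chosen, what the synthetic fixtures do and
do not emulate, and the numerical/design choices made where the procedure
was genuinely open.

## Coordinate and orientation conventions

Protospacer positions are 1-based with position 1 at the 5′, PAM-distal end
and the PAM at positions 21–23. Genomic intervals are 0-based half-open
internally and in BED output; human-readable TSV reports use 1-based
inclusive coordinates and say so in their headers. Sequences are uppercased
on ingestion. A `GenomicTarget` always reads 5′→3′ on the coding (query)
strand; minus-strand protospacer edits are complemented onto that strand
before codon lookup.

## Guide scoring

Each editable base scores `S = E − DP − WP`.

- `E` (points): 5 for BE4-Gam, 10 for ancBE4max, evoBE4max and ABE8e,
  reflecting the much lower in vivo efficiency of the first-generation
  editor.
- `DP = E × PF(preceding base)`: the dinucleotide-context penalty. The
  factors per editor (T/C/A/G): BE4-Gam 0/0.4/0.6/0.8; ancBE4max
  0/0.2/0.2/0.8; evoBE4max 0/0.2/0.8/0.2; ABE8e all 0.
- `WP = E × 0.8` when the base is inside the observed window but outside
  the peak window; targeting outside the observed window is an error, not a
  penalty. Windows (observed, peak): BE4-Gam 3–10 (4–8); ancBE4max 3–9
  (4–7); evoBE4max 1–11 (4–8); ABE8e 3–11 (4–8).

A guide's rank is the maximum `S` over its editable bases; ties break
toward the smaller (5′-most) position for determinism. Scores may be
negative (e.g. 10 − 8 − 8 = −6) and ranking is simply descending. The
preceding base for position 1 comes from the genomic flank when available;
for a bare 20-mer with no flank the context is unknown and the editor's
worst-case factor is charged, so unknown context can only demote a guide.
When the user overrides the editing-window limits, the published penalty
constants no longer describe the chemistry, so guides are reported
unscored in positional order.

Custom editors (e.g. PAM variants) round-trip through a JSON profile with
the same fields; invariants (peak ⊆ observed, factors in [0,1], C→T or A→G
chemistry only) are enforced at construction.

## Spliced query mapping

Queries are usually spliced cDNA. The mapper uses exact 16-mer seeding,
diagonal grouping, O(n²) colinear chaining over diagonal envelopes, and
match-based resolution of seedless junction bases; identity is computed as
matches / query length and alignments below 0.98 are rejected — the
threshold is exact (a 100-nt query with 2 substitutions passes, with 3 it
fails). Junction bases that match both exon diagonals are genuinely
ambiguous without splice-motif information; they are assigned toward the
genomic 5′ side so that mapping a query and its reverse complement yields
mirror-image blocks. Queries mapping equally well to two loci raise an
ambiguity error rather than silently picking one. Introns are any genomic
gap ≥ 1 nt between chained blocks; no canonical-splice check is made at
mapping time. Users with a GFF3/BED12 gene model can bypass mapping
entirely; both routes produce identical targets on the fixtures and this is
tested.

This replaces an external spliced aligner. The contract is the identity
threshold and the block structure, not the algorithm; exact seeding is
sufficient at the desk scale the fixtures exercise (it will not find an
alignment whose every exon is shorter than the seed or saturated with
substitutions denser than one per 16 nt).

## Consequence prediction

Per-base consequences assume full conversion of that base alone; the
combined consequence converts every substrate base in the active window
simultaneously and reports the most severe resulting class (ordering:
nonsense > stop_loss > start_loss > missense > synonymous > splice_site >
intronic > noncoding). Classes follow the usual definitions (nonsense iff
the new codon is a stop and the old is not; start_loss only for codon 1 =
ATG). Intronic edits within the two first/last intron bases are classed
`splice_site` — the GT/AG dinucleotides — a definition adopted here
because splice-disrupting guides are practically useful but the boundary
width was an open choice. Bases upstream of the selected reading-frame
start or in a trailing partial codon are `noncoding`. Frames F1/F2/F3
shift the codon phase of the first query base by 0/1/2.

## Cloning oligos

T7 polymerase initiates on G. If the protospacer starts with G the spacer
is used as-is; otherwise the two most-5′ bases are both replaced by G
(default), with a `replace-one` mode available since usage varies between
labs. Overhangs default to TAGG/AAAC (DR274-style annealed cloning) and
are fully configurable; the overhangs are a vector convention, not a
property of the method.

## Off-target search

PAM-anchored enumeration of every NGG window on both strands with
early-abort Hamming comparison. Limits are conjunctive: ≤ 2 mismatches in
the 12-nt PAM-proximal core AND ≤ 4 over the spacer (a disjunctive reading
would allow 4 core mismatches, defeating the core's purpose). PAM bases
must match their IUPAC pattern and never count as spacer mismatches;
windows containing N are skipped; the 0-mismatch on-target is always
reported and listed first. Hits without a substrate base in the editing
window are dropped: a base editor does no harm where it has nothing to
deaminate.

Ranking uses `threat = Σ 1.2^(21−p)` over mismatch positions `p`. Only the
ordering is contractual — mismatches closer to the PAM make a site a worse
Cas9 substrate, so moving any mismatch one step toward the PAM strictly
lowers the threat — and the property suite checks exactly that
monotonicity, not the constant. Context annotation is overlap-based:
exonic on ≥ 1 bp exon overlap, else intronic within a gene span, else
intergenic (unknown without models).

## Variant modelability

The classification pipeline: keep variants whose clinical significance is
exactly `Pathogenic`, that are single-nucleotide, and that carry at least
one of the coding Sequence Ontology terms SO:0001578, SO:0001582,
SO:0001583, SO:0001587; accept an ortholog position only when the
alignment is unique and the (strand-adjusted) fish base equals the human
reference; call the editor class from the required fish-strand edit (C→T
or G→A → CBE, A→G or T→C → ABE, transversions → none); and enumerate every
NGG protospacer placing the target base at window positions 4–8 in the
fish context. The window is fixed to 4–8 here — the standard display
window — independent of the editor-specific observed windows used in
design mode, because the classification asks "can any common editor do
this", not "how well".

*Stringent* means at least one candidate guide has no other substrate base
at window positions 4–8 (no bystander possible); *permissive* means at
least one candidate guide exists. Stringency therefore implies
permissiveness, and on any table the stringent count ≤ permissive count.
Any second substrate base in the window breaks stringency, including ones
whose edit would be synonymous: without a reliable fish gene model for
every context the protein-level innocence of a bystander cannot be
established, so the conservative reading is the default. Genome-scale
ClinVar counts depend on the database and alignment version and are out of
scope; the pipeline is validated end-to-end on the synthetic table below.

## Synthetic fixtures: what they emulate and what they do not

- **Decoy genomes** (`make_fixture_genome`): i.i.d. uniform random
  sequence with near-matches of a spacer planted at controlled mismatch
  profiles and verified exhaustively to contain *no accidental* admissible
  near-match (resampling on collision, bounded attempts). They exercise
  the search limits exactly, but real genomes have repeat structure and
  biased composition that produce far more candidate windows; a green test
  establishes correctness of the limits, not genome-scale recall/runtime.
- **Gene fixtures** (`make_fixture_gene`): a stop-free CDS of uniformly
  drawn sense codons split by GT..AG introns (defaults: exons 120 + 141 nt,
  intron 200 nt, 300-nt flanks — small but typical proportions for a
  compact fish gene). No codon-usage bias, no UTRs, no alternative
  isoforms.
- **Variant tables** (`make_variant_table`, default n = 200): cycle
  through ten constructed categories (stringent/permissive CBE and ABE
  cases including G→A addressed on the opposite strand, transversions,
  diverged and ambiguous orthologs, non-pathogenic and noncoding entries).
  Contexts are built on alternating two-letter backgrounds so that exactly
  one admissible guide exists and its bystander content is controlled —
  classification truth is known by construction. Real ClinVar contexts
  have arbitrary PAM densities and multiple competing guides.

Fixture outputs are byte-identical for a fixed seed.

## Known limitations

- The mapper is exact-seeded: heavily diverged or micro-exon queries that
  a gapped aligner would rescue are reported unmapped.
- Off-target search considers mismatches only — no DNA/RNA bulges — and
  the threat score is ordinal, not an empirically calibrated cleavage
  probability.
- Consequence prediction assumes complete conversion of the stated base
  set; partial editing, indel by-products and nickase-dependent outcomes
  are experimental matters outside the model.
- Editor profiles are constants, not learned models; they summarise
  published in vitro behaviour confirmed in vivo and are not predictive of
  per-locus efficiency percentages.
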