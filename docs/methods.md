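# Methods

`mitocircle` analyses the two ways louse mitochondrial genomes depart from the
canonical single 37-gene circle: extreme gene-order rearrangement, and
fragmentation into minicircular chromosomes. This note describes the models
and procedures each module implements, the parameters that matter, and what
the synthetic-data generators do and do not emulate.

## Gene boundaries as rearrangement characters

The unit of comparison is the *gene boundary*: an ordered, strand-aware pair
of immediately adjacent genes. Reading a junction from the opposite strand
reverses the order and flips both strands, so `X→Y` and `−Y→−X` denote the
same junction; one canonical representative (the lexicographically smaller of
the pair and its reverse-complement) is stored. Duplicate gene copies
(`trnK_2`, suffixed in coordinate order) compare on the base token, since
homology among copies is not inferable from a single genome: any copy of trnK
adjacent to nad4 realises the trnK–nad4 boundary.

A boundary found in the reference arrangement — by default the packaged
ancestral insect (pancrustacean ground-pattern) gene order — is
*plesiomorphic*; all others are *derived*. Junctions interrupted by a single
tRNA (`trnF–trnX–nad6`) match the parent boundary (`trnF–nad6`) only in the
optional collapse-tRNA mode (`collapse_trna=1`); strict adjacency is the
default, and pooled counts are reported under both conventions because they
genuinely differ.

For a taxon whose genome is only partly sequenced, a boundary's state is
unknown (`?`) only when at least one of its two genes is absent from every
sequenced chromosome; two present but non-adjacent genes score 0.

## Character mapping on the phylogeny

Each shared derived boundary becomes a binary character on a rooted tree
(Newick input; polytomies are treated as hard — a gain on a polytomy edge
serves all its daughters). Because these characters are defined as absent
from the ancestral arrangement, the root is anchored to state 0 through a
virtual ancestral edge; a gain on that edge is legal and counted, which lets
a boundary shared by the outgroup and part of the ingroup map as a single
origin with subsequent losses.

**Fitch (minimum change).** Unknown tips are free. A dynamic program over
per-node Pareto sets of (gains, losses, unknowns-forced-present) enumerates
every co-optimal split of the minimum change count. The reported
reconstruction minimises, in order: (1) the number of `?` tips that must be
assigned the derived state, then (2) the number of gains. Rule (1) is the
package's answer to a real ambiguity: when a single-origin map (one gain, one
loss) ties with two independent gains but only works by treating unknown tips
as present, the tie should not be broken *by the missing data*, so the
convergent map is reported. For characters whose co-optimal splits tie on
forced unknowns, the rule reduces to plain fewest-gains.

**Dollo (single origin).** The one gain sits on the edge above the most
recent common ancestor of the 1-tips; a second dynamic program finds the
minimum number of 1→0 losses covering the 0-tips inside that clade, with `?`
tips assigned whichever state avoids losses. Unknown tips inside the clade
are reported separately — they are the honest price of the single-origin
reading.

**Classification.** A character is a *clean synapomorphy* iff the selected
Fitch split is one gain, zero losses, and its clade contains no unknown tips;
a *synapomorphy with loss or unknown* iff it has one gain otherwise; and
*convergent* iff it needs two or more gains. Tests verify the Fitch change
count against exhaustive enumeration of all internal labellings (trees to 7
tips), and check monotonicity under added missing data.

The packaged ten-genus study tree and A–K character matrix are encoded from
the documented boundary-sharing pattern; the unprinted placement of two taxa
and the gene inventories of the partial genomes were fixed analytically so
that the single-origin loss/unknown accounting of the documented mapping is
reproduced (one such count is off by one irreducibly: with a hard polytomy
the loss and unknown counts for character D cannot both match; the loss count
was kept). The matrix builder derives `?` states from gene inventories at run
time rather than shipping final states.

## Homopolymer runs and slippage deletions

Replication slippage between two same-base homopolymer runs deletes the
intervening segment and fuses the runs. The scanner reports all maximal runs
of a base at or above a length floor (default 10, the conventional threshold
for "long" mononucleotide runs), on the deposited strand by default
(`both_strands` available; every report records the choice). Deletion
candidates are enumerated over ordered same-base run pairs whose spanned
deletion falls in a size window (default 100 bp to genome−200 bp, suppressing
trivial and near-total deletions); circular spans are supported. Gene
casualties (fully removed vs truncated) come from feature overlap.

The junction model fixes how much run survives: `max` (default — slippage
retains one template run, so the fused run is the longer of the two), `sum`,
or either single run. The arithmetic identity *deleted + retained = original*
holds under every model and is tested.

Diagnostic amplicon sizes are pure length arithmetic: on the deleted template
the product is `up_offset + down_offset` (the offsets measured from primer
outer ends to the breakpoints); on the full template the deleted span sits in
between. No primer thermodynamics is modelled.

## Minicircle typology

A species' chromosome set is typed from gene content and control-region
structure. *Major gene* means PCG or rRNA. With a full 37-gene chromosome:
`canonical` alone, `type1` if a reduced chromosome coexists (heteroplasmic
deletion product). With no full chromosome: `type2` when some chromosome
still carries ≥ 2 major genes and control regions are short without shared
blocks; `type3` when no chromosome exceeds one major gene and every
chromosome carries a large control region (default threshold 600 bp — the
observed gap separating type-3 control regions, ≥ ~700 bp, from the largest
single-chromosome louse control region, < 300 bp) with conserved blocks
shared across chromosomes. Block evidence comes from the control-region
module when supplied; with no evidence the size criterion alone decides and
the report says so. Inter-feature gaps ≥ 50 bp (configurable down to 40)
materialise as control-region pseudo-features. The completeness inventory
lists missing genes against the 37-token vocabulary, duplicates collapsed.

## Control-region structure

**Conserved blocks** are maximal collinear segments present in all input
control regions. Seeds are 8-mers exactly shared by every sequence (all
occurrence combinations are tried, since short k-mers recur by chance in
AT-rich sequence). Each seed is extended ungapped by X-drop (X = 300),
scoring each column by its mean pairwise identity against the midpoint of the
identity floor and the composition-dependent random baseline
(Σ f<sub>b</sub>², ~29 % at 30 % GC); edges are then refined by a
maximum-scoring-subarray pass against the midpoint of the measured core
identity and that baseline. A block is accepted only if its *worst* pairwise
identity clears the floor (default 80 %) and it is at least 30 bp; blocks are
chained collinearly and numbered left to right along the shortest control
region. Identity is ungapped throughout; gapped refinement is out of scope.
Below roughly 95 % within-block identity, edge localisation genuinely
degrades: a partially conserved 6-column edge cannot be distinguished from a
chance look-alike flank with the same column pattern.

**Macrorepeats** (tandem or dispersed units ≥ 40 bp at ≥ 90 % identity) are
found by self-comparison: exact 12-mer seeds at distance *d* open a diagonal
band, extended while identity holds and refined by the same max-subarray
trim. A band of matched length *m* ≥ *d* is a tandem repeat of period *d*
spanning *m* + *d* bases; shorter bands are dispersed pairs. Spans contained
in a repeat with a smaller unit are dropped.

**Hairpins.** The stem-loop finder returns the highest-scoring inverted
repeat with loop 3–20 nt, scoring +2 per Watson–Crick pair, +1 per G·T pair
(the only non-canonical pair admitted), −2 per single-base bulge (≤ 3).
Mismatched columns are not allowed. The search (memoised outward extension
from every loop seed) is exact and is tested against independent recursive
enumeration on regions ≤ 60 nt. Ties go to the longer stem, then the leftmost
loop. The structure string uses `>`/`<` for the paired arms, `+` for G·T
pairs and `^` for bulges.

## Reciprocal best hits

Hit tables are standard 12-column tabular alignment output; the search itself
is never run here. HSPs collapse to the maximum bitscore per query–subject
pair; the best hit per query is the top bitscore, ties broken by lower
e-value, then lexicographic subject id (so results are reproducible across
input orderings); a pair is orthologous iff each is the other's best hit.
Category summaries report matched/total and a one-decimal percentage per
functional category and overall, plus the list of reference genes with no
reciprocal pair. The packaged 315-gene reference (six categories: OXPHOS 74,
other metabolic 87, protein synthesis 113, DNA synthesis 15, transport/cell
rescue 22, miscellaneous 4) carries synthetic placeholder gene ids —
clearly labelled — to be substituted with real gene-level content.

## Synthetic data: what it emulates, and what it does not

All generators draw from a single seeded numpy Generator; identical seed and
parameters give byte-identical output. Defaults are the study conditions:

| knob | default | why |
|---|---|---|
| GC content | 0.30 | louse mtDNA is AT-rich |
| genome size | ~14.9 kb | canonical complete mt genome |
| planted runs | 28 T / 19 T | the documented deletion-flanking runs |
| deletion span | 7218 bp | the documented heteroplasmic deletion |
| background runs | capped at 8 | the planted pair is the only 10+ pair |
| type-3 NCR length | ~700–1100 bp | observed type-3 control regions |
| NCR blocks | 150/250/142 bp, 97 % identity | three blocks; concerted evolution keeps within-individual copies near-identical; at 97 % block edges are recoverable to ±5 bp, which degrades below ~95 % |
| repeat units | 60-mers, 2–4 copies | macrorepeat scale (53/67 bp observed) |
| hairpin | 12 bp stem, 5 nt loop, in block 1 | stem-loop placement in block 1 |
| ortholog census | 315 genes, decoy rate 0.3 | ne-mt census size |

Gene sequences are random at the target composition — no codon structure, no
substitution model along a tree, no realistic tRNA folding. Consequently,
passing recovery tests demonstrates that the detectors find the *structures*
they claim to find (runs, breakpoints, blocks, repeats, stems, reciprocal
pairs) at realistic sizes and noise levels; they say nothing about annotation
quality, alignment of diverged sequence, or rate heterogeneity in real data.
Rearrangement events are single-gene translocations and block inversions
applied to the ancestral order, with a per-event ledger of boundaries
created/destroyed that recovery tests replay.

## Numerical and degenerate-input conventions

Coordinates are 1-based closed intervals (a feature 710..737 is 28 bp);
origin-spanning features on circles are permitted with end < start. Orders
with fewer than two genes yield no boundaries (warning, not error). A
character with no presence state is rejected. Linearisation is
rotation-invariant and reads the majority strand (ties toward the strand
carrying cox1); a genome lacking cox1 needs an explicit anchor. Unknown gene
names always raise — nothing passes through silently. All tie-breaks
(bitscore/e-value/subject id; hairpin score/stem length/position; Fitch
forced-unknowns/gains) are deterministic and documented above.

## Known limitations

- Breakpoint-distance phylogenetics, rearrangement-event reconstruction
  (DCJ/sorting) and tree inference are out of scope; the tree is an input.
- Block identity is ungapped; indel-riddled control regions would fragment
  blocks rather than align through gaps.
- The hairpin model scores a single stem; multi-loop or nested structures and
  thermodynamic stability are not modelled.
- Minicircle typing trusts the supplied annotations; it does not detect genes.
- The Fitch tie policy (minimise reliance on unknowns, then gains) is a
  modelling choice; both it and the plain fewest-gains alternative are
  co-optimal readings of the same data, and the full co-optimal split list is
  always reported alongside the classification.
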