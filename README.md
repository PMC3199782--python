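# mitocircle

Comparative analysis of rearranged and minicircular mitochondrial genomes,
built for the parasitic-louse situation: mt genomes that are both the most
rearranged among arthropods and, in many lineages, fragmented into
*minicircles* — chromosomes far smaller than the canonical ~15 kb circle,
each carrying a subset of the 37 canonical genes (13 protein-coding genes,
2 rRNAs, 22 tRNAs).

It is a library plus a thin `mitocircle` CLI for researchers in molecular
evolution who have annotated genomes (GenBank) or gene-order tables and want
to answer, reproducibly:

- which **gene adjacencies** (boundaries) are retained from the ancestral
  insect arrangement (plesiomorphic) and which are derived, and which derived
  boundaries are shared between taxa;
- whether a shared derived boundary is a **synapomorphy or a convergence**,
  by mapping it as a binary character on a rooted phylogeny under both
  minimum-change (Fitch) and single-origin/multiple-loss (Dollo) parsimony;
- whether a reduced chromosome is a **replication-slippage deletion
  product**: homopolymer runs, candidate run pairs, gene casualties, and the
  diagnostic PCR product sizes that confirm a deletion;
- what **type of minicircle set** a species carries (heteroplasmic deletion
  product; multi-gene minicircles with plain control regions; single-gene
  minicircles with large, conserved-block control regions);
- the **structure of control regions**: conserved blocks shared across
  chromosomes, macrorepeats, and a candidate stem-loop;
- which genes of a reference set have **reciprocal best-hit orthologs** in a
  genome, summarised by functional category.

Every stage has a seeded synthetic-data generator that plants known structure
and returns a truth record, so the full pipeline runs and is tested with no
downloads.

## The characters at the core

For gene orders, the unit of analysis is the boundary `X→Y` between adjacent
signed genes; `X→Y` and `−Y→−X` are the same junction and share one canonical
key. On a rooted tree with tip states in {0, 1, ?} (unknown = a flanking gene
is unsequenced), Fitch mapping minimises gains (0→1) plus losses (1→0) with
the root anchored at 0, reporting every co-optimal (gains, losses) split;
Dollo mapping places the single gain above the MRCA of the 1-tips and counts
the losses that cover the 0-tips inside that clade. A character is a *clean
synapomorphy* when one gain, no losses and no unknown tips inside its clade
explain it; *convergent* when two or more origins are required. When a
single-origin map only ties by treating unknown tips as present, the
convergent map is preferred — missing data should not subsidise a
synapomorphy claim (see `docs/methods.md`).

## Worked example

Generate a heteroplasmic genome pair — a ~14.9 kb circle with a planted
7218 bp deletion between poly-T runs of 28 and 19 bases — then recover the
deletion and size the diagnostic amplicons:

```python
from mitocircle.synthetic import make_deleted_pair
from mitocircle.minicircle import (find_homopolymers,
                                   enumerate_deletion_candidates, amplicon_size)

full, deleted, truth = make_deleted_pair(seed=1)
runs = find_homopolymers(full.sequence, "T", min_len=10, genome=full)
for r in runs:
    print(r)
# HomopolymerRun(base='T', start=4305, end=4332, host_features=('atp6',))
# HomopolymerRun(base='T', start=11532, end=11550, host_features=('trnS2',))

[cand] = [c for c in enumerate_deletion_candidates(full, runs)
          if c.deleted_length == truth["deleted_length"]]
print(cand.deleted_length, len(cand.removed_genes), len(cand.truncated_genes))
# 7218 17 2
print(amplicon_size(cand, 325, 73, "deleted"), amplicon_size(cand, 325, 73, "full"))
# 398 7616
```

The two runs are the only 10+ poly-T runs (28 and 19 T, each inside a gene);
the unique candidate at the planted span removes 17 genes and truncates 2;
with primers whose outer ends sit 325 bp upstream and 73 bp downstream of the
breakpoints, the deletion-bearing chromosome yields a 398 bp product where
the full chromosome would give 7616 bp — the short product is the diagnostic
signature of the deletion.

Mapping the packaged ten-louse boundary characters A–K on the packaged study
tree:

```python
from mitocircle.charmap import build_study_matrix, study_tree, map_characters
print(map_characters(study_tree(), build_study_matrix())[
    ["fitch_gains", "fitch_losses", "dollo_losses", "dollo_unknowns", "class"]])
```

```
           fitch_gains  fitch_losses  dollo_losses  dollo_unknowns                              class
character
A                    1             2             2               3  synapomorphy_with_loss_or_unknown
B                    2             0             2               0                         convergent
C                    1             2             2               1  synapomorphy_with_loss_or_unknown
D                    2             0             2               3                         convergent
E                    1             0             0               3  synapomorphy_with_loss_or_unknown
F                    1             0             0               0                 clean_synapomorphy
G                    2             0             2               3                         convergent
H                    1             0             0               0                 clean_synapomorphy
I                    1             1             1               1  synapomorphy_with_loss_or_unknown
J                    1             1             1               1  synapomorphy_with_loss_or_unknown
K                    2             0             1               2                         convergent
```

F and H (rrnL–trnW, trnM–rrnS) are clean synapomorphies of the
goniodid + (Quadraceps, Philopterus) clade; five characters map as single
origins with secondary losses or unknown states; four (B, D, G, K) require
two independent origins under minimum change.

Same analyses from the shell:

```bash
mitocircle simulate --seed 3 --out fixtures/   # GenBank + hit tables + truth.json
mitocircle type-set fixtures/minicircles.gb    # -> {"minicircle_type": "type3", ...}
mitocircle scan-runs fixtures/deleted_pair.gb
mitocircle charmap                             # packaged tree and matrix
mitocircle bbh --fwd fixtures/hits_fwd.tsv --rev fixtures/hits_rev.tsv
```

## File formats

- **GenBank flat files** for annotated genomes (read; a minimal writer covers
  synthetic output). Circularity from the LOCUS topology field
  (`--force-circular` available in the library via `AnnotatedGenome`).
- **Gene-order TSV**: `taxon<TAB>trnI,cox1,-trnQ,...` — one taxon per row,
  signed tokens, optional third column `linear`.
- **Character matrix TSV**: taxa × characters, cells `0`/`1`/`?`; trees in
  Newick.
- **Hit tables**: standard 12-column tabular alignment output.

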