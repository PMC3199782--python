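"""Homopolymer-slippage deletions and minicircle chromosome-set typing.

Replication slippage between two same-base homopolymer runs can delete the
intervening segment, fusing the runs into one and leaving a heteroplasmic mix
of full-length and reduced ("minicircle") chromosomes.  This module scans for
runs, enumerates candidate run pairs whose spanned deletion fits a size
window, predicts diagnostic PCR product sizes on both templates, and types a
species' chromosome set:

* canonical -- one chromosome carries all 37 genes, no reduced chromosome;
* type 1 -- a full chromosome coexists with >= 1 reduced one (heteroplasmic
  deletion product);
* type 2 -- no full chromosome; some chromosome still carries >= 2 major
  genes (PCG or rRNA) and control regions are short without shared blocks;
* type 3 -- no chromosome carries more than one major gene and every
  chromosome has a large control region built from conserved blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import AnnotatedGenome, GeneFeature, materialize_ncrs
from .vocab import CANONICAL_GENES, base_token, is_major

VALID_BASES = set("ACGTacgt")

#: smallest control region counted as "large" for type-3 calls.  Observed
#: type-3 NCRs start near 700 bp while the largest single-chromosome louse
#: NCR is under 300 bp, so the default sits in the gap.
LARGE_NCR_THRESHOLD = 600

JUNCTION_MODELS = ("max", "sum", "five_prime", "three_prime")


@dataclass(frozen=True)
class HomopolymerRun:
    base: str
    start: int  # 1-based inclusive
    end: int
    host_features: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DeletionCandidate:
    run_5p: HomopolymerRun
    run_3p: HomopolymerRun
    deleted_start: int  # 1-based, first deleted base
    deleted_end: int    # last deleted base (may wrap on a circle)
    deleted_length: int
    removed_genes: tuple[str, ...]
    truncated_genes: tuple[str, ...]
    junction_model: str
    fused_run_length: int
    genome_id: str = ""
    genome_length: int = 0


def find_homopolymers(
    sequence: str,
    base: str,
    min_len: int,
    genome: AnnotatedGenome | None = None,
    both_strands: bool = False,
) -> list[HomopolymerRun]:
    """All maximal runs of ``base`` with length >= min_len, in coordinate order.

    With ``both_strands`` runs of the complementary base are reported too
    (coordinates always on the given sequence).  When a genome is supplied,
    each run is annotated with the features it overlaps.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    bad = [i + 1 for i, c in enumerate(sequence) if c not in VALID_BASES]
    if bad:
        head = ", ".join(map(str, bad[:10]))
        raise ValueError(f"non-nucleotide characters at positions {head}"
                         + ("..." if len(bad) > 10 else ""))
    targets = {base.upper()}
    if both_strands:
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}[base.upper()]
        targets.add(comp)
    seq = sequence.upper()
    runs: list[HomopolymerRun] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] in targets:
            j = i
            while j + 1 < n and seq[j + 1] == seq[i]:
                j += 1
            if j - i + 1 >= min_len:
                hosts = ()
                if genome is not None:
                    hosts = tuple(
                        f.name for f in genome.features
                        if _overlaps(f, i + 1, j + 1, genome.length)
                    )
                runs.append(HomopolymerRun(seq[i], i + 1, j + 1, hosts))
            i = j + 1
        else:
            i += 1
    return runs


def _overlaps(f: GeneFeature, start: int, end: int, length: int) -> bool:
    if f.end >= f.start:
        return not (end < f.start or start > f.end)
    # origin-spanning feature
    return start <= f.end or end >= f.start


def enumerate_deletion_candidates(
    genome: AnnotatedGenome,
    runs: Sequence[HomopolymerRun],
    min_deleted: int = 100,
    max_deleted: int | None = None,
    junction_model: str = "max",
) -> list[DeletionCandidate]:
    """One candidate per ordered same-base run pair within the size window.

    The slippage junction fuses the two runs into a single run; under the
    default model its length is the longer of the two (one run survives as
    template), so the deleted segment reaches from just past the fused run's
    end to the end of the downstream run.  Circular spans are supported.
    """
    if junction_model not in JUNCTION_MODELS:
        raise ValueError(f"junction_model must be one of {JUNCTION_MODELS}")
    if max_deleted is None:
        max_deleted = genome.length - 200
    out = []
    for r5 in runs:
        for r3 in runs:
            if r5 is r3 or r5.base != r3.base:
                continue
            if not genome.circular and r3.start <= r5.start:
                continue
            cand = _candidate(genome, r5, r3, junction_model)
            if cand is not None and min_deleted <= cand.deleted_length <= max_deleted:
                out.append(cand)
    out.sort(key=lambda c: (c.deleted_start, c.deleted_end))
    return out


def _fused_length(l5: int, l3: int, model: str) -> int:
    return {"max": max(l5, l3), "sum": l5 + l3,
            "five_prime": l5, "three_prime": l3}[model]


def _candidate(genome: AnnotatedGenome, r5: HomopolymerRun, r3: HomopolymerRun,
               model: str) -> DeletionCandidate | None:
    L = genome.length
    arc = (r3.end - r5.start) % L + 1  # forward arc covering both runs
    fused = _fused_length(r5.length, r3.length, model)
    deleted_len = arc - fused
    if deleted_len <= 0:
        return None
    del_start = (r5.start - 1 + fused) % L + 1
    del_end = r3.end
    removed, truncated = _casualties(genome, del_start, del_end)
    return DeletionCandidate(
        run_5p=r5, run_3p=r3, deleted_start=del_start, deleted_end=del_end,
        deleted_length=deleted_len, removed_genes=removed, truncated_genes=truncated,
        junction_model=model, fused_run_length=fused,
        genome_id=genome.id, genome_length=L,
    )


def _positions(start: int, end: int, L: int) -> tuple[tuple[int, int], ...]:
    """A possibly-wrapping 1-based interval as plain intervals."""
    if end >= start:
        return ((start, end),)
    return ((start, L), (1, end))


def _casualties(genome: AnnotatedGenome, del_start: int, del_end: int
                ) -> tuple[tuple[str, ...], tuple[str, ...]]:
    removed, truncated = [], []
    dspans = _positions(del_start, del_end, genome.length)

    def overlap_len(f: GeneFeature) -> int:
        total = 0
        for fs, fe in _positions(f.start, f.end, genome.length):
            for ds, de in dspans:
                total += max(0, min(fe, de) - max(fs, ds) + 1)
        return total

    for f in genome.features:
        if f.gene_class == "NCR":
            continue
        ov = overlap_len(f)
        if ov == 0:
            continue
        if ov >= f.length(genome.length):
            removed.append(f.name)
        else:
            truncated.append(f.name)
    return tuple(removed), tuple(truncated)


def amplicon_size(candidate: DeletionCandidate, up_offset: int, down_offset: int,
                  template: str = "deleted") -> int:
    """Diagnostic PCR product length across the deletion junction.

    Offsets are measured from the primers' outer ends to the two deletion
    breakpoints.  On the deleted template the product is simply
    ``up_offset + down_offset``; on the full template the deleted span is
    still in between.
    """
    if up_offset < 0 or down_offset < 0:
        raise ValueError("offsets must be >= 0")
    if template == "deleted":
        retained = candidate.genome_length - candidate.deleted_length
        if up_offset + down_offset > retained:
            raise ValueError("primer offsets exceed the deleted-template length")
        return up_offset + down_offset
    if template == "full":
        size = up_offset + candidate.deleted_length + down_offset
        if size > candidate.genome_length:
            raise ValueError("primer offsets exceed the full-template length")
        return size
    raise ValueError("template must be 'deleted' or 'full'")


# ---------------------------------------------------------------------------
# chromosome-set typing
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeReport:
    id: str
    length: int
    genes_by_class: dict[str, list[str]]
    major_gene_count: int
    ncr_lengths: list[int]


@dataclass
class ChromosomeSetReport:
    chromosomes: list[ChromosomeReport]
    minicircle_type: str  # canonical | type1 | type2 | type3 | unclassified
    missing_genes: tuple[str, ...]
    present_genes: frozenset[str] = field(default_factory=frozenset)
    notes: tuple[str, ...] = ()


def _chrom_report(g: AnnotatedGenome, ncr_min_gap: int) -> ChromosomeReport:
    with_ncrs = materialize_ncrs(g, min_gap=ncr_min_gap) if g.features else g
    by_class: dict[str, list[str]] = {"PCG": [], "rRNA": [], "tRNA": [], "NCR": []}
    ncr_lengths = []
    for f in with_ncrs.features:
        by_class.setdefault(f.gene_class, []).append(f.name)
        if f.gene_class == "NCR":
            ncr_lengths.append(f.length(g.length))
    majors = sum(1 for f in with_ncrs.features if f.gene_class in ("PCG", "rRNA")
                 and not f.partial)
    return ChromosomeReport(g.id, g.length, by_class, majors, ncr_lengths)


def type_chromosome_set(
    genomes: Sequence[AnnotatedGenome],
    ncr_block_evidence: bool | None = None,
    large_ncr: int = LARGE_NCR_THRESHOLD,
    ncr_min_gap: int = 50,
) -> ChromosomeSetReport:
    """Classify a species' chromosome set into the minicircle typology.

    ``ncr_block_evidence`` should be True when conserved-block analysis of the
    control regions found blocks shared across chromosomes, False when it
    found none, and None when no such analysis is available (control-region
    size alone then decides type 3; the report notes this).
    """
    if not genomes:
        raise ValueError("empty chromosome set")
    reports = [_chrom_report(g, ncr_min_gap) for g in genomes]
    notes: list[str] = []
    present: set[str] = set()
    full_flags = []
    for g in genomes:
        names = g.gene_names()
        present |= names
        full_flags.append(set(CANONICAL_GENES) <= names)
    missing = tuple(sorted(set(CANONICAL_GENES) - present))
    any_full = any(full_flags)
    any_reduced = any(not f for f in full_flags)
    max_majors = max(r.major_gene_count for r in reports)
    all_large_ncr = all(r.ncr_lengths and max(r.ncr_lengths) >= large_ncr for r in reports)

    if any_full and not any_reduced:
        mtype = "canonical"
    elif any_full and any_reduced:
        mtype = "type1"
    elif max_majors >= 2 and not (all_large_ncr and ncr_block_evidence):
        mtype = "type2"
    elif max_majors <= 1 and all_large_ncr and ncr_block_evidence is not False:
        mtype = "type3"
        if ncr_block_evidence is None:
            notes.append("type3 called on control-region size alone; no block evidence supplied")
    else:
        mtype = "unclassified"
    return ChromosomeSetReport(
        chromosomes=reports, minicircle_type=mtype, missing_genes=missing,
        present_genes=frozenset(present), notes=tuple(notes),
    )


def completeness(report: ChromosomeSetReport) -> dict[str, list[str]]:
    """Missing genes against the 37-gene vocabulary, grouped by class."""
    from .vocab import gene_class
    out: dict[str, list[str]] = {"PCG": [], "rRNA": [], "tRNA": []}
    for g in report.missing_genes:
        out[gene_class(g)].append(g)
    return out
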