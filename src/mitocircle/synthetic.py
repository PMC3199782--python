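"""Seeded generators for fixture genomes, control regions and hit tables.

Every analysis stage in this package can be exercised without downloads: the
generators plant known structure (rearrangements, homopolymer-flanked
deletions, minicircle chromosome sets, conserved NCR blocks, reciprocal-best
hit pairs) and return a machine-readable truth record alongside the data, so
recovery tests compare detector output against planted truth.

Defaults emulate the study conditions: an AT-rich (~30 % GC) 37-gene circular
genome near 15 kb; a heteroplasmic deletion of 7218 bp between poly-T runs of
28 and 19 bases; type-3 minicircles of one major gene, one tRNA and a 700-1100
bp control region with three conserved blocks and a stem-loop in block 1; a
315-gene ortholog census.  Identical seed and parameters give byte-identical
output (the generators draw exclusively from one numpy Generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .boundaries import ancestral_insect_order, extract_boundaries
from .genome_io import AnnotatedGenome, GeneFeature, GeneOrder, flip, unsigned
from .vocab import base_token, gene_class

BASES = np.array(list("ACGT"))

#: typical metazoan mt gene lengths (bp) used to realise sequences
GENE_LENGTHS = {
    "cox1": 1536, "cox2": 684, "cox3": 789, "cob": 1137,
    "nad1": 936, "nad2": 978, "nad3": 354, "nad4": 1339, "nad4L": 297,
    "nad5": 1719, "nad6": 525, "atp6": 678, "atp8": 162,
    "rrnS": 750, "rrnL": 1250,
}
TRNA_LENGTH = 65


@dataclass
class GeneratorSpec:
    """Bundle of generator knobs (CLI/YAML surface); functions take them singly."""

    seed: int = 0
    n_translocations: int = 0
    n_inversions: int = 0
    run_5p_len: int = 28
    run_3p_len: int = 19
    deletion_span: int = 7218
    homopolymer_base: str = "T"
    junction_model: str = "max"
    minicircle_type: str = "type3"
    n_chromosomes: int = 3
    block_lengths: tuple[int, ...] = (150, 250, 142)
    block_identity: float = 97.0
    repeat_unit: int = 60
    hairpin_stem: int = 12
    hairpin_loop: int = 5
    n_genes: int = 315
    decoy_rate: float = 0.3
    missing_genes: tuple[str, ...] = ()
    gc: float = 0.30


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_sequence(rng, n: int, gc: float = 0.30) -> str:
    rng = _rng(rng)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def _cap_runs(seq: str, base: str, max_run: int, rng) -> str:
    """Break homopolymer runs of ``base`` longer than max_run."""
    rng = _rng(rng)
    out = list(seq)
    count = 0
    others = [b for b in "ACGT" if b != base]
    for i, c in enumerate(out):
        if c == base:
            count += 1
            if count > max_run:
                out[i] = others[int(rng.integers(len(others)))]
                count = 0
        else:
            count = 0
    return "".join(out)


def gene_length(token: str) -> int:
    tok = base_token(unsigned(token))
    if tok in GENE_LENGTHS:
        return GENE_LENGTHS[tok]
    return TRNA_LENGTH


def realize_genome(
    gid: str,
    order: GeneOrder,
    rng,
    gc: float = 0.30,
    ncr_length: int = 0,
    cap_base: str | None = None,
    max_run: int = 8,
    spacer: int = 2,
) -> AnnotatedGenome:
    """Give a gene order coordinates and a random sequence.

    Genes are laid out in order with small spacers; an optional control region
    of ``ncr_length`` is appended after the last gene (on a circle this is the
    gap between the final gene and the origin).  ``cap_base`` breaks any
    background homopolymer run of that base longer than ``max_run`` so planted
    runs are the only long ones.
    """
    rng = _rng(rng)
    feats = []
    pos = 1
    for tok in order.tokens:
        name = unsigned(tok)
        strand = "-" if tok.startswith("-") else "+"
        ln = gene_length(tok)
        feats.append(GeneFeature(name, pos, pos + ln - 1, strand, False, gene_class(name)))
        pos += ln + spacer
    length = pos - 1 - spacer + (spacer + ncr_length if ncr_length else 0)
    seq = random_sequence(rng, length, gc)
    if cap_base:
        seq = _cap_runs(seq, cap_base, max_run, rng)
    return AnnotatedGenome(id=gid, length=length, circular=order.circular,
                           sequence=seq, features=feats)


# ---------------------------------------------------------------------------
# rearranged genomes with an event ledger
# ---------------------------------------------------------------------------

def translocate(order: GeneOrder, src: int, dst: int) -> GeneOrder:
    """Move the gene at index src so it ends up at index dst of the new order."""
    toks = list(order.tokens)
    g = toks.pop(src)
    toks.insert(dst % (len(toks) + 1), g)
    return GeneOrder(tuple(toks), order.circular)


def invert(order: GeneOrder, start: int, k: int) -> GeneOrder:
    """Reverse-complement the k-gene block beginning at index start."""
    toks = list(order.tokens)
    n = len(toks)
    idx = [(start + i) % n for i in range(k)]
    block = [flip(toks[i]) for i in reversed(idx)]
    for i, b in zip(idx, block):
        toks[i] = b
    return GeneOrder(tuple(toks), order.circular)


def make_rearranged_genome(
    seed,
    n_translocations: int = 0,
    n_inversions: int = 0,
    ancestral: GeneOrder | None = None,
    realize: bool = False,
    gc: float = 0.30,
) -> tuple[GeneOrder | AnnotatedGenome, list[dict]]:
    """Apply random single-gene translocations and block inversions.

    The ledger records each event with the boundary keys it destroyed and
    created, so derived-boundary counts can be audited against ground truth.
    """
    rng = _rng(seed)
    order = ancestral if ancestral is not None else ancestral_insect_order()
    ledger: list[dict] = []
    events = ["t"] * n_translocations + ["i"] * n_inversions
    for ev in events:
        before = {b.key for b in extract_boundaries(order)}
        n = len(order.tokens)
        if ev == "t":
            src = int(rng.integers(n))
            dst = int(rng.integers(n - 1))
            new = translocate(order, src, dst)
            detail = {"event": "translocation", "gene": order.tokens[src], "src": src, "dst": dst}
        else:
            start = int(rng.integers(n))
            k = int(rng.integers(2, max(3, n // 4)))
            new = invert(order, start, k)
            detail = {"event": "inversion", "start": start, "k": k}
        after = {b.key for b in extract_boundaries(new)}
        detail["destroyed"] = sorted(before - after)
        detail["created"] = sorted(after - before)
        ledger.append(detail)
        order = new
    if realize:
        return realize_genome("synthetic_rearranged", order, rng, gc=gc), ledger
    return order, ledger


# ---------------------------------------------------------------------------
# homopolymer-flanked deletion pairs
# ---------------------------------------------------------------------------

def make_deleted_pair(
    seed,
    run_5p_len: int = 28,
    run_3p_len: int = 19,
    deletion_span: int = 7218,
    base: str = "T",
    junction_model: str = "max",
    gc: float = 0.30,
    order: GeneOrder | None = None,
) -> tuple[AnnotatedGenome, AnnotatedGenome, dict]:
    """A full genome with two planted runs plus its slippage-deletion product.

    ``deletion_span`` is the number of bases removed; the two runs fuse into a
    single run per ``junction_model`` (default: the longer run survives).
    Background runs of ``base`` are capped at 8 so the planted pair is the
    only 10+ pair.  The truth record carries run coordinates, breakpoints and
    gene casualties.
    """
    from .minicircle import _candidate, _fused_length, find_homopolymers  # local: avoid cycle

    rng = _rng(seed)
    if order is None:
        order = ancestral_insect_order()
    full = realize_genome("synthetic_full", order, rng, gc=gc, ncr_length=300,
                          cap_base=base, max_run=8)
    L = full.length
    fused = _fused_length(run_5p_len, run_3p_len, junction_model)
    if deletion_span > 0 and not (200 <= deletion_span <= L - 200):
        raise ValueError(f"deletion_span {deletion_span} out of range for genome of {L}")
    # place the 5' run inside a feature, away from the origin for simplicity
    s5 = int(rng.integers(100, L - (run_5p_len + deletion_span + run_3p_len) - 100))
    e5 = s5 + run_5p_len - 1
    e3 = s5 - 1 + fused + deletion_span + (run_3p_len if junction_model == "sum" else 0)
    # ensure arc - fused == deletion_span for the chosen model
    arc = fused + deletion_span
    e3 = s5 - 1 + arc
    s3 = e3 - run_3p_len + 1
    seq = list(full.sequence)
    for pos in range(s5 - 1, e5):
        seq[pos] = base
    for pos in range(s3 - 1, e3):
        seq[pos] = base
    # re-break any accidental extensions at the run edges
    for edge in (s5 - 2, e5, s3 - 2, e3):
        if 0 <= edge < L and seq[edge] == base and not (s5 - 1 <= edge < e5) \
                and not (s3 - 1 <= edge < e3):
            seq[edge] = "A" if base != "A" else "C"
    full = AnnotatedGenome(id=full.id, length=L, circular=True,
                           sequence="".join(seq), features=full.features)
    runs = [r for r in find_homopolymers(full.sequence, base, 10, genome=full)
            if (r.start, r.end) in ((s5, e5), (s3, e3))]
    if len(runs) != 2:
        raise RuntimeError("planted runs not recoverable")
    cand = _candidate(full, runs[0], runs[1], junction_model)
    assert cand is not None and cand.deleted_length == deletion_span
    deleted = _apply_deletion(full, cand.deleted_start, cand.deleted_end)
    truth = {
        "base": base, "run_5p": (s5, e5), "run_3p": (s3, e3),
        "deleted_span": (cand.deleted_start, cand.deleted_end),
        "deleted_length": cand.deleted_length,
        "fused_run_length": cand.fused_run_length,
        "removed_genes": cand.removed_genes, "truncated_genes": cand.truncated_genes,
        "full_length": L, "deleted_chromosome_length": deleted.length,
        "junction_model": junction_model,
    }
    return full, deleted, truth


def _apply_deletion(g: AnnotatedGenome, del_start: int, del_end: int) -> AnnotatedGenome:
    """Remove a (possibly wrapping) span, rotating so the junction is interior."""
    L = g.length
    dlen = (del_end - del_start) % L + 1
    keep = [((del_end + i) % L) + 1 for i in range(L - dlen)]  # old 1-based kept positions
    old_to_new = {old: i + 1 for i, old in enumerate(keep)}
    seq = "".join(g.sequence[p - 1] for p in keep) if g.sequence else None
    feats = []
    for f in g.features:
        span = [(f.start, f.end)] if f.end >= f.start else [(f.start, L), (1, f.end)]
        kept_pos = sorted(
            old_to_new[p] for s, e in span for p in range(s, e + 1) if p in old_to_new
        )
        if not kept_pos:
            continue
        full_len = f.length(L)
        contiguous = kept_pos[-1] - kept_pos[0] + 1 == len(kept_pos)
        if not contiguous:
            continue  # feature split across the junction: drop
        partial = f.partial or len(kept_pos) < full_len
        feats.append(GeneFeature(f.name, kept_pos[0], kept_pos[-1], f.strand,
                                 partial, f.gene_class))
    return AnnotatedGenome(id=g.id + "_deleted", length=L - dlen, circular=True,
                           sequence=seq, features=feats)


# ---------------------------------------------------------------------------
# control regions with planted blocks / repeats / hairpin
# ---------------------------------------------------------------------------

def _mutate(rng, seq: str, identity: float) -> str:
    rng = _rng(rng)
    rate = max(0.0, 1.0 - identity / 100.0)
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def make_ncr_set(
    seed,
    n: int = 3,
    block_lengths: Sequence[int] = (150, 250, 142),
    block_identity: float = 97.0,
    repeat_unit: int = 60,
    repeat_copies: Sequence[int] = (2, 3, 4),
    hairpin_stem: int = 12,
    hairpin_loop: int = 5,
    spacer_range: tuple[int, int] = (60, 160),
    gc: float = 0.30,
) -> tuple[dict[str, str], dict]:
    """Control regions sharing conserved blocks, with per-chromosome repeats.

    Blocks appear in the same order in every NCR (beginning / middle / end),
    separated by chromosome-specific spacers; chromosome i carries
    ``repeat_copies[i]`` tandem copies of its own ``repeat_unit``-mer; a
    perfect inverted repeat (stem-loop) is embedded inside block 1.  Truth
    holds per-chromosome block coordinates, repeat spans and hairpin position.
    """
    rng = _rng(seed)
    masters = []
    for ln in block_lengths:
        blk = random_sequence(rng, ln, gc)
        masters.append(blk)
    # plant the hairpin in master block 1
    stem = random_sequence(rng, hairpin_stem, 0.5)
    loop = random_sequence(rng, hairpin_loop, gc)
    hp = stem + loop + _revcomp(stem)
    off = max(0, (len(masters[0]) - len(hp)) // 2)
    masters[0] = masters[0][:off] + hp + masters[0][off + len(hp):]
    units = [random_sequence(rng, repeat_unit, gc) for _ in range(n)]
    seqs: dict[str, str] = {}
    truth: dict = {"blocks": {}, "repeats": {}, "hairpin_master_offset": off,
                   "hairpin": (off + 1, off + len(hp))}
    for i in range(n):
        name = f"ncr{i + 1}"
        parts: list[str] = []
        coords = []
        pos = 0
        copies = repeat_copies[i % len(repeat_copies)]
        for j, master in enumerate(masters):
            blk = _mutate(rng, master, block_identity)
            if j == 0:  # keep the hairpin intact
                blk = blk[:off] + hp + blk[off + len(hp):]
            parts.append(blk)
            coords.append((pos + 1, pos + len(blk)))
            pos += len(blk)
            if j < len(masters) - 1:
                sp = random_sequence(rng, int(rng.integers(*spacer_range)), gc)
                if j == 0:  # repeats sit between blocks 1 and 2
                    rep = units[i] * copies
                    truth["repeats"][name] = (pos + len(sp) // 2 + 1,
                                              pos + len(sp) // 2 + len(rep),
                                              repeat_unit, copies)
                    sp = sp[: len(sp) // 2] + rep + sp[len(sp) // 2:]
                parts.append(sp)
                pos += len(sp)
        seqs[name] = "".join(parts)
        truth["blocks"][name] = coords
    return seqs, truth


def _revcomp(s: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in reversed(s))


# ---------------------------------------------------------------------------
# minicircle chromosome sets
# ---------------------------------------------------------------------------

def make_minicircle_set(
    seed,
    mtype: str = "type3",
    n_chromosomes: int = 3,
    gc: float = 0.30,
) -> tuple[list[AnnotatedGenome], dict]:
    """A species' chromosome set of the requested type, with truth record.

    type1: full 37-gene genome + one deletion product; type2: multi-gene
    chromosomes (>= 2 major genes each, short plain NCRs, no full genome);
    type3: one major gene + one tRNA + a large conserved-block NCR per
    chromosome.
    """
    rng = _rng(seed)
    anc = ancestral_insect_order()
    truth: dict = {"type": mtype}
    if mtype == "canonical":
        g = realize_genome("synthetic_canonical", anc, rng, gc=gc, ncr_length=120)
        truth["chromosomes"] = {g.id: sorted(g.gene_names())}
        truth["missing"] = []
        return [g], truth
    if mtype == "type1":
        span = int(rng.integers(4000, 8000))
        full, deleted, dtruth = make_deleted_pair(rng, deletion_span=span, gc=gc)
        truth["deletion"] = dtruth
        truth["chromosomes"] = {full.id: sorted(full.gene_names()),
                                deleted.id: sorted(deleted.gene_names())}
        truth["missing"] = []
        return [full, deleted], truth
    majors = [t for t in anc.tokens if gene_class(unsigned(t)) in ("PCG", "rRNA")]
    trnas = [t for t in anc.tokens if gene_class(unsigned(t)) == "tRNA"]
    rng.shuffle(majors)
    rng.shuffle(trnas)
    chroms: list[AnnotatedGenome] = []
    used: set[str] = set()
    if mtype == "type2":
        per = 2 + int(rng.integers(0, 2))
        for i in range(n_chromosomes):
            picks = majors[i * per:(i + 1) * per]
            if len(picks) < 2:
                break
            ts = trnas[i * 3:(i + 1) * 3]
            order = GeneOrder(tuple(picks + ts), circular=True)
            g = realize_genome(f"synthetic_t2_{i + 1}", order, rng, gc=gc,
                               ncr_length=int(rng.integers(60, 240)))
            chroms.append(g)
            used |= g.gene_names()
    elif mtype == "type3":
        ncrs, ncr_truth = make_ncr_set(rng, n=n_chromosomes, gc=gc)
        truth["ncr"] = ncr_truth
        for i in range(n_chromosomes):
            order = GeneOrder((majors[i], trnas[i]), circular=True)
            ncr_seq = ncrs[f"ncr{i + 1}"]
            g = realize_genome(f"synthetic_t3_{i + 1}", order, rng, gc=gc,
                               ncr_length=len(ncr_seq))
            seq = g.sequence[: g.length - len(ncr_seq)] + ncr_seq
            g = AnnotatedGenome(id=g.id, length=g.length, circular=True,
                                sequence=seq, features=g.features)
            chroms.append(g)
            used |= g.gene_names()
    else:
        raise ValueError(f"unknown minicircle type {mtype!r}")
    truth["chromosomes"] = {g.id: sorted(g.gene_names()) for g in chroms}
    truth["missing"] = sorted({base_token(unsigned(t)) for t in anc.tokens} - used)
    return chroms, truth


# ---------------------------------------------------------------------------
# hit tables with planted reciprocal-best pairs
# ---------------------------------------------------------------------------

def make_hit_tables(
    seed,
    genes: Sequence[str] | int = 40,
    decoy_rate: float = 0.3,
    missing: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, set[tuple[str, str]]]:
    """Forward and reverse hit tables with planted orthologs and decoy hits.

    Each gene ``g`` (other than ``missing`` ones, which get no hits at all)
    has ortholog ``g.orth`` with the top bitscore in both directions; decoys
    are weaker off-target hits added at ``decoy_rate`` per gene per direction.
    """
    rng = _rng(seed)
    if isinstance(genes, int):
        genes = [f"g{i + 1:04d}" for i in range(genes)]
    genes = list(genes)
    targets = {g: f"{g}.orth" for g in genes}
    fwd_rows, rev_rows = [], []

    def row(q, s, bit, ev):
        return [q, s, round(float(rng.uniform(40, 95)), 1), int(rng.integers(80, 400)),
                0, 0, 1, 100, 1, 100, ev, round(bit, 1)]

    for g in genes:
        if g in missing:
            continue
        bit = float(rng.uniform(450, 900))
        fwd_rows.append(row(g, targets[g], bit, 1e-100))
        rev_rows.append(row(targets[g], g, bit * float(rng.uniform(0.9, 1.0)), 1e-95))
        for other in rng.choice(genes, size=int(rng.random() < decoy_rate) * 2, replace=False):
            if other == g:
                continue
            fwd_rows.append(row(g, targets[str(other)], float(rng.uniform(50, 400)), 1e-20))
            rev_rows.append(row(targets[str(other)], g, float(rng.uniform(50, 400)), 1e-20))
    cols = ["query", "subject", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    fwd = pd.DataFrame(fwd_rows, columns=cols)
    rev = pd.DataFrame(rev_rows, columns=cols)
    planted = {(g, targets[g]) for g in genes if g not in missing}
    return fwd, rev, planted
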