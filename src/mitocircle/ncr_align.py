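"""Structure of minicircle control regions (NCRs).

Type-3 minicircle control regions are built from sequence blocks conserved
across the chromosomes of one species, separated by chromosome-specific
macrorepeats, with a putative stem-loop (replication-origin candidate) inside
one conserved block.  Three finders reproduce that report:

* ``conserved_blocks`` -- maximal collinear blocks present in every input NCR,
  found by shared k-mer seeding and ungapped extension under an identity floor;
* ``find_macrorepeats`` -- tandem and dispersed repeats via self-comparison on
  k-mer diagonals;
* ``find_hairpin`` -- the highest-scoring inverted repeat, allowing G.T pairs
  and a bounded number of single-base bulges, scored
  ``2*WC + 1*(G.T) - 2*bulges`` with ties to the longest stem.

All identities are ungapped percentages.  Defaults (k=8 seeds, blocks >= 30 bp
at >= 80 % identity) are recorded in every report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "T"), ("T", "G")}
COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def reverse_complement(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# conserved blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    id: int
    spans: tuple[tuple[str, int, int], ...]  # (chromosome, start, end) 1-based
    identity: float  # mean pairwise %, ungapped

    def span(self, chrom: str) -> tuple[int, int]:
        for c, s, e in self.spans:
            if c == chrom:
                return (s, e)
        raise KeyError(chrom)


@dataclass
class NCRBlockMap:
    chromosomes: tuple[str, ...]
    blocks: list[Block] = field(default_factory=list)
    repeats: list["Repeat"] = field(default_factory=list)
    hairpin: "Hairpin | None" = None
    params: dict = field(default_factory=dict)


def _mean_pairwise_identity(cols: list[tuple[str, ...]]) -> float:
    if not cols:
        return 0.0
    n = len(cols[0])
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    tot = 0.0
    for col in cols:
        tot += sum(1 for i, j in pairs if col[i] == col[j]) / len(pairs)
    return 100.0 * tot / len(cols)


def conserved_blocks(
    ncrs: Mapping[str, str] | Sequence[str],
    min_block: int = 30,
    min_identity: float = 80.0,
    k: int = 8,
) -> NCRBlockMap:
    """Maximal collinear blocks shared by all input control regions.

    Seeds are k-mers exactly shared by every sequence; each seed is extended
    ungapped in both directions while the block's mean pairwise identity stays
    at or above ``min_identity``.  Overlapping blocks are merged; block order
    must be consistent across chromosomes (collinear chaining); numbering
    follows position in the shortest NCR.
    """
    if not isinstance(ncrs, Mapping):
        ncrs = {f"chr{i + 1}": s for i, s in enumerate(ncrs)}
    seqs = {c: s.upper() for c, s in ncrs.items()}
    dropped = [c for c, s in seqs.items() if len(s) < min_block]
    for c in dropped:
        logger.warning("chromosome %s shorter than min_block, excluded", c)
        del seqs[c]
    if len(seqs) < 2:
        raise ValueError("need at least two control regions")
    chroms = sorted(seqs, key=lambda c: (len(seqs[c]), c))
    ref = chroms[0]  # shortest NCR fixes block numbering
    others = chroms[1:]
    index = {c: _kmer_index(seqs[c], k) for c in others}

    raw: list[tuple[tuple[int, ...], int, float]] = []  # (starts per chrom, length, identity)
    i = 0
    L = len(seqs[ref])
    while i + k <= L:
        kmer = seqs[ref][i:i + k]
        hits = [index[c].get(kmer) for c in others]
        found = None
        if all(h is not None for h in hits):
            # an 8-mer can recur by chance; try every occurrence combination
            # and keep the best-supported extension
            for combo in _combinations(hits, cap=32):  # type: ignore[arg-type]
                starts, length, ident = _extend(seqs, [ref] + others,
                                                [i] + list(combo), k, min_identity)
                if length >= min_block and _min_pairwise(seqs, [ref] + others,
                                                         starts, length) >= min_identity:
                    if found is None or length > found[1]:
                        found = (tuple(starts), length, ident)
        if found is not None:
            raw.append(found)
            i = found[0][0] + found[1]  # jump past the block on the reference
        else:
            i += 1

    blocks = _chain_collinear(raw)
    out = []
    for n, (starts, length, ident) in enumerate(blocks, start=1):
        spans = tuple(
            (c, s + 1, s + length) for c, s in zip([ref] + others, starts)
        )
        out.append(Block(id=n, spans=spans, identity=round(ident, 1)))
    return NCRBlockMap(
        chromosomes=tuple(chroms), blocks=out,
        params={"k": k, "min_block": min_block, "min_identity": min_identity},
    )


def _combinations(hits: list[list[int]], cap: int) -> list[tuple[int, ...]]:
    out: list[tuple[int, ...]] = [()]
    for h in hits:
        out = [c + (p,) for c in out for p in h]
        if len(out) > cap:
            out = out[:cap]
    return out


def _min_pairwise(seqs: Mapping[str, str], chroms: list[str], starts: list[int],
                  length: int) -> float:
    """Worst pairwise ungapped identity over the block."""
    texts = [seqs[c] for c in chroms]
    worst = 100.0
    for a in range(len(texts)):
        for b in range(a + 1, len(texts)):
            m = sum(1 for j in range(length)
                    if texts[a][starts[a] + j] == texts[b][starts[b] + j])
            worst = min(worst, 100.0 * m / length)
    return worst


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i:i + k], []).append(i)
    return idx


def _extend(seqs: Mapping[str, str], chroms: list[str], starts: list[int],
            k: int, min_identity: float, xdrop: float = 300.0
            ) -> tuple[list[int], int, float]:
    """Grow an ungapped multi-sequence block around a seed by X-drop.

    Each column scores its mean pairwise identity minus the floor, so
    conserved columns are positive and unrelated flanking columns strongly
    negative.  Extension continues until the running score falls ``xdrop``
    below its maximum; the block ends at the maximum-scoring extent, which
    keeps a long conserved core from leaking into flanking sequence.
    """
    texts = [seqs[c] for c in chroms]
    offs = list(starts)
    length = k
    # extension floor: midpoint between the identity floor and the identity
    # expected between unrelated sequences of this base composition, so
    # occasional mutated columns inside a real block do not read as its end
    counts: dict[str, int] = {}
    tot = 0
    for t in texts:
        for ch in t:
            counts[ch] = counts.get(ch, 0) + 1
            tot += 1
    e_random = 100.0 * sum((n / tot) ** 2 for n in counts.values())
    floor = (min_identity + e_random) / 2.0

    def col_ident(o: list[int], j: int) -> float:
        return _mean_pairwise_identity([tuple(t[p + j] for t, p in zip(texts, o))])

    # right
    cum = best = 0.0
    best_j = length - 1
    j = length
    while all(o + j < len(t) for o, t in zip(offs, texts)):
        cum += col_ident(offs, j) - floor
        if cum > best:
            best, best_j = cum, j
        if cum < best - xdrop:
            break
        j += 1
    length = best_j + 1
    # left
    cum = best = 0.0
    best_step = 0
    step = 1
    while all(o - step >= 0 for o in offs):
        trial = [o - step for o in offs]
        cum += col_ident(trial, 0) - floor
        if cum > best:
            best, best_step = cum, step
        if cum < best - xdrop:
            break
        step += 1
    offs = [o - best_step for o in offs]
    length += best_step
    # refine edges: keep the contiguous stretch maximising column identity
    # (max-subarray) scored against the midpoint between the core's measured
    # identity and the random baseline -- steep enough to shed chance
    # look-alike columns, tolerant enough to keep mutated columns inside
    core_ident = _mean_pairwise_identity(
        [tuple(t[p + j] for t, p in zip(texts, offs)) for j in range(length)]
    )
    refine_floor = (core_ident + e_random) / 2.0
    scores = [col_ident(offs, j) - refine_floor for j in range(length)]
    lo, hi = _max_subarray(scores)
    offs = [o + lo for o in offs]
    length = hi - lo + 1
    ident = _mean_pairwise_identity(
        [tuple(t[p + j] for t, p in zip(texts, offs)) for j in range(length)]
    )
    return offs, length, ident


def _max_subarray(scores: list[float]) -> tuple[int, int]:
    """Indices (inclusive) of the maximum-sum contiguous stretch."""
    best = -float("inf")
    best_span = (0, 0)
    cur = 0.0
    start = 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur, start = s, i
        else:
            cur += s
        if cur > best:
            best, best_span = cur, (start, i)
    return best_span


def _chain_collinear(raw: list[tuple[tuple[int, ...], int, float]]
                     ) -> list[tuple[tuple[int, ...], int, float]]:
    """Keep a maximal-coverage chain of blocks monotone in every chromosome."""
    raw = sorted(set(raw), key=lambda b: b[0][0])
    best: list[tuple[tuple[int, ...], int, float]] = []
    n = len(raw)
    score = [b[1] for b in raw]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if all(raw[j][0][d] + raw[j][1] <= raw[i][0][d] for d in range(len(raw[i][0]))):
                if score[j] + raw[i][1] > score[i]:
                    score[i] = score[j] + raw[i][1]
                    prev[i] = j
    if not raw:
        return []
    i = max(range(n), key=lambda x: score[x])
    while i != -1:
        best.append(raw[i])
        i = prev[i]
    return best[::-1]


# ---------------------------------------------------------------------------
# macrorepeats
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Repeat:
    start: int  # 1-based span of the whole repeat region
    end: int
    unit_length: int
    copies: int
    tandem: bool
    identity: float


def find_macrorepeats(
    ncr: str,
    min_unit: int = 40,
    min_copies: int = 2,
    min_identity: float = 90.0,
    k: int = 12,
) -> list[Repeat]:
    """Tandem and dispersed repeats with unit >= min_unit at >= min_identity.

    Self-comparison on exact k-mer seeds: two occurrences of a k-mer at
    distance d seed a match band; the band is extended ungapped while identity
    holds.  A band of matched length m at distance d is a tandem repeat of
    period d spanning m + d bases ((m + d) // d copies) when m >= d, otherwise
    a dispersed pair of m-length copies.
    """
    seq = ncr.upper()
    n = len(seq)
    if n < 2 * min_unit:
        return []
    idx = _kmer_index(seq, k)
    seeds_by_d: dict[int, list[int]] = {}
    for positions in idx.values():
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                d = positions[b] - positions[a]
                if d >= min_unit:
                    seeds_by_d.setdefault(d, []).append(positions[a])
    out: list[Repeat] = []
    for d, seeds in sorted(seeds_by_d.items()):
        seeds.sort()
        covered_to = -1
        for s in seeds:
            if s <= covered_to:
                continue
            lo, hi, ident = _extend_diagonal(seq, s, d, k, min_identity)
            m = hi - lo + 1
            covered_to = hi
            if m >= d:  # tandem: period d over span m + d
                copies = (m + d) // d
                if copies >= min_copies and d >= min_unit:
                    out.append(Repeat(lo + 1, min(hi + d, n - 1) + 1, d, copies, True,
                                      round(ident, 1)))
            elif m >= min_unit:
                copies = 2
                if copies >= min_copies:
                    out.append(Repeat(lo + 1, min(hi + d, n - 1) + 1, m, copies, False,
                                      round(ident, 1)))
    return _dedupe_repeats(out)


def _extend_diagonal(seq: str, start: int, d: int, k: int,
                     min_identity: float) -> tuple[int, int, float]:
    """Maximal x-range with seq[x] == seq[x+d] at >= min_identity around a seed."""
    n = len(seq)
    lo = hi = start
    hi = start + k - 1
    matches = k
    length = k
    # right
    while hi + 1 + d < n:
        m2 = matches + (seq[hi + 1] == seq[hi + 1 + d])
        if 100.0 * m2 / (length + 1) < min_identity:
            break
        hi += 1
        matches, length = m2, length + 1
    # left
    while lo - 1 >= 0 and lo - 1 + d < n:
        m2 = matches + (seq[lo - 1] == seq[lo - 1 + d])
        if 100.0 * m2 / (length + 1) < min_identity:
            break
        lo -= 1
        matches, length = m2, length + 1
    # refine edges: max-scoring stretch against the identity floor, so the
    # span does not leak into flanking sequence
    scores = [(100.0 if seq[x] == seq[x + d] else 0.0) - min_identity
              for x in range(lo, hi + 1)]
    a, b = _max_subarray(scores)
    lo, hi = lo + a, lo + b
    matches = sum(1 for x in range(lo, hi + 1) if seq[x] == seq[x + d])
    return lo, hi, 100.0 * matches / max(1, hi - lo + 1)


def _dedupe_repeats(reps: list[Repeat]) -> list[Repeat]:
    """Drop repeats whose span is contained in one with a smaller unit."""
    reps = sorted(reps, key=lambda r: (r.unit_length, r.start))
    kept: list[Repeat] = []
    for r in reps:
        redundant = any(
            o.start <= r.start and o.end >= r.end and o.unit_length <= r.unit_length
            for o in kept
        )
        if not redundant:
            kept.append(r)
    return sorted(kept, key=lambda r: r.start)


# ---------------------------------------------------------------------------
# hairpin (inverted repeat with G.T pairs and bulges)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hairpin:
    left_start: int  # 1-based arm coordinates within the scanned region
    left_end: int
    right_start: int
    right_end: int
    score: int
    pairs: int
    wc_pairs: int
    gu_pairs: int
    bulges: int
    structure: str  # per-base annotation: > < + ^ .

PAIR_WC = 2
PAIR_GU = 1
BULGE_PENALTY = 2


def find_hairpin(
    region: str,
    min_stem: int = 6,
    max_loop: int = 20,
    allow_gu: bool = True,
    max_bulges: int = 3,
    min_loop: int = 3,
) -> Hairpin | None:
    """Highest-scoring stem-loop in ``region`` (exhaustive over bulge placements).

    Score = 2 x Watson-Crick pairs + 1 x G.T pairs - 2 x bulges; ties resolved
    toward more pairs, then the leftmost loop.  Returns None when no stem of
    ``min_stem`` pairs exists.
    """
    seq = region.upper()
    n = len(seq)
    if n < 2 * min_stem + min_loop:
        return None

    @lru_cache(maxsize=None)
    def grow(i: int, j: int, b: int) -> tuple[tuple[int, int, int, int, tuple], ...]:
        """Pareto outcomes (score, pairs, wc, gu, ops) extending outward from (i, j)."""
        outcomes = {(0, 0, 0, 0, ())}
        if i >= 0 and j < n:
            a, c = seq[i], seq[j]
            kind = None
            if (a, c) in WC:
                kind = ("wc", PAIR_WC)
            elif allow_gu and (a, c) in GU:
                kind = ("gu", PAIR_GU)
            if kind:
                for sc, p, w, g, ops in grow(i - 1, j + 1, b):
                    outcomes.add((sc + kind[1], p + 1, w + (kind[0] == "wc"),
                                  g + (kind[0] == "gu"), (("p", i, j),) + ops))
        if b < max_bulges:
            if i >= 0:
                for sc, p, w, g, ops in grow(i - 1, j, b + 1):
                    outcomes.add((sc - BULGE_PENALTY, p, w, g, (("bl", i, -1),) + ops))
            if j < n:
                for sc, p, w, g, ops in grow(i, j + 1, b + 1):
                    outcomes.add((sc - BULGE_PENALTY, p, w, g, (("br", -1, j),) + ops))
        # prune: keep best score per pair count
        best: dict[int, tuple] = {}
        for o in outcomes:
            if o[1] not in best or (o[0], o[1]) > (best[o[1]][0], best[o[1]][1]):
                best[o[1]] = o
        return tuple(best.values())

    best: tuple | None = None
    for l2 in range(n):  # last base of left arm (0-based)
        for loop in range(min_loop, max_loop + 1):
            r1 = l2 + loop + 1
            if r1 >= n:
                break
            for sc, p, w, g, ops in grow(l2, r1, 0):
                if p < min_stem:
                    continue
                cand = (sc, p, -l2, w, g, ops, l2, r1)
                if best is None or cand[:3] > best[:3]:
                    best = cand
    grow.cache_clear()
    if best is None:
        return None
    sc, p, _, w, g, ops, l2, r1 = best
    bulges = sum(1 for op in ops if op[0] != "p")
    struct = ["."] * n
    li, rj = [], []
    for op, i, j in ops:
        if op == "p":
            a, c = seq[i], seq[j]
            struct[i] = ">" if (a, c) in WC else "+"
            struct[j] = "<" if (a, c) in WC else "+"
            li.append(i)
            rj.append(j)
        elif op == "bl":
            struct[i] = "^"
            li.append(i)
        else:
            struct[j] = "^"
            rj.append(j)
    return Hairpin(
        left_start=min(li) + 1, left_end=max(li) + 1,
        right_start=min(rj) + 1, right_end=max(rj) + 1,
        score=sc, pairs=p, wc_pairs=w, gu_pairs=g, bulges=bulges,
        structure="".join(struct),
    )
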