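"""Gene-adjacency (boundary) extraction and plesiomorphic/derived classification.

A boundary is an ordered, strand-aware pair of immediately neighbouring genes.
Reading the same junction from the other strand reverses the order and flips
both signs, so ``X -> Y`` and ``-Y -> -X`` are the same physical junction; one
canonical representative is stored.  Duplicate copies of a gene (``trnK_2``)
compare on the base token: any copy of trnK next to nad4 realises trnK-nad4.

Boundaries present in a reference (ancestral) arrangement are plesiomorphic;
all others are derived and serve as the characters of the rearrangement
analysis.  Partial genomes make a boundary's state unknown (?) only when at
least one of its two genes is absent from every sequenced chromosome of the
taxon; two present-but-non-adjacent genes score 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import GeneOrder, flip, read_gene_order_table, unsigned
from .vocab import base_token, gene_class

logger = logging.getLogger(__name__)


def canonical_key(upstream: str, downstream: str) -> str:
    """Orientation-normalised identifier of an adjacency.

    Signs are kept (strand matters) but duplicate suffixes are collapsed; of
    the pair and its reverse-complement the lexicographically smaller wins.
    """
    u = _collapse(upstream)
    v = _collapse(downstream)
    fwd = (u, v)
    rev = (flip(v), flip(u))
    a, b = min(fwd, rev)
    return f"{a}|{b}"


def _collapse(token: str) -> str:
    sign = "-" if token.startswith("-") else ""
    return sign + base_token(unsigned(token))


@dataclass(frozen=True)
class Boundary:
    upstream: str
    downstream: str
    modified: tuple[str, ...] = ()  # intervening tRNAs skipped in collapse mode

    @property
    def key(self) -> str:
        return canonical_key(self.upstream, self.downstream)

    def genes(self) -> tuple[str, str]:
        return (base_token(unsigned(self.upstream)), base_token(unsigned(self.downstream)))


def extract_boundaries(order: GeneOrder, collapse_trna: int = 0) -> set[Boundary]:
    """One boundary per adjacent ordered pair; wrap-around pair iff circular.

    With ``collapse_trna=k`` additional *modified* boundaries are emitted for
    gene pairs separated by 1..k intervening tRNAs (a junction like
    trnF-trnX-nad6 then also realises trnF-nad6).
    """
    toks = order.tokens
    if len(toks) < 2:
        logger.warning("order with < 2 genes has no boundaries")
        return set()
    out: set[Boundary] = set()
    n = len(toks)
    pairs = range(n) if order.circular else range(n - 1)
    for i in pairs:
        out.add(Boundary(toks[i], toks[(i + 1) % n]))
    if collapse_trna > 0:
        for i in range(n):
            skipped: list[str] = []
            for step in range(1, collapse_trna + 1):
                j = (i + step) % n
                if not order.circular and i + step >= n:
                    break
                if gene_class(unsigned(toks[j])) != "tRNA":
                    break
                skipped.append(unsigned(toks[j]))
                k = (i + step + 1) % n
                if not order.circular and i + step + 1 >= n:
                    break
                out.add(Boundary(toks[i], toks[k], modified=tuple(skipped)))
    return out


@dataclass
class BoundaryTable:
    """Boundaries of one taxon (union over its chromosomes) with classification."""

    taxon: str
    boundaries: set[Boundary]
    genes: set[str] = field(default_factory=set)  # base tokens present anywhere
    classification: dict[str, str] = field(default_factory=dict)  # key -> plesiomorphic|derived
    reference_id: str | None = None

    def keys(self) -> set[str]:
        return {b.key for b in self.boundaries}

    def derived_keys(self) -> set[str]:
        return {k for k, c in self.classification.items() if c == "derived"}

    def plesiomorphic_keys(self) -> set[str]:
        return {k for k, c in self.classification.items() if c == "plesiomorphic"}


def build_boundary_table(
    taxon: str, orders: Sequence[GeneOrder], collapse_trna: int = 0
) -> BoundaryTable:
    bounds: set[Boundary] = set()
    genes: set[str] = set()
    for order in orders:
        bounds |= extract_boundaries(order, collapse_trna=collapse_trna)
        genes |= {base_token(g) for g in order.names()}
    return BoundaryTable(taxon=taxon, boundaries=bounds, genes=genes)


def ancestral_insect_order() -> GeneOrder:
    """The packaged ancestral-insect (pancrustacean ground pattern) arrangement."""
    with resources.as_file(resources.files("mitocircle.fixtures") / "ancestral_insect.tsv") as p:
        [(_, order)] = read_gene_order_table(p)
    return order


def classify_boundaries(table: BoundaryTable, reference: GeneOrder | None = None) -> BoundaryTable:
    """Mark each boundary plesiomorphic iff its key occurs in the reference."""
    if reference is None:
        reference = ancestral_insect_order()
    ref_keys = {b.key for b in extract_boundaries(reference)}
    ref_genes = {base_token(g) for g in reference.names()}
    missing = {g for b in table.boundaries for g in b.genes()} - ref_genes
    if missing:
        logger.warning("%s: genes absent from reference, boundaries forced derived: %s",
                       table.taxon, sorted(missing))
    classification = {}
    for b in table.boundaries:
        classification[b.key] = "plesiomorphic" if b.key in ref_keys else "derived"
    table.classification = classification
    table.reference_id = "ancestral_insect"
    return table


def shared_derived(
    tables: Sequence[BoundaryTable],
    groups: Mapping[str, Sequence[str]] | None = None,
    min_units: int = 2,
) -> pd.DataFrame:
    """Incidence matrix of derived boundaries shared by >= min_units taxon-units.

    Rows are derived boundary keys, columns taxa, cells '1'/'0'/'?'.  A declared
    group of taxa (e.g. two confamilial genera) counts as a single unit when
    tallying how widely a boundary is shared.
    """
    if len(tables) < 2:
        return pd.DataFrame(columns=[t.taxon for t in tables])
    taxa = [t.taxon for t in tables]
    groups = dict(groups or {})
    grouped: dict[str, str] = {}
    for gname, members in groups.items():
        for m in members:
            if m in grouped:
                raise ValueError(f"taxon {m} appears in overlapping groups")
            grouped[m] = gname
    unit_of = {t: grouped.get(t, t) for t in taxa}

    all_derived: set[str] = set()
    for t in tables:
        if not t.classification:
            raise ValueError(f"table for {t.taxon} is unclassified; run classify_boundaries first")
        all_derived |= t.derived_keys()

    by_taxon = {t.taxon: t for t in tables}
    rows = {}
    for key in sorted(all_derived):
        a, b = key.split("|")
        ga, gb = base_token(unsigned(a)), base_token(unsigned(b))
        states = {}
        units_present = set()
        for taxon in taxa:
            t = by_taxon[taxon]
            if key in t.keys():
                states[taxon] = "1"
                units_present.add(unit_of[taxon])
            elif ga not in t.genes or gb not in t.genes:
                states[taxon] = "?"
            else:
                states[taxon] = "0"
        if len(units_present) >= min_units:
            rows[key] = states
    return pd.DataFrame.from_dict(rows, orient="index", columns=taxa).fillna("0")


def boundary_summary(tables: Sequence[BoundaryTable]) -> dict:
    """Per-taxon plesiomorphic/derived counts plus pooled sharing statistics."""
    per_taxon = {}
    derived_occurrence: dict[str, int] = {}
    for t in tables:
        if not t.classification:
            raise ValueError(f"table for {t.taxon} is unclassified")
        per_taxon[t.taxon] = {
            "plesiomorphic": len(t.plesiomorphic_keys()),
            "derived": len(t.derived_keys()),
        }
        for k in t.derived_keys():
            derived_occurrence[k] = derived_occurrence.get(k, 0) + 1
    unique = [k for k, n in derived_occurrence.items() if n == 1]
    shared = [k for k, n in derived_occurrence.items() if n >= 2]
    return {
        "per_taxon": per_taxon,
        "derived_total_distinct": len(derived_occurrence),
        "unique_derived": len(unique),
        "shared_derived": len(shared),
        "shared_occurrences": sum(derived_occurrence[k] for k in shared),
    }
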