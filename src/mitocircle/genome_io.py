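"""Reading, writing and normalising annotated mitochondrial genomes.

Two interchange forms are supported:

* GenBank flat files (via Biopython), the deposition format for complete
  genomes.  Reading normalises feature names onto the canonical vocabulary
  and takes circularity from the LOCUS topology field.
* A plain TSV gene-order dialect (one taxon per row, signed comma-separated
  tokens) for encoding published gene-order maps without sequence.

Coordinates are 1-based closed intervals throughout: a feature annotated
710..737 is 28 bases long.  Circular genomes are linearised for comparison on
the tRNA immediately upstream of cox1 on the majority strand, so that every
rotation of the same circle yields the same token list.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .vocab import AMBIGUOUS_TRNAS, CANONICAL_GENES, base_token, gene_class, normalize_gene_name

logger = logging.getLogger(__name__)

#: inter-feature gaps at least this long become NCR pseudo-features.  The
#: smallest control-region candidate worth reporting in lice is ~48 bp, so the
#: default sits just above random inter-gene spacers; adjustable down to 40.
DEFAULT_NCR_MIN_GAP = 50


@dataclass(frozen=True)
class GeneFeature:
    """An oriented, typed gene feature on a chromosome (1-based, inclusive)."""

    name: str
    start: int
    end: int
    strand: str = "+"
    partial: bool = False
    gene_class: str = "PCG"

    def length(self, chrom_length: int | None = None) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        if chrom_length is None:
            raise ValueError(f"origin-spanning feature {self.name} needs chromosome length")
        return chrom_length - self.start + 1 + self.end

    @property
    def signed(self) -> str:
        return self.name if self.strand == "+" else f"-{self.name}"


@dataclass
class AnnotatedGenome:
    """A circular or linear mt chromosome with ordered gene features."""

    id: str
    length: int
    circular: bool = True
    sequence: str | None = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.id}: declared length {self.length} != sequence length {len(self.sequence)}"
            )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if not (1 <= f.start <= self.length and 1 <= f.end <= self.length):
                raise ValueError(f"{self.id}: feature {f.name} {f.start}..{f.end} outside 1..{self.length}")
            if f.end < f.start and not self.circular:
                raise ValueError(f"{self.id}: origin-spanning feature {f.name} on a linear chromosome")
        overlaps = self._overlapping()
        if overlaps:
            logger.info("%s: overlapping features: %s", self.id, ", ".join(overlaps))

    def _overlapping(self) -> list[str]:
        out = []
        for a, b in zip(self.features, self.features[1:]):
            if b.start <= a.end and a.end >= a.start:
                out.append(f"{a.name}/{b.name}")
        return out

    def gene_order(self) -> "GeneOrder":
        """Gene order (coding features only, NCRs dropped) as signed tokens."""
        tokens = tuple(f.signed for f in self.features if f.gene_class != "NCR")
        return GeneOrder(tokens=tokens, circular=self.circular)

    def gene_names(self, collapse_duplicates: bool = True) -> set[str]:
        names = {f.name for f in self.features if f.gene_class != "NCR"}
        if collapse_duplicates:
            names = {base_token(n) for n in names}
        return names


@dataclass(frozen=True)
class GeneOrder:
    """An ordered list of signed gene tokens; sign encodes strand."""

    tokens: tuple[str, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        seen = Counter(unsigned(t) for t in self.tokens)
        dups = [t for t, n in seen.items() if n > 1]
        if dups:
            raise ValueError(f"duplicate tokens without suffix: {dups}")

    def __len__(self) -> int:
        return len(self.tokens)

    def names(self) -> tuple[str, ...]:
        return tuple(unsigned(t) for t in self.tokens)

    def reverse_complement(self) -> "GeneOrder":
        return GeneOrder(tuple(flip(t) for t in reversed(self.tokens)), self.circular)

    def rotate(self, k: int) -> "GeneOrder":
        if not self.circular:
            raise ValueError("cannot rotate a linear order")
        k %= len(self.tokens)
        return GeneOrder(self.tokens[k:] + self.tokens[:k], self.circular)


def unsigned(token: str) -> str:
    return token[1:] if token.startswith("-") else token


def flip(token: str) -> str:
    return token[1:] if token.startswith("-") else f"-{token}"


# ---------------------------------------------------------------------------
# name normalisation with duplicate suffixing
# ---------------------------------------------------------------------------

def _suffix_duplicates(names: Sequence[str]) -> list[str]:
    """Attach _2, _3 ... to repeated tokens in coordinate order."""
    counts = Counter(names)
    seen: Counter = Counter()
    out = []
    for n in names:
        if counts[n] > 1:
            seen[n] += 1
            out.append(n if seen[n] == 1 else f"{n}_{seen[n]}")
        else:
            out.append(n)
    return out


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "gene", "misc_feature", "D-loop"}


def _feature_name(feat) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def _resolve_trna_isoacceptor(name: str, feat) -> str:
    """Use a GenBank anticodon qualifier to split trnL/trnS when present."""
    if name not in AMBIGUOUS_TRNAS:
        return name
    ac = None
    if "anticodon" in feat.qualifiers:
        raw = str(feat.qualifiers["anticodon"][0]).lower()
        # formats like (pos:...,aa:Leu,seq:tag) or just "tag"
        if "seq:" in raw:
            ac = raw.split("seq:", 1)[1].strip("() ").replace("u", "t")[:3]
        elif len(raw.strip("() ")) == 3:
            ac = raw.strip("() ").replace("u", "t")
    if ac:
        if name == "trnL":
            return "trnL1" if ac == "tag" else "trnL2"
        return "trnS1" if ac == "tct" else "trnS2"
    warnings.warn(f"ambiguous isoacceptor {name} left unresolved")
    return name


def read_genbank(path: str | Path, force_circular: bool = False) -> list[AnnotatedGenome]:
    """Read one AnnotatedGenome per record of a GenBank flat file.

    Feature names are normalised; duplicates get ``_2``/``_3`` suffixes in
    coordinate order; circularity is taken from the LOCUS topology field
    (``force_circular`` overrides it for records deposited without one).
    Unknown gene names raise (listing the raw name) rather than passing through.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc
    genomes = []
    for rec in records:
        circular = force_circular or \
            (rec.annotations.get("topology", "") or "").lower() == "circular"
        feats = []
        seen_spans: set[tuple[int, int, str]] = set()
        for feat in rec.features:
            if feat.type not in _FEATURE_TYPES or feat.type == "source":
                continue
            raw = _feature_name(feat)
            if raw is None:
                continue
            if feat.type in ("misc_feature", "D-loop"):
                name, cls = "NCR", "NCR"
            else:
                name = normalize_gene_name(raw)
                name = _resolve_trna_isoacceptor(name, feat)
                try:
                    cls = gene_class(name)
                except ValueError:
                    raise ValueError(f"{path}: unknown gene name {raw!r} in record {rec.id}")
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            key = (start, end, name)
            if key in seen_spans:  # gene + CDS/tRNA pair annotating the same span
                continue
            seen_spans.add(key)
            partial = "<" in str(feat.location) or ">" in str(feat.location)
            feats.append(GeneFeature(name, start, end, strand, partial, cls))
        names = _suffix_duplicates([f.name for f in feats])
        feats = [replace(f, name=n) for f, n in zip(feats, names)]
        if not feats:
            logger.warning("%s: record %s has no gene features", path, rec.id)
        genomes.append(
            AnnotatedGenome(
                id=rec.id or rec.name,
                length=len(rec.seq),
                circular=circular,
                sequence=str(rec.seq) if len(rec.seq) else None,
                features=feats,
            )
        )
    return genomes


def write_genbank(genomes: Iterable[AnnotatedGenome], path: str | Path) -> None:
    """Minimal GenBank writer for synthetic output (round-trips read_genbank)."""
    records = []
    for g in genomes:
        seq = Seq(g.sequence if g.sequence is not None else "N" * g.length)
        rec = SeqRecord(seq, id=g.id, name=g.id[:16], description="synthetic mt chromosome")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if g.circular else "linear"
        for f in g.features:
            ftype = {"PCG": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "NCR": "misc_feature"}[f.gene_class]
            loc = FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "-" else 1)
            rec.features.append(SeqFeature(loc, type=ftype, qualifiers={"gene": [f.name]}))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


# ---------------------------------------------------------------------------
# NCR materialisation
# ---------------------------------------------------------------------------

def materialize_ncrs(genome: AnnotatedGenome, min_gap: int = DEFAULT_NCR_MIN_GAP) -> AnnotatedGenome:
    """Turn inter-feature gaps >= min_gap into NCR pseudo-features."""
    if min_gap < 40:
        raise ValueError("min_gap below 40 bases would call spacers NCRs")
    coding = [f for f in genome.features if f.gene_class != "NCR"]
    if not coding:
        return genome
    ncrs = []
    n = 0
    for a, b in zip(coding, coding[1:]):
        gap = b.start - a.end - 1
        if gap >= min_gap:
            n += 1
            ncrs.append(GeneFeature(f"NCR{n}", a.end + 1, b.start - 1, "+", False, "NCR"))
    if genome.circular:
        gap = genome.length - coding[-1].end + coding[0].start - 1
        if gap >= min_gap:
            n += 1
            start = coding[-1].end + 1
            end = coding[0].start - 1
            if start > genome.length:
                start -= genome.length
            if end < 1:
                end += genome.length
            ncrs.append(GeneFeature(f"NCR{n}", start, end, "+", False, "NCR"))
    return AnnotatedGenome(
        id=genome.id, length=genome.length, circular=genome.circular,
        sequence=genome.sequence, features=coding + ncrs,
    )


# ---------------------------------------------------------------------------
# linearisation
# ---------------------------------------------------------------------------

def majority_strand(order: GeneOrder) -> str:
    """Strand carrying more features; ties go to the strand carrying cox1."""
    plus = sum(1 for t in order.tokens if not t.startswith("-"))
    minus = len(order.tokens) - plus
    if plus != minus:
        return "+" if plus > minus else "-"
    for t in order.tokens:
        if base_token(unsigned(t)) == "cox1":
            return "-" if t.startswith("-") else "+"
    return "+"


def linearize(order: GeneOrder | AnnotatedGenome, anchor_rule: str = "auto") -> GeneOrder:
    """Rotate a circular order to start at the tRNA immediately upstream of cox1.

    "Upstream" is read on the majority strand: if most genes (or cox1, on a
    tie) sit on the minus strand the circle is reverse-complemented first, so
    rotations and global strand flips of the same genome linearise identically.
    ``anchor_rule`` may also name a gene token to anchor on directly.
    """
    if isinstance(order, AnnotatedGenome):
        order = order.gene_order()
    if not order.circular:
        return order
    toks = order.tokens
    if majority_strand(order) == "-":
        order = order.reverse_complement()
        toks = order.tokens
    if anchor_rule == "auto":
        cox1_idx = [i for i, t in enumerate(toks) if base_token(unsigned(t)) == "cox1"]
        if not cox1_idx:
            raise ValueError("no cox1 in order and no fallback anchor supplied")
        i = cox1_idx[0]
        j = (i - 1) % len(toks)
        if gene_class(unsigned(toks[j])) != "tRNA":
            # no tRNA immediately upstream: anchor on cox1 itself
            j = i
        return GeneOrder(toks[j:] + toks[:j], circular=True)
    anchor_idx = [i for i, t in enumerate(toks) if unsigned(t) == anchor_rule]
    if not anchor_idx:
        raise ValueError(f"anchor gene {anchor_rule!r} not present")
    j = anchor_idx[0]
    return GeneOrder(toks[j:] + toks[:j], circular=True)


# ---------------------------------------------------------------------------
# gene-order tables
# ---------------------------------------------------------------------------

def parse_order_tokens(text: str, *, where: str = "") -> GeneOrder:
    raw = [t.strip() for t in text.split(",") if t.strip()]
    if not raw:
        raise ValueError(f"empty gene order{where}")
    tokens = []
    for col, tok in enumerate(raw, start=1):
        sign = ""
        if tok.startswith("-"):
            sign, tok = "-", tok[1:]
        try:
            norm = normalize_gene_name(tok)
        except ValueError as exc:
            raise ValueError(f"unknown token {tok!r}{where}, column {col}") from exc
        tokens.append(sign + norm)
    suffixed = _suffix_duplicates([unsigned(t) for t in tokens])
    tokens = [("-" if t.startswith("-") else "") + s for t, s in zip(tokens, suffixed)]
    return GeneOrder(tuple(tokens), circular=True)


def read_gene_order_table(path: str | Path) -> list[tuple[str, GeneOrder]]:
    """Read a TSV of ``taxon<TAB>tok1,tok2,...`` rows (``#`` lines skipped).

    A trailing ``linear`` in a third column marks a non-circular fragment.
    """
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise ValueError(f"{path}: row {lineno} is empty or malformed")
        taxon = parts[0].strip()
        order = parse_order_tokens(parts[1], where=f" ({path}, row {lineno})")
        if len(parts) > 2 and parts[2].strip().lower() == "linear":
            order = GeneOrder(order.tokens, circular=False)
        out.append((taxon, order))
    return out


def write_gene_order_table(rows: Iterable[tuple[str, GeneOrder]], path: str | Path) -> None:
    lines = []
    for taxon, order in rows:
        topo = "" if order.circular else "\tlinear"
        lines.append(f"{taxon}\t{','.join(order.tokens)}{topo}")
    Path(path).write_text("\n".join(lines) + "\n")
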