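"""Canonical 37-gene mitochondrial vocabulary and name normalisation.

The bilaterian mitochondrial genome carries 13 protein-coding genes (PCGs),
two ribosomal RNAs and 22 transfer RNAs.  tRNAs are named ``trnX`` by the
single-letter amino-acid code, with the two leucine and two serine isoacceptors
distinguished as ``trnL1``/``trnL2`` (anticodons TAG/TAA) and ``trnS1``/``trnS2``
(TCT/TGA).  Everything downstream of annotation -- boundary extraction,
character coding, minicircle typing -- keys on these canonical tokens.
"""

from __future__ import annotations

PCGS: tuple[str, ...] = (
    "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "atp6", "atp8",
)

RRNAS: tuple[str, ...] = ("rrnS", "rrnL")

# 22 tRNAs; leucine and serine each have two isoacceptors.
TRNAS: tuple[str, ...] = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

CANONICAL_GENES: tuple[str, ...] = PCGS + RRNAS + TRNAS

# tokens accepted from tables where the isoacceptor is not resolved
AMBIGUOUS_TRNAS: tuple[str, ...] = ("trnL", "trnS")

GENE_CLASSES = {"PCG", "rRNA", "tRNA", "NCR"}

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# Alias table for names seen in GenBank records and hand-made tables.
_ALIASES: dict[str, str] = {
    "coi": "cox1", "cox1": "cox1", "co1": "cox1", "coxi": "cox1",
    "coii": "cox2", "cox2": "cox2", "co2": "cox2", "coxii": "cox2",
    "coiii": "cox3", "cox3": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cob": "cob", "cytb": "cob", "cyt b": "cob", "cyt-b": "cob", "cb": "cob",
    "atp6": "atp6", "atpase6": "atp6", "atpase 6": "atp6", "a6": "atp6",
    "atp8": "atp8", "atpase8": "atp8", "atpase 8": "atp8", "a8": "atp8",
    "nad1": "nad1", "nd1": "nad1", "nadh1": "nad1",
    "nad2": "nad2", "nd2": "nad2", "nadh2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nadh3": "nad3",
    "nad4": "nad4", "nd4": "nad4", "nadh4": "nad4",
    "nad4l": "nad4L", "nd4l": "nad4L", "nadh4l": "nad4L",
    "nad5": "nad5", "nd5": "nad5", "nadh5": "nad5",
    "nad6": "nad6", "nd6": "nad6", "nadh6": "nad6",
    "rrns": "rrnS", "12s": "rrnS", "s-rrna": "rrnS", "srrna": "rrnS",
    "12s rrna": "rrnS", "rrn12": "rrnS", "mtssu": "rrnS", "ssu": "rrnS",
    "small subunit ribosomal rna": "rrnS", "12s ribosomal rna": "rrnS",
    "rrnl": "rrnL", "16s": "rrnL", "l-rrna": "rrnL", "lrrna": "rrnL",
    "16s rrna": "rrnL", "rrn16": "rrnL", "mtlsu": "rrnL", "lsu": "rrnL",
    "large subunit ribosomal rna": "rrnL", "16s ribosomal rna": "rrnL",
}


def _trna_alias(low: str) -> str | None:
    """Map tRNA spellings (tRNA-Lys, trnK, trnL2, tRNA-Leu(TAA)...) to a token."""
    low = low.strip()
    for prefix in ("trna-", "trna_", "trna ", "trn", "trna"):
        if low.startswith(prefix):
            rest = low[len(prefix):].strip()
            break
    else:
        return None
    if not rest:
        return None
    # explicit anticodon qualifier, e.g. "leu(taa)" / "l(uaa)"
    anticodon = None
    if "(" in rest and rest.endswith(")"):
        rest, ac = rest[:-1].split("(", 1)
        anticodon = ac.strip().replace("u", "t")
        rest = rest.strip()
    if rest in _AA3_TO_1:
        letter = _AA3_TO_1[rest]
    elif len(rest) <= 2 and rest[0].isalpha():
        letter = rest[0].upper()
        if len(rest) == 2:
            if rest[1] in "12":
                return f"trn{letter}{rest[1]}" if letter in "LS" else None
            return None
    else:
        return None
    if letter in ("L", "S"):
        if anticodon:
            if letter == "L":
                return "trnL1" if anticodon == "tag" else "trnL2"
            return "trnS1" if anticodon == "tct" else "trnS2"
        return f"trn{letter}"  # ambiguous isoacceptor, resolved/flagged upstream
    if letter in "ACDEFGHIKMNPQRTVWY":
        return f"trn{letter}"
    return None


def normalize_gene_name(raw_name: str) -> str:
    """Map a raw annotation name onto the canonical vocabulary.

    Returns one of the 37 canonical tokens, or the ambiguous ``trnL``/``trnS``
    when a table gives no isoacceptor information.  Raises ``ValueError`` for
    anything that has no normalisation rule; silent pass-through is never done.
    """
    if not raw_name or not raw_name.strip():
        raise ValueError("empty gene name")
    name = raw_name.strip()
    # strip a duplicate suffix and re-attach afterwards
    suffix = ""
    base = name
    if "_" in name:
        stem, _, tail = name.rpartition("_")
        if tail.isdigit():
            base, suffix = stem, f"_{tail}"
    low = base.lower()
    if base in CANONICAL_GENES or base in AMBIGUOUS_TRNAS:
        return base + suffix
    if low in _ALIASES:
        return _ALIASES[low] + suffix
    trna = _trna_alias(low)
    if trna is not None:
        return trna + suffix
    # case-insensitive canonical (e.g. "NAD4L", "RrnS")
    for tok in CANONICAL_GENES:
        if low == tok.lower():
            return tok + suffix
    raise ValueError(f"no normalization rule for gene name {raw_name!r}")


def base_token(token: str) -> str:
    """Strip a duplicate suffix: ``trnK_3`` -> ``trnK``."""
    stem, _, tail = token.rpartition("_")
    if tail.isdigit() and stem:
        return stem
    return token


def gene_class(token: str) -> str:
    """Functional class of a canonical token (duplicates collapse first)."""
    tok = base_token(token)
    if tok in PCGS:
        return "PCG"
    if tok in RRNAS:
        return "rRNA"
    if tok in TRNAS or tok in AMBIGUOUS_TRNAS:
        return "tRNA"
    if tok == "NCR" or tok.startswith("NCR"):
        return "NCR"
    raise ValueError(f"unknown gene token {token!r}")


def is_major(token: str) -> bool:
    """Major gene = PCG or rRNA (the unit minicircle typing counts)."""
    return gene_class(token) in ("PCG", "rRNA")
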