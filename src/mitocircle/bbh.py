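"""Reciprocal best-hit (BBH) orthology from tabular similarity hits.

Operates on standard 12-column tabular alignment output (query, subject,
percent identity, alignment length, mismatches, gap opens, q.start, q.end,
s.start, s.end, e-value, bitscore).  The search itself is outside scope: hit
tables are inputs.  Multiple HSPs for one query-subject pair collapse to the
maximum bitscore; per query the best subject is the one with the highest
bitscore (ties: lower e-value, then lexicographic subject id); a pair (a, b)
is orthologous iff a's best hit is b and b's best hit is a.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class CategorySummary:
    category: str
    total: int
    matched: int

    @property
    def percent(self) -> float:
        return round(100.0 * self.matched / self.total, 1) if self.total else 0.0


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column tab-separated hit table; bad rows raise with line number."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS,
                         dtype={"query": str, "subject": str}, comment="#")
    except Exception as exc:
        raise ValueError(f"{path}: unparseable hit table: {exc}") from exc
    for col in ("evalue", "bitscore"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise ValueError(f"{path}: unparseable {col} at line {int(bad.idxmax()) + 1}")
        df[col] = pd.to_numeric(df[col])
    if (df["evalue"] < 0).any():
        raise ValueError(f"{path}: negative e-value")
    return df


def best_hit(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query after collapsing HSPs to max bitscore."""
    if hits.empty:
        return {}
    collapsed = (
        hits.groupby(["query", "subject"], as_index=False)
        .agg(bitscore=("bitscore", "max"), evalue=("evalue", "min"))
    )
    ranked = collapsed.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    top = ranked.drop_duplicates("query", keep="first")
    return dict(zip(top["query"], top["subject"]))


def reciprocal_pairs(forward: Mapping[str, str], reverse: Mapping[str, str]
                     ) -> set[tuple[str, str]]:
    """(a, b) pairs with forward[a] == b and reverse[b] == a."""
    return {(a, b) for a, b in forward.items() if reverse.get(b) == a}


def read_reference(path: str | Path | None = None) -> pd.DataFrame:
    """Reference gene list with one functional category per gene.

    Without a path, the packaged synthetic 315-gene nuclear-encoded,
    mitochondrially-targeted reference (six categories at the study's census
    sizes) is used; real gene-level content can be substituted.
    """
    if path is None:
        with resources.as_file(
            resources.files("mitocircle.fixtures") / "ne_mt_categories_synthetic.tsv"
        ) as p:
            return read_reference(p)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                     names=["gene", "category"], header=None)
    if df["category"].isna().any():
        missing = df.loc[df["category"].isna(), "gene"].tolist()
        raise ValueError(f"uncategorized genes: {missing[:5]}")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate genes in reference")
    return df


def category_summary(pairs: Iterable[tuple[str, str]], reference: pd.DataFrame
                     ) -> tuple[list[CategorySummary], list[str]]:
    """Per-category and overall match counts, plus the list of absent genes."""
    matched_genes = {a for a, _ in pairs}
    out = []
    for cat, sub in reference.groupby("category", sort=False):
        got = sum(1 for g in sub["gene"] if g in matched_genes)
        out.append(CategorySummary(cat, len(sub), got))
    out.append(CategorySummary("overall", len(reference),
                               sum(s.matched for s in out)))
    absent = [g for g in reference["gene"] if g not in matched_genes]
    return out, absent


def summary_frame(summaries: Sequence[CategorySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.category, s.total, s.matched, s.percent) for s in summaries],
        columns=["category", "total", "matched", "percent"],
    )
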