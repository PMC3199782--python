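"""Binary rearrangement characters mapped on a rooted phylogeny.

Each derived gene boundary is a binary character: present (1), absent (0) or
unknown (?, the sequenced chromosomes lack a flanking gene).  Characters are
absent from the ancestral arrangement by construction, so the root is anchored
to state 0 through a virtual ancestral edge; a gain on that edge is legal and
counted (a boundary may be derived for the whole study clade).

Two optimisations are computed:

* **Fitch** (minimum change): unknowns are free to take either state.  All
  co-optimal (gains, losses) splits of the minimum change count are
  enumerated.  The reported reconstruction minimises, in order, (i) the number
  of unknown tips that must be assigned the derived state and (ii) the number
  of gains.  Rule (i) keeps a single-origin reading from resting on missing
  data: when one gain plus one loss ties with two independent gains but the
  single-origin map only works by treating unknown tips as present, the
  convergent map is reported.
* **Dollo** (single origin): one gain on the edge above the MRCA of the
  1-tips, then the minimum number of 1->0 losses covering the 0-tips inside
  that clade; unknown tips inside the clade are assigned whichever state
  avoids losses and are reported separately.

Polytomies are hard: one gain on a polytomy edge serves all its daughters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

STATES = ("0", "1", "?")


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

@dataclass
class Node:
    label: str | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list[str]:
        if self.is_tip:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.tips())
        return out

    def walk(self) -> Iterable["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()


class Phylogeny:
    """A rooted tree with uniquely-labelled tips; polytomies permitted."""

    def __init__(self, root: Node):
        self.root = root
        tips = root.tips()
        if len(tips) != len(set(tips)):
            raise ValueError("tip labels are not unique")
        self.tip_labels = tips

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(_convert(tree.seed_node))

    @classmethod
    def from_file(cls, path: str | Path) -> "Phylogeny":
        return cls.from_newick(Path(path).read_text())

    def mrca(self, labels: Iterable[str]) -> Node:
        want = set(labels)
        missing = want - set(self.tip_labels)
        if missing:
            raise ValueError(f"taxa not on tree: {sorted(missing)}")
        node = self.root
        while True:
            carriers = [c for c in node.children if want & set(c.tips())]
            if len(carriers) == 1 and not carriers[0].is_tip:
                node = carriers[0]
            elif len(carriers) == 1 and carriers[0].is_tip:
                return carriers[0]
            else:
                return node


def _convert(dnode) -> Node:
    if dnode.is_leaf():
        return Node(label=dnode.taxon.label if dnode.taxon else dnode.label)
    return Node(label=None, children=[_convert(c) for c in dnode.child_nodes()])


def study_tree() -> Phylogeny:
    """The packaged ten-genus louse topology (user-replaceable fixture)."""
    with resources.as_file(resources.files("mitocircle.fixtures") / "louse_study_tree.nwk") as p:
        return Phylogeny.from_file(p)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class MappingResult:
    character: str
    scheme: str  # fitch | dollo
    gains: int
    losses: int
    unknown_tips: int
    min_changes: int | None = None
    co_optimal: list[tuple[int, int]] = field(default_factory=list)
    origin_node: tuple[str, ...] | None = None  # tips of the gain clade
    assignment: dict[str, str] = field(default_factory=dict)  # tip -> assigned state


# ---------------------------------------------------------------------------
# Fitch (minimum change) with co-optimal split enumeration
# ---------------------------------------------------------------------------

def _pareto(triples: Iterable[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Keep triples (gains, losses, forced_unknowns) not dominated elementwise."""
    items = sorted(set(triples))
    keep: list[tuple[int, int, int]] = []
    for t in items:
        if not any(k[0] <= t[0] and k[1] <= t[1] and k[2] <= t[2] and k != t for k in items):
            keep.append(t)
    return keep


def _fitch_sets(node: Node, states: Mapping[str, str]) -> dict[str, list[tuple[int, int, int]]]:
    """Pareto sets of (gains, losses, forced-?-present) per possible node state."""
    if node.is_tip:
        s = states.get(node.label, "?")
        if s == "0":
            return {"0": [(0, 0, 0)], "1": []}
        if s == "1":
            return {"0": [], "1": [(0, 0, 0)]}
        return {"0": [(0, 0, 0)], "1": [(0, 0, 1)]}
    child_sets = [_fitch_sets(c, states) for c in node.children]
    out: dict[str, list[tuple[int, int, int]]] = {}
    for s in ("0", "1"):
        acc: list[tuple[int, int, int]] = [(0, 0, 0)]
        for cs in child_sets:
            step: list[tuple[int, int, int]] = []
            for g0, l0, q0 in acc:
                for cstate in ("0", "1"):
                    for g, l, q in cs[cstate]:
                        dg = 1 if (s == "0" and cstate == "1") else 0
                        dl = 1 if (s == "1" and cstate == "0") else 0
                        step.append((g0 + g + dg, l0 + l + dl, q0 + q))
            acc = _pareto(step)
            if not acc:
                break
        out[s] = acc
    return out


def _trace(node: Node, states: Mapping[str, str], target: tuple[str, tuple[int, int, int]],
           assignment: dict, gain_edges: list, loss_edges: list) -> None:
    """Reconstruct one labelling achieving the target (state, triple) at node."""
    s, (g, l, q) = target
    if node.is_tip:
        assignment[node.label] = s
        return
    child_sets = [_fitch_sets(c, states) for c in node.children]
    # find child states/triples summing to (g,l,q)
    choices: list[tuple[str, tuple[int, int, int]]] = []

    def rec(i: int, rg: int, rl: int, rq: int, picked: list) -> bool:
        if i == len(child_sets):
            if (rg, rl, rq) == (0, 0, 0):
                choices.extend(picked)
                return True
            return False
        for cstate in ("0", "1"):
            for trip in child_sets[i][cstate]:
                dg = 1 if (s == "0" and cstate == "1") else 0
                dl = 1 if (s == "1" and cstate == "0") else 0
                ng, nl, nq = rg - trip[0] - dg, rl - trip[1] - dl, rq - trip[2]
                if ng >= 0 and nl >= 0 and nq >= 0:
                    if rec(i + 1, ng, nl, nq, picked + [(cstate, trip)]):
                        return True
        return False

    if not rec(0, g, l, q, []):
        raise RuntimeError("fitch backtrace failed")
    for child, (cstate, trip) in zip(node.children, choices):
        if s == "0" and cstate == "1":
            gain_edges.append(child)
        if s == "1" and cstate == "0":
            loss_edges.append(child)
        _trace(child, states, (cstate, trip), assignment, gain_edges, loss_edges)


def fitch_map(tree: Phylogeny, states: Mapping[str, str], character: str = "",
              root_state: str = "0") -> MappingResult:
    """Minimum-change mapping of a binary character with unknowns.

    ``states`` maps tip label -> {0,1,?}; tips absent from the mapping are ?.
    Raises if a taxon in ``states`` is missing from the tree.
    """
    _check_taxa(tree, states)
    sets = _fitch_sets(tree.root, states)
    candidates: list[tuple[str, tuple[int, int, int]]] = []
    for s in ("0", "1"):
        for g, l, q in sets[s]:
            dg = 1 if (root_state == "0" and s == "1") else 0
            dl = 1 if (root_state == "1" and s == "0") else 0
            candidates.append((s, (g + dg, l + dl, q)))
    min_changes = min(g + l for _, (g, l, _) in candidates)
    co = sorted({(g, l) for _, (g, l, _) in candidates if g + l == min_changes})
    # selection: fewest forced-present unknowns, then fewest gains
    best = min(
        (c for c in candidates if c[1][0] + c[1][1] == min_changes),
        key=lambda c: (c[1][2], c[1][0]),
    )
    root_s, (g, l, q) = best
    # backtrace for the assignment and the origin clade
    assignment: dict[str, str] = {}
    gain_edges: list[Node] = []
    loss_edges: list[Node] = []
    root_triple = (g - (1 if (root_state == "0" and root_s == "1") else 0),
                   l - (1 if (root_state == "1" and root_s == "0") else 0), q)
    _trace(tree.root, states, (root_s, root_triple), assignment, gain_edges, loss_edges)
    if root_s == "1" and root_state == "0":
        gain_edges.append(tree.root)
    origin = tuple(sorted(gain_edges[0].tips())) if len(gain_edges) == 1 else None
    return MappingResult(
        character=character, scheme="fitch", gains=g, losses=l, unknown_tips=q,
        min_changes=min_changes, co_optimal=co, origin_node=origin,
        assignment=assignment,
    )


def _check_taxa(tree: Phylogeny, states: Mapping[str, str]) -> None:
    missing = set(states) - set(tree.tip_labels)
    if missing:
        raise ValueError(f"matrix taxa missing from tree: {sorted(missing)}")
    bad = {v for v in states.values() if v not in STATES}
    if bad:
        raise ValueError(f"invalid states: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Dollo (single origin, multiple losses)
# ---------------------------------------------------------------------------

def _dollo_losses(node: Node, states: Mapping[str, str]) -> tuple[int, int]:
    """(cost keeping state 1, cost after loss) below ``node``; ? tips free."""
    if node.is_tip:
        s = states.get(node.label, "?")
        if s == "1":
            return (0, 10 ** 6)  # a 1-tip cannot sit below a loss
        if s == "0":
            return (10 ** 6, 0)
        return (0, 0)
    keep = 0
    lost = 0
    for c in node.children:
        k, l = _dollo_losses(c, states)
        keep += min(k, l + 1)  # lose on the child edge, or keep
        lost += l
    return keep, lost


def _dollo_assign(node: Node, states: Mapping[str, str], state: str,
                  assignment: dict[str, str]) -> None:
    if node.is_tip:
        s = states.get(node.label, "?")
        assignment[node.label] = s if s in ("0", "1") else state
        return
    for c in node.children:
        k, l = _dollo_losses(c, states)
        cstate = state
        if state == "1" and l + 1 < k:
            cstate = "0"
        _dollo_assign(c, states, cstate, assignment)


def dollo_map(tree: Phylogeny, states: Mapping[str, str], character: str = "") -> MappingResult:
    """Single-origin optimisation: gain above the MRCA of the 1-tips, losses within."""
    _check_taxa(tree, states)
    ones = [t for t, s in states.items() if s == "1"]
    if not ones:
        raise ValueError(f"character {character or '?'} has no tip in state 1")
    clade = tree.mrca(ones)
    keep, _ = _dollo_losses(clade, states)
    clade_tips = set(clade.tips())
    unknown_in_clade = sum(1 for t in clade_tips if states.get(t, "?") == "?")
    assignment = {t: states.get(t, "?") for t in tree.tip_labels}
    for t in tree.tip_labels:
        if t not in clade_tips and assignment.get(t) == "?":
            assignment[t] = "0"
    _dollo_assign(clade, states, "1", assignment)
    return MappingResult(
        character=character, scheme="dollo", gains=1, losses=keep,
        unknown_tips=unknown_in_clade, origin_node=tuple(sorted(clade_tips)),
        assignment=assignment,
    )


# ---------------------------------------------------------------------------
# classification and batch mapping
# ---------------------------------------------------------------------------

CLEAN = "clean_synapomorphy"
SYN_WITH = "synapomorphy_with_loss_or_unknown"
CONVERGENT = "convergent"


def classify_character(fitch: MappingResult, dollo: MappingResult) -> str:
    """Class of a derived boundary from its two mappings.

    clean: a single gain, no losses, and no unknown tip inside the gain clade;
    with_loss_or_unknown: a single gain otherwise; convergent: >= 2 gains in
    the reported minimum-change reconstruction.
    """
    if fitch.character != dollo.character:
        raise ValueError("results describe different characters")
    if fitch.gains == 1 and fitch.losses == 0 and fitch.unknown_tips == 0:
        return CLEAN
    if fitch.gains == 1:
        return SYN_WITH
    return CONVERGENT


def map_characters(tree: Phylogeny, matrix: pd.DataFrame,
                   scheme: str = "both") -> pd.DataFrame:
    """Map every matrix column; rows = characters, mapping counts as columns."""
    rows = []
    for char in matrix.columns:
        states = {t: str(matrix.loc[t, char]) for t in matrix.index}
        rec: dict = {"character": char}
        f = d = None
        if scheme in ("fitch", "both"):
            f = fitch_map(tree, states, char)
            rec.update(fitch_gains=f.gains, fitch_losses=f.losses,
                       fitch_unknowns=f.unknown_tips, min_changes=f.min_changes,
                       co_optimal=";".join(f"{g}g{l}l" for g, l in f.co_optimal))
        if scheme in ("dollo", "both"):
            d = dollo_map(tree, states, char)
            rec.update(dollo_losses=d.losses, dollo_unknowns=d.unknown_tips)
        if f is not None and d is not None:
            rec["class"] = classify_character(f, d)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("character")


# ---------------------------------------------------------------------------
# the study matrix, rebuilt from boundary incidence + gene inventories
# ---------------------------------------------------------------------------

def build_study_matrix() -> pd.DataFrame:
    """Character matrix (taxa x A-K) for the ten-louse study set.

    1 where the junction is observed, ? where the taxon's sequenced genes lack
    a flanking gene, 0 where both genes are present but not adjacent.
    """
    fx = resources.files("mitocircle.fixtures")
    chars: list[tuple[str, str, str, set[str]]] = []
    with resources.as_file(fx / "louse_boundary_characters.tsv") as p:
        for line in Path(p).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            label, g1, g2, present = line.split("\t")
            chars.append((label, g1, g2, set(present.split(","))))
    content: dict[str, set[str] | None] = {}
    with resources.as_file(fx / "louse_gene_content.tsv") as p:
        for line in Path(p).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            taxon, genes = line.split("\t")
            content[taxon] = None if genes.strip() == "ALL" else set(genes.split(","))
    data: dict[str, dict[str, str]] = {}
    for label, g1, g2, present in chars:
        col = {}
        for taxon, genes in content.items():
            if taxon in present:
                col[taxon] = "1"
            elif genes is not None and (g1 not in genes or g2 not in genes):
                col[taxon] = "?"
            else:
                col[taxon] = "0"
        data[label] = col
    return pd.DataFrame(data, columns=[c[0] for c in chars],
                        index=list(content)).sort_index()


def read_character_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    bad = set(df.values.ravel()) - set(STATES)
    if bad:
        raise ValueError(f"invalid matrix states: {sorted(bad)}")
    for char in df.columns:
        if "1" not in set(df[char]):
            raise ValueError(f"character {char} has no presence state")
    return df
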