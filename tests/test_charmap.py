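"""Fitch/Dollo character mapping: oracle equivalence and the study accounting."""

import random

import pytest

from mitocircle.charmap import (CLEAN, CONVERGENT, SYN_WITH, Phylogeny,
                                classify_character, dollo_map, fitch_map,
                                map_characters)

from conftest import fitch_oracle, random_phylogeny


def _random_states(rng, tips, p_unknown=0.25):
    states = {}
    for t in tips:
        r = rng.random()
        states[t] = "?" if r < p_unknown else ("1" if r < p_unknown + 0.4 else "0")
    return states


def test_fitch_equals_exhaustive_minimum_on_small_trees():
    """The DP change count matches brute-force enumeration of all labellings
    (trees of up to 7 tips, unknown tips free)."""
    rng = random.Random(42)
    for _ in range(150):
        n = rng.randint(2, 7)
        tree = random_phylogeny(rng, n)
        states = _random_states(rng, tree.tip_labels)
        f = fitch_map(tree, states)
        assert f.min_changes == fitch_oracle(tree, states)
        assert f.gains + f.losses == f.min_changes


def test_fitch_reported_split_is_co_optimal():
    rng = random.Random(7)
    for _ in range(50):
        tree = random_phylogeny(rng, rng.randint(3, 7))
        states = _random_states(rng, tree.tip_labels)
        f = fitch_map(tree, states)
        assert (f.gains, f.losses) in f.co_optimal


def test_adding_unknown_tip_never_increases_change_count():
    rng = random.Random(3)
    for _ in range(60):
        tree = random_phylogeny(rng, rng.randint(3, 7))
        states = _random_states(rng, tree.tip_labels, p_unknown=0.0)
        base = fitch_map(tree, states).min_changes
        flip = rng.choice(tree.tip_labels)
        states2 = dict(states, **{flip: "?"})
        assert fitch_map(tree, states2).min_changes <= base


def test_tip_relabeling_leaves_counts_unchanged():
    rng = random.Random(11)
    tree = random_phylogeny(rng, 6)
    states = _random_states(rng, tree.tip_labels)
    f1 = fitch_map(tree, states)
    mapping = {t: f"x_{t}" for t in tree.tip_labels}
    for node in tree.root.walk():
        if node.is_tip:
            node.label = mapping[node.label]
    tree2 = Phylogeny(tree.root)
    f2 = fitch_map(tree2, {mapping[t]: s for t, s in states.items()})
    assert (f1.gains, f1.losses, f1.min_changes) == (f2.gains, f2.losses, f2.min_changes)


def test_fitch_count_never_exceeds_dollo_count():
    rng = random.Random(19)
    for _ in range(60):
        tree = random_phylogeny(rng, rng.randint(3, 7))
        states = _random_states(rng, tree.tip_labels)
        if "1" not in states.values():
            continue
        f = fitch_map(tree, states)
        d = dollo_map(tree, states)
        assert f.min_changes <= 1 + d.losses


def test_constant_present_character_is_single_root_gain():
    tree = Phylogeny.from_newick("((a,b),(c,d));")
    f = fitch_map(tree, {t: "1" for t in "abcd"})
    assert (f.gains, f.losses) == (1, 0)
    assert f.origin_node == ("a", "b", "c", "d")


def test_dollo_errors_without_presence():
    tree = Phylogeny.from_newick("((a,b),c);")
    with pytest.raises(ValueError):
        dollo_map(tree, {"a": "0", "b": "0", "c": "?"})


def test_taxon_missing_from_tree_raises():
    tree = Phylogeny.from_newick("((a,b),c);")
    with pytest.raises(ValueError):
        fitch_map(tree, {"a": "1", "zz": "0"})


def test_dollo_clade_confined_presence_has_no_losses():
    tree = Phylogeny.from_newick("(((a,b),c),(d,e));")
    d = dollo_map(tree, {"a": "1", "b": "1", "c": "0", "d": "0", "e": "0"})
    assert d.losses == 0
    assert d.origin_node == ("a", "b")


# ---------------------------------------------------------------------------
# the ten-louse study accounting
# ---------------------------------------------------------------------------

def test_study_matrix_states(study_matrix):
    assert list(study_matrix.columns) == list("ABCDEFGHIJK")
    assert study_matrix.loc["Heterodoxus", "B"] == "1"
    assert study_matrix.loc["Quadraceps", "C"] == "?"  # flanking genes unsequenced
    assert study_matrix.loc["Pediculus", "C"] == "0"  # genes present, not adjacent


def test_study_character_classes(study_tree, study_matrix):
    """Two clean synapomorphies (F,H); five single-origin characters with
    losses or unknowns (A,C,E,I,J); four convergent characters (B,D,G,K)."""
    res = map_characters(study_tree, study_matrix, scheme="both")
    classes = res["class"]
    assert sorted(classes[classes == CLEAN].index) == ["F", "H"]
    assert sorted(classes[classes == SYN_WITH].index) == ["A", "C", "E", "I", "J"]
    assert sorted(classes[classes == CONVERGENT].index) == ["B", "D", "G", "K"]


@pytest.mark.parametrize(
    "char, losses, unknowns",
    [("B", 2, 0), ("G", 2, 3), ("K", 1, 2), ("D", 2, 3)],
)
def test_study_dollo_accounting(study_tree, study_matrix, char, losses, unknowns):
    """Single-origin loss/unknown counts for the convergent characters."""
    states = {t: study_matrix.loc[t, char] for t in study_matrix.index}
    d = dollo_map(study_tree, states, char)
    assert (d.losses, d.unknown_tips) == (losses, unknowns)


def test_clean_synapomorphy_clade_is_goniodid_plus_qp(study_tree, study_matrix):
    states = {t: study_matrix.loc[t, "F"] for t in study_matrix.index}
    f = fitch_map(study_tree, states, "F")
    assert f.origin_node == ("Campanulotes", "Coloceras", "Philopterus", "Quadraceps")
    assert (f.gains, f.losses, f.unknown_tips) == (1, 0, 0)


def test_classify_uses_unknowns_inside_clade(study_tree, study_matrix):
    """E maps as a single gain with no losses but its clade contains unknown
    tips, so it is not a clean synapomorphy."""
    states = {t: study_matrix.loc[t, "E"] for t in study_matrix.index}
    f = fitch_map(study_tree, states, "E")
    d = dollo_map(study_tree, states, "E")
    assert (f.gains, f.losses) == (1, 0)
    assert f.unknown_tips > 0
    assert classify_character(f, d) == SYN_WITH
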