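"""Boundary extraction, canonicalisation and plesiomorphic/derived accounting."""

import itertools
import random

import pytest

from mitocircle.boundaries import (Boundary, ancestral_insect_order,
                                   boundary_summary, build_boundary_table,
                                   canonical_key, classify_boundaries,
                                   extract_boundaries, shared_derived)
from mitocircle.genome_io import GeneOrder, parse_order_tokens, read_gene_order_table
from mitocircle.synthetic import invert, translocate
from importlib import resources


def test_canonical_key_identifies_reverse_complement_pair():
    assert canonical_key("trnY", "cox2") == canonical_key("-cox2", "-trnY")
    assert canonical_key("trnY", "cox2") != canonical_key("cox2", "trnY")


def test_duplicate_suffixes_collapse_in_keys():
    assert canonical_key("trnK_3", "nad4") == canonical_key("trnK", "nad4")


def test_circular_order_has_one_boundary_per_gene():
    order = parse_order_tokens("cox1,cox2,cox3,cob,nad1")
    assert len(extract_boundaries(order)) == 5
    linear = GeneOrder(order.tokens, circular=False)
    assert len(extract_boundaries(linear)) == 4


def test_single_gene_order_has_no_boundaries():
    assert extract_boundaries(GeneOrder(("cox1",), circular=True)) == set()


def test_reverse_complement_gives_identical_boundary_set():
    rng = random.Random(0)
    anc = ancestral_insect_order()
    for _ in range(10):
        toks = list(anc.tokens)
        rng.shuffle(toks)
        order = GeneOrder(tuple(toks), circular=True)
        fwd = {b.key for b in extract_boundaries(order)}
        rev = {b.key for b in extract_boundaries(order.reverse_complement())}
        assert fwd == rev


def test_collapse_trna_mode_matches_parent_boundary():
    """A one-tRNA-interrupted junction (trnF-trnX-nad6) realises the parent
    trnF-nad6 boundary only in collapse mode."""
    order = parse_order_tokens("trnF,trnD,nad6,cox1,cob")
    strict = {b.key for b in extract_boundaries(order)}
    collapsed = {b.key for b in extract_boundaries(order, collapse_trna=1)}
    parent = canonical_key("trnF", "nad6")
    assert parent not in strict
    assert parent in collapsed


def test_single_translocation_changes_exactly_three_boundaries():
    """Brute force over every single-gene translocation of a 10-gene circle."""
    genes = ("cox1", "cox2", "cox3", "cob", "nad1", "nad2", "nad3", "nad4", "atp6", "atp8")
    base = GeneOrder(genes, circular=True)
    ref = {b.key for b in extract_boundaries(base)}
    for src, dst in itertools.product(range(10), range(9)):
        moved = translocate(base, src, dst)
        # rotations of the same circle are identical; skip no-op moves
        if any(moved.rotate(k).tokens == base.tokens for k in range(10)):
            continue
        diff = ref ^ {b.key for b in extract_boundaries(moved)}
        assert len(diff) == 6  # 3 destroyed + 3 created


def test_block_inversion_changes_exactly_two_boundaries():
    genes = ("cox1", "cox2", "cox3", "cob", "nad1", "nad2", "nad3", "nad4", "atp6", "atp8")
    base = GeneOrder(genes, circular=True)
    ref = {b.key for b in extract_boundaries(base)}
    for start, k in itertools.product(range(10), range(2, 8)):
        inv = invert(base, start, k)
        diff = ref ^ {b.key for b in extract_boundaries(inv)}
        assert len(diff) == 4  # 2 destroyed + 2 created


def test_identity_with_reference_is_all_plesiomorphic():
    anc = ancestral_insect_order()
    t = build_boundary_table("anc_copy", [anc])
    t = classify_boundaries(t, anc)
    assert len(t.derived_keys()) == 0
    assert len(t.plesiomorphic_keys()) == 37


def test_most_rearranged_fixture_has_zero_plesiomorphic_boundaries():
    """The packaged synthetic stand-in for the most-rearranged complete genome
    shares no boundary with the ancestral insect arrangement."""
    with resources.as_file(resources.files("mitocircle.fixtures")
                           / "ibidoecus_synthetic_order.tsv") as p:
        [(_, order)] = read_gene_order_table(p)
    t = classify_boundaries(build_boundary_table("Ibidoecus_synthetic", [order]))
    assert len(t.plesiomorphic_keys()) == 0
    assert len(t.derived_keys()) == 37
    derived = t.derived_keys()
    for pair in [("trnI", "cox1"), ("trnY", "cox2"), ("trnF", "nad6"),
                 ("trnA", "trnG"), ("trnS2", "trnW"), ("trnL2", "cob")]:
        assert canonical_key(*pair) in derived


def test_shared_derived_recovers_planted_sharing():
    anc = ancestral_insect_order()
    shared_order = translocate(anc, 5, 20)  # same derived boundaries in two taxa
    tables = []
    for name, order in [("a", shared_order), ("b", shared_order), ("c", anc)]:
        tables.append(classify_boundaries(build_boundary_table(name, [order]), anc))
    m = shared_derived(tables, min_units=2)
    assert len(m) == 3  # one translocation creates three shared derived boundaries
    assert (m.loc[:, ["a", "b"]] == "1").all().all()
    assert (m.loc[:, "c"] == "0").all()


def test_shared_derived_unknown_states_from_missing_genes():
    anc = ancestral_insect_order()
    moved = translocate(anc, 5, 20)
    partial = GeneOrder(("cox1", "cob", "nad2"), circular=True)  # lacks the moved genes
    tables = [classify_boundaries(build_boundary_table(n, [o]), anc)
              for n, o in [("a", moved), ("b", moved), ("p", partial)]]
    m = shared_derived(tables, min_units=2)
    assert (m.loc[:, "p"] == "?").all()


def test_shared_derived_group_counts_as_one_unit():
    anc = ancestral_insect_order()
    moved = translocate(anc, 5, 20)
    tables = [classify_boundaries(build_boundary_table(n, [o]), anc)
              for n, o in [("g1", moved), ("g2", moved), ("x", anc)]]
    grouped = shared_derived(tables, groups={"fam": ["g1", "g2"]}, min_units=2)
    assert grouped.empty  # the two sharers collapse into one unit
    with pytest.raises(ValueError):
        shared_derived(tables, groups={"fam": ["g1"], "fam2": ["g1", "g2"]})


def test_shared_derived_monotone_in_min_units():
    anc = ancestral_insect_order()
    t1 = translocate(anc, 5, 20)
    tables = [classify_boundaries(build_boundary_table(n, [o]), anc)
              for n, o in [("a", t1), ("b", t1), ("c", anc)]]
    all_rows = shared_derived(tables, min_units=1)
    some = shared_derived(tables, min_units=2)
    assert set(some.index) <= set(all_rows.index)
    derived_union = set().union(*(t.derived_keys() for t in tables))
    assert set(all_rows.index) == derived_union


def test_boundary_summary_counts():
    anc = ancestral_insect_order()
    moved = translocate(anc, 5, 20)
    tables = [classify_boundaries(build_boundary_table(n, [o]), anc)
              for n, o in [("a", moved), ("b", moved)]]
    s = boundary_summary(tables)
    assert s["per_taxon"]["a"]["derived"] == 3
    assert s["unique_derived"] == 0  # identical genomes share every derived boundary
    assert s["shared_derived"] == 3
    assert s["shared_occurrences"] == 6
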