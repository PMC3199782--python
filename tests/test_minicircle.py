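"""Homopolymer scanning, deletion candidates, amplicons, chromosome typing."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocircle.minicircle import (amplicon_size, completeness,
                                   enumerate_deletion_candidates,
                                   find_homopolymers, type_chromosome_set)
from mitocircle.synthetic import make_deleted_pair, make_minicircle_set


def naive_runs(seq: str, base: str, min_len: int):
    """Quadratic oracle: every maximal run checked by explicit expansion."""
    out = []
    for i in range(len(seq)):
        if seq[i] == base and (i == 0 or seq[i - 1] != base):
            j = i
            while j + 1 < len(seq) and seq[j + 1] == base:
                j += 1
            if j - i + 1 >= min_len:
                out.append((i + 1, j + 1))
    return out


@settings(max_examples=50, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=300), st.integers(2, 6))
def test_scanner_agrees_with_quadratic_oracle(seq, min_len):
    got = [(r.start, r.end) for r in find_homopolymers(seq, "T", min_len)]
    assert got == naive_runs(seq, "T", min_len)


def test_scanner_rejects_non_nucleotides():
    with pytest.raises(ValueError, match="position"):
        find_homopolymers("ACGTNNACGT", "T", 2)


def test_scanner_both_strands_reports_complement_runs():
    runs = find_homopolymers("TTTTAAAA", "T", 4, both_strands=True)
    assert [(r.base, r.start, r.end) for r in runs] == [("T", 1, 4), ("A", 5, 8)]


def test_no_target_base_gives_empty():
    assert find_homopolymers("ACGACG", "T", 2) == []


def test_planted_run_recovery_with_host_annotation():
    full, _, truth = make_deleted_pair(11)
    runs = find_homopolymers(full.sequence, "T", 10, genome=full)
    assert [(r.start, r.end) for r in runs] == [truth["run_5p"], truth["run_3p"]]
    assert all(r.host_features for r in runs)


def test_candidate_matches_planted_deletion_and_casualties():
    full, deleted, truth = make_deleted_pair(3)
    runs = find_homopolymers(full.sequence, "T", 10, genome=full)
    cands = enumerate_deletion_candidates(full, runs)
    hits = [c for c in cands if c.deleted_length == truth["deleted_length"]]
    assert len(hits) == 1
    c = hits[0]
    assert c.removed_genes == truth["removed_genes"]
    assert c.truncated_genes == truth["truncated_genes"]
    assert deleted.length == full.length - c.deleted_length


def test_candidate_between_runs_with_no_feature_has_no_casualties():
    from mitocircle.genome_io import AnnotatedGenome, GeneFeature
    seq = list("ACG" * 400)
    seq[349:370] = "T" * 21
    seq[449:470] = "T" * 21
    g = AnnotatedGenome(
        id="toy", length=1200, circular=True, sequence="".join(seq[:1200]),
        features=[GeneFeature("cox1", 1, 300), GeneFeature("cob", 700, 900)],
    )
    runs = find_homopolymers(g.sequence, "T", 10, genome=g)
    assert len(runs) == 2
    cands = enumerate_deletion_candidates(g, runs, min_deleted=20, max_deleted=200)
    assert cands
    for c in cands:
        assert c.removed_genes == () and c.truncated_genes == ()


def test_amplicon_size_arithmetic():
    full, _, truth = make_deleted_pair(7)
    runs = find_homopolymers(full.sequence, "T", 10, genome=full)
    [c] = [c for c in enumerate_deletion_candidates(full, runs)
           if c.deleted_length == truth["deleted_length"]]
    assert amplicon_size(c, 325, 73, "deleted") == 398
    assert amplicon_size(c, 325, 73, "full") == 325 + truth["deleted_length"] + 73
    assert amplicon_size(c, 0, 0, "deleted") == 0
    # additivity: full minus deleted product equals the deleted span
    assert amplicon_size(c, 325, 73, "full") - amplicon_size(c, 325, 73, "deleted") \
        == c.deleted_length


def test_amplicon_offsets_exceeding_template_raise():
    full, _, truth = make_deleted_pair(8)
    runs = find_homopolymers(full.sequence, "T", 10, genome=full)
    [c] = [c for c in enumerate_deletion_candidates(full, runs)
           if c.deleted_length == truth["deleted_length"]]
    with pytest.raises(ValueError):
        amplicon_size(c, full.length, full.length, "deleted")
    with pytest.raises(ValueError):
        amplicon_size(c, -1, 0, "deleted")


@pytest.mark.parametrize("mtype", ["canonical", "type1", "type2", "type3"])
def test_generated_sets_type_correctly(mtype):
    chroms, truth = make_minicircle_set(23, mtype)
    rep = type_chromosome_set(chroms)
    assert rep.minicircle_type == mtype
    assert sorted(rep.missing_genes) == truth["missing"]


def test_typing_is_permutation_invariant():
    chroms, _ = make_minicircle_set(9, "type1")
    rng = random.Random(1)
    for _ in range(3):
        rng.shuffle(chroms)
        assert type_chromosome_set(chroms).minicircle_type == "type1"


def test_adding_full_chromosome_turns_type2_into_type1():
    chroms2, _ = make_minicircle_set(12, "type2")
    full, _ = make_minicircle_set(12, "canonical")
    assert type_chromosome_set(chroms2 + full).minicircle_type == "type1"


def test_empty_set_raises():
    with pytest.raises(ValueError):
        type_chromosome_set([])


def test_completeness_inventory():
    chroms, truth = make_minicircle_set(5, "type3")
    rep = type_chromosome_set(chroms)
    inv = completeness(rep)
    assert sorted(inv["PCG"] + inv["rRNA"] + inv["tRNA"]) == truth["missing"]
    full, _ = make_minicircle_set(5, "canonical")
    assert completeness(type_chromosome_set(full)) == {"PCG": [], "rRNA": [], "tRNA": []}
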