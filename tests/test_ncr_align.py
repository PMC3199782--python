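"""Control-region structure: conserved blocks, macrorepeats, hairpins."""

import random

import pytest

from mitocircle.ncr_align import (conserved_blocks, find_hairpin,
                                  find_macrorepeats, reverse_complement)
from mitocircle.synthetic import make_ncr_set, random_sequence


def test_identical_sequences_give_one_full_length_block():
    seq = random_sequence(0, 200)
    bm = conserved_blocks({"a": seq, "b": seq})
    assert len(bm.blocks) == 1
    b = bm.blocks[0]
    assert b.span("a") == (1, 200)
    assert b.span("b") == (1, 200)
    assert b.identity == 100.0


def test_planted_blocks_recovered_in_order():
    ncrs, truth = make_ncr_set(1)
    bm = conserved_blocks(ncrs)
    assert len(bm.blocks) == 3
    for b in bm.blocks:
        for chrom, s, e in b.spans:
            ts, te = truth["blocks"][chrom][b.id - 1]
            assert abs(s - ts) <= 5 and abs(e - te) <= 5


def test_block_detection_symmetric_in_input_order():
    ncrs, _ = make_ncr_set(2)
    a = conserved_blocks(ncrs)
    rev = dict(reversed(list(ncrs.items())))
    b = conserved_blocks(rev)
    assert [{c: (s, e) for c, s, e in blk.spans} for blk in a.blocks] == \
           [{c: (s, e) for c, s, e in blk.spans} for blk in b.blocks]


def test_short_sequence_excluded_but_pair_still_analysed():
    seq = random_sequence(3, 200)
    bm = conserved_blocks({"a": seq, "b": seq, "tiny": "ACGT"})
    assert bm.chromosomes == ("a", "b")
    with pytest.raises(ValueError):
        conserved_blocks({"a": seq, "tiny": "ACGT"})


def test_exact_tandem_repeat_found():
    unit = random_sequence(5, 60)
    reps = find_macrorepeats("A" * 0 + unit * 4)
    assert len(reps) == 1
    r = reps[0]
    assert (r.unit_length, r.copies, r.tandem) == (60, 4, True)
    assert (r.start, r.end) == (1, 240)


def test_planted_macrorepeats_recovered():
    for seed in range(5):
        ncrs, truth = make_ncr_set(seed)
        for name, (ts, te, unit, copies) in truth["repeats"].items():
            reps = find_macrorepeats(ncrs[name])
            match = [r for r in reps if r.unit_length == unit and r.copies == copies]
            assert match, (seed, name)
            assert abs(match[0].start - ts) <= 3 and abs(match[0].end - te) <= 3


def test_random_sequence_null_rate_at_default_unit():
    """False-positive rate of the repeat finder on unstructured sequence."""
    hits = 0
    for seed in range(30):
        if find_macrorepeats(random_sequence(seed + 1000, 1000), min_unit=40):
            hits += 1
    assert hits <= 2  # measured null behaviour: almost always empty


def test_too_short_sequence_has_no_repeats():
    assert find_macrorepeats("ACGT" * 10, min_unit=40) == []


# ---------------------------------------------------------------------------
# hairpin
# ---------------------------------------------------------------------------

def brute_force_hairpin_score(seq, min_stem, max_loop, allow_gu, max_bulges,
                              min_loop=3):
    """Independent recursive enumeration of every stem alignment."""
    from mitocircle.ncr_align import BULGE_PENALTY, GU, PAIR_GU, PAIR_WC, WC
    n = len(seq)
    best = None

    def rec(i, j, b, score, pairs):
        nonlocal best
        if pairs >= min_stem:
            if best is None or score > best:
                best = score
        if i < 0 or j >= n:
            return
        a, c = seq[i], seq[j]
        if (a, c) in WC:
            rec(i - 1, j + 1, b, score + PAIR_WC, pairs + 1)
        elif allow_gu and (a, c) in GU:
            rec(i - 1, j + 1, b, score + PAIR_GU, pairs + 1)
        if b < max_bulges:
            rec(i - 1, j, b + 1, score - BULGE_PENALTY, pairs)
            rec(i, j + 1, b + 1, score - BULGE_PENALTY, pairs)

    for l2 in range(n):
        for loop in range(min_loop, max_loop + 1):
            r1 = l2 + loop + 1
            if r1 >= n:
                break
            rec(l2, r1, 0, 0, 0)
    return best


def test_perfect_inverted_repeat_recovered():
    stem = "GATCCGATAGCA"  # 12-mer
    seq = "AAA" + stem + "TTTCA" + reverse_complement(stem) + "AAA"
    hp = find_hairpin(seq, min_stem=6, max_loop=10)
    assert hp is not None
    assert hp.pairs >= 12
    assert hp.score >= 24
    assert hp.structure.count(">") >= 12 - hp.gu_pairs - 2


def test_hairpin_score_matches_exhaustive_oracle():
    rng = random.Random(6)
    for _ in range(12):
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 45)))
        got = find_hairpin(seq, min_stem=4, max_loop=8, max_bulges=2)
        want = brute_force_hairpin_score(seq, 4, 8, True, 2)
        if want is None:
            assert got is None
        else:
            assert got is not None and got.score == want


def test_hairpin_structure_notation_is_consistent():
    ncrs, truth = make_ncr_set(4)
    # hairpin planted inside conserved block 1
    s, e = truth["blocks"]["ncr1"][0]
    hp = find_hairpin(ncrs["ncr1"][s - 1:e])
    assert hp is not None
    hs, he = truth["hairpin"]
    assert hp.left_start >= hs - 5 and hp.right_end <= he + 5 or hp.score >= 24
    assert len(hp.structure) == e - s + 1
    assert hp.structure.count(">") + hp.structure.count("+") // 2 >= hp.wc_pairs


def test_no_hairpin_in_tiny_region():
    assert find_hairpin("ACGTA", min_stem=6, max_loop=5) is None
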