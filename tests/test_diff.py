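import numpy as np
import pytest

from oracles import lis_oracle, nw_oracle_transcript
from straindiff.diff import (
    Anchor,
    DiffError,
    DiffParams,
    align_gap,
    apply_variants,
    chain_anchors,
    diff_genomes,
    index_anchors,
)
from straindiff.io import GenomeSequence
from straindiff.sequtil import random_dna


def _genome(seq, gid="g"):
    return GenomeSequence(gid, seq)


# ---------------------------------------------------------------------------
# anchors

def test_identical_genomes_anchor_on_the_diagonal():
    rng = np.random.default_rng(0)
    seq = random_dna(rng, 2000)
    anchors = index_anchors(_genome(seq, "a"), _genome(seq, "b"), k=15)
    assert anchors and all(a.pos_a == a.pos_b for a in anchors)


def test_single_insert_splits_anchors_into_two_offsets():
    rng = np.random.default_rng(1)
    a = random_dna(rng, 10_000)
    b = a[:5000] + random_dna(rng, 100) + a[5000:]
    anchors = index_anchors(_genome(a, "a"), _genome(b, "b"), k=15)
    offsets = {an.pos_b - an.pos_a for an in anchors}
    assert offsets <= {0, 100} and offsets == {0, 100}


def test_anchors_equal_exhaustive_kmer_dictionary_oracle():
    rng = np.random.default_rng(2)
    a = random_dna(rng, 2000)
    b = a[:800] + random_dna(rng, 37) + a[800:1500] + a[1600:]
    k = 15
    found = {(an.pos_a, an.pos_b) for an in index_anchors(_genome(a, "a"), _genome(b, "b"), k)}

    def positions(s):
        occ = {}
        for i in range(len(s) - k + 1):
            occ.setdefault(s[i : i + k], []).append(i)
        return occ

    pa, pb = positions(a), positions(b)
    expected = {
        (pa[km][0], pb[km][0])
        for km in set(pa) & set(pb)
        if len(pa[km]) == 1 and len(pb[km]) == 1 and "N" not in km
    }
    assert found == expected


def test_index_anchors_validates_k():
    g = _genome("ACGT" * 10)
    with pytest.raises(ValueError):
        index_anchors(g, g, k=9)
    with pytest.raises(ValueError):
        index_anchors(g, g, k=41)


# ---------------------------------------------------------------------------
# chaining

def test_collinear_anchors_all_retained():
    anchors = [Anchor(i * 40, i * 40, 21) for i in range(50)]
    assert chain_anchors(anchors) == anchors


def test_single_translocated_anchor_dropped():
    anchors = sorted(
        [Anchor(i * 40, i * 40, 21) for i in range(50)] + [Anchor(1001, 90_000, 21)],
        key=lambda a: a.pos_a,
    )
    chained = chain_anchors(anchors)
    assert len(chained) == 50 and all(a.pos_a == a.pos_b for a in chained)


def test_chain_cardinality_matches_quadratic_lis_oracle():
    rng = np.random.default_rng(3)
    for _ in range(25):
        n = int(rng.integers(5, 60))
        pos_a = rng.choice(100_000, size=n, replace=False)
        pos_b = rng.choice(100_000, size=n, replace=False)
        anchors = sorted(
            (Anchor(int(a), int(b), 21) for a, b in zip(pos_a, pos_b)),
            key=lambda a: a.pos_a,
        )
        assert len(chain_anchors(anchors)) == lis_oracle(
            [(a.pos_a, a.pos_b) for a in anchors]
        )


# ---------------------------------------------------------------------------
# gap classification

def test_empty_vs_long_segment_is_one_long_insert():
    frags = align_gap("", "GATTACA")
    assert len(frags) == 1 and frags[0].kind == "long_insert" and frags[0].alt == "GATTACA"


def test_single_base_deletion_is_indel():
    frags = align_gap("A", "")
    assert len(frags) == 1 and frags[0].kind == "indel_1bp" and frags[0].ref == "A"


def test_equal_segments_yield_no_fragments():
    assert align_gap("ACGT", "ACGT") == []


def test_hamming_shortcut_equals_full_alignment_decomposition():
    # 3 mismatches at equal length: shortcut and DP must agree
    frags = align_gap("AAAAAA", "ATATAA")
    assert [f.kind for f in frags] == ["substitution", "substitution"]


def _decompose_with_oracle(seg_a, seg_b):
    transcript = nw_oracle_transcript(seg_a, seg_b)
    out, ia, ib, i = [], 0, 0, 0
    while i < len(transcript):
        j = i
        while j < len(transcript) and transcript[j] == transcript[i]:
            j += 1
        op, run = transcript[i], j - i
        if op == "X":
            out.extend(("substitution", ia + t, ib + t) for t in range(run))
            ia, ib = ia + run, ib + run
        elif op == "I":
            out.append(("long_insert" if run >= 2 else "indel_1bp", ia, ib))
            ib += run
        elif op == "D":
            out.append(("long_insert" if run >= 2 else "indel_1bp", ia, ib))
            ia += run
        else:
            ia, ib = ia + run, ib + run
        i = j
    return out


def test_gap_decomposition_matches_nw_oracle_on_random_pairs():
    rng = np.random.default_rng(4)
    for _ in range(80):
        seg_a = random_dna(rng, int(rng.integers(0, 40)))
        seg_b = random_dna(rng, int(rng.integers(0, 40)))
        got = [(f.kind, f.a_off, f.b_off) for f in align_gap(seg_a, seg_b)]
        assert got == _decompose_with_oracle(seg_a, seg_b)


# ---------------------------------------------------------------------------
# whole diff

def test_identical_genomes_diff_clean():
    rng = np.random.default_rng(5)
    seq = random_dna(rng, 20_000)
    report = diff_genomes(_genome(seq, "a"), _genome(seq, "b"))
    assert report.variants == []
    assert report.aligned_identity == pytest.approx(100.0)
    assert min(report.chain_coverage.values()) > 0.99


def test_unrelated_genomes_raise_near_identity_error():
    rng = np.random.default_rng(6)
    with pytest.raises(DiffError, match="not near-identical"):
        diff_genomes(
            _genome(random_dna(rng, 5000), "a"), _genome(random_dna(rng, 5000), "b")
        )


def test_synthetic_truth_recovered_at_exact_coordinates(small_sim):
    report = diff_genomes(small_sim["genome_a"], small_sim["genome_b"])
    truth = small_sim["truth"]
    got = sorted(
        (v.kind, v.carrier, v.pos_a, v.pos_b, v.ref_allele, v.alt_allele)
        for v in report.variants
    )
    expected = sorted(
        (v.kind, v.carrier, v.pos_a, v.pos_b, v.ref_allele, v.alt_allele)
        for v in truth.variants
    )
    assert got == expected


def test_diff_round_trip_reconstructs_genome_b(small_sim):
    report = diff_genomes(small_sim["genome_a"], small_sim["genome_b"])
    assert apply_variants(small_sim["genome_a"], report.variants) == (
        small_sim["genome_b"].sequence
    )


def test_diff_symmetry_swaps_carriers(small_sim):
    fwd = diff_genomes(small_sim["genome_a"], small_sim["genome_b"])
    rev = diff_genomes(small_sim["genome_b"], small_sim["genome_a"])
    def key(v, swapped):
        # a substitution has no meaningful carrier; insertions swap theirs
        carrier = "" if v.kind == "substitution" else v.carrier
        if swapped:
            return (v.kind, carrier, v.pos_b, v.pos_a, v.alt_allele, v.ref_allele)
        return (v.kind, carrier, v.pos_a, v.pos_b, v.ref_allele, v.alt_allele)

    assert {key(v, False) for v in fwd.variants} == {
        key(v, True) for v in rev.variants
    }


def test_adding_one_insert_adds_exactly_one_record(small_sim):
    ga, gb = small_sim["genome_a"], small_sim["genome_b"]
    base = diff_genomes(ga, gb)
    rng = np.random.default_rng(8)
    pos = 41_000
    extra = random_dna(rng, 120)
    gb2 = GenomeSequence(gb.id, gb.sequence[:pos] + extra + gb.sequence[pos:])
    aug = diff_genomes(ga, gb2)
    assert len(aug.variants) == len(base.variants) + 1
    base_keys = {(v.kind, v.pos_a, v.ref_allele, v.alt_allele) for v in base.variants}
    aug_keys = {(v.kind, v.pos_a, v.ref_allele, v.alt_allele) for v in aug.variants}
    (new,) = aug_keys - base_keys
    assert new[0] == "long_insert" and len(new[3]) == 120


def test_aligned_identity_respects_variant_base_bound(small_sim):
    report = diff_genomes(small_sim["genome_a"], small_sim["genome_b"])
    total_variant_bases = sum(v.length for v in report.variants)
    genome_length = max(len(small_sim["genome_a"]), len(small_sim["genome_b"]))
    bound = 100.0 * (1.0 - total_variant_bases / genome_length)
    assert report.aligned_identity >= bound - 1e-9


def test_round_trip_on_fuzzed_random_pairs():
    """Applying the reported variants to A must rebuild B, whatever the
    mutation mix; exercised over many random small pairs."""
    rng = np.random.default_rng(9)
    params = DiffParams(k=15)
    for trial in range(30):
        a = random_dna(rng, int(rng.integers(1200, 2000)))
        b = list(a)
        for _ in range(int(rng.integers(1, 6))):
            p = int(rng.integers(50, len(b) - 50))
            kind = rng.integers(0, 4)
            if kind == 0:
                b[p] = "ACGT"[int(rng.integers(0, 4))]
            elif kind == 1:
                b.insert(p, "ACGT"[int(rng.integers(0, 4))])
            elif kind == 2:
                del b[p]
            else:
                b[p:p] = list(random_dna(rng, int(rng.integers(2, 120))))
        gb = GenomeSequence("b", "".join(b))
        report = diff_genomes(GenomeSequence("a", a), gb, params)
        assert apply_variants(GenomeSequence("a", a), report.variants) == gb.sequence


def test_circular_rotation_recovers_rotated_genome():
    rng = np.random.default_rng(10)
    seq = random_dna(rng, 20_000)
    rotated = seq[7000:] + seq[:7000]
    ga = GenomeSequence("a", seq, topology="circular")
    gb = GenomeSequence("b", rotated, topology="circular")
    report = diff_genomes(ga, gb, DiffParams(circular=True))
    assert report.variants == []
    assert report.rotation_offset != 0
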