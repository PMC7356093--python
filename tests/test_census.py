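import numpy as np
import pytest

from oracles import census_oracle
from straindiff.census import (
    ElementCopy,
    ElementType,
    RepeatPair,
    classify_copies,
    detect_excision_scars,
    element_type_from_members,
    find_terminal_repeats,
    scan_copies,
    terminal_inverted_repeat,
)
from straindiff.io import GenomeSequence
from straindiff.pipeline import analyse_pair, carrier_locus
from straindiff.sequtil import random_dna, revcomp
from straindiff.simulate import SimulationConfig, simulate_strain_pair


def _element(rng, length=200, tir_len=12):
    tir = random_dna(rng, tir_len)
    return tir + random_dna(rng, length - 2 * tir_len) + revcomp(tir), tir


# ---------------------------------------------------------------------------
# terminal repeats

def test_constructed_palindromic_ends_detected():
    insert = "TGACC" + "NNNN" + revcomp("TGACC")
    rp = find_terminal_repeats(insert, "GGGGGGG", "CCCCCCC", min_tir_len=5, min_dr_len=3)
    assert rp is not None and rp.tir_seq == "TGACC" and rp.tir_len == 5


def test_insert_without_inverted_ends_reports_absent():
    rng = np.random.default_rng(14)
    assert (
        find_terminal_repeats(random_dna(rng, 60), "GGGGG", "CCCCC", min_tir_len=10)
        is None
    )


def test_short_insert_reports_absent_not_error():
    assert find_terminal_repeats("ACGTACGT", "GGGGG", "CCCCC", min_tir_len=10) is None


def test_tsd_prefixed_insert_recovers_both_repeats():
    """A leftmost-normalised insert presents as TSD + element, with the other
    TSD copy starting the right flank."""
    rng = np.random.default_rng(15)
    elem, tir = _element(rng)
    tsd = "GATT"  # deliberately not reverse-complement symmetric
    rp = find_terminal_repeats(tsd + elem, "TTTTTTTTTT", tsd + "ACCTGAAACC")
    assert rp is not None
    assert rp.tir_seq == tir and rp.dr_seq == tsd and rp.offset == len(tsd)


def test_scar_style_insert_detects_flanking_direct_repeat():
    rng = np.random.default_rng(16)
    elem, tir = _element(rng)
    tsd = "CATG"
    rp = find_terminal_repeats(elem, "TTTTTT" + tsd, tsd + "GGACCTGAAA")
    assert rp is not None
    assert rp.tir_seq == tir and rp.dr_seq == tsd and rp.offset == 0


def test_truth_repeats_recovered_on_synthetic_inserts(small_sim):
    genomes = {g.id: g for g in (small_sim["genome_a"], small_sim["genome_b"])}
    library = small_sim["library"]
    for v in small_sim["truth"].variants:
        if v.kind != "long_insert" or not v.tir_seq:
            continue
        carrier = genomes[v.carrier]
        run = v.ref_allele or v.alt_allele
        s0 = (v.pos_a if v.ref_allele else v.pos_b) - 1
        lf = carrier.sequence[s0 - 30 : s0]
        rf = carrier.sequence[s0 + len(run) : s0 + len(run) + 30]
        rp = find_terminal_repeats(run, lf, rf)
        assert rp is not None
        true_tir = library[v.type_id - 1].repeat.tir_seq
        # a single copy may present a chance-extended repeat; the family TIR
        # must still be inside it (or be an extension of it)
        assert true_tir in rp.tir_seq or rp.tir_seq in true_tir


# ---------------------------------------------------------------------------
# copy scan

def _implant(rng, genome_len, elem, positions):
    g = list(random_dna(rng, genome_len))
    for p, seq in sorted(zip(positions, [elem] * len(positions)), reverse=True):
        g[p:p] = list(seq)
    return "".join(g)


def test_scan_finds_implanted_copies_at_exact_coordinates():
    rng = np.random.default_rng(17)
    elem, tir = _element(rng)
    positions = [5_000, 20_000, 33_333]
    seq = _implant(rng, 50_000, elem, positions)
    etype = ElementType(1, elem, RepeatPair(tir, len(tir)))
    copies = scan_copies(GenomeSequence("g", seq), etype)
    got = [(c.start, c.end) for c in copies]
    # each earlier implant shifts the later ones by the element length
    expected = [
        (p + i * len(elem) + 1, p + (i + 1) * len(elem))
        for i, p in enumerate(sorted(positions))
    ]
    assert got == expected


def test_scan_without_tir_occurrences_is_empty():
    rng = np.random.default_rng(18)
    etype = ElementType(1, "TTTTACGTACGTACGTAAAA", RepeatPair("GGGGCCCCAA", 10))
    assert scan_copies(GenomeSequence("g", random_dna(rng, 10_000)), etype) == []


def test_scan_matches_quadratic_oracle_on_50kb_genome():
    rng = np.random.default_rng(19)
    elem, tir = _element(rng, length=300, tir_len=10)
    # full copies plus a truncated one, all TIR-bounded
    truncated = elem[:40] + elem[-40:]
    g = list(random_dna(rng, 50_000))
    for p, s in sorted(
        [(4_000, elem), (15_000, elem), (30_000, truncated), (44_000, elem)],
        reverse=True,
    ):
        g[p:p] = list(s)
    seq = "".join(g)
    etype = ElementType(1, elem, RepeatPair(tir, len(tir)))
    lo, hi = max(int(0.3 * len(elem)), 2 * len(tir)), int(1.05 * len(elem))
    got = [(c.start - 1, c.end) for c in scan_copies(GenomeSequence("g", seq), etype)]
    assert got == census_oracle(seq, tir, revcomp(tir), lo, hi)


def test_every_copy_is_tir_bounded(small_result, small_sim):
    genomes = {g.id: g for g in (small_sim["genome_a"], small_sim["genome_b"])}
    checked = 0
    for gid, copies in small_result.copies.items():
        seq = genomes[gid].sequence
        for c in copies:
            tir = small_result.element_types[c.type_id].repeat.tir_seq
            body = seq[c.start - 1 : c.end]
            assert body.startswith(tir) and body.endswith(revcomp(tir))
            checked += 1
    assert checked > 0


def test_scan_is_strand_symmetric():
    rng = np.random.default_rng(20)
    elem, tir = _element(rng)
    seq = _implant(rng, 20_000, elem, [3_000, 12_000])
    etype = ElementType(1, elem, RepeatPair(tir, len(tir)))
    fwd = scan_copies(GenomeSequence("g", seq), etype)
    rev = scan_copies(GenomeSequence("g", revcomp(seq)), etype)
    n = len(seq)
    reflected = sorted((n - c.end + 1, n - c.start + 1) for c in rev)
    assert reflected == [(c.start, c.end) for c in fwd]
    assert [c.strand for c in fwd] == [
        {"+": "-", "-": "+"}[c.strand] for c in reversed(rev)
    ]


def test_census_recall_and_precision_complete_on_exact_copies():
    config = SimulationConfig(
        genome_length=60_000,
        n_genes=8,
        inserts_a=[2, 0, 1],
        inserts_b=[1, 2, 1],
        n_shared_copies=[8, 4, 0],
        insert_divergence=0.0,
        seed=5,
    )
    ga, gb, fa, fb, truth, library = simulate_strain_pair(config)
    result = analyse_pair(ga, gb, fa, fb)
    found = {
        (gid, c.start, c.end) for gid, cs in result.copies.items() for c in cs
    }
    expected = {
        (c.genome_id, c.start, c.end)
        for c in truth.copies
        if library[c.type_id - 1].repeat is not None
    }
    assert found == expected


# ---------------------------------------------------------------------------
# classification

def test_full_length_classification_by_longest_copy():
    etype = ElementType(1, "A" * 1731, RepeatPair("GGGGGGGGGG", 10))

    def copy(length, start):
        return ElementCopy("g", start, start + length - 1, 1, "+", length)

    copies = [copy(1731, 1), copy(853, 5000), copy(853, 9000)]
    flags = [c.full_length for c in classify_copies(copies, etype, 10)]
    assert flags == [True, False, False]

    (single,) = classify_copies([copy(853, 5000)], etype, 10)
    assert single.full_length  # a lone copy is full length by definition

    boundary = classify_copies([copy(1731, 1), copy(1720, 5000)], etype, 10)
    assert [c.full_length for c in boundary] == [True, False]
    at_tol = classify_copies([copy(1731, 1), copy(1721, 5000)], etype, 10)
    assert [c.full_length for c in at_tol] == [True, True]


def test_type_vote_marks_tirless_family_non_transposon():
    rng = np.random.default_rng(22)
    members = []
    core = random_dna(rng, 150)
    for _ in range(3):
        members.append((core, random_dna(rng, 30), random_dna(rng, 30)))
    etype = element_type_from_members(3, members)
    assert not etype.is_transposon


def test_terminal_inverted_repeat_on_bare_element():
    rng = np.random.default_rng(23)
    elem, tir = _element(rng)
    rp = terminal_inverted_repeat(elem)
    # chance one-base extensions beyond the constructed repeat are possible
    assert rp is not None and rp.tir_seq.startswith(tir)


# ---------------------------------------------------------------------------
# excision scars

def test_implanted_scar_is_detected_exactly(small_sim, small_result):
    truth_scars = {(s.genome_id, s.position) for s in small_sim["truth"].scars}
    found = {(s.genome_id, s.position) for s in small_result.scars}
    assert truth_scars and found == truth_scars
    assert all(s.evidence == "tandem_duplicated_target" for s in small_result.scars)


def test_ordinary_insertions_leave_no_scar():
    config = SimulationConfig(
        genome_length=60_000,
        n_genes=8,
        inserts_a=[2, 0, 0],
        inserts_b=[1, 2, 0],
        n_shared_copies=[6, 3, 0],
        n_scars=0,
        seed=6,
    )
    ga, gb, fa, fb, truth, _ = simulate_strain_pair(config)
    result = analyse_pair(ga, gb, fa, fb)
    assert truth.scars == [] and result.scars == []
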