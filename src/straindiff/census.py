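"""Transposon identification and genome-wide copy census.

A differential insert is called a transposon when its ends carry a terminal
inverted repeat (TIR): a prefix whose reverse complement terminates the
element.  Because insertion duplicates the target site, a leftmost-normalised
insert usually carries that target-site duplication (TSD) as a prefix, so the
detector first strips the TSD (recognised against the flanking sequence) and
then measures the TIR on the core.

Additional copies are censused by exact string match of the TIR and its
reverse complement, paired within a length window — mirroring how a fully
identical element family can be enumerated without any similarity search.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left, bisect_right
from typing import Sequence

from .diff import DiffReport, VariantRecord
from .io import GenomeSequence
from .sequtil import revcomp


@dataclasses.dataclass(frozen=True)
class RepeatPair:
    """Terminal inverted repeat plus (optional) target-site duplication.

    ``offset`` locates the element body relative to the insert placement the
    detector was given: an inserted run is only defined up to shifts through
    repeated context, and the TSD travels with the run, so the element start
    can sit ``offset`` bases to the right of the reported insertion point.
    """

    tir_seq: str  # left TIR; the element ends with revcomp(tir_seq)
    tir_len: int
    dr_seq: str = ""  # TSD / flanking direct repeat, may be empty
    dr_len: int = 0
    offset: int = 0
    body_len: int = 0  # element body length at that placement


@dataclasses.dataclass
class ElementType:
    type_id: int
    consensus: str
    repeat: RepeatPair | None = None

    @property
    def is_transposon(self) -> bool:
        return self.repeat is not None


@dataclasses.dataclass(frozen=True)
class ElementCopy:
    genome_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    type_id: int
    strand: str
    length: int
    full_length: bool = False
    cds_count: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.length:
            raise ValueError("copy length inconsistent with interval")


@dataclasses.dataclass(frozen=True)
class ScarRecord:
    genome_id: str
    position: int  # 1-based position of the empty site
    dr_seq: str
    evidence: str  # tandem_duplicated_target


def _longest_tir(core: str, cap: int) -> int:
    best = 0
    rc = revcomp(core)
    for length in range(1, min(cap, len(core) // 2) + 1):
        if core[:length] == rc[:length] and "N" not in core[:length]:
            best = length
    return best


def terminal_inverted_repeat(seq: str, min_tir_len: int = 10) -> RepeatPair | None:
    """TIR of a bare element sequence (no flank / TSD reasoning)."""
    if len(seq) < 2 * min_tir_len:
        return None
    tir_len = _longest_tir(seq, cap=len(seq) // 2)
    if tir_len < min_tir_len:
        return None
    return RepeatPair(tir_seq=seq[:tir_len], tir_len=tir_len, body_len=len(seq))


def find_terminal_repeats(
    insert_seq: str,
    left_flank: str,
    right_flank: str,
    min_tir_len: int = 10,
    min_dr_len: int = 3,
    max_tsd_len: int = 16,
) -> RepeatPair | None:
    """Detect the TIR (and TSD, when present) of a differential insert.

    An inserted run is only defined up to shifts through repeated context,
    and insertion duplicates the target site, so the element body may sit at
    any shift-equivalent placement of the run, behind a TSD prefix.  The
    detector therefore enumerates every placement reachable by rotating the
    run against its flanks, and at each placement the candidate TSDs: the
    run prefix matching the right flank (a TSD carried inside the called
    run), the left-flank suffix matching the right flank (a TSD already
    outside the run, as at a differential element locus between two target
    copies), or none.  The candidate whose core has the longest exact TIR
    wins; ties prefer a TSD-bearing, least-shifted placement.  Returns None
    when no core has a TIR of at least ``min_tir_len``.
    """
    if min(len(left_flank), len(right_flank)) < 1:
        raise ValueError("flanking sequence required")
    if len(insert_seq) < 2 * min_tir_len:
        return None

    placements: list[tuple[int, str, str, str]] = [
        (0, insert_seq, left_flank, right_flank)
    ]
    run, lf, rf = insert_seq, left_flank, right_flank
    r = 0
    while rf and run[0] == rf[0] and r < max_tsd_len:  # rotate right
        lf, run, rf = lf + run[0], run[1:] + rf[0], rf[1:]
        r += 1
        placements.append((r, run, lf, rf))
    run, lf, rf = insert_seq, left_flank, right_flank
    r = 0
    while lf and run[-1] == lf[-1] and r > -max_tsd_len:  # rotate left
        lf, run, rf = lf[:-1], lf[-1] + run[:-1], run[-1] + rf
        r -= 1
        placements.append((r, run, lf, rf))

    best: tuple[tuple[int, bool, int, int], RepeatPair] | None = None
    for r, run, lf, rf in placements:
        candidates: list[tuple[int, str]] = [(0, "")]  # (prefix trim, dr_seq)
        max_l = min(max_tsd_len, len(lf), len(rf), len(run) - 1)
        for length in range(min_dr_len, max_l + 1):
            if run[:length] == rf[:length]:
                candidates.append((length, run[:length]))
            if lf.endswith(rf[:length]):
                candidates.append((0, rf[:length]))
        for trim, dr in candidates:
            core = run[trim:]
            if len(core) < 2 * min_tir_len:
                continue
            tir_len = _longest_tir(core, cap=len(core) // 2)
            if tir_len < min_tir_len:
                continue
            key = (tir_len, bool(dr), -abs(r), -trim)
            if best is None or key > best[0]:
                best = (
                    key,
                    RepeatPair(
                        tir_seq=core[:tir_len],
                        tir_len=tir_len,
                        dr_seq=dr,
                        dr_len=len(dr),
                        offset=r + trim,
                        body_len=len(core),
                    ),
                )
    return best[1] if best else None


def element_type_from_members(
    type_id: int,
    members: Sequence[tuple[str, str, str]],
    min_tir_len: int = 10,
    min_dr_len: int = 3,
) -> ElementType:
    """Build a type's element model from its differential-insert members.

    ``members`` are (insert_run, left_flank, right_flank) triples.  Terminal
    repeats are detected per member and the TIR is decided by majority vote
    over the detected TIR strings: a single copy can present a chance-extended
    inverted repeat reaching into its private target-site duplication, but
    only the repeat shared by the family is identical across members.  The
    winning member supplies the element-body consensus.  A type where no
    member shows a TIR is returned repeat-less (not a transposon).
    """
    detections: list[tuple[int, RepeatPair]] = []
    for i, (run, lf, rf) in enumerate(members):
        rp = find_terminal_repeats(run, lf, rf, min_tir_len, min_dr_len)
        if rp is not None:
            detections.append((i, rp))
    if not detections:
        longest = max((m[0] for m in members), key=len)
        return ElementType(type_id=type_id, consensus=longest, repeat=None)
    votes: dict[str, int] = {}
    for _, rp in detections:
        votes[rp.tir_seq] = votes.get(rp.tir_seq, 0) + 1
    tir_seq = max(votes, key=lambda t: (votes[t], -len(t), t))
    idx, rp = next(d for d in detections if d[1].tir_seq == tir_seq)
    run, lf, rf = members[idx]
    ctx = lf + run + rf
    body = ctx[len(lf) + rp.offset : len(lf) + rp.offset + rp.body_len]
    return ElementType(type_id=type_id, consensus=body, repeat=rp)


def left_normalise_tandem(seq: str, point: int, dr_len: int) -> int:
    """Leftmost cut point of a tandem ``dr_len``-periodic repeat at ``point``."""
    while point - dr_len - 1 >= 0 and seq[point - dr_len - 1] == seq[point - 1]:
        point -= 1
    return point


def _find_all(haystack: str, needle: str) -> list[int]:
    out: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _kmer_set(seq: str, k: int = 11) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _assign_strand(copy_seq: str, consensus: str) -> str:
    """Orient a copy against the type consensus by shared-k-mer vote.

    A TIR-bounded element reads identically at both ends on both strands, so
    orientation comes from the interior; ties fall to '+'.
    """
    kc = _kmer_set(copy_seq)
    fwd = len(kc & _kmer_set(consensus))
    rev = len(kc & _kmer_set(revcomp(consensus)))
    return "-" if rev > fwd else "+"


def scan_copies(
    genome: GenomeSequence,
    etype: ElementType,
    length_window: tuple[int, int] | None = None,
) -> list[ElementCopy]:
    """All genome-wide copies of a transposon type by exact TIR match.

    Left ends are exact occurrences of the TIR, right ends exact occurrences
    of its reverse complement; a candidate copy is any left/right pairing
    whose span falls in ``length_window`` (default 0.3x..1.05x the consensus
    length).  Candidates are accepted greedily shortest-span first, without
    overlap, which keeps nested or adjacent occurrences from producing
    chimeric calls.
    """
    if not etype.is_transposon:
        raise ValueError(f"type {etype.type_id} has no terminal repeats to scan for")
    tir = etype.repeat.tir_seq
    if not tir:
        raise ValueError("empty TIR")
    if length_window is None:
        full = len(etype.consensus)
        length_window = (max(int(0.3 * full), 2 * len(tir)), int(1.05 * full))
    lo, hi = length_window

    seq = genome.sequence
    lefts = _find_all(seq, tir)
    rights = _find_all(seq, revcomp(tir))  # start positions of the right TIR
    ends = [r + len(tir) for r in rights]  # exclusive copy ends

    candidates: list[tuple[int, int]] = []  # (start0, end0 exclusive)
    for left in lefts:
        j0 = bisect_left(ends, left + lo)
        j1 = bisect_right(ends, left + hi)
        for end in ends[j0:j1]:
            if end - left >= 2 * len(tir):
                candidates.append((left, end))
    candidates.sort(key=lambda c: (c[1] - c[0], c[0]))

    accepted: list[tuple[int, int]] = []
    for start, end in candidates:
        if any(start < e and s < end for s, e in accepted):
            continue
        accepted.append((start, end))
    accepted.sort()

    copies: list[ElementCopy] = []
    for start, end in accepted:
        copies.append(
            ElementCopy(
                genome_id=genome.id,
                start=start + 1,
                end=end,
                type_id=etype.type_id,
                strand=_assign_strand(seq[start:end], etype.consensus),
                length=end - start,
            )
        )
    return copies


def classify_copies(
    copies: Sequence[ElementCopy],
    etype: ElementType,
    full_length_tolerance: int = 10,
) -> list[ElementCopy]:
    """Mark copies full-length iff within tolerance of the type's longest copy."""
    mine = [c for c in copies if c.type_id == etype.type_id]
    if not mine:
        return []
    longest = max(c.length for c in mine)
    return [
        dataclasses.replace(c, full_length=abs(c.length - longest) <= full_length_tolerance)
        for c in mine
    ]


def detect_excision_scars(
    diff: DiffReport,
    genomes: dict[str, GenomeSequence],
    censuses: dict[str, Sequence[ElementCopy]] | None = None,
    min_tir_len: int = 10,
    min_dr_len: int = 3,
    flank: int = 30,
) -> list[ScarRecord]:
    """Look for excision scars at differential element loci.

    For every long insert whose carrier-side sequence is an element (TIR
    found; confirmed against the carrier's census when given), the empty
    orthologous site in the other genome is inspected: a tandem duplication
    of the target (dr_seq immediately repeated) is the signature of an
    element that was once there and excised; a single copy of the target is
    an ordinary pre-insertion site and is not reported.
    """
    scars: list[ScarRecord] = []
    for v in diff.variants:
        if v.kind != "long_insert":
            continue
        carrier_is_a = bool(v.ref_allele)
        carrier = genomes[diff.genome_a if carrier_is_a else diff.genome_b]
        other = genomes[diff.genome_b if carrier_is_a else diff.genome_a]
        run = v.ref_allele or v.alt_allele
        start0 = (v.pos_a if carrier_is_a else v.pos_b) - 1
        lf = carrier.sequence[max(start0 - flank, 0) : start0]
        rf = carrier.sequence[start0 + len(run) : start0 + len(run) + flank]
        if not lf or not rf:
            continue
        rep = find_terminal_repeats(run, lf, rf, min_tir_len, min_dr_len)
        if rep is None or rep.dr_len < min_dr_len:
            continue
        if censuses is not None:
            carrier_copies = censuses.get(carrier.id, [])
            if not any(
                c.start >= start0 + 1 and c.end <= start0 + len(run)
                for c in carrier_copies
            ):
                continue
        # element-body insertion point in the empty genome, correcting for
        # the shift-equivalent placement the detector settled on
        point = (v.pos_b if carrier_is_a else v.pos_a) + rep.offset
        L = rep.dr_len
        left_ok = point - L >= 0 and (
            other.sequence[point - L : point] == other.sequence[point : point + L]
        )
        if left_ok:
            # the cut within a tandem repeat is ambiguous; report leftmost
            point = left_normalise_tandem(other.sequence, point, L)
            scars.append(
                ScarRecord(
                    genome_id=other.id,
                    position=point + 1,
                    dr_seq=other.sequence[point - L : point],
                    evidence="tandem_duplicated_target",
                )
            )
    return scars
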