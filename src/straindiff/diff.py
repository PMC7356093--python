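"""Whole-genome diff of two near-identical assemblies.

Strategy: index k-mers that occur exactly once in each genome and are shared
(anchors), chain a maximal collinear subset (weighted longest increasing
subsequence over runs of consecutive anchors), then align the sequence
between consecutive chain blocks and classify every discrepancy as a
substitution, a one-letter indel, or a long insert (>= 2 bp of extra
sequence in one genome).

Because transposon copies are repeated, no anchor ever falls inside one:
the k-mer uniqueness requirement is what makes the chain immune to the
dispersed element copies that dominate these genomes.

Insertions and deletions are reported leftmost-normalised (shifted left
through any repeated context), which makes coordinates well-defined and
comparable across runs and against simulator truth tables.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .align import nw_transcript
from .io import GenomeSequence


class DiffError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Anchor:
    """A k-mer occurring exactly once in each genome (0-based offsets)."""

    pos_a: int
    pos_b: int
    k: int


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One difference between assemblies.

    ``ref_allele`` is the sequence in genome A, ``alt_allele`` in genome B
    (A-as-reference view).  For an insertion carried by B, ``pos_b`` is the
    1-based start of the inserted run in B and ``pos_a`` the 1-based position
    of the base in A immediately before the insertion point (0 = before the
    first base); symmetrically for an insertion carried by A.
    """

    kind: str  # substitution | indel_1bp | long_insert
    carrier: str  # genome id bearing the event (extra sequence for insertions)
    pos_a: int
    pos_b: int
    ref_allele: str
    alt_allele: str
    length: int

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if self.length != 1 or self.ref_allele == self.alt_allele:
                raise ValueError("substitution must be a single differing base")
        elif self.kind == "indel_1bp":
            if self.length != 1:
                raise ValueError("indel_1bp must have length 1")
        elif self.kind == "long_insert":
            if self.length < 2:
                raise ValueError("long_insert must have length >= 2")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")


@dataclasses.dataclass
class DiffParams:
    k: int = 21
    # Hamming shortcut for equal-length gaps.  With match +1 / mismatch -1 /
    # gap -2, d substitutions score L-2d while any gapped alignment of
    # equal-length segments scores at most L-5, so the shortcut provably
    # equals the full alignment only for d <= 2.
    substitution_ceiling: int = 2
    long_insert_min: int = 2
    coverage_floor: float = 0.5
    circular: bool = False


@dataclasses.dataclass
class DiffReport:
    genome_a: str
    genome_b: str
    variants: list[VariantRecord]
    aligned_identity: float  # percent over aligned columns
    chain_coverage: dict[str, float]  # fraction of each genome in chained anchors
    rotation_offset: int = 0  # genome B rotation applied for circular inputs

    def counts(self) -> dict[str, int]:
        out = {"substitution": 0, "indel_1bp": 0, "long_insert": 0}
        for v in self.variants:
            out[v.kind] += 1
        return out


# ---------------------------------------------------------------------------
# anchors

def _kmer_positions(seq: str, k: int) -> dict[str, int]:
    """k-mer -> position for k-mers occurring exactly once (no N)."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in counts:
            counts[kmer] = -1  # repeated
        else:
            counts[kmer] = i
    counts = {km: p for km, p in counts.items() if p >= 0 and "N" not in km}
    return counts


def index_anchors(
    genome_a: GenomeSequence, genome_b: GenomeSequence, k: int = 21
) -> list[Anchor]:
    """Shared k-mers unique in both genomes, sorted by position in A."""
    if k < 15:
        raise ValueError(f"k must be >= 15, got {k}")
    if k > len(genome_a) or k > len(genome_b):
        raise ValueError("k exceeds a genome length")
    pos_a = _kmer_positions(genome_a.sequence, k)
    pos_b = _kmer_positions(genome_b.sequence, k)
    anchors = [
        Anchor(pos_a=pa, pos_b=pos_b[km], k=k)
        for km, pa in pos_a.items()
        if km in pos_b
    ]
    anchors.sort(key=lambda a: a.pos_a)
    return anchors


# ---------------------------------------------------------------------------
# chaining

@dataclasses.dataclass
class _Block:
    a: int  # start in A
    b: int  # start in B
    count: int  # number of merged anchors
    k: int

    @property
    def span(self) -> int:
        return self.count - 1 + self.k

    @property
    def a_end(self) -> int:
        return self.a + self.span

    @property
    def b_end(self) -> int:
        return self.b + self.span


def _merge_blocks(anchors: Sequence[Anchor]) -> list[_Block]:
    """Merge runs of consecutive anchors with a common diagonal offset."""
    blocks: list[_Block] = []
    for anc in anchors:
        if (
            blocks
            and anc.pos_a == blocks[-1].a + blocks[-1].count
            and anc.pos_b == blocks[-1].b + blocks[-1].count
        ):
            blocks[-1].count += 1
        else:
            blocks.append(_Block(a=anc.pos_a, b=anc.pos_b, count=1, k=anc.k))
    return blocks


def _chain_blocks(blocks: list[_Block]) -> list[_Block]:
    """Weighted LIS over blocks: maximise total anchor count, strictly
    increasing in both genomes; ties broken by minimal total |pos_b - pos_a|
    drift, then by earliest predecessor."""
    m = len(blocks)
    if m == 0:
        return []
    best_count = [0] * m
    best_drift = [0] * m
    prev = [-1] * m
    for i, bi in enumerate(blocks):
        drift_i = bi.count * abs(bi.b - bi.a)
        best_count[i] = bi.count
        best_drift[i] = drift_i
        for j in range(i):
            bj = blocks[j]
            # anchor starts strictly increasing in both genomes (plain LIS);
            # physical overlap of up to k-1 bases is trimmed later
            if bj.a + bj.count - 1 < bi.a and bj.b + bj.count - 1 < bi.b:
                cand_count = best_count[j] + bi.count
                cand_drift = best_drift[j] + drift_i
                if cand_count > best_count[i] or (
                    cand_count == best_count[i] and cand_drift < best_drift[i]
                ):
                    best_count[i] = cand_count
                    best_drift[i] = cand_drift
                    prev[i] = j
    end = max(
        range(m), key=lambda i: (best_count[i], -best_drift[i], -i)
    )
    chain: list[_Block] = []
    while end != -1:
        chain.append(blocks[end])
        end = prev[end]
    chain.reverse()
    return chain


def chain_anchors(anchors: Sequence[Anchor]) -> list[Anchor]:
    """Maximal-cardinality collinear subset (strictly increasing in both
    genomes).  Equal-cardinality ties prefer minimal total offset drift."""
    blocks = _chain_blocks(_merge_blocks(anchors))
    out: list[Anchor] = []
    for b in blocks:
        for i in range(b.count):
            out.append(Anchor(pos_a=b.a + i, pos_b=b.b + i, k=b.k))
    return out


# ---------------------------------------------------------------------------
# gap classification

@dataclasses.dataclass(frozen=True)
class GapFragment:
    """A variant fragment in gap-local 0-based offsets."""

    kind: str
    a_off: int
    b_off: int
    ref: str
    alt: str


def _hamming(x: str, y: str) -> int:
    return sum(1 for a, b in zip(x, y) if a != b or a == "N")


def _transcript_to_fragments(seg_a: str, seg_b: str, transcript: str) -> list[GapFragment]:
    frags: list[GapFragment] = []
    ia = ib = 0
    i = 0
    n = len(transcript)
    while i < n:
        op = transcript[i]
        j = i
        while j < n and transcript[j] == op:
            j += 1
        run = j - i
        if op == "X":
            for t in range(run):
                frags.append(
                    GapFragment(
                        "substitution",
                        ia + t,
                        ib + t,
                        seg_a[ia + t],
                        seg_b[ib + t],
                    )
                )
            ia += run
            ib += run
        elif op == "I":  # extra sequence in B
            kind = "long_insert" if run >= 2 else "indel_1bp"
            frags.append(GapFragment(kind, ia, ib, "", seg_b[ib : ib + run]))
            ib += run
        elif op == "D":  # extra sequence in A
            kind = "long_insert" if run >= 2 else "indel_1bp"
            frags.append(GapFragment(kind, ia, ib, seg_a[ia : ia + run], ""))
            ia += run
        else:  # M
            ia += run
            ib += run
        i = j
    return frags


def align_gap(
    seg_a: str, seg_b: str, substitution_ceiling: int = 2
) -> list[GapFragment]:
    """Classify the discrepancy between two inter-anchor segments.

    Returns variant fragments in gap-local coordinates.  Shortcuts: an empty
    side is a pure insertion; equal lengths with a small Hamming distance are
    plain substitutions; everything else goes through the full global
    aligner and its edit transcript is decomposed into runs.
    """
    if not seg_a and not seg_b:
        return []
    if not seg_a:
        kind = "long_insert" if len(seg_b) >= 2 else "indel_1bp"
        return [GapFragment(kind, 0, 0, "", seg_b)]
    if not seg_b:
        kind = "long_insert" if len(seg_a) >= 2 else "indel_1bp"
        return [GapFragment(kind, 0, 0, seg_a, "")]
    if len(seg_a) == len(seg_b):
        d = _hamming(seg_a, seg_b)
        if d <= substitution_ceiling:
            return [
                GapFragment("substitution", i, i, a, b)
                for i, (a, b) in enumerate(zip(seg_a, seg_b))
                if a != b or a == "N"
            ]
    return _transcript_to_fragments(seg_a, seg_b, nw_transcript(seg_a, seg_b))


def _gap_column_stats(seg_a: str, seg_b: str, frags: list[GapFragment]) -> tuple[int, int]:
    """(aligned columns, matching columns) for one gap."""
    variant_a = sum(len(f.ref) for f in frags)
    variant_b = sum(len(f.alt) for f in frags)
    subs = sum(1 for f in frags if f.kind == "substitution")
    gap_cols = (variant_a - subs) + (variant_b - subs)
    matches = len(seg_a) - variant_a  # bases of A in matching columns
    columns = matches + subs + gap_cols
    return columns, matches


# ---------------------------------------------------------------------------
# leftmost normalisation

def left_normalise_insertion(carrier_seq: str, start0: int, length: int) -> int:
    """Shift an inserted run left through repeated context.

    ``start0`` is the 0-based start of the run within the carrier genome;
    the shift is valid while the base before the run equals its last base.
    Returns the normalised start.
    """
    while start0 > 0 and carrier_seq[start0 - 1] == carrier_seq[start0 + length - 1]:
        start0 -= 1
    return start0


# ---------------------------------------------------------------------------
# the full diff

def _rotate(seq: str, offset: int) -> str:
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def diff_genomes(
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    params: DiffParams | None = None,
) -> DiffReport:
    """Index -> chain -> per-gap classify; see module docstring."""
    params = params or DiffParams()
    a_seq, b_seq = genome_a.sequence, genome_b.sequence

    rotation = 0
    if params.circular and (
        genome_a.topology == "circular" or genome_b.topology == "circular"
    ):
        anchors0 = index_anchors(genome_a, genome_b, params.k)
        if anchors0:
            first = min(anchors0, key=lambda a: a.pos_a)
            rotation = first.pos_b - first.pos_a
            b_seq = _rotate(b_seq, rotation)
            genome_b = GenomeSequence(genome_b.id, b_seq, genome_b.topology)

    anchors = index_anchors(genome_a, genome_b, params.k)
    chain = _chain_blocks(_merge_blocks(anchors))

    anchored_a = sum(b.span for b in chain)
    coverage = {
        genome_a.id: anchored_a / len(a_seq),
        genome_b.id: anchored_a / len(b_seq),
    }
    if min(coverage.values()) < params.coverage_floor:
        raise DiffError(
            "genomes not near-identical: anchor chain covers "
            f"{min(coverage.values()):.2%} (< floor {params.coverage_floor:.0%})"
        )

    # walk chain blocks, trimming any residual overlap (blocks are exact
    # matches, so trimming the downstream block's start is always safe)
    variants: list[VariantRecord] = []
    columns = matches = 0
    prev_a = prev_b = 0
    trimmed: list[_Block] = []
    for blk in chain:
        delta = max(prev_a - blk.a, prev_b - blk.b, 0)
        if delta >= blk.span:
            continue
        blk = _Block(a=blk.a + delta, b=blk.b + delta, count=1, k=blk.span - delta)
        trimmed.append(blk)
        prev_a, prev_b = blk.a_end, blk.b_end

    prev_a = prev_b = 0
    segments: list[tuple[int, int, str, str]] = []
    for blk in trimmed:
        segments.append((prev_a, prev_b, a_seq[prev_a : blk.a], b_seq[prev_b : blk.b]))
        columns += blk.span
        matches += blk.span
        prev_a, prev_b = blk.a_end, blk.b_end
    segments.append((prev_a, prev_b, a_seq[prev_a:], b_seq[prev_b:]))

    for ga, gb, seg_a, seg_b in segments:
        frags = align_gap(seg_a, seg_b, params.substitution_ceiling)
        cols, mats = _gap_column_stats(seg_a, seg_b, frags)
        columns += cols
        matches += mats
        for f in frags:
            variants.append(
                _fragment_to_record(
                    f, ga, gb, genome_a, genome_b, a_seq, b_seq
                )
            )

    variants.sort(key=lambda v: (v.pos_a, v.pos_b, v.kind))
    identity = 100.0 * matches / columns if columns else 100.0
    return DiffReport(
        genome_a=genome_a.id,
        genome_b=genome_b.id,
        variants=variants,
        aligned_identity=identity,
        chain_coverage=coverage,
        rotation_offset=rotation,
    )


def _fragment_to_record(
    f: GapFragment,
    gap_a0: int,
    gap_b0: int,
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    a_seq: str,
    b_seq: str,
) -> VariantRecord:
    if f.kind == "substitution":
        return VariantRecord(
            kind="substitution",
            carrier=genome_b.id,
            pos_a=gap_a0 + f.a_off + 1,
            pos_b=gap_b0 + f.b_off + 1,
            ref_allele=f.ref,
            alt_allele=f.alt,
            length=1,
        )
    if f.alt:  # extra sequence in B
        start0 = left_normalise_insertion(b_seq, gap_b0 + f.b_off, len(f.alt))
        shift = (gap_b0 + f.b_off) - start0
        return VariantRecord(
            kind=f.kind,
            carrier=genome_b.id,
            pos_a=gap_a0 + f.a_off - shift,
            pos_b=start0 + 1,
            ref_allele="",
            alt_allele=b_seq[start0 : start0 + len(f.alt)],
            length=len(f.alt),
        )
    start0 = left_normalise_insertion(a_seq, gap_a0 + f.a_off, len(f.ref))
    shift = (gap_a0 + f.a_off) - start0
    return VariantRecord(
        kind=f.kind,
        carrier=genome_a.id,
        pos_a=start0 + 1,
        pos_b=gap_b0 + f.b_off - shift,
        ref_allele=a_seq[start0 : start0 + len(f.ref)],
        alt_allele="",
        length=len(f.ref),
    )


# ---------------------------------------------------------------------------
# reconstruction (round-trip check and CLI utility)

def apply_variants(genome_a: GenomeSequence, variants: Sequence[VariantRecord]) -> str:
    """Apply a DiffReport's variants to genome A, reconstructing genome B."""
    a = genome_a.sequence

    def sort_key(v: VariantRecord) -> float:
        if v.kind != "substitution" and v.alt_allele:  # insertion relative to A
            return v.pos_a + 0.5
        return float(v.pos_a)

    out: list[str] = []
    cursor = 0  # 0-based next index of A to copy
    for v in sorted(variants, key=sort_key):
        if v.kind == "substitution":
            out.append(a[cursor : v.pos_a - 1])
            out.append(v.alt_allele)
            cursor = v.pos_a
        elif v.alt_allele:  # insertion in B after base pos_a
            out.append(a[cursor : v.pos_a])
            out.append(v.alt_allele)
            cursor = v.pos_a
        else:  # deletion from A (run starts at pos_a)
            out.append(a[cursor : v.pos_a - 1])
            cursor = v.pos_a - 1 + v.length
    out.append(a[cursor:])
    return "".join(out)
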