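"""Synthetic strain pairs with machine-readable ground truth.

The generator emulates the situation the pipeline is built for: two strains
of one species whose genomes are identical except for transposition and a
handful of point events.  It produces an ancestral genome with a gene
annotation, a small library of mobile-element types (terminal inverted
repeats + random core; one type deliberately repeat-less), shared dispersed
copies implanted before the strains split, per-strain differential
insertions with target-site duplication, one-letter indels, substitutions,
and optional excision scars (tandem target duplication with the element
gone).  Every implanted event is recorded in a truth table in the same
leftmost-normalised coordinates the differ reports, so recovery can be
scored exactly.

All randomness flows from one master seed through per-stage substreams, so
identical (config, seed) yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .census import ElementType, RepeatPair, left_normalise_tandem
from .diff import left_normalise_insertion
from .io import FeatureRecord, GenomeSequence
from .sequtil import random_dna, revcomp

_STOPS = {"TAA", "TAG", "TGA"}


@dataclasses.dataclass(frozen=True)
class ElementTypeSpec:
    element_length: int
    tir_len: int
    dr_len: int
    has_tir: bool = True

    def __post_init__(self) -> None:
        if self.has_tir and self.element_length <= 2 * self.tir_len:
            raise ValueError("element_length must exceed 2 * tir_len")
        if self.element_length < 2:
            raise ValueError("element_length must be >= 2")


def _default_types() -> list[ElementTypeSpec]:
    return [
        ElementTypeSpec(element_length=853, tir_len=24, dr_len=4),
        ElementTypeSpec(element_length=782, tir_len=26, dr_len=6),
        ElementTypeSpec(element_length=378, tir_len=0, dr_len=0, has_tir=False),
    ]


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic strain pair.

    Defaults mirror the scale of the real comparison this package models:
    three element types (two transposon-like with TIRs and TSDs, one
    repeat-less), eight differential inserts per strain with the second
    transposon type confined to strain B, dispersed shared copies, four
    one-letter indels, one substitution, and one insert disrupting a gene.
    The genome is kept at 200 kb so a full pipeline run stays interactive;
    ``full_scale_config`` scales positions up.
    """

    genome_length: int = 200_000
    gc_content: float = 0.40
    n_genes: int = 20
    element_types: list[ElementTypeSpec] = dataclasses.field(default_factory=_default_types)
    # per-type differential insert counts per strain
    inserts_a: list[int] = dataclasses.field(default_factory=lambda: [6, 0, 2])
    inserts_b: list[int] = dataclasses.field(default_factory=lambda: [3, 4, 1])
    n_shared_copies: list[int] = dataclasses.field(default_factory=lambda: [30, 12, 0])
    n_indel_1bp: int = 4
    n_substitutions: int = 1
    n_scars: int = 0
    disrupt_gene: bool = True
    insert_divergence: float = 0.005  # per-base core substitution rate, differential inserts
    margin: int = 50  # exclusion margin between implanted events
    genome_a_id: str = "strainA"
    genome_b_id: str = "strainB"
    seed: int = 0

    def __post_init__(self) -> None:
        n_types = len(self.element_types)
        for name in ("inserts_a", "inserts_b", "n_shared_copies"):
            vec = getattr(self, name)
            if len(vec) != n_types or any(c < 0 for c in vec):
                raise ValueError(f"{name} must give a count >= 0 per element type")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0,1)")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        for n in (self.n_genes, self.n_indel_1bp, self.n_substitutions, self.n_scars):
            if n < 0:
                raise ValueError("counts must be >= 0")


def full_scale_config(seed: int = 0, genome_length: int = 400_000) -> SimulationConfig:
    """Preset mirroring a full-size strain comparison's event structure:
    16 differential inserts split 8 + 8, the second transposon type only in
    strain B, and dispersed copy counts of the reported order."""
    return SimulationConfig(
        genome_length=genome_length,
        n_genes=max(20, genome_length // 10_000),
        inserts_a=[7, 0, 1],
        inserts_b=[3, 4, 1],
        n_shared_copies=[27, 12, 0],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# truth containers

@dataclasses.dataclass(frozen=True)
class TruthVariant:
    kind: str  # long_insert | indel_1bp | substitution
    carrier: str
    pos_a: int
    pos_b: int
    ref_allele: str
    alt_allele: str
    length: int
    type_id: int = 0  # element type for long inserts; 0 = not an element
    tir_seq: str = ""
    dr_seq: str = ""
    disrupted_locus_tag: str = ""
    from_scar: bool = False


@dataclasses.dataclass(frozen=True)
class TruthCopy:
    genome_id: str
    start: int  # 1-based inclusive, element body only (TIR..revcomp TIR)
    end: int
    type_id: int
    strand: str
    source: str  # shared | differential | scar


@dataclasses.dataclass(frozen=True)
class TruthScar:
    genome_id: str
    position: int  # 1-based empty-site position
    dr_seq: str


@dataclasses.dataclass
class TruthSet:
    variants: list[TruthVariant]
    copies: list[TruthCopy]
    scars: list[TruthScar]

    def sorted(self) -> "TruthSet":
        return TruthSet(
            variants=sorted(self.variants, key=lambda v: (v.carrier, v.pos_a, v.pos_b)),
            copies=sorted(self.copies, key=lambda c: (c.genome_id, c.start)),
            scars=sorted(self.scars, key=lambda s: (s.genome_id, s.position)),
        )


# ---------------------------------------------------------------------------
# stage 1: ancestor

def _substreams(seed: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


def _sample_free_position(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    extent: int,
    reserved: list[tuple[int, int]],
    margin: int,
    what: str,
    validate=None,
) -> int:
    for _ in range(20_000):
        p = int(rng.integers(lo, hi - extent))
        if all(p + extent + margin <= s or e + margin <= p for s, e in reserved):
            if validate is not None and not validate(p):
                continue
            reserved.append((p, p + extent))
            return p
    raise ValueError(
        f"could not place {what} without overlap; the genome is too crowded "
        "(try a longer genome or fewer events)"
    )


def _fix_orf(coding: list[str]) -> None:
    """Force start/stop codons and purge internal stops in place."""
    coding[0:3] = ["A", "T", "G"]
    coding[-3:] = ["T", "A", "A"]
    for i in range(3, len(coding) - 3, 3):
        if "".join(coding[i : i + 3]) in _STOPS:
            coding[i + 2] = "T"  # TAA->TAT, TAG->TAT, TGA->TGT


def simulate_ancestor(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[FeatureRecord]]:
    """I.i.d. genome at the requested GC with non-overlapping CDS features.

    Genes are 300-1500 bp (multiples of three), carry proper start/stop
    codons, and are free of internal in-frame stops, so translation-based
    checks downstream are meaningful.
    """
    rng = _substreams(config.seed)[0]
    L = config.genome_length
    seq = list(random_dna(rng, L, config.gc_content))
    reserved: list[tuple[int, int]] = []
    features: list[FeatureRecord] = []
    for idx in range(config.n_genes):
        glen = 3 * int(rng.integers(100, 501))  # 300..1503 bp
        p = _sample_free_position(
            rng, 200, L - 200, glen, reserved, margin=60, what=f"gene {idx + 1}"
        )
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        coding = seq[p : p + glen] if strand == "+" else list(revcomp("".join(seq[p : p + glen])))
        _fix_orf(coding)
        block = coding if strand == "+" else list(revcomp("".join(coding)))
        seq[p : p + glen] = block
        features.append(
            FeatureRecord(
                seqid="ancestor",
                start=p + 1,
                end=p + glen,
                strand=strand,
                feature_type="CDS",
                locus_tag=f"SYN_{idx + 1:04d}",
                product="hypothetical protein",
            )
        )
    genome = GenomeSequence(id="ancestor", sequence="".join(seq))
    features.sort(key=lambda f: f.start)
    return genome, features


# ---------------------------------------------------------------------------
# stage 2: element library

def build_element_library(config: SimulationConfig) -> list[ElementType]:
    """One ElementType per configured spec: TIR + random core + revcomp(TIR)
    for transposon-like types, plain random sequence for repeat-less ones.
    Cores are redrawn until mutually dissimilar (<50% shared 11-mers)."""
    rng = _substreams(config.seed)[1]
    types: list[ElementType] = []
    kmer_sets: list[set[str]] = []
    for i, spec in enumerate(config.element_types, start=1):
        for _ in range(100):
            if spec.has_tir:
                tir = random_dna(rng, spec.tir_len, config.gc_content)
                core = random_dna(
                    rng, spec.element_length - 2 * spec.tir_len, config.gc_content
                )
                seq = tir + core + revcomp(tir)
                repeat = RepeatPair(tir_seq=tir, tir_len=spec.tir_len)
            else:
                seq = random_dna(rng, spec.element_length, config.gc_content)
                # a repeat-less type must not carry an accidental TIR
                rc = revcomp(seq)
                if any(seq[:t] == rc[:t] for t in range(6, len(seq) // 2 + 1)):
                    continue
                repeat = None
            ks = {seq[j : j + 11] for j in range(len(seq) - 10)}
            if all(len(ks & other) < 0.5 * len(ks) for other in kmer_sets):
                kmer_sets.append(ks)
                types.append(ElementType(type_id=i, consensus=seq, repeat=repeat))
                break
        else:  # pragma: no cover - astronomically unlikely with random draws
            raise RuntimeError("failed to draw mutually dissimilar element cores")
    return types


def _mutate_core(
    rng: np.random.Generator, seq: str, protected: int, rate: float
) -> str:
    """Substitute bases at ``rate`` outside the first/last ``protected`` bases."""
    if rate <= 0 or len(seq) <= 2 * protected:
        return seq
    chars = list(seq)
    lo, hi = protected, len(seq) - protected
    n_sites = hi - lo
    hits = np.flatnonzero(rng.random(n_sites) < rate)
    for h in hits:
        i = lo + int(h)
        options = [b for b in "ACGT" if b != chars[i]]
        chars[i] = options[int(rng.integers(0, 3))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# stage 3: derive the strain pair

@dataclasses.dataclass
class _Event:
    kind: str  # long_insert | scar | indel_ins | indel_del | substitution
    strain: str  # "A" or "B" (carrier of the change)
    p: int  # 0-based position in the shared (post-copy) ancestor
    type_idx: int = -1  # index into the library
    strand: str = "+"
    payload: str = ""  # element sequence / inserted base / substituted base
    locus_tag: str = ""


class _CoordMap:
    """Cumulative coordinate shift from implanted events of one strain."""

    def __init__(self) -> None:
        self.breaks: list[tuple[int, int]] = []  # (shared coord, delta), sorted

    def add(self, q: int, delta: int) -> None:
        self.breaks.append((q, delta))

    def map(self, c: int) -> int:
        return c + sum(d for q, d in self.breaks if q <= c)


def derive_strain_pair(
    ancestor: GenomeSequence,
    features: Sequence[FeatureRecord],
    library: Sequence[ElementType],
    config: SimulationConfig,
) -> tuple[GenomeSequence, GenomeSequence, list[FeatureRecord], list[FeatureRecord], TruthSet]:
    """Implant shared copies, then per-strain events; return both strains,
    lifted annotations, and the truth table (see module docstring)."""
    rng = _substreams(config.seed)[2]
    margin = config.margin
    specs = config.element_types

    # ---- shared dispersed copies go into the common ancestor -------------
    g0 = ancestor.sequence
    reserved: list[tuple[int, int]] = [(f.start - 1, f.end) for f in features]
    shared: list[tuple[int, int, str]] = []  # (position, type_idx, strand)
    for t_idx, n in enumerate(config.n_shared_copies):
        ext = specs[t_idx].dr_len + len(library[t_idx].consensus)
        for _ in range(n):
            p = _sample_free_position(
                rng, 200, len(g0) - 200, ext, reserved, margin,
                what=f"shared copy of type {t_idx + 1}",
            )
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            shared.append((p, t_idx, strand))
    shared.sort()

    pieces: list[str] = []
    cursor = 0
    offset = 0
    shared_copies_g1: list[tuple[int, int, str]] = []  # (start in G1, type_idx, strand)
    shifts: list[tuple[int, int]] = []  # liftover of G0 -> G1
    for p, t_idx, strand in shared:
        spec = specs[t_idx]
        elem = library[t_idx].consensus
        if strand == "-":
            elem = revcomp(elem)
        t0 = g0[p : p + spec.dr_len]
        pieces.append(g0[cursor : p + spec.dr_len])
        pieces.append(elem + t0)
        shared_copies_g1.append((p + spec.dr_len + offset, t_idx, strand))
        offset += len(elem) + spec.dr_len
        shifts.append((p + spec.dr_len, len(elem) + spec.dr_len))
        cursor = p + spec.dr_len
    pieces.append(g0[cursor:])
    g1 = "".join(pieces)

    def lift_g1(c: int) -> int:
        return c + sum(d for q, d in shifts if q <= c)

    features_g1 = [
        dataclasses.replace(f, start=lift_g1(f.start - 1) + 1, end=lift_g1(f.end - 1) + 1)
        for f in features
    ]

    # ---- choose per-strain events in G1 coordinates ----------------------
    reserved = [(f.start - 1, f.end) for f in features_g1]
    reserved += [
        (s, s + len(library[t].consensus)) for s, t, _ in shared_copies_g1
    ]
    events: list[_Event] = []

    def unambiguous_target(p: int, dr: int) -> bool:
        """Reject insertion targets already flanked by a copy of themselves:
        such a site is locally indistinguishable from an excision scar."""
        if dr == 0:
            return True
        t0 = g1[p : p + dr]
        return g1[p - dr : p] != t0 and g1[p + dr : p + 2 * dr] != t0

    def new_insert_event(strain: str, t_idx: int) -> _Event:
        spec = specs[t_idx]
        elem = library[t_idx].consensus
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        payload = revcomp(elem) if strand == "-" else elem
        payload = _mutate_core(
            rng, payload, spec.tir_len, config.insert_divergence
        )
        ext = spec.dr_len + len(payload)
        p = _sample_free_position(
            rng, 200, len(g1) - 200, ext, reserved, margin,
            what=f"differential insert of type {t_idx + 1}",
            validate=lambda p: unambiguous_target(p, spec.dr_len),
        )
        return _Event("long_insert", strain, p, t_idx, strand, payload)

    insert_plan: list[tuple[str, int]] = []
    for t_idx, n in enumerate(config.inserts_a):
        insert_plan += [("A", t_idx)] * n
    for t_idx, n in enumerate(config.inserts_b):
        insert_plan += [("B", t_idx)] * n

    disrupt_idx = -1
    if config.disrupt_gene and features_g1:
        # prefer a strain-B transposon insert, mirroring a disruption in the
        # strain that lost the phenotype
        for pref in (
            lambda s, t: s == "B" and specs[t].has_tir,
            lambda s, t: specs[t].has_tir,
            lambda s, t: True,
        ):
            hits = [i for i, (s, t) in enumerate(insert_plan) if pref(s, t)]
            if hits:
                disrupt_idx = hits[0]
                break

    for i, (strain, t_idx) in enumerate(insert_plan):
        if i == disrupt_idx:
            spec = specs[t_idx]
            elem = library[t_idx].consensus
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            payload = _mutate_core(
                rng,
                revcomp(elem) if strand == "-" else elem,
                spec.tir_len,
                config.insert_divergence,
            )
            candidates = [
                f for f in features_g1
                if f.end - f.start + 1 >= 2 * 30 + spec.dr_len + 10
            ]
            gene = candidates[int(rng.integers(0, len(candidates)))]
            while True:
                p = int(
                    rng.integers(gene.start - 1 + 30, gene.end - 30 - spec.dr_len)
                )
                if unambiguous_target(p, spec.dr_len):
                    break
            events.append(
                _Event("long_insert", strain, p, t_idx, strand, payload,
                       locus_tag=gene.locus_tag)
            )
        else:
            events.append(new_insert_event(strain, t_idx))

    for t_idx_choice in range(config.n_scars):
        tir_types = [i for i, s in enumerate(specs) if s.has_tir and s.dr_len >= 3]
        if not tir_types:
            raise ValueError("scars need a transposon type with a TSD")
        t_idx = tir_types[t_idx_choice % len(tir_types)]
        spec = specs[t_idx]
        elem = library[t_idx].consensus
        payload = _mutate_core(rng, elem, spec.tir_len, config.insert_divergence)
        ext = spec.dr_len + len(payload)
        p = _sample_free_position(
            rng, 200, len(g1) - 200, ext, reserved, margin, what="excision scar",
            validate=lambda p: unambiguous_target(p, spec.dr_len),
        )
        events.append(_Event("scar", "A", p, t_idx, "+", payload))

    for i in range(config.n_indel_1bp):
        strain = "A" if rng.integers(0, 2) == 0 else "B"
        kind = "indel_ins" if rng.integers(0, 2) == 0 else "indel_del"
        p = _sample_free_position(
            rng, 200, len(g1) - 200, 1, reserved, margin, what=f"indel {i + 1}"
        )
        payload = "ACGT"[int(rng.integers(0, 4))] if kind == "indel_ins" else ""
        events.append(_Event(kind, strain, p, payload=payload))

    for i in range(config.n_substitutions):
        strain = "A" if rng.integers(0, 2) == 0 else "B"
        p = _sample_free_position(
            rng, 200, len(g1) - 200, 1, reserved, margin, what=f"substitution {i + 1}"
        )
        current = g1[p]
        options = [b for b in "ACGT" if b != current]
        events.append(
            _Event("substitution", strain, p, payload=options[int(rng.integers(0, 3))])
        )

    events.sort(key=lambda e: e.p)

    # ---- build each strain and its coordinate map ------------------------
    def build(strain: str) -> tuple[str, _CoordMap]:
        cmap = _CoordMap()
        parts: list[str] = []
        cur = 0
        for e in events:
            spec = specs[e.type_idx] if e.type_idx >= 0 else None
            if e.kind in ("long_insert", "scar"):
                dr = spec.dr_len
                t0 = g1[e.p : e.p + dr]
                if e.kind == "long_insert" and e.strain == strain:
                    parts.append(g1[cur : e.p + dr])
                    parts.append(e.payload + t0)
                    cmap.add(e.p + dr, len(e.payload) + dr)
                    cur = e.p + dr
                elif e.kind == "scar":
                    if strain == "A":
                        parts.append(g1[cur : e.p + dr])
                        parts.append(e.payload + t0)
                        cmap.add(e.p + dr, len(e.payload) + dr)
                    else:
                        parts.append(g1[cur : e.p + dr])
                        parts.append(t0)
                        cmap.add(e.p + dr, dr)
                    cur = e.p + dr
            elif e.kind == "indel_ins" and e.strain == strain:
                parts.append(g1[cur : e.p])
                parts.append(e.payload)
                cmap.add(e.p, 1)
                cur = e.p
            elif e.kind == "indel_del" and e.strain == strain:
                parts.append(g1[cur : e.p])
                cmap.add(e.p + 1, -1)
                cur = e.p + 1
            elif e.kind == "substitution" and e.strain == strain:
                parts.append(g1[cur : e.p])
                parts.append(e.payload)
                cur = e.p + 1
        parts.append(g1[cur:])
        return "".join(parts), cmap

    seq_a, map_a = build("A")
    seq_b, map_b = build("B")
    id_a, id_b = config.genome_a_id, config.genome_b_id

    # ---- truth records in final coordinates -------------------------------
    variants: list[TruthVariant] = []
    copies: list[TruthCopy] = [
        TruthCopy(
            genome_id=gid,
            start=cmap.map(s) + 1,
            end=cmap.map(s) + len(library[t].consensus),
            type_id=t + 1,
            strand=strand,
            source="shared",
        )
        for s, t, strand in shared_copies_g1
        for gid, cmap in ((id_a, map_a), (id_b, map_b))
    ]
    scars: list[TruthScar] = []

    for e in events:
        if e.kind == "long_insert":
            spec = specs[e.type_idx]
            dr = spec.dr_len
            run = e.payload + g1[e.p : e.p + dr]  # element + duplicated target
            carrier = e.strain
            c_map = map_a if carrier == "A" else map_b
            # insertion point in shared coords is e.p + dr (after the target);
            # map() at that point already includes this event's delta, so
            # subtract it back to land at the run start
            start0 = c_map.map(e.p + dr) - len(run)
            c_seq = seq_a if carrier == "A" else seq_b
            o_map = map_b if carrier == "A" else map_a
            norm = left_normalise_insertion(c_seq, start0, len(run))
            shift = start0 - norm
            point_other = o_map.map(e.p + dr) - shift
            run_norm = c_seq[norm : norm + len(run)]
            cid = id_a if carrier == "A" else id_b
            if carrier == "A":
                pa, pb, ref, alt = norm + 1, point_other, run_norm, ""
            else:
                pa, pb, ref, alt = point_other, norm + 1, "", run_norm
            etype = library[e.type_idx]
            variants.append(
                TruthVariant(
                    kind="long_insert",
                    carrier=cid,
                    pos_a=pa,
                    pos_b=pb,
                    ref_allele=ref,
                    alt_allele=alt,
                    length=len(run),
                    type_id=e.type_idx + 1,
                    tir_seq=etype.repeat.tir_seq if etype.repeat else "",
                    dr_seq=g1[e.p : e.p + dr],
                    disrupted_locus_tag=e.locus_tag,
                )
            )
            body_start = c_map.map(e.p + dr) - len(run) + 0  # run start
            copies.append(
                TruthCopy(
                    genome_id=cid,
                    start=body_start + 1,
                    end=body_start + len(e.payload),
                    type_id=e.type_idx + 1,
                    strand=e.strand,
                    source="differential",
                )
            )
        elif e.kind == "scar":
            spec = specs[e.type_idx]
            dr = spec.dr_len
            t0 = g1[e.p : e.p + dr]
            run = e.payload  # element only; both strains keep a target copy
            start0 = map_a.map(e.p + dr) - len(run) - dr
            norm = left_normalise_insertion(seq_a, start0, len(run))
            shift = start0 - norm
            point_b = map_b.map(e.p + dr) - dr - shift  # run placement in B
            run_norm = seq_a[norm : norm + len(run)]
            etype = library[e.type_idx]
            variants.append(
                TruthVariant(
                    kind="long_insert",
                    carrier=id_a,
                    pos_a=norm + 1,
                    pos_b=point_b,
                    ref_allele=run_norm,
                    alt_allele="",
                    length=len(run),
                    type_id=e.type_idx + 1,
                    tir_seq=etype.repeat.tir_seq if etype.repeat else "",
                    dr_seq=t0,
                    from_scar=True,
                )
            )
            copies.append(
                TruthCopy(
                    genome_id=id_a,
                    start=start0 + 1,
                    end=start0 + len(run),
                    type_id=e.type_idx + 1,
                    strand=e.strand,
                    source="scar",
                )
            )
            # the element sat between the two target copies, independent of
            # how the called run normalises
            scar_point = left_normalise_tandem(seq_b, map_b.map(e.p + dr) - dr, dr)
            scars.append(
                TruthScar(
                    genome_id=id_b,
                    position=scar_point + 1,
                    dr_seq=seq_b[scar_point - dr : scar_point],
                )
            )
        elif e.kind == "indel_ins":
            carrier = e.strain
            c_seq, c_map = (seq_a, map_a) if carrier == "A" else (seq_b, map_b)
            o_map = map_b if carrier == "A" else map_a
            start0 = c_map.map(e.p) - 1
            norm = left_normalise_insertion(c_seq, start0, 1)
            shift = start0 - norm
            point_other = o_map.map(e.p) - shift
            cid = id_a if carrier == "A" else id_b
            base = c_seq[norm]
            if carrier == "A":
                pa, pb, ref, alt = norm + 1, point_other, base, ""
            else:
                pa, pb, ref, alt = point_other, norm + 1, "", base
            variants.append(
                TruthVariant("indel_1bp", cid, pa, pb, ref, alt, 1)
            )
        elif e.kind == "indel_del":
            # the base G1[e.p] survives only in the *other* strain
            carrier = "B" if e.strain == "A" else "A"
            c_seq, c_map = (seq_a, map_a) if carrier == "A" else (seq_b, map_b)
            o_map = map_b if carrier == "A" else map_a
            start0 = c_map.map(e.p)
            norm = left_normalise_insertion(c_seq, start0, 1)
            shift = start0 - norm
            point_other = o_map.map(e.p + 1) - shift  # point before the site
            cid = id_a if carrier == "A" else id_b
            base = c_seq[norm]
            if carrier == "A":
                pa, pb, ref, alt = norm + 1, point_other, base, ""
            else:
                pa, pb, ref, alt = point_other, norm + 1, "", base
            variants.append(
                TruthVariant("indel_1bp", cid, pa, pb, ref, alt, 1)
            )
        elif e.kind == "substitution":
            pa = map_a.map(e.p) + 1
            pb = map_b.map(e.p) + 1
            ref = seq_a[pa - 1]
            alt = seq_b[pb - 1]
            variants.append(
                TruthVariant("substitution", id_b, pa, pb, ref, alt, 1)
            )

    # ---- lift annotations into each strain --------------------------------
    def lift_features(gid: str, cmap: _CoordMap, seq_len: int) -> list[FeatureRecord]:
        out = []
        for f in features_g1:
            s = cmap.map(f.start - 1) + 1
            t = cmap.map(f.end - 1) + 1
            out.append(dataclasses.replace(f, seqid=gid, start=s, end=min(t, seq_len)))
        return out

    feats_a = lift_features(id_a, map_a, len(seq_a))
    feats_b = lift_features(id_b, map_b, len(seq_b))

    genome_a = GenomeSequence(id=id_a, sequence=seq_a)
    genome_b = GenomeSequence(id=id_b, sequence=seq_b)

    truth = TruthSet(variants=variants, copies=copies, scars=scars).sorted()
    _self_check(truth, genome_a, genome_b)
    return genome_a, genome_b, feats_a, feats_b, truth


def _self_check(truth: TruthSet, ga: GenomeSequence, gb: GenomeSequence) -> None:
    """Every recorded run must occur verbatim at its recorded position."""
    seqs = {ga.id: ga.sequence, gb.id: gb.sequence}
    for v in truth.variants:
        if v.kind == "substitution":
            assert seqs[ga.id][v.pos_a - 1] == v.ref_allele
            assert seqs[gb.id][v.pos_b - 1] == v.alt_allele
            continue
        run = v.ref_allele or v.alt_allele
        pos = v.pos_a if v.ref_allele else v.pos_b
        assert seqs[v.carrier][pos - 1 : pos - 1 + v.length] == run, (
            f"truth inconsistency for {v.kind} at {pos} in {v.carrier}"
        )


def simulate_strain_pair(config: SimulationConfig):
    """Convenience wrapper: ancestor -> library -> derived pair."""
    ancestor, features = simulate_ancestor(config)
    library = build_element_library(config)
    return derive_strain_pair(ancestor, features, library, config) + (library,)


# ---------------------------------------------------------------------------
# truth table serialisation

def write_truth(truth: TruthSet, out_dir: str | os.PathLike) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = truth.sorted()
    var_df = pd.DataFrame(
        [dataclasses.asdict(v) for v in truth.variants],
        columns=[f.name for f in dataclasses.fields(TruthVariant)],
    )
    tsv_path = out_dir / "truth_variants.tsv"
    var_df.to_csv(tsv_path, sep="\t", index=False)
    payload = {
        "variants": [dataclasses.asdict(v) for v in truth.variants],
        "copies": [dataclasses.asdict(c) for c in truth.copies],
        "scars": [dataclasses.asdict(s) for s in truth.scars],
    }
    json_path = out_dir / "truth.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return {"tsv": tsv_path, "json": json_path}


def read_truth(json_path: str | os.PathLike) -> TruthSet:
    with open(json_path) as fh:
        payload = json.load(fh)
    return TruthSet(
        variants=[TruthVariant(**v) for v in payload["variants"]],
        copies=[TruthCopy(**c) for c in payload["copies"]],
        scars=[TruthScar(**s) for s in payload["scars"]],
    ).sorted()
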