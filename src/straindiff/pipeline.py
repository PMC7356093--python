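"""End-to-end orchestration: diff -> type -> census -> scars -> impact."""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .census import (
    ElementCopy,
    ElementType,
    ScarRecord,
    classify_copies,
    detect_excision_scars,
    element_type_from_members,
    scan_copies,
)
from .diff import DiffParams, DiffReport, VariantRecord, diff_genomes
from .impact import DisruptionReport, map_variant_to_features
from .insert_types import InsertTypeAssignment, cluster_inserts
from .io import FeatureRecord, GenomeSequence

FLANK = 30


@dataclasses.dataclass
class PipelineResult:
    diff: DiffReport
    insert_assignments: list[InsertTypeAssignment]  # parallel to long inserts
    long_inserts: list[VariantRecord]
    element_types: dict[int, ElementType]
    copies: dict[str, list[ElementCopy]]  # per genome id
    scars: list[ScarRecord]
    disruptions: list[DisruptionReport]

    @property
    def transposon_type_ids(self) -> list[int]:
        return sorted(t for t, e in self.element_types.items() if e.is_transposon)


def carrier_locus(v: VariantRecord) -> int:
    """1-based start of an insertion's run within its carrier genome."""
    return v.pos_a if v.ref_allele else v.pos_b


def analyse_pair(
    genome_a: GenomeSequence,
    genome_b: GenomeSequence,
    features_a: Sequence[FeatureRecord] = (),
    features_b: Sequence[FeatureRecord] = (),
    params: DiffParams | None = None,
    identity_threshold: float = 90.0,
    min_tir_len: int = 10,
    min_dr_len: int = 3,
    promoter_window: int = 150,
) -> PipelineResult:
    """Run the whole comparison on one genome pair."""
    genomes = {genome_a.id: genome_a, genome_b.id: genome_b}
    features = {genome_a.id: list(features_a), genome_b.id: list(features_b)}

    report = diff_genomes(genome_a, genome_b, params)
    inserts = [v for v in report.variants if v.kind == "long_insert"]

    assignments: list[InsertTypeAssignment] = []
    element_types: dict[int, ElementType] = {}
    copies: dict[str, list[ElementCopy]] = {genome_a.id: [], genome_b.id: []}
    if inserts:
        ids = [f"insert_{i + 1}" for i in range(len(inserts))]
        seqs = [v.ref_allele or v.alt_allele for v in inserts]
        assignments = cluster_inserts(ids, seqs, identity_threshold)
        members: dict[int, list[tuple[str, str, str]]] = {}
        for a, v in zip(assignments, inserts):
            carrier = genomes[v.carrier]
            s0 = carrier_locus(v) - 1
            run = v.ref_allele or v.alt_allele
            members.setdefault(a.type_id, []).append(
                (
                    run,
                    carrier.sequence[max(s0 - FLANK, 0) : s0],
                    carrier.sequence[s0 + len(run) : s0 + len(run) + FLANK],
                )
            )
        for type_id, mem in sorted(members.items()):
            element_types[type_id] = element_type_from_members(
                type_id, mem, min_tir_len, min_dr_len
            )
        for type_id, etype in element_types.items():
            if not etype.is_transposon:
                continue
            for g in genomes.values():
                found = scan_copies(g, etype)
                copies[g.id].extend(classify_copies(found, etype))
        for gid in copies:
            copies[gid].sort(key=lambda c: c.start)

    scars = detect_excision_scars(
        report, genomes, censuses=copies, min_tir_len=min_tir_len, min_dr_len=min_dr_len
    )

    disruptions: list[DisruptionReport] = []
    for v in report.variants:
        gid = v.carrier
        if features[gid]:
            disruptions.append(
                map_variant_to_features(v, features[gid], genomes[gid], promoter_window)
            )

    return PipelineResult(
        diff=report,
        insert_assignments=assignments,
        long_inserts=inserts,
        element_types=element_types,
        copies=copies,
        scars=scars,
        disruptions=disruptions,
    )
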