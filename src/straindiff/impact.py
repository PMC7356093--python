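"""Consequences of variants and element copies on gene annotations.

Region calls use closed-interval overlap against CDS features (an event
touching a CDS boundary counts as CDS), then a strand-aware promoter window
upstream of the CDS start, then intergenic.  Effects: long inserts and
element copies inside a CDS disrupt the gene; indels whose length is not a
multiple of three shift the reading frame; substitutions are translated
in-frame with the bacterial genetic code (translation table 11) to decide
synonymous / missense / nonsense.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Sequence

import yaml
from Bio.Seq import Seq

from .align import align_pair, GAP_CHAR
from .census import ElementCopy
from .diff import VariantRecord
from .io import FeatureRecord, GenomeSequence
from .sequtil import revcomp

TRANSLATION_TABLE = 11
DEFAULT_PROMOTER_WINDOW = 150


@dataclasses.dataclass(frozen=True)
class DisruptionReport:
    event_id: str
    feature: str  # locus_tag or "intergenic"
    region: str  # CDS | promoter | intergenic
    effect: str  # gene_disrupted | frameshift | synonymous | missense | nonsense | none


@dataclasses.dataclass(frozen=True)
class GenePanelRow:
    gene_name: str
    locus_a: str
    locus_b: str
    cds_identity: float | None  # percent; None when a locus tag is unresolvable
    promoter_identity: float | None
    differs: bool
    missing: bool = False


def _event_interval(event: VariantRecord | ElementCopy, genome_id: str) -> tuple[int, int]:
    """1-based inclusive footprint of the event in ``genome_id``."""
    if isinstance(event, ElementCopy):
        return event.start, event.end
    if event.kind == "substitution":
        # diff assigns the B-side id as the substitution carrier
        pos = event.pos_b if genome_id == event.carrier else event.pos_a
        return pos, pos
    carrier_is_a = bool(event.ref_allele)
    if genome_id == event.carrier:
        start = event.pos_a if carrier_is_a else event.pos_b
        return start, start + event.length - 1
    # non-carrier genome: the event is a point between two bases
    point = event.pos_b if carrier_is_a else event.pos_a
    return max(point, 1), point + 1


def _promoter_interval(cds: FeatureRecord, window: int, genome_len: int) -> tuple[int, int]:
    if cds.strand == "+":
        return max(1, cds.start - window), cds.start - 1
    return cds.end + 1, min(genome_len, cds.end + window)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _substitution_effect(
    variant: VariantRecord, cds: FeatureRecord, genome: GenomeSequence, pos: int
) -> str:
    """Translate the affected codon before and after the substitution."""
    cds_seq = genome.sequence[cds.start - 1 : cds.end]
    offset = pos - cds.start  # 0-based within the forward-strand CDS slice
    # ref/alt are in A/B orientation; apply whichever differs from this genome
    current = genome.sequence[pos - 1]
    alt_base = variant.alt_allele if variant.alt_allele != current else variant.ref_allele
    alt_cds = cds_seq[:offset] + alt_base + cds_seq[offset + 1 :]
    if cds.strand == "-":
        cds_seq, alt_cds = revcomp(cds_seq), revcomp(alt_cds)
    usable = len(cds_seq) - len(cds_seq) % 3
    aa_ref = str(Seq(cds_seq[:usable]).translate(table=TRANSLATION_TABLE))
    aa_alt = str(Seq(alt_cds[:usable]).translate(table=TRANSLATION_TABLE))
    if aa_ref == aa_alt:
        return "synonymous"
    codon_idx = next(i for i, (x, y) in enumerate(zip(aa_ref, aa_alt)) if x != y)
    return "nonsense" if aa_alt[codon_idx] == "*" else "missense"


def map_variant_to_features(
    event: VariantRecord | ElementCopy,
    features: Sequence[FeatureRecord],
    genome: GenomeSequence,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> DisruptionReport:
    """Call region (CDS / promoter / intergenic) and effect for one event.

    ``genome`` and ``features`` must be the annotation of the genome carrying
    the event (for copies and insertions) or either genome (substitutions).
    """
    if isinstance(event, ElementCopy):
        interval = (event.start, event.end)
        event_id = f"copy:{event.genome_id}:{event.start}-{event.end}"
        kind = "element_copy"
    else:
        interval = _event_interval(event, genome.id)
        event_id = f"{event.kind}:{event.carrier}:{interval[0]}"
        kind = event.kind
    if interval[0] < 1 or interval[1] > len(genome) + 1:
        raise ValueError(f"event {event_id} outside genome bounds")

    cds_features = [f for f in features if f.feature_type == "CDS"]
    hit = next((f for f in cds_features if _overlaps(interval, (f.start, f.end))), None)
    if hit is not None:
        if kind in ("long_insert", "element_copy"):
            effect = "gene_disrupted"
        elif kind == "indel_1bp":
            effect = "frameshift"  # length 1 is never a multiple of 3
        else:
            effect = _substitution_effect(event, hit, genome, interval[0])
        return DisruptionReport(event_id, hit.locus_tag, "CDS", effect)

    for f in cds_features:
        if _overlaps(interval, _promoter_interval(f, promoter_window, len(genome))):
            return DisruptionReport(event_id, f.locus_tag, "promoter", "none")
    return DisruptionReport(event_id, "intergenic", "intergenic", "none")


def _gapped_identity(seq_x: str, seq_y: str) -> float:
    ax, ay = align_pair(seq_x, seq_y)
    matches = sum(1 for a, b in zip(ax, ay) if a == b and a != GAP_CHAR)
    return 100.0 * matches / len(ax)


def _extract_regions(
    genome: GenomeSequence,
    features: Sequence[FeatureRecord],
    locus_tag: str,
    promoter_window: int,
) -> tuple[str, str] | None:
    cds = next(
        (f for f in features if f.locus_tag == locus_tag and f.feature_type == "CDS"),
        None,
    )
    if cds is None:
        return None
    cds_seq = genome.sequence[cds.start - 1 : cds.end]
    p0, p1 = _promoter_interval(cds, promoter_window, len(genome))
    prom_seq = genome.sequence[p0 - 1 : p1] if p0 <= p1 else ""
    if cds.strand == "-":
        cds_seq = revcomp(cds_seq)
        prom_seq = revcomp(prom_seq)
    return cds_seq, prom_seq


def load_default_panel() -> list[dict]:
    """The packaged sulfur-metabolism gene panel (locus-tag pairs)."""
    text = resources.files("straindiff").joinpath("data/sulfur_gene_panel.yaml").read_text()
    return yaml.safe_load(text)["genes"]


def compare_gene_panel(
    genome_a: GenomeSequence,
    features_a: Sequence[FeatureRecord],
    genome_b: GenomeSequence,
    features_b: Sequence[FeatureRecord],
    panel: Sequence[dict],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> list[GenePanelRow]:
    """Compare coding and promoter regions of a gene panel between strains.

    Each panel entry maps a gene name to its locus tag in each annotation
    (keys: gene, locus_a, locus_b).  Identities are percent matching columns
    over a global alignment, gaps counted as differences, so any inserted,
    deleted or substituted base flags the row.
    """
    rows: list[GenePanelRow] = []
    for entry in panel:
        gene = entry["gene"]
        la, lb = entry["locus_a"], entry["locus_b"]
        ra = _extract_regions(genome_a, features_a, la, promoter_window)
        rb = _extract_regions(genome_b, features_b, lb, promoter_window)
        if ra is None or rb is None:
            rows.append(GenePanelRow(gene, la, lb, None, None, False, missing=True))
            continue
        cds_id = _gapped_identity(ra[0], rb[0])
        prom_id = _gapped_identity(ra[1], rb[1]) if ra[1] and rb[1] else 100.0
        rows.append(
            GenePanelRow(
                gene_name=gene,
                locus_a=la,
                locus_b=lb,
                cds_identity=cds_id,
                promoter_identity=prom_id,
                differs=(cds_id < 100.0 or prom_id < 100.0),
            )
        )
    return rows


def count_cds_in_copy(copy: ElementCopy, features: Sequence[FeatureRecord]) -> int:
    """CDS features fully contained within the copy's interval."""
    return sum(
        1
        for f in features
        if f.feature_type == "CDS" and f.start >= copy.start and f.end <= copy.end
    )
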