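"""Reading and writing the formats the pipeline touches.

Genomes travel as FASTA, annotations as GFF3, results as TSV (1-based
inclusive coordinates) and BED (0-based half-open).  Internally every module
works 0-based half-open; the conversion to the human-facing convention
happens only here, so an off-by-one cannot creep between stages.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequtil import DNA_ALPHABET


@dataclasses.dataclass(frozen=True)
class GenomeSequence:
    """One assembly: identifier, uppercase sequence over {A,C,G,T,N}, topology."""

    id: str
    sequence: str
    topology: str = "linear"  # or "circular"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear|circular, got {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class FeatureRecord:
    """One annotated feature, GFF3-style 1-based inclusive coordinates."""

    seqid: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    feature_type: str
    locus_tag: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad feature interval [{self.start},{self.end}]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Load FASTA records, uppercasing and validating the DNA alphabet.

    Characters outside {A,C,G,T,N} are rejected with their 1-based position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genomes: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        for i, ch in enumerate(seq):
            if ch not in DNA_ALPHABET:
                raise ValueError(
                    f"illegal character {ch!r} at position {i + 1} of record {rec.id!r}"
                )
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        genomes.append(GenomeSequence(id=rec.id, sequence=seq))
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


def write_fasta(genomes: Iterable[GenomeSequence], path: str | os.PathLike) -> None:
    """Write records with 60-column wrapping (Bio.SeqIO default)."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in field.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, _, value = item.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(path: str | os.PathLike, genome: GenomeSequence) -> list[FeatureRecord]:
    """Parse a GFF3 file, validating coordinates against ``genome``.

    Only rows whose seqid matches ``genome.id`` are returned; ``locus_tag``
    and ``product`` attributes are extracted when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    features: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if seqid != genome.id:
                continue
            start, end = int(start_s), int(end_s)
            if not 1 <= start <= end <= len(genome):
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}] outside genome "
                    f"{genome.id!r} of length {len(genome)}"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = _parse_gff_attributes(attr_s)
            features.append(
                FeatureRecord(
                    seqid=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_type=ftype,
                    locus_tag=attrs.get("locus_tag", attrs.get("ID", "")),
                    product=attrs.get("product", ""),
                )
            )
    return features


def write_gff3(
    features: Sequence[FeatureRecord], genome: GenomeSequence, path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for f in sorted(features, key=lambda f: (f.seqid, f.start, f.end)):
            attrs = []
            if f.locus_tag:
                attrs.append(f"ID={f.locus_tag}")
                attrs.append(f"locus_tag={f.locus_tag}")
            if f.product:
                attrs.append(f"product={f.product}")
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        "straindiff",
                        f.feature_type,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.feature_type == "CDS" else ".",
                        ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# coordinate conversions (tested both ways)

def to_bed_interval(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> BED 0-based half-open."""
    return start_1based - 1, end_1based


def from_bed_interval(start0: int, end0: int) -> tuple[int, int]:
    """BED 0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def write_report_tables(
    variants: Sequence,
    out_dir: str | os.PathLike,
    *,
    stage: str = "diff",
) -> dict[str, Path]:
    """Emit a stage's variant records as TSV (1-based) and BED (0-based).

    Row order is deterministic: genome id, then coordinate, then kind.
    Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in variants:
        rows.append(
            {
                "kind": v.kind,
                "carrier": v.carrier,
                "pos_a": v.pos_a,
                "pos_b": v.pos_b,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "length": v.length,
            }
        )
    df = pd.DataFrame(
        rows, columns=["kind", "carrier", "pos_a", "pos_b", "ref", "alt", "length"]
    )
    if len(df):
        df = df.sort_values(["carrier", "pos_a", "pos_b", "kind"], kind="stable")
    tsv_path = out_dir / f"{stage}_variants.tsv"
    df.to_csv(tsv_path, sep="\t", index=False)

    bed_path = out_dir / f"{stage}_inserts.bed"
    with open(bed_path, "w") as fh:
        for row in df.itertuples(index=False):
            if row.kind != "long_insert":
                continue
            pos = row.pos_a if row.carrier.endswith("a") else row.pos_b
            # carrier-genome coordinates of the inserted run
            carrier_pos = row.pos_a if row.ref else row.pos_b
            start0, end0 = to_bed_interval(carrier_pos, carrier_pos + row.length - 1)
            fh.write(f"{row.carrier}\t{start0}\t{end0}\tlong_insert\n")
            del pos
    return {"tsv": tsv_path, "bed": bed_path}


def write_copies_tables(copies: Sequence, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Element-copy census as TSV (1-based) and BED (0-based half-open)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "genome_id": c.genome_id,
            "start": c.start,
            "end": c.end,
            "type_id": c.type_id,
            "strand": c.strand,
            "length": c.length,
            "full_length": c.full_length,
        }
        for c in copies
    ]
    df = pd.DataFrame(
        rows,
        columns=["genome_id", "start", "end", "type_id", "strand", "length", "full_length"],
    )
    if len(df):
        df = df.sort_values(["genome_id", "start", "type_id"], kind="stable")
    tsv_path = out_dir / "copies.tsv"
    df.to_csv(tsv_path, sep="\t", index=False)
    bed_path = out_dir / "copies.bed"
    with open(bed_path, "w") as fh:
        for row in df.itertuples(index=False):
            start0, end0 = to_bed_interval(row.start, row.end)
            fh.write(
                f"{row.genome_id}\t{start0}\t{end0}\ttype{row.type_id}\t0\t{row.strand}\n"
            )
    return {"tsv": tsv_path, "bed": bed_path}
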