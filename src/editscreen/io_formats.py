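"""Readers and writers for the formats the screen touches.

FASTA and FASTQ parsing is delegated to Biopython, GFF3 parsing to
gffutils, and SAM parsing to pysam; this module adapts their records to
the small domain types used downstream and converts alignments into
per-base observations.

Coordinates are 1-based inclusive everywhere except transient interval
arithmetic.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
import pysam
from Bio import SeqIO

from .errors import FormatError, UsageError, ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True, slots=True)
class GenomeSequence:
    """One reference contig; sequence stored uppercase over {A,C,G,T,N}."""

    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def base_at(self, pos: int) -> str:
        """Return the base at 1-based ``pos``; out-of-range is an error."""
        if not 1 <= pos <= len(self.seq):
            raise UsageError(
                f"position {pos} outside contig {self.name!r} (length {len(self.seq)})"
            )
        return self.seq[pos - 1]

    def region(self, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval [start, end]."""
        if start > end:
            raise UsageError(f"start {start} > end {end}")
        if start < 1 or end > len(self.seq):
            raise UsageError(
                f"interval [{start},{end}] outside contig {self.name!r} "
                f"(length {len(self.seq)})"
            )
        return self.seq[start - 1 : end]


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene with exon structure and optional CDS, in genomic coordinates."""

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.gene_start > self.gene_end:
            raise ValidationError(f"{self.gene_id}: start > end")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValidationError(f"{self.gene_id}: exon start {start} > end {end}")
            if start <= prev_end:
                raise ValidationError(f"{self.gene_id}: exons overlap or unsorted")
            if start < self.gene_start or end > self.gene_end:
                raise ValidationError(
                    f"{self.gene_id}: exon ({start},{end}) outside gene span"
                )
            prev_end = end
        for start, end, frame in self.cds:
            if start > end:
                raise ValidationError(f"{self.gene_id}: CDS start {start} > end {end}")
            if frame not in {0, 1, 2}:
                raise ValidationError(f"{self.gene_id}: bad CDS frame {frame}")
            if not any(es <= start and end <= ee for es, ee in self.exons):
                raise ValidationError(
                    f"{self.gene_id}: CDS ({start},{end}) not inside an exon"
                )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intervals between consecutive exons, 1-based inclusive."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    def contains(self, pos: int) -> bool:
        return self.gene_start <= pos <= self.gene_end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e, _ in self.cds)


@dataclass(frozen=True, slots=True)
class AlignedObservation:
    """One aligned read base: the substrate of the pileup and bias filters.

    ``read_offset`` indexes the base within the stored (aligner
    orientation) read sequence, so distance to the nearer read end is
    ``min(read_offset, read_length - 1 - read_offset)``.
    """

    sample: str
    source: str  # "DNA" | "RNA"
    chrom: str
    pos: int
    base: str
    strand: str
    read_offset: int
    read_length: int
    read_id: str

    def end_distance(self) -> int:
        return min(self.read_offset, self.read_length - 1 - self.read_offset)


@dataclass(frozen=True, slots=True)
class RawRead:
    """A raw (possibly unaligned) sequencing read."""

    read_id: str
    seq: str
    mate: int = 1


@dataclass(frozen=True, slots=True)
class SiteRecord:
    """One row of a site table (the shape of the published screen table)."""

    tissue: str
    chrom: str
    pos: int
    dna_allele: str
    rna_allele: str
    canonical: bool
    replicates: int
    gene_names: tuple[str, ...] = ()
    localization: str = ""


SITE_TABLE_COLUMNS = (
    "tissue",
    "chrom",
    "pos",
    "dna_allele",
    "rna_allele",
    "canonical",
    "replicates",
    "gene_names",
    "localization",
)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into a list of uppercased contigs."""
    path = Path(path)
    with open(path) as handle:
        first = None
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise FormatError(f"{path}: empty FASTA file")
        if not first[1].startswith(">"):
            raise FormatError(
                f"{path}: line {first[0]}: expected FASTA header, got {first[1]!r}"
            )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        records.append(GenomeSequence(name=rec.id, seq=seq))
    return records


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene/exon/CDS with Parent links) from GFF3.

    Exons of all transcripts of a gene are merged into a single
    non-overlapping footprint; CDS intervals keep their annotated frames.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = []
        cds = []
        for child in db.children(gene.id):
            if child.featuretype == "exon":
                exons.append((child.start, child.end))
            elif child.featuretype == "CDS":
                frame = int(child.frame) if child.frame not in (None, ".") else 0
                cds.append((child.start, child.end, frame))
        for start, end in exons:
            if start < gene.start or end > gene.end:
                raise ValidationError(
                    f"{path}: exon ({start},{end}) outside gene {gene.id} "
                    f"span ({gene.start},{gene.end})"
                )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                gene_start=gene.start,
                gene_end=gene.end,
                exons=_merge_intervals(exons),
                cds=tuple(sorted(cds)),
            )
        )
    return models


def extract_observations(
    sam_path: str | Path, sample: str, source: str
) -> Iterator[AlignedObservation]:
    """Stream per-base observations from a SAM file.

    One observation is emitted per aligned M/=/X base; insertions and
    soft clips consume the read only, deletions and splice gaps (N)
    consume the reference only. Unmapped records are skipped, as are
    records whose CIGAR is inconsistent with the stored sequence.
    """
    if source not in {"DNA", "RNA"}:
        raise UsageError(f"source must be DNA or RNA, got {source!r}")
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            seq = rec.query_sequence.upper()
            try:
                pairs = rec.get_aligned_pairs(matches_only=True)
            except ValueError as exc:  # malformed CIGAR
                logger.warning("skipping record %s: %s", rec.query_name, exc)
                continue
            if rec.infer_query_length() != len(seq):
                logger.warning(
                    "skipping record %s: CIGAR/sequence length mismatch",
                    rec.query_name,
                )
                continue
            strand = "-" if rec.is_reverse else "+"
            read_length = len(seq)
            chrom = rec.reference_name
            for qpos, rpos in pairs:
                yield AlignedObservation(
                    sample=sample,
                    source=source,
                    chrom=chrom,
                    pos=rpos + 1,
                    base=seq[qpos],
                    strand=strand,
                    read_offset=qpos,
                    read_length=read_length,
                    read_id=rec.query_name,
                )


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream raw reads from FASTQ; mate number parsed from a /1 or /2 suffix."""
    path = Path(path)
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            name = rec.id
            mate = 1
            if name.endswith("/1") or name.endswith("/2"):
                mate = int(name[-1])
                name = name[:-2]
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"{path}: read {rec.id!r} has an empty sequence")
            yield RawRead(read_id=name, seq=seq, mate=mate)
    except ValueError as exc:  # Biopython signals truncated records this way
        raise FormatError(f"{path}: {exc}") from exc


def _parse_bool(text: str) -> bool:
    if text.lower() in {"yes", "true", "1"}:
        return True
    if text.lower() in {"no", "false", "0"}:
        return False
    raise FormatError(f"cannot parse boolean field {text!r}")


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read a TSV site table (header required)."""
    path = Path(path)
    records = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: missing header")
        missing = set(SITE_TABLE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            gene_names = tuple(
                name for name in row["gene_names"].split(",") if name
            )
            records.append(
                SiteRecord(
                    tissue=row["tissue"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    dna_allele=row["dna_allele"],
                    rna_allele=row["rna_allele"],
                    canonical=_parse_bool(row["canonical"]),
                    replicates=int(row["replicates"]),
                    gene_names=gene_names,
                    localization=row["localization"],
                )
            )
    return records


def write_site_table(records: Sequence[SiteRecord], path: str | Path) -> None:
    """Write site records as TSV; ``read_site_table`` round-trips the output."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_TABLE_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.tissue,
                    rec.chrom,
                    rec.pos,
                    rec.dna_allele,
                    rec.rna_allele,
                    "yes" if rec.canonical else "no",
                    rec.replicates,
                    ",".join(rec.gene_names),
                    rec.localization,
                ]
            )


def load_table2_fixture() -> list[SiteRecord]:
    """Load the packaged transcription of the published screen table."""
    from importlib.resources import files

    path = files("editscreen.data").joinpath("table2_sites.tsv")
    return read_site_table(str(path))
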