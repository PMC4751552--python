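"""Synthetic matched DNA/RNA cohorts with known truth.

The simulator writes a small reference genome (FASTA), gene models
(GFF3), per-sample aligned DNA and RNA reads (SAM), raw DNA reads
including unaligned paralog reads (FASTQ), and a truth table (TSV), so
every pipeline stage is testable without external data.

Artifact classes
----------------
``genomic_SNP``          sample is homozygous for the alternate allele in
                         both DNA and RNA — must NOT be detected.
``paralog_duplication``  extra DNA reads from a duplicated segment
                         carrying the RNA allele appear only in the raw
                         FASTQ (never in the SAM) — multimapping filter.
``strand_artifact``      the alternate base rides exclusively on one
                         alignment strand — strand filter.
``extremity_artifact``   the alternate base appears only within 10 bp of
                         read ends — extremity filter.
``splice_adjacent_error`` the site sits 1–3 bp inside an exon end —
                         splice filter.
``homopolymer_context``  an AAAA run flanks the site — homopolymer filter.
``ssr_context``          an (AC)6 repeat ends within 3 bp of the site —
                         SSR filter.

All randomness flows through numpy Generators derived from the single
``rng_seed``; the same seed yields byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import UsageError, ValidationError
from .filters import find_ssrs, reverse_complement
from .io_formats import GeneModel, GenomeSequence

BASES = ("A", "C", "G", "T")

ARTIFACT_CLASSES = (
    "genomic_SNP",
    "paralog_duplication",
    "strand_artifact",
    "extremity_artifact",
    "splice_adjacent_error",
    "homopolymer_context",
    "ssr_context",
)

#: expected flagging filter per artifact class ("" = survives/not detected)
EXPECTED_FLAG = {
    None: "",
    "genomic_SNP": "",
    "paralog_duplication": "multimapping",
    "strand_artifact": "strand",
    "extremity_artifact": "extremity",
    "splice_adjacent_error": "splice",
    "homopolymer_context": "homopolymer",
    "ssr_context": "ssr",
}

TRUTH_COLUMNS = (
    "chrom",
    "pos",
    "tissue",
    "dna_allele",
    "rna_allele",
    "truth_class",
    "expected_detected",
    "expected_flag",
    "n_expected_samples",
)

_GENE_OFFSET = 200
_GENE_PITCH = 2400
_EXON_LEN = 600
_INTRON_LEN = 600
_PARALOG_FLANK = 100
_MIN_RELIABLE_RATE = 0.3


@dataclass(frozen=True, slots=True)
class PlantedSite:
    """One planted DNA→RNA difference (true edit or artifact)."""

    pos: int
    dna_allele: str
    rna_allele: str
    rates: tuple[float, ...]
    tissue: str = "liver"
    chrom: str = "chr1"
    artifact: str | None = None

    def __post_init__(self) -> None:
        if self.artifact is not None and self.artifact not in ARTIFACT_CLASSES:
            raise UsageError(f"unknown artifact class {self.artifact!r}")
        if any(not 0.0 <= r <= 1.0 for r in self.rates):
            raise UsageError("editing rates must lie in [0, 1]")
        if self.dna_allele == self.rna_allele:
            raise UsageError("planted site needs two distinct alleles")


@dataclass(frozen=True, slots=True)
class SimulationConfig:
    """Cohort layout: eight samples of 2x101 bp-style reads by default."""

    genome_length: int = 10_000
    n_genes: int = 4
    n_samples: int = 8
    planted_sites: tuple[PlantedSite, ...] = ()
    dna_depth: int = 30
    rna_depth: int = 30
    read_length: int = 101
    error_rate: float = 0.0
    rng_seed: int = 101

    def __post_init__(self) -> None:
        if self.dna_depth < 1 or self.rna_depth < 1:
            raise UsageError("depths must be >= 1")
        positions = [(s.chrom, s.pos) for s in self.planted_sites]
        if len(positions) != len(set(positions)):
            raise UsageError("planted site positions must be unique")
        for site in self.planted_sites:
            if len(site.rates) != self.n_samples:
                raise UsageError(
                    f"site at {site.pos}: {len(site.rates)} rates for "
                    f"{self.n_samples} samples"
                )

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(f"s{i + 1}" for i in range(self.n_samples))

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(sorted({s.tissue for s in self.planted_sites})) or ("liver",)


def gene_layout(n_genes: int) -> list[dict]:
    """Deterministic two-exon gene coordinates used by the simulator."""
    genes = []
    for i in range(n_genes):
        g = _GENE_OFFSET + i * _GENE_PITCH
        genes.append(
            {
                "gene_id": f"gene{i + 1}",
                "start": g,
                "end": g + 2 * _EXON_LEN + _INTRON_LEN - 1,
                "strand": "-" if i == 1 else "+",
                "exons": (
                    (g, g + _EXON_LEN - 1),
                    (g + _EXON_LEN + _INTRON_LEN, g + 2 * _EXON_LEN + _INTRON_LEN - 1),
                ),
            }
        )
    return genes


def _gene_models(config: SimulationConfig) -> list[GeneModel]:
    models = []
    for spec in gene_layout(config.n_genes):
        (e1s, e1e), (e2s, e2e) = spec["exons"]
        cds1 = (e1s + 100, e1e)  # 500 bp
        cds2 = (e2s, e2s + 499)  # 500 bp
        if spec["strand"] == "+":
            cds = ((cds1[0], cds1[1], 0), (cds2[0], cds2[1], 1))
        else:
            cds = ((cds1[0], cds1[1], 1), (cds2[0], cds2[1], 0))
        models.append(
            GeneModel(
                gene_id=spec["gene_id"],
                chrom="chr1",
                strand=spec["strand"],
                gene_start=spec["start"],
                gene_end=spec["end"],
                exons=spec["exons"],
                cds=cds,
            )
        )
    return models


def default_config(seed: int = 101, tissue: str = "liver") -> SimulationConfig:
    """The standard eight-sample cohort: two true edits plus one site per
    artifact class, all placed in exons of the deterministic gene layout."""
    n = 8
    on5 = (0.4,) * 5 + (0.0,) * 3
    all8 = (0.5,) * n
    # artifact-context sites express high so their flag verdicts are stable
    mid = (0.8,) * n
    sites = (
        PlantedSite(pos=500, dna_allele="A", rna_allele="G", rates=on5, tissue=tissue),
        PlantedSite(pos=4100, dna_allele="T", rna_allele="C", rates=all8, tissue=tissue),
        PlantedSite(
            pos=1600, dna_allele="A", rna_allele="G", rates=(1.0,) * n,
            tissue=tissue, artifact="genomic_SNP",
        ),
        PlantedSite(
            pos=2900, dna_allele="A", rna_allele="G", rates=mid,
            tissue=tissue, artifact="paralog_duplication",
        ),
        PlantedSite(
            pos=5300, dna_allele="A", rna_allele="G", rates=mid,
            tissue=tissue, artifact="strand_artifact",
        ),
        PlantedSite(
            pos=6500, dna_allele="C", rna_allele="T", rates=mid,
            tissue=tissue, artifact="extremity_artifact",
        ),
        PlantedSite(
            pos=7998, dna_allele="A", rna_allele="G", rates=mid,
            tissue=tissue, artifact="splice_adjacent_error",
        ),
        PlantedSite(
            pos=8900, dna_allele="T", rna_allele="C", rates=mid,
            tissue=tissue, artifact="homopolymer_context",
        ),
        PlantedSite(
            pos=650, dna_allele="A", rna_allele="T", rates=mid,
            tissue=tissue, artifact="ssr_context",
        ),
    )
    return SimulationConfig(planted_sites=sites, rng_seed=seed)


def _context_is_clean(seq: list[str], pos: int, length: int) -> bool:
    """No homopolymer flank and no SSR within +-3 bp of a 1-based pos."""
    if pos - 4 >= 1:
        left = seq[pos - 5 : pos - 1]
        if len(set(left)) == 1:
            return False
    if pos + 4 <= length:
        right = seq[pos : pos + 4]
        if len(set(right)) == 1:
            return False
    lo = max(1, pos - 45)
    hi = min(length, pos + 45)
    region = "".join(seq[lo - 1 : hi])
    for ssr in find_ssrs(region, region_start=lo):
        if ssr.start - 3 <= pos <= ssr.end + 3:
            return False
    return True


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, GenomeSequence], list[GeneModel]]:
    """Build the reference contig and gene models.

    Bases are i.i.d. uniform except where artifact specs demand a
    homopolymer or SSR context, which are written verbatim; flanks of
    every other planted site are re-drawn until free of accidental
    homopolymer/SSR contexts.
    """
    genes = _gene_models(config)
    if genes and genes[-1].gene_end > config.genome_length:
        raise ValidationError(
            f"genome_length {config.genome_length} too short for "
            f"{config.n_genes} genes (need {genes[-1].gene_end})"
        )
    rng = np.random.default_rng([config.rng_seed, 0])
    seq = list(rng.choice(BASES, size=config.genome_length))
    planted_positions = {s.pos for s in config.planted_sites}
    for site in config.planted_sites:
        seq[site.pos - 1] = site.dna_allele
        if site.artifact == "homopolymer_context":
            # C AAAA [site]; right flank left random (scrubbed below if needed)
            seq[site.pos - 6] = "C"
            for i in range(site.pos - 5, site.pos - 1):
                seq[i] = "A"
        elif site.artifact == "ssr_context":
            # (AC)6 occupying [pos-13, pos-2], broken on both sides
            seq[site.pos - 15] = "G"
            for k in range(12):
                seq[site.pos - 14 + k] = "AC"[k % 2]
            seq[site.pos - 2] = "G"
    # scrub accidental repeat contexts around sites that must stay clean
    for site in config.planted_sites:
        if site.artifact in {"homopolymer_context", "ssr_context"}:
            continue
        for _ in range(200):
            if _context_is_clean(seq, site.pos, config.genome_length):
                break
            for p in range(max(1, site.pos - 15), min(config.genome_length, site.pos + 15) + 1):
                if p not in planted_positions:
                    seq[p - 1] = rng.choice(BASES)
        else:
            raise ValidationError(
                f"could not scrub repeat context around position {site.pos}"
            )
    genome = {"chr1": GenomeSequence(name="chr1", seq="".join(seq))}
    return genome, genes


def write_fasta(genome: dict[str, GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for contig in genome.values():
            handle.write(f">{contig.name}\n")
            for i in range(0, len(contig.seq), width):
                handle.write(contig.seq[i : i + width] + "\n")


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene in genes:
            gid = gene.gene_id
            handle.write(
                f"{gene.chrom}\tsim\tgene\t{gene.gene_start}\t{gene.gene_end}\t.\t"
                f"{gene.strand}\t.\tID={gid};Name={gid}\n"
            )
            tid = f"{gid}.t1"
            handle.write(
                f"{gene.chrom}\tsim\tmRNA\t{gene.gene_start}\t{gene.gene_end}\t.\t"
                f"{gene.strand}\t.\tID={tid};Parent={gid}\n"
            )
            for i, (start, end) in enumerate(gene.exons, start=1):
                handle.write(
                    f"{gene.chrom}\tsim\texon\t{start}\t{end}\t.\t{gene.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
            for i, (start, end, frame) in enumerate(gene.cds, start=1):
                handle.write(
                    f"{gene.chrom}\tsim\tCDS\t{start}\t{end}\t.\t{gene.strand}\t"
                    f"{frame}\tID={tid}.cds{i};Parent={tid}\n"
                )


def _sam_header(genome: dict[str, GenomeSequence]) -> str:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for contig in genome.values():
        lines.append(f"@SQ\tSN:{contig.name}\tLN:{len(contig.seq)}")
    return "\n".join(lines) + "\n"


def _apply_errors(bases: list[str], rng: np.random.Generator, rate: float) -> None:
    if rate <= 0:
        return
    n_err = rng.binomial(len(bases), rate)
    for idx in rng.choice(len(bases), size=n_err, replace=False):
        current = bases[idx]
        choices = [b for b in BASES if b != current]
        bases[idx] = choices[rng.integers(0, 3)]


def _haplotype(config: SimulationConfig, genome_seq: str, sample_idx: int) -> str:
    hap = list(genome_seq)
    for site in config.planted_sites:
        if site.artifact == "genomic_SNP" and site.rates[sample_idx] > 0:
            hap[site.pos - 1] = site.rna_allele
    return "".join(hap)


def simulate_dna_reads(
    config: SimulationConfig,
    genome: dict[str, GenomeSequence],
    out_dir: str | Path,
) -> dict[str, dict[str, Path]]:
    """Write per-sample DNA SAM and FASTQ (FASTQ includes paralog reads).

    Reads are sampled uniformly to ~``dna_depth`` mean coverage; strand
    alternates read-by-read. Paralog reads come from a 200 bp duplicate
    of the region around each ``paralog_duplication`` site carrying the
    RNA allele, and are written to FASTQ only (unaligned).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contig = genome["chr1"]
    length = len(contig.seq)
    rl = config.read_length
    header = _sam_header(genome)
    paths: dict[str, dict[str, Path]] = {}
    for s_idx, sample in enumerate(config.samples):
        rng = np.random.default_rng([config.rng_seed, 1, s_idx])
        hap = _haplotype(config, contig.seq, s_idx)
        n_reads = math.ceil(config.dna_depth * length / rl)
        starts = np.sort(rng.integers(1, length - rl + 2, size=n_reads))
        sam_path = out_dir / f"{sample}.dna.sam"
        fq_path = out_dir / f"{sample}.dna.fastq"
        with open(sam_path, "w") as sam, open(fq_path, "w") as fq:
            sam.write(header)
            for i, start in enumerate(starts):
                bases = list(hap[start - 1 : start - 1 + rl])
                _apply_errors(bases, rng, config.error_rate)
                seq = "".join(bases)
                strand = "+" if i % 2 == 0 else "-"
                flag = 0 if strand == "+" else 16
                name = f"{sample}_dna_{i}"
                sam.write(
                    f"{name}\t{flag}\tchr1\t{start}\t60\t{rl}M\t*\t0\t0\t"
                    f"{seq}\t{'I' * rl}\n"
                )
                fq_seq = seq if strand == "+" else reverse_complement(seq)
                fq.write(f"@{name}/1\n{fq_seq}\n+\n{'I' * rl}\n")
            # unaligned paralog reads: FASTQ only
            p = 0
            for site in config.planted_sites:
                if site.artifact != "paralog_duplication":
                    continue
                seg_start = site.pos - _PARALOG_FLANK
                segment = list(hap[seg_start - 1 : seg_start - 1 + 2 * _PARALOG_FLANK])
                segment[site.pos - seg_start] = site.rna_allele
                segment = "".join(segment)
                n_para = math.ceil(config.dna_depth * len(segment) / rl)
                for j in range(n_para):
                    off = rng.integers(0, len(segment) - rl + 1)
                    bases = list(segment[off : off + rl])
                    _apply_errors(bases, rng, config.error_rate)
                    seq = "".join(bases)
                    if j % 2 == 1:
                        seq = reverse_complement(seq)
                    fq.write(
                        f"@{sample}_paralog_{p}/1\n{seq}\n+\n{'I' * rl}\n"
                    )
                    p += 1
        paths[sample] = {"sam": sam_path, "fastq": fq_path}
    return paths


def _transcript_blocks(
    exons: Sequence[tuple[int, int]], tstart: int, tlen: int
) -> list[tuple[int, int]]:
    """Genomic (start, length) blocks of transcript interval [tstart, tstart+tlen)."""
    blocks = []
    offset = 0
    remaining = tlen
    for es, ee in exons:
        exon_len = ee - es + 1
        if tstart < offset + exon_len and remaining > 0:
            local = max(tstart - offset, 0)
            take = min(exon_len - local, remaining)
            blocks.append((es + local, take))
            remaining -= take
        offset += exon_len
        if remaining == 0:
            break
    if remaining:
        raise UsageError("transcript interval exceeds transcript length")
    return blocks


def simulate_rna_reads(
    config: SimulationConfig,
    genome: dict[str, GenomeSequence],
    genes: Sequence[GeneModel],
    out_dir: str | Path,
) -> dict[tuple[str, str], Path]:
    """Write splice-aware RNA SAM per (sample, tissue).

    Coverage is exonic only; reads crossing an intron get an N gap in
    the CIGAR. Planted edits are expressed per covering read according
    to their artifact class: Bernoulli(rate) for true edits and
    positional artifacts, one-strand-only for ``strand_artifact``,
    read-end-only for ``extremity_artifact``; ``genomic_SNP`` alleles
    come from the sample haplotype itself.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contig = genome["chr1"]
    rl = config.read_length
    header = _sam_header(genome)
    sites_by_tissue: dict[str, list[PlantedSite]] = {}
    for site in config.planted_sites:
        sites_by_tissue.setdefault(site.tissue, []).append(site)
    paths: dict[tuple[str, str], Path] = {}
    for t_idx, tissue in enumerate(config.tissues):
        tissue_sites = [
            s for s in sites_by_tissue.get(tissue, []) if s.artifact != "genomic_SNP"
        ]
        for s_idx, sample in enumerate(config.samples):
            rng = np.random.default_rng([config.rng_seed, 2, t_idx, s_idx])
            hap = _haplotype(config, contig.seq, s_idx)
            path = out_dir / f"{sample}.{tissue}.rna.sam"
            records = []
            r = 0
            for gene in genes:
                tseq = "".join(hap[es - 1 : ee] for es, ee in gene.exons)
                tlen = len(tseq)
                if tlen < rl:
                    continue
                n_reads = math.ceil(config.rna_depth * tlen / rl)
                tstarts = rng.integers(0, tlen - rl + 1, size=n_reads)
                for tstart in tstarts:
                    blocks = _transcript_blocks(gene.exons, int(tstart), rl)
                    bases = list(tseq[tstart : tstart + rl])
                    strand = "+" if r % 2 == 0 else "-"
                    # genomic position -> read offset for covered sites
                    offset_map = {}
                    read_off = 0
                    for bstart, blen in blocks:
                        for site in tissue_sites:
                            if bstart <= site.pos < bstart + blen:
                                offset_map[site.pos] = read_off + (site.pos - bstart)
                        read_off += blen
                    for site in tissue_sites:
                        off = offset_map.get(site.pos)
                        if off is None:
                            continue
                        rate = site.rates[s_idx]
                        if site.artifact == "strand_artifact":
                            edited = strand == "+"
                        elif site.artifact == "extremity_artifact":
                            edited = min(off, rl - 1 - off) < 10
                        else:
                            edited = bool(rate > 0 and rng.random() < rate)
                        if edited:
                            bases[off] = site.rna_allele
                    _apply_errors(bases, rng, config.error_rate)
                    seq = "".join(bases)
                    cigar_parts = []
                    prev_end = None
                    for bstart, blen in blocks:
                        if prev_end is not None:
                            cigar_parts.append(f"{bstart - prev_end - 1}N")
                        cigar_parts.append(f"{blen}M")
                        prev_end = bstart + blen - 1
                    flag = 0 if strand == "+" else 16
                    records.append(
                        (
                            blocks[0][0],
                            f"{sample}_{tissue}_rna_{r}\t{flag}\tchr1\t{blocks[0][0]}\t60\t"
                            f"{''.join(cigar_parts)}\t*\t0\t0\t{seq}\t{'I' * rl}\n",
                        )
                    )
                    r += 1
            records.sort(key=lambda item: item[0])
            with open(path, "w") as sam:
                sam.write(header)
                for _, line in records:
                    sam.write(line)
            paths[(sample, tissue)] = path
    return paths


def write_truth(config: SimulationConfig, path: str | Path) -> None:
    """Write the planted-truth table consistent with the generated files."""
    with open(path, "w") as handle:
        handle.write("\t".join(TRUTH_COLUMNS) + "\n")
        for site in config.planted_sites:
            if site.artifact == "genomic_SNP":
                n_expected = 0
                detected = "no"
            elif site.artifact in {"strand_artifact", "extremity_artifact"}:
                n_expected = config.n_samples
                detected = "yes"
            else:
                n_expected = sum(1 for r in site.rates if r >= _MIN_RELIABLE_RATE)
                detected = "yes" if n_expected >= 3 else "no"
            handle.write(
                "\t".join(
                    [
                        site.chrom,
                        str(site.pos),
                        site.tissue,
                        site.dna_allele,
                        site.rna_allele,
                        site.artifact or "true_edit",
                        detected,
                        EXPECTED_FLAG[site.artifact],
                        str(n_expected),
                    ]
                )
                + "\n"
            )


def read_truth(path: str | Path) -> list[dict[str, str]]:
    rows = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise ValidationError(f"{path}: unexpected truth-table header")
        for line in handle:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, object]:
    """Generate the full dataset under ``out_dir``; returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, genes = simulate_genome(config)
    fasta = out_dir / "genome.fa"
    gff = out_dir / "genes.gff3"
    truth = out_dir / "truth.tsv"
    write_fasta(genome, fasta)
    write_gff3(genes, gff)
    dna = simulate_dna_reads(config, genome, out_dir)
    rna = simulate_rna_reads(config, genome, genes, out_dir)
    write_truth(config, truth)
    return {
        "genome": fasta,
        "gff3": gff,
        "truth": truth,
        "dna": dna,
        "rna": rna,
        "config": config,
    }
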