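"""Genomic localization and coding consequences of edited sites.

A minimal re-implementation of the localization categories used in the
screen's reporting: coding (missense/synonymous), noncoding exon,
intron, 5 kb gene flanks (upstream/downstream by gene strand) and
intergenic, with nearest-gene naming inside a 10 kb radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .errors import UsageError, ValidationError
from .filters import reverse_complement
from .io_formats import GeneModel, GenomeSequence

#: localization categories from most to least severe
CATEGORY_SEVERITY = (
    "exon_cds_missense",
    "exon_cds_synonymous",
    "exon_noncoding",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)

DEFAULT_FLANK_BP = 5_000
DEFAULT_NAMING_RADIUS = 10_000


@dataclass(frozen=True, slots=True)
class FeatureLocalization:
    """Where a site falls relative to the gene models."""

    category: str
    gene_names: tuple[str, ...]
    distance_bp: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_SEVERITY:
            raise UsageError(f"unknown category {self.category!r}")


def _gene_distance(model: GeneModel, pos: int) -> int:
    if model.contains(pos):
        return 0
    if pos < model.gene_start:
        return model.gene_start - pos
    return pos - model.gene_end


def coding_consequence(
    pos: int,
    gene_model: GeneModel,
    genome: Mapping[str, GenomeSequence],
    rna_allele: str,
) -> str:
    """"missense" or "synonymous" for a site inside a CDS interval.

    The codon is reconstructed from the annotated CDS segments and
    phases on the gene's strand; the edited allele is complemented for
    minus-strand genes before translation.
    """
    if not gene_model.in_cds(pos):
        raise UsageError(
            f"position {pos} is not inside a CDS of {gene_model.gene_id}"
        )
    contig = genome[gene_model.chrom]
    segments = list(gene_model.cds)  # sorted by genomic start
    if gene_model.strand == "-":
        segments = segments[::-1]

    cds_seq_parts = []
    site_index = None
    cum = 0
    phase0 = segments[0][2]
    for start, end, frame in segments:
        expected = (3 - ((cum - phase0) % 3)) % 3 if cum else phase0
        if frame != expected:
            raise ValidationError(
                f"{gene_model.gene_id}: CDS segment ({start},{end}) has frame "
                f"{frame}, expected {expected}"
            )
        seg_seq = contig.region(start, end)
        if gene_model.strand == "-":
            seg_seq = reverse_complement(seg_seq)
            if start <= pos <= end:
                site_index = cum + (end - pos)
        else:
            if start <= pos <= end:
                site_index = cum + (pos - start)
        cds_seq_parts.append(seg_seq)
        cum += end - start + 1
    assert site_index is not None
    cds_seq = "".join(cds_seq_parts)

    coding = cds_seq[phase0:]
    idx = site_index - phase0
    if idx < 0:
        raise ValidationError(
            f"{gene_model.gene_id}: position {pos} precedes the first complete codon"
        )
    codon_start = (idx // 3) * 3
    ref_codon = coding[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        raise ValidationError(
            f"{gene_model.gene_id}: incomplete terminal codon at position {pos}"
        )
    allele = (
        reverse_complement(rna_allele)
        if gene_model.strand == "-"
        else rna_allele
    )
    alt_codon = list(ref_codon)
    alt_codon[idx % 3] = allele
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq("".join(alt_codon)).translate())
    return "synonymous" if ref_aa == alt_aa else "missense"


def localize_site(
    chrom: str,
    pos: int,
    gene_models: Sequence[GeneModel],
    *,
    genome: Mapping[str, GenomeSequence] | None = None,
    rna_allele: str | None = None,
    flank_bp: int = DEFAULT_FLANK_BP,
    naming_radius: int = DEFAULT_NAMING_RADIUS,
) -> FeatureLocalization:
    """Assign exactly one localization category to a site.

    Overlap precedence is exon > intron > flank > intergenic; flank side
    is resolved by gene strand. When several gene models apply, all
    their names are reported and the most severe category wins. Sites
    inside a CDS need ``genome`` and ``rna_allele`` to resolve the
    missense/synonymous sub-category.
    """
    per_gene: list[tuple[str, str]] = []  # (category, gene_id)
    nearest: tuple[int, GeneModel] | None = None
    for model in gene_models:
        if model.chrom != chrom:
            continue
        dist = _gene_distance(model, pos)
        if nearest is None or dist < nearest[0]:
            nearest = (dist, model)
        if model.contains(pos):
            if model.in_exon(pos):
                if model.in_cds(pos):
                    if genome is None or rna_allele is None:
                        raise UsageError(
                            "coding site needs genome and rna_allele to localize"
                        )
                    consequence = coding_consequence(pos, model, genome, rna_allele)
                    per_gene.append((f"exon_cds_{consequence}", model.gene_id))
                else:
                    per_gene.append(("exon_noncoding", model.gene_id))
            else:
                per_gene.append(("intron", model.gene_id))
        elif dist <= flank_bp:
            before_start = pos < model.gene_start
            if (model.strand == "+") == before_start:
                per_gene.append(("upstream", model.gene_id))
            else:
                per_gene.append(("downstream", model.gene_id))

    if per_gene:
        category = min(per_gene, key=lambda cg: CATEGORY_SEVERITY.index(cg[0]))[0]
        names = tuple(dict.fromkeys(g for _, g in per_gene))
        distance = 0 if any(c not in {"upstream", "downstream"} for c, _ in per_gene) \
            else (nearest[0] if nearest else None)
        return FeatureLocalization(
            category=category, gene_names=names, distance_bp=distance
        )

    if nearest is not None and nearest[0] <= naming_radius:
        return FeatureLocalization(
            category="intergenic",
            gene_names=(nearest[1].gene_id,),
            distance_bp=nearest[0],
        )
    return FeatureLocalization(
        category="intergenic",
        gene_names=(),
        distance_bp=nearest[0] if nearest else None,
    )
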