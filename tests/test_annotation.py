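import random

import pytest
from Bio.Seq import Seq

from editscreen.annotation import (
    FeatureLocalization,
    coding_consequence,
    localize_site,
)
from editscreen.errors import UsageError
from editscreen.filters import reverse_complement
from editscreen.io_formats import GeneModel, GenomeSequence


def _genome(seq):
    return {"chr1": GenomeSequence(name="chr1", seq=seq)}


def _plus_gene(start=11, cds_len=30):
    # single-exon gene, CDS = whole exon
    return GeneModel(
        gene_id="g1",
        chrom="chr1",
        strand="+",
        gene_start=start,
        gene_end=start + cds_len - 1,
        exons=((start, start + cds_len - 1),),
        cds=((start, start + cds_len - 1, 0),),
    )


# ---------------------------------------------------------------------------
# coding consequence


def test_att_to_gtt_is_missense():
    # codon 1 of the CDS is ATT (Ile); editing A->G gives GTT (Val)
    seq = "G" * 10 + "ATTCCCGGGTTTAAACCCGGGTTTAAACCC" + "G" * 10
    gene = _plus_gene()
    assert coding_consequence(11, gene, _genome(seq), "G") == "missense"


def test_wobble_position_synonymous():
    # CTT -> CTC is Leu -> Leu
    seq = "G" * 10 + "CTTCCCGGGTTTAAACCCGGGTTTAAACCC" + "G" * 10
    gene = _plus_gene()
    assert coding_consequence(13, gene, _genome(seq), "C") == "synonymous"


def test_minus_strand_consequence_on_transcript_strand():
    # minus-strand CDS; genomic T->C at the codon's genomic position equals
    # transcript A->G
    transcript_cds = "ATGGCTAAA"  # M A K
    genomic = reverse_complement(transcript_cds)
    seq = "G" * 10 + genomic + "G" * 10
    gene = GeneModel(
        gene_id="gm",
        chrom="chr1",
        strand="-",
        gene_start=11,
        gene_end=19,
        exons=((11, 19),),
        cds=((11, 19, 0),),
    )
    # transcript position 4 (codon 2 pos 1: G of GCT) is genomic position 16,
    # genomic base C; editing genomic C->T equals transcript G->A: GCT->ACT
    assert seq[15] == "C"
    assert coding_consequence(16, gene, _genome(seq), "T") == "missense"


def test_consequence_outside_cds_is_usage_error():
    seq = "G" * 60
    gene = _plus_gene()
    with pytest.raises(UsageError):
        coding_consequence(5, gene, _genome(seq), "A")


def test_consequence_agrees_with_full_cds_translation_oracle():
    rng = random.Random(19)
    for _ in range(150):
        n_codons = rng.randint(4, 12)
        cds = "ATG" + "".join(
            rng.choice("ACGT") for _ in range(3 * (n_codons - 1))
        )
        strand = rng.choice("+-")
        genomic = cds if strand == "+" else reverse_complement(cds)
        pad = 10
        seq = "G" * pad + genomic + "G" * pad
        start = pad + 1
        end = pad + len(cds)
        gene = GeneModel(
            gene_id="g",
            chrom="chr1",
            strand=strand,
            gene_start=start,
            gene_end=end,
            exons=((start, end),),
            cds=((start, end, 0),),
        )
        pos = rng.randint(start, end)
        ref_base = seq[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref_base])
        got = coding_consequence(pos, gene, _genome(seq), alt)
        # oracle: translate the full mutated CDS
        mutated = seq[: pos - 1] + alt + seq[pos:]
        mutated_cds = (
            mutated[start - 1 : end]
            if strand == "+"
            else reverse_complement(mutated[start - 1 : end])
        )
        ref_protein = str(Seq(cds).translate())
        alt_protein = str(Seq(mutated_cds).translate())
        expected = "synonymous" if ref_protein == alt_protein else "missense"
        assert got == expected


# ---------------------------------------------------------------------------
# localization


@pytest.fixture()
def annotated_world():
    rng = random.Random(29)
    seq = "".join(rng.choice("ACGT") for _ in range(40_000))
    # plant a clean CDS at 20001..20030 so consequence calls are deterministic
    seq = seq[:20000] + "ATGGCTAAATTTCCCGGGAAACCCTTTGGG" + seq[20030:]
    gene = GeneModel(
        gene_id="gene_plus",
        chrom="chr1",
        strand="+",
        gene_start=20001,
        gene_end=21000,
        exons=((20001, 20100), (20501, 21000)),
        cds=((20001, 20030, 0),),
    )
    return _genome(seq), [gene]


def test_localize_cds_missense(annotated_world):
    genome, genes = annotated_world
    # pos 20004 is codon 2 position 1 (GCT): G->A gives ACT, missense
    loc = localize_site("chr1", 20004, genes, genome=genome, rna_allele="A")
    assert loc.category == "exon_cds_missense"
    assert loc.gene_names == ("gene_plus",)


def test_localize_noncoding_exon(annotated_world):
    genome, genes = annotated_world
    loc = localize_site("chr1", 20050, genes, genome=genome, rna_allele="A")
    assert loc.category == "exon_noncoding"


def test_localize_intron(annotated_world):
    genome, genes = annotated_world
    loc = localize_site("chr1", 20300, genes)
    assert loc.category == "intron"


def test_localize_downstream_of_plus_gene(annotated_world):
    genome, genes = annotated_world
    loc = localize_site("chr1", 24000, genes)  # 3 kb past gene end
    assert loc.category == "downstream"
    assert loc.distance_bp == 3000


def test_localize_upstream_of_plus_gene(annotated_world):
    genome, genes = annotated_world
    loc = localize_site("chr1", 16001, genes)  # 4 kb before gene start
    assert loc.category == "upstream"


def test_localize_intergenic_with_naming_radius(annotated_world):
    genome, genes = annotated_world
    loc = localize_site("chr1", 12001, genes)  # 8 kb away: beyond flank, within 10 kb
    assert loc.category == "intergenic"
    assert loc.gene_names == ("gene_plus",)
    assert loc.distance_bp == 8000


def test_localize_far_intergenic_nameless(annotated_world):
    genome, genes = annotated_world
    loc = localize_site("chr1", 1000, genes)
    assert loc.category == "intergenic"
    assert loc.gene_names == ()


def test_flank_side_respects_minus_strand(annotated_world):
    genome, genes = annotated_world
    minus = GeneModel(
        gene_id="gene_minus",
        chrom="chr1",
        strand="-",
        gene_start=30001,
        gene_end=31000,
        exons=((30001, 31000),),
    )
    loc = localize_site("chr1", 32000, [minus])
    assert loc.category == "upstream"
    loc = localize_site("chr1", 29000, [minus])
    assert loc.category == "downstream"


def test_multi_gene_overlap_reports_all_names_and_most_severe(annotated_world):
    genome, genes = annotated_world
    second = GeneModel(
        gene_id="gene_b",
        chrom="chr1",
        strand="+",
        gene_start=20001,
        gene_end=20400,
        exons=((20001, 20040), (20200, 20400)),
    )
    loc = localize_site(
        "chr1", 20004, genes + [second], genome=genome, rna_allele="A"
    )
    assert set(loc.gene_names) == {"gene_plus", "gene_b"}
    assert loc.category == "exon_cds_missense"


def test_every_site_gets_exactly_one_category(annotated_world):
    genome, genes = annotated_world
    rng = random.Random(37)
    for _ in range(200):
        pos = rng.randint(1, 40_000)
        loc = localize_site("chr1", pos, genes, genome=genome, rna_allele="A")
        assert isinstance(loc, FeatureLocalization)
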