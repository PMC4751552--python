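"""Shared fixtures: small hand-built objects plus one session-scoped
simulated cohort that the pipeline-level tests share."""

from __future__ import annotations

from pathlib import Path

import pytest

from editscreen.io_formats import AlignedObservation, GeneModel, GenomeSequence
from editscreen.pileup import AlleleCounts, CandidateSite, PileupColumn
from editscreen.pipeline import PipelineParams, run_pipeline
from editscreen.simulate import default_config, read_truth, simulate_dataset

DEFAULT_SEED = 101


def make_obs(
    pos: int,
    base: str,
    *,
    chrom: str = "chr1",
    sample: str = "s1",
    source: str = "RNA",
    strand: str = "+",
    read_offset: int = 50,
    read_length: int = 101,
    read_id: str = "r0",
) -> AlignedObservation:
    return AlignedObservation(
        sample=sample,
        source=source,
        chrom=chrom,
        pos=pos,
        base=base,
        strand=strand,
        read_offset=read_offset,
        read_length=read_length,
        read_id=read_id,
    )


def make_column(
    obs_specs,
    *,
    pos: int = 100,
    source: str = "RNA",
    chrom: str = "chr1",
    sample: str = "s1",
    ref_base: str = "A",
) -> PileupColumn:
    """obs_specs: iterable of (base, strand) or (base, strand, offset, length, read_id)."""
    obs = []
    for i, spec in enumerate(obs_specs):
        base, strand = spec[0], spec[1]
        offset = spec[2] if len(spec) > 2 else 50
        length = spec[3] if len(spec) > 3 else 101
        read_id = spec[4] if len(spec) > 4 else f"r{i}"
        obs.append(
            make_obs(
                pos,
                base,
                chrom=chrom,
                sample=sample,
                source=source,
                strand=strand,
                read_offset=offset,
                read_length=length,
                read_id=read_id,
            )
        )
    return PileupColumn(
        chrom=chrom, pos=pos, ref_base=ref_base, sample=sample, source=source, obs=obs
    )


def make_candidate(
    *,
    pos: int = 100,
    dna_allele: str = "A",
    rna_allele: str = "G",
    rna_obs_specs=None,
    chrom: str = "chr1",
    sample: str = "s1",
    tissue: str = "liver",
) -> CandidateSite:
    if rna_obs_specs is None:
        rna_obs_specs = [(dna_allele, "+")] * 9 + [(dna_allele, "-")] * 9
        rna_obs_specs += [(rna_allele, "+")] * 6 + [(rna_allele, "-")] * 6
    rna_col = make_column(rna_obs_specs, pos=pos, chrom=chrom, sample=sample)
    dna_specs = [(dna_allele, "+")] * 10 + [(dna_allele, "-")] * 10
    dna_col = make_column(dna_specs, pos=pos, source="DNA", chrom=chrom, sample=sample)
    return CandidateSite(
        sample=sample,
        tissue=tissue,
        chrom=chrom,
        pos=pos,
        dna_allele=dna_allele,
        rna_allele=rna_allele,
        dna_counts=dna_col.counts(),
        rna_counts=rna_col.counts(),
    )


@pytest.fixture(scope="session")
def sim_cohort(tmp_path_factory):
    """Default synthetic cohort: dataset files, pipeline result and truth."""
    data_dir = tmp_path_factory.mktemp("sim_data")
    out_dir = tmp_path_factory.mktemp("sim_out")
    config = default_config(seed=DEFAULT_SEED)
    files = simulate_dataset(config, data_dir)
    result = run_pipeline(data_dir, out_dir, PipelineParams())
    truth = {int(r["pos"]): r for r in read_truth(files["truth"])}
    return {
        "config": config,
        "files": files,
        "data_dir": Path(data_dir),
        "out_dir": Path(out_dir),
        "result": result,
        "truth": truth,
    }


@pytest.fixture()
def toy_genome():
    seq = "ACGTTGCATGCAATGCGTAGCTAGCATCGATCGTACGATCGATTGCAGCT" * 4
    return {"chr1": GenomeSequence(name="chr1", seq=seq)}


@pytest.fixture()
def two_exon_gene():
    return GeneModel(
        gene_id="g1",
        chrom="chr1",
        strand="+",
        gene_start=10,
        gene_end=170,
        exons=((10, 60), (120, 170)),
        cds=((20, 60, 0), (120, 150, 1)),
    )
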