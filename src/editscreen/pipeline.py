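"""End-to-end orchestration: detection → artifact filters → replication →
annotation, with per-filter attrition reporting and the published-table
consistency checks.

Attrition is counted at per-sample-candidate granularity so that
``unbiased = initial − |union of flagged|`` holds exactly; fractions are
reported against the initial candidate pool.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .annotation import localize_site
from .errors import UsageError
from .filters import FILTER_NAMES, BiasFlags, FilterContext, find_ssrs
from .io_formats import (
    GeneModel,
    GenomeSequence,
    SiteRecord,
    extract_observations,
    load_table2_fixture,
    read_fasta,
    read_fastq,
    read_gff3,
    read_site_table,
    write_site_table,
)
from .pileup import CandidateSite, PileupColumn, detect_candidates
from .replication import (
    EditingEvent,
    classify_substitution,
    cluster_span,
    deduplicate_union,
    filter_by_min_replicates,
    merge_candidates,
    substitution_spectrum,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class PipelineParams:
    """Tunable thresholds; defaults mirror the screening protocol."""

    min_cov: int = 15
    min_reps: int = 3
    min_alt_reads: int = 2
    max_discordant_frac: float = 0.0
    end_window: int = 10
    max_end_frac: float = 0.5
    delta_max: float = 0.5
    flank_bp: int = 5_000
    naming_radius: int = 10_000
    consensus_length: int = 40
    max_pileup_depth: int = 10_000


@dataclass(slots=True)
class AttritionReport:
    """Stage counts for one tissue, per sample-candidate."""

    tissue: str
    initial: int
    flagged: dict[str, int]
    flagged_any: int
    unbiased: int
    events_by_min_reps: dict[int, int]

    def fractions(self) -> dict[str, float]:
        if self.initial == 0:
            return {name: 0.0 for name in FILTER_NAMES}
        return {name: self.flagged[name] / self.initial for name in FILTER_NAMES}

    def as_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "initial_candidates": self.initial,
            "flagged_counts": dict(self.flagged),
            "flagged_fractions": self.fractions(),
            "flagged_any": self.flagged_any,
            "unbiased": self.unbiased,
            "events_by_min_reps": {str(k): v for k, v in self.events_by_min_reps.items()},
        }


@dataclass(slots=True)
class PipelineResult:
    candidates: list[CandidateSite]
    flags: dict[tuple, BiasFlags]
    events_by_tissue: dict[str, list[EditingEvent]]
    attrition: dict[str, AttritionReport]
    site_records: dict[str, list[SiteRecord]]


def _candidate_key(c: CandidateSite) -> tuple:
    return (c.sample, c.tissue, c.chrom, c.pos, c.dna_allele, c.rna_allele)


def discover_dataset(data_dir: str | Path) -> dict:
    """Map a simulated-dataset directory by its naming convention."""
    data_dir = Path(data_dir)
    fasta = data_dir / "genome.fa"
    gff = data_dir / "genes.gff3"
    for path in (fasta, gff):
        if not path.exists():
            raise UsageError(f"missing input file: {path}")
    samples = sorted(p.name.split(".")[0] for p in data_dir.glob("*.dna.sam"))
    if not samples:
        raise UsageError(f"no *.dna.sam files under {data_dir}")
    rna: dict[tuple[str, str], Path] = {}
    for path in data_dir.glob("*.rna.sam"):
        sample, tissue, _, _ = path.name.split(".")
        rna[(sample, tissue)] = path
    tissues = sorted({t for _, t in rna})
    return {
        "genome": fasta,
        "gff3": gff,
        "samples": samples,
        "tissues": tissues,
        "dna_sam": {s: data_dir / f"{s}.dna.sam" for s in samples},
        "dna_fastq": {s: data_dir / f"{s}.dna.fastq" for s in samples},
        "rna_sam": rna,
    }


def detect_sample_candidates(
    dna_index: Mapping[tuple[str, int], list],
    rna_index: Mapping[tuple[str, int], list],
    genome: Mapping[str, GenomeSequence],
    sample: str,
    tissue: str,
    params: PipelineParams,
) -> list[CandidateSite]:
    """Run the detection criteria over every RNA-covered position."""
    candidates = []
    for (chrom, pos), rna_obs in sorted(rna_index.items()):
        if len(rna_obs) < params.min_cov:
            continue
        dna_obs = dna_index.get((chrom, pos), [])
        if len(dna_obs) < params.min_cov:
            continue
        ref_base = genome[chrom].base_at(pos)
        dna_col = PileupColumn(
            chrom=chrom, pos=pos, ref_base=ref_base, sample=sample,
            source="DNA", obs=dna_obs[: params.max_pileup_depth],
        )
        rna_col = PileupColumn(
            chrom=chrom, pos=pos, ref_base=ref_base, sample=sample,
            source="RNA", obs=rna_obs[: params.max_pileup_depth],
        )
        cand = detect_candidates(
            dna_col,
            rna_col,
            params.min_cov,
            tissue=tissue,
            max_discordant_frac=params.max_discordant_frac,
            min_alt_reads=params.min_alt_reads,
        )
        if cand is not None:
            candidates.append(cand)
    return candidates


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Run detection, the six filters, replication and annotation.

    ``data_dir`` follows the simulator's naming convention; every
    intermediate table is serialized under ``out_dir``.
    """
    dataset = discover_dataset(data_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome = {g.name: g for g in read_fasta(dataset["genome"])}
    gene_models = read_gff3(dataset["gff3"])
    ssrs = []
    for name, contig in genome.items():
        ssrs.extend(find_ssrs(contig.seq, chrom=name))

    all_candidates: list[CandidateSite] = []
    all_flags: dict[tuple, BiasFlags] = {}
    log_lines: list[str] = []

    for sample in dataset["samples"]:
        dna_index: dict[tuple[str, int], list] = defaultdict(list)
        for obs in extract_observations(dataset["dna_sam"][sample], sample, "DNA"):
            dna_index[(obs.chrom, obs.pos)].append(obs)
        dna_reads = list(read_fastq(dataset["dna_fastq"][sample]))
        for tissue in dataset["tissues"]:
            rna_path = dataset["rna_sam"].get((sample, tissue))
            if rna_path is None:
                continue
            rna_index: dict[tuple[str, int], list] = defaultdict(list)
            for obs in extract_observations(rna_path, sample, "RNA"):
                rna_index[(obs.chrom, obs.pos)].append(obs)
            candidates = detect_sample_candidates(
                dna_index, rna_index, genome, sample, tissue, params
            )
            context = FilterContext(
                genome=genome,
                gene_models=gene_models,
                rna_observations=rna_index,
                dna_reads=dna_reads,
                ssrs=ssrs,
                end_window=params.end_window,
                max_end_frac=params.max_end_frac,
                delta_max=params.delta_max,
                consensus_length=params.consensus_length,
            )
            for cand in candidates:
                flags = apply_filters_logged(cand, context, log_lines)
                all_flags[_candidate_key(cand)] = flags
            all_candidates.extend(candidates)

    write_candidates_tsv(all_candidates, out_dir / "candidates.tsv")
    write_flags_tsv(all_candidates, all_flags, out_dir / "flags.tsv")

    # replication + spectrum per tissue
    events_by_tissue: dict[str, list[EditingEvent]] = {}
    attrition: dict[str, AttritionReport] = {}
    site_records: dict[str, list[SiteRecord]] = {}
    spectrum_rows = []
    for tissue in dataset["tissues"]:
        tissue_cands = [c for c in all_candidates if c.tissue == tissue]
        unbiased = [
            c for c in tissue_cands if all_flags[_candidate_key(c)].unbiased
        ]
        merged = merge_candidates(unbiased, tissue)
        events_by_min_reps = {}
        for n in (1, 2, 3):
            kept = filter_by_min_replicates(merged, n)
            events_by_min_reps[n] = len(kept)
            fractions, tv = substitution_spectrum(kept)
            for label, frac in fractions.items():
                spectrum_rows.append(
                    {"tissue": tissue, "min_reps": n, "class": label, "fraction": frac}
                )
            spectrum_rows.append(
                {"tissue": tissue, "min_reps": n, "class": "transversions", "fraction": tv}
            )
        final = filter_by_min_replicates(merged, params.min_reps)
        events_by_tissue[tissue] = final
        flagged_counts = {
            name: sum(
                1
                for c in tissue_cands
                if getattr(all_flags[_candidate_key(c)], name)
            )
            for name in FILTER_NAMES
        }
        attrition[tissue] = AttritionReport(
            tissue=tissue,
            initial=len(tissue_cands),
            flagged=flagged_counts,
            flagged_any=len(tissue_cands) - len(unbiased),
            unbiased=len(unbiased),
            events_by_min_reps=events_by_min_reps,
        )
        records = []
        for event in final:
            loc = localize_site(
                event.chrom,
                event.pos,
                gene_models,
                genome=genome,
                rna_allele=event.rna_allele,
            )
            records.append(
                SiteRecord(
                    tissue=tissue,
                    chrom=event.chrom,
                    pos=event.pos,
                    dna_allele=event.dna_allele,
                    rna_allele=event.rna_allele,
                    canonical=event.canonical,
                    replicates=event.n_replicates,
                    gene_names=loc.gene_names,
                    localization=loc.category,
                )
            )
        site_records[tissue] = records
        write_site_table(records, out_dir / f"events_{tissue}.tsv")

    unique, common = deduplicate_union(events_by_tissue)
    with open(out_dir / "unique_sites.tsv", "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "dna_allele", "rna_allele", "shared"])
        for key in unique:
            writer.writerow(list(key) + ["yes" if key in common else "no"])

    with open(out_dir / "spectrum.tsv", "w", newline="") as handle:
        writer = csv.DictWriter(
            handle,
            fieldnames=["tissue", "min_reps", "class", "fraction"],
            delimiter="\t",
            lineterminator="\n",
        )
        writer.writeheader()
        writer.writerows(spectrum_rows)

    with open(out_dir / "attrition.json", "w") as handle:
        json.dump(
            {tissue: report.as_dict() for tissue, report in attrition.items()},
            handle,
            indent=2,
        )
        handle.write("\n")

    with open(out_dir / "pipeline.log", "w") as handle:
        handle.write("\n".join(log_lines) + ("\n" if log_lines else ""))

    return PipelineResult(
        candidates=all_candidates,
        flags=all_flags,
        events_by_tissue=events_by_tissue,
        attrition=attrition,
        site_records=site_records,
    )


def apply_filters_logged(
    candidate: CandidateSite, context: FilterContext, log_lines: list[str]
) -> BiasFlags:
    from .filters import apply_filters

    flags = apply_filters(candidate, context)
    if not flags.unbiased:
        log_lines.append(
            f"dropped {candidate.sample}/{candidate.tissue} "
            f"{candidate.chrom}:{candidate.pos} "
            f"{candidate.dna_allele}>{candidate.rna_allele} "
            f"flags={','.join(flags.flagged_filters())}"
        )
    return flags


def write_candidates_tsv(candidates: Sequence[CandidateSite], path: Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "sample",
                "tissue",
                "chrom",
                "pos",
                "dna_allele",
                "rna_allele",
                "dna_depth",
                "rna_depth",
                "rna_alt_count",
            ]
        )
        for c in candidates:
            writer.writerow(
                [
                    c.sample,
                    c.tissue,
                    c.chrom,
                    c.pos,
                    c.dna_allele,
                    c.rna_allele,
                    c.dna_counts.depth,
                    c.rna_counts.depth,
                    c.rna_counts.count(c.rna_allele),
                ]
            )


def write_flags_tsv(
    candidates: Sequence[CandidateSite],
    flags: Mapping[tuple, BiasFlags],
    path: Path,
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["sample", "tissue", "chrom", "pos", "dna_allele", "rna_allele"]
            + list(FILTER_NAMES)
            + ["unbiased"]
        )
        for c in candidates:
            f = flags[_candidate_key(c)]
            writer.writerow(
                [c.sample, c.tissue, c.chrom, c.pos, c.dna_allele, c.rna_allele]
                + [int(getattr(f, name)) for name in FILTER_NAMES]
                + [int(f.unbiased)]
            )


# ---------------------------------------------------------------------------
# published-table consistency checks


def _records_to_events(records: Sequence[SiteRecord]) -> dict[str, list[EditingEvent]]:
    by_tissue: dict[str, list[EditingEvent]] = defaultdict(list)
    for rec in records:
        by_tissue[rec.tissue].append(
            EditingEvent(
                tissue=rec.tissue,
                chrom=rec.chrom,
                pos=rec.pos,
                dna_allele=rec.dna_allele,
                rna_allele=rec.rna_allele,
                samples_detected=frozenset(
                    f"r{i + 1}" for i in range(rec.replicates)
                ),
            )
        )
    return dict(by_tissue)


def cluster_positions(positions: Sequence[int], max_gap: int = 2000) -> list[list[int]]:
    """Single-linkage clusters of positions with consecutive gaps <= max_gap."""
    clusters: list[list[int]] = []
    for pos in sorted(positions):
        if clusters and pos - clusters[-1][-1] <= max_gap:
            clusters[-1].append(pos)
        else:
            clusters.append([pos])
    return clusters


def compute_table2_stats(records: Sequence[SiteRecord]) -> dict[str, int]:
    """Recompute the derived tallies and cluster spans of the site table."""
    events_by_tissue = _records_to_events(records)
    unique, common = deduplicate_union(events_by_tissue)
    canonical_unique = [
        key for key in unique
        if classify_substitution(key[2], key[3]).is_canonical_collapsed
    ]
    retained = {
        tissue: filter_by_min_replicates(events, 3)
        for tissue, events in events_by_tissue.items()
    }

    liver_mpzl1 = [
        rec.pos
        for rec in records
        if rec.tissue == "Liver"
        and rec.chrom == "1"
        and {"MPZL1", "BRP44"} <= set(rec.gene_names)
    ]
    wat_chr12 = [
        rec.pos for rec in records if rec.tissue == "WAT" and rec.chrom == "12"
    ]
    wat_chr1 = [
        rec.pos for rec in records if rec.tissue == "WAT" and rec.chrom == "1"
    ]
    nox4_cluster = max(cluster_positions(wat_chr1), key=len)

    return {
        "unique_canonical_sites": len(canonical_unique),
        "unique_events": len(unique),
        "common_to_both_tissues": len(common),
        "wat_retained": len(retained.get("WAT", [])),
        "liver_retained": len(retained.get("Liver", [])),
        "canonical_chromosomes": len({key[0] for key in canonical_unique}),
        "mpzl1_cluster_span": cluster_span(liver_mpzl1),
        "flnb_cluster_span": cluster_span(wat_chr12),
        "nox4_cluster_span": cluster_span(nox4_cluster),
    }


#: published values the fixture-derived tallies are checked against
TABLE2_EXPECTED = {
    "unique_canonical_sites": 25,
    "unique_events": 27,
    "common_to_both_tissues": 3,
    "wat_retained": 19,
    "liver_retained": 11,
    "canonical_chromosomes": 13,
    "mpzl1_cluster_span": 26,
    "flnb_cluster_span": 951,
    "nox4_cluster_span": 1391,
}


def table2_check(fixture_path: str | Path | None = None) -> dict[str, dict]:
    """Compare the recomputed fixture tallies with the published values."""
    records = (
        read_site_table(fixture_path) if fixture_path else load_table2_fixture()
    )
    stats = compute_table2_stats(records)
    return {
        name: {
            "value": stats[name],
            "expected": TABLE2_EXPECTED[name],
            "pass": stats[name] == TABLE2_EXPECTED[name],
        }
        for name in TABLE2_EXPECTED
    }
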