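"""Per-position pileups and the candidate-detection criteria.

A candidate DNA→RNA difference is called by explicit allele counting:
the genomic DNA must be strictly homozygous (every read supporting one
allele unless a discordance tolerance is configured), the RNA must
support exactly one alternative allele (triallelic sites are excluded),
and both sources must reach the coverage floor.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import UsageError
from .io_formats import AlignedObservation

BASES = ("A", "C", "G", "T")

#: defaults mirroring the screening protocol
MIN_COVERAGE = 15
MAX_PILEUP_DEPTH = 10_000
MIN_ALT_READS = 2


@dataclass(frozen=True, slots=True)
class AlleleCounts:
    """Base counts at one position, split by alignment strand.

    N bases never count as allele support and are excluded entirely.
    """

    forward: Mapping[str, int]
    reverse: Mapping[str, int]

    @classmethod
    def from_observations(cls, obs: Iterable[AlignedObservation]) -> "AlleleCounts":
        fwd: dict[str, int] = {b: 0 for b in BASES}
        rev: dict[str, int] = {b: 0 for b in BASES}
        for o in obs:
            if o.base not in fwd:
                continue  # N or ambiguity code: no allele support
            (fwd if o.strand == "+" else rev)[o.base] += 1
        return cls(forward=fwd, reverse=rev)

    def count(self, base: str) -> int:
        return self.forward.get(base, 0) + self.reverse.get(base, 0)

    @property
    def depth(self) -> int:
        return sum(self.forward.values()) + sum(self.reverse.values())

    @property
    def forward_depth(self) -> int:
        return sum(self.forward.values())

    @property
    def reverse_depth(self) -> int:
        return sum(self.reverse.values())

    def as_dict(self) -> dict[str, int]:
        return {b: self.count(b) for b in BASES}


@dataclass(slots=True)
class PileupColumn:
    """All read-base observations at one position for one sample/source."""

    chrom: str
    pos: int
    ref_base: str
    sample: str
    source: str
    obs: list[AlignedObservation]

    def __post_init__(self) -> None:
        for o in self.obs:
            if (o.chrom, o.pos, o.sample, o.source) != (
                self.chrom,
                self.pos,
                self.sample,
                self.source,
            ):
                raise UsageError(
                    f"observation {o.read_id} at {o.chrom}:{o.pos} does not "
                    f"belong to column {self.chrom}:{self.pos} "
                    f"({self.sample}/{self.source})"
                )

    @property
    def depth(self) -> int:
        return len(self.obs)

    def counts(self) -> AlleleCounts:
        return AlleleCounts.from_observations(self.obs)


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """Result of the strict counting genotyper on a DNA column."""

    allele: str | None
    maf: float
    is_homozygous: bool


@dataclass(frozen=True, slots=True)
class CandidateSite:
    """A per-sample DNA→RNA difference passing the detection criteria."""

    sample: str
    tissue: str
    chrom: str
    pos: int
    dna_allele: str
    rna_allele: str
    dna_counts: AlleleCounts
    rna_counts: AlleleCounts

    def __post_init__(self) -> None:
        if self.dna_allele == self.rna_allele:
            raise UsageError("candidate with identical DNA and RNA alleles")


def build_pileup(
    observations: Iterable[AlignedObservation],
    chrom: str,
    pos: int,
    *,
    ref_base: str = "N",
    sample: str | None = None,
    source: str | None = None,
    max_depth: int = MAX_PILEUP_DEPTH,
) -> PileupColumn:
    """Collect the observations overlapping (chrom, pos) into a column.

    Deletions and splice gaps contribute no observation by construction
    (``extract_observations`` only emits aligned M/=/X bases). Depth is
    capped at ``max_depth`` by truncating in input order.
    """
    selected = []
    for o in observations:
        if o.chrom == chrom and o.pos == pos:
            if sample is None:
                sample = o.sample
            if source is None:
                source = o.source
            selected.append(o)
            if len(selected) >= max_depth:
                break
    if sample is None or source is None:
        raise UsageError(
            "empty pileup needs explicit sample= and source= to build a column"
        )
    return PileupColumn(
        chrom=chrom, pos=pos, ref_base=ref_base, sample=sample, source=source,
        obs=selected,
    )


def group_by_position(
    observations: Iterable[AlignedObservation],
) -> dict[tuple[str, int], list[AlignedObservation]]:
    """Index an observation stream by (chrom, pos)."""
    index: dict[tuple[str, int], list[AlignedObservation]] = defaultdict(list)
    for o in observations:
        index[(o.chrom, o.pos)].append(o)
    return dict(index)


def call_dna_genotype(
    column: PileupColumn, max_discordant_frac: float = 0.0
) -> GenotypeCall:
    """Call the genomic genotype by strict allele counting.

    Homozygous iff the majority allele's frequency is at least
    ``1 - max_discordant_frac``; the default 0.0 demands that every read
    support a single allele. Either the reference or the alternative
    allele may be the homozygous one.
    """
    if column.source != "DNA":
        raise UsageError("call_dna_genotype expects a DNA column")
    counts = column.counts()
    depth = counts.depth
    if depth == 0:
        return GenotypeCall(allele=None, maf=0.0, is_homozygous=False)
    major = max(BASES, key=counts.count)
    maf = counts.count(major) / depth
    return GenotypeCall(
        allele=major,
        maf=maf,
        is_homozygous=maf >= 1.0 - max_discordant_frac,
    )


def call_rna_alleles(
    column: PileupColumn,
    min_alt_reads: int = MIN_ALT_READS,
    min_alt_frac: float = 0.0,
) -> set[str]:
    """Bases supported by the RNA column (count and fraction floors)."""
    if column.source != "RNA":
        raise UsageError("call_rna_alleles expects an RNA column")
    counts = column.counts()
    depth = counts.depth
    if depth == 0:
        return set()
    return {
        b
        for b in BASES
        if counts.count(b) >= min_alt_reads and counts.count(b) / depth >= min_alt_frac
    }


def detect_candidates(
    dna_column: PileupColumn,
    rna_column: PileupColumn,
    min_cov: int = MIN_COVERAGE,
    *,
    tissue: str = "",
    max_discordant_frac: float = 0.0,
    min_alt_reads: int = MIN_ALT_READS,
    min_alt_frac: float = 0.0,
) -> CandidateSite | None:
    """Apply the per-sample detection criteria to a matched column pair.

    Returns a candidate iff the DNA is homozygous for allele A, the RNA
    supports exactly {A, B} or {B} with B ≠ A (anything else, including
    triallelic support, is rejected), and both depths reach ``min_cov``.
    """
    if (dna_column.chrom, dna_column.pos) != (rna_column.chrom, rna_column.pos):
        raise UsageError(
            f"mismatched coordinates: DNA {dna_column.chrom}:{dna_column.pos} "
            f"vs RNA {rna_column.chrom}:{rna_column.pos}"
        )
    if dna_column.sample != rna_column.sample:
        raise UsageError("DNA and RNA columns must come from the same sample")
    dna_counts = dna_column.counts()
    rna_counts = rna_column.counts()
    if dna_counts.depth < min_cov or rna_counts.depth < min_cov:
        return None
    genotype = call_dna_genotype(dna_column, max_discordant_frac)
    if not genotype.is_homozygous or genotype.allele is None:
        return None
    supported = call_rna_alleles(rna_column, min_alt_reads, min_alt_frac)
    alt = supported - {genotype.allele}
    if len(alt) != 1 or len(supported) > 2:
        return None
    rna_allele = alt.pop()
    return CandidateSite(
        sample=dna_column.sample,
        tissue=tissue,
        chrom=dna_column.chrom,
        pos=dna_column.pos,
        dna_allele=genotype.allele,
        rna_allele=rna_allele,
        dna_counts=dna_counts,
        rna_counts=rna_counts,
    )
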