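"""Cross-sample merging, biological-replication filtering and the
12-class substitution spectrum with canonical collapsing.

Because the sequencing libraries are not strand-specific, the
complements of the two canonical substitution classes (A→G for
ADAR-mediated and C→T for APOBEC-mediated editing) are themselves
treated as canonical, i.e. the canonical set is {A→G, T→C, C→T, G→A}.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import UsageError
from .pileup import BASES, CandidateSite

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})
CANONICAL = frozenset({("A", "G"), ("T", "C"), ("C", "T"), ("G", "A")})

#: the 12 ordered substitution classes, canonical ones first
ALL_CLASSES: tuple[tuple[str, str], ...] = (
    ("A", "G"),
    ("T", "C"),
    ("C", "T"),
    ("G", "A"),
    ("A", "C"),
    ("A", "T"),
    ("C", "A"),
    ("C", "G"),
    ("G", "C"),
    ("G", "T"),
    ("T", "A"),
    ("T", "G"),
)


@dataclass(frozen=True, slots=True)
class SubstitutionClass:
    """One of the 12 ordered DNA→RNA base substitutions."""

    dna_allele: str
    rna_allele: str

    def __post_init__(self) -> None:
        if self.dna_allele not in BASES or self.rna_allele not in BASES:
            raise UsageError(
                f"invalid substitution {self.dna_allele}->{self.rna_allele}"
            )
        if self.dna_allele == self.rna_allele:
            raise UsageError("substitution requires two distinct bases")

    @property
    def label(self) -> str:
        return f"{self.dna_allele}>{self.rna_allele}"

    @property
    def is_transition(self) -> bool:
        return (self.dna_allele, self.rna_allele) in TRANSITIONS

    @property
    def is_canonical_collapsed(self) -> bool:
        return (self.dna_allele, self.rna_allele) in CANONICAL


@dataclass(frozen=True, slots=True)
class EditingEvent:
    """A per-tissue merged editing site with replicate support."""

    tissue: str
    chrom: str
    pos: int
    dna_allele: str
    rna_allele: str
    samples_detected: frozenset[str]

    def __post_init__(self) -> None:
        if not self.samples_detected:
            raise UsageError("an event needs at least one supporting sample")

    @property
    def n_replicates(self) -> int:
        return len(self.samples_detected)

    @property
    def substitution(self) -> SubstitutionClass:
        return SubstitutionClass(self.dna_allele, self.rna_allele)

    @property
    def canonical(self) -> bool:
        return self.substitution.is_canonical_collapsed

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.dna_allele, self.rna_allele)


def classify_substitution(dna_allele: str, rna_allele: str) -> SubstitutionClass:
    """Classify a DNA→RNA base change into one of the 12 classes."""
    return SubstitutionClass(dna_allele, rna_allele)


def collapse_complement(cls: SubstitutionClass) -> SubstitutionClass:
    """Map X→Y to complement(X)→complement(Y); an involution."""
    return SubstitutionClass(
        _COMPLEMENT[cls.dna_allele], _COMPLEMENT[cls.rna_allele]
    )


def merge_candidates(
    candidates: Iterable[CandidateSite], tissue: str
) -> list[EditingEvent]:
    """Group per-sample candidates of one tissue into events.

    Event identity includes both alleles, so the same position with
    different RNA alleles yields distinct events. The total replicate
    count across events equals the number of input candidates.
    """
    grouped: dict[tuple[str, int, str, str], set[str]] = defaultdict(set)
    for cand in candidates:
        key = (cand.chrom, cand.pos, cand.dna_allele, cand.rna_allele)
        if cand.sample in grouped[key]:
            raise UsageError(
                f"duplicate candidate for sample {cand.sample} at "
                f"{cand.chrom}:{cand.pos}"
            )
        grouped[key].add(cand.sample)
    return [
        EditingEvent(
            tissue=tissue,
            chrom=chrom,
            pos=pos,
            dna_allele=dna,
            rna_allele=rna,
            samples_detected=frozenset(samples),
        )
        for (chrom, pos, dna, rna), samples in sorted(grouped.items())
    ]


def filter_by_min_replicates(
    events: Iterable[EditingEvent], min_reps: int = 3
) -> list[EditingEvent]:
    """Keep events detected in at least ``min_reps`` biological replicates."""
    return [e for e in events if e.n_replicates >= min_reps]


def substitution_spectrum(
    events: Sequence[EditingEvent],
) -> tuple[dict[str, float], float]:
    """Per-class fractions over the 12 substitution classes.

    Returns (fractions keyed by class label, transversion fraction).
    Fractions sum to 1 over a non-empty event list.
    """
    labels = [SubstitutionClass(d, r).label for d, r in ALL_CLASSES]
    counts = {label: 0 for label in labels}
    transversions = 0
    total = 0
    for event in events:
        cls = event.substitution
        counts[cls.label] += 1
        if not cls.is_transition:
            transversions += 1
        total += 1
    if total == 0:
        return {label: 0.0 for label in labels}, 0.0
    return (
        {label: count / total for label, count in counts.items()},
        transversions / total,
    )


def deduplicate_union(
    events_by_tissue: Mapping[str, Sequence[EditingEvent]],
) -> tuple[list[tuple[str, int, str, str]], list[tuple[str, int, str, str]]]:
    """Unique (chrom, pos, dna, rna) keys across tissues and the shared ones.

    ``common`` holds keys present in every tissue (intersection).
    """
    key_sets = {
        tissue: {e.key for e in events}
        for tissue, events in events_by_tissue.items()
    }
    unique: set[tuple[str, int, str, str]] = set()
    for keys in key_sets.values():
        unique |= keys
    common: set[tuple[str, int, str, str]] = set()
    if key_sets:
        common = set.intersection(*key_sets.values())
    return sorted(unique), sorted(common)


def cluster_span(positions: Iterable[int]) -> int:
    """Genomic span (max − min) of same-chromosome positions; 0 for one site."""
    pos = list(positions)
    if not pos:
        raise UsageError("cluster_span needs at least one position")
    return max(pos) - min(pos)
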