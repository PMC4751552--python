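"""The five artifact filters applied to candidate DNA→RNA differences.

Each filter answers one question about a candidate site: is the edited
allele concentrated at read extremities, imbalanced across alignment
strands, adjacent to an annotated splice junction, embedded in a
homopolymer or simple-sequence-repeat context, or explainable by reads
from a paralogous/unassembled locus (searched for in the raw genomic
reads of the same sample)? All filters are evaluated independently so
per-filter attrition can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import UsageError
from .io_formats import AlignedObservation, GeneModel, GenomeSequence, RawRead
from .pileup import BASES, CandidateSite

FILTER_NAMES = ("extremity", "strand", "splice", "homopolymer", "ssr", "multimapping")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class BiasFlags:
    """The six boolean artifact verdicts plus per-filter diagnostics."""

    extremity: bool
    strand: bool
    splice: bool
    homopolymer: bool
    ssr: bool
    multimapping: bool
    diagnostics: Mapping[str, object] = field(default_factory=dict)

    @property
    def unbiased(self) -> bool:
        return not any(self.as_dict().values())

    def as_dict(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in FILTER_NAMES}

    def flagged_filters(self) -> tuple[str, ...]:
        return tuple(name for name, hit in self.as_dict().items() if hit)


@dataclass(frozen=True, slots=True)
class SSRAnnotation:
    """A maximal perfect tandem repeat of a primitive 1–6 bp motif."""

    chrom: str
    start: int
    end: int
    motif: str
    copies: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.copies:
            raise UsageError("SSR interval length inconsistent with motif x copies")


@dataclass(frozen=True, slots=True)
class ConsensusSequence:
    """Consensus window centered on the edited allele, built from edited reads."""

    seq: str
    center_index: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.center_index < len(self.seq):
            raise UsageError("center index outside consensus sequence")


def flag_extremity_bias(
    candidate: CandidateSite,
    rna_obs: Iterable[AlignedObservation],
    end_window: int = 10,
    max_end_frac: float = 0.5,
) -> bool:
    """True iff the edited allele is mostly seen near read extremities.

    Only observations of the edited nucleotide are considered; the
    distance to the nearer read end uses the stored read orientation.
    """
    edited = [
        o
        for o in rna_obs
        if o.pos == candidate.pos
        and o.chrom == candidate.chrom
        and o.base == candidate.rna_allele
    ]
    if not edited:
        raise UsageError(
            f"no edited-allele observations at {candidate.chrom}:{candidate.pos}"
        )
    near_end = sum(1 for o in edited if o.end_distance() < end_window)
    return near_end / len(edited) > max_end_frac


def strand_delta(candidate: CandidateSite) -> float | None:
    """|p_f - p_r| of per-strand edited-allele proportions; None if a strand is empty."""
    counts = candidate.rna_counts
    fwd_depth = counts.forward_depth
    rev_depth = counts.reverse_depth
    if fwd_depth == 0 or rev_depth == 0:
        return None
    p_f = counts.forward.get(candidate.rna_allele, 0) / fwd_depth
    p_r = counts.reverse.get(candidate.rna_allele, 0) / rev_depth
    return abs(p_f - p_r)


def flag_strand_bias(candidate: CandidateSite, delta_max: float = 0.5) -> bool:
    """True iff edited-allele support differs markedly between strands.

    A site with zero coverage on either strand is flagged (conservative).
    """
    delta = strand_delta(candidate)
    if delta is None:
        return True
    return delta > delta_max


def _junction_windows(
    model: GeneModel, exon_range: tuple[int, int], intron_range: tuple[int, int]
) -> list[tuple[int, int]]:
    windows = []
    for istart, iend in model.introns:
        # junction between the exon ending at istart-1 and this intron
        windows.append((istart - exon_range[1], istart - exon_range[0]))
        windows.append((istart + intron_range[0] - 1, istart + intron_range[1] - 1))
        # junction between this intron and the exon starting at iend+1
        windows.append((iend + exon_range[0], iend + exon_range[1]))
        windows.append((iend - intron_range[1] + 1, iend - intron_range[0] + 1))
    return windows


def flag_splice_bias(
    candidate: CandidateSite,
    gene_models: Sequence[GeneModel],
    exon_range: tuple[int, int] = (1, 3),
    intron_range: tuple[int, int] = (3, 8),
) -> bool:
    """True iff the site sits in the error-prone zone around a splice junction.

    Distance 1 is the base adjacent to the junction on each side; the
    exon side is biased for distances in ``exon_range`` and the intron
    side for distances in ``intron_range`` (both inclusive).
    """
    pos = candidate.pos
    for model in gene_models:
        if model.chrom != candidate.chrom or not model.contains(pos):
            continue
        for lo, hi in _junction_windows(model, exon_range, intron_range):
            if lo <= pos <= hi:
                return True
    return False


def flag_homopolymer(
    candidate: CandidateSite,
    genome: Mapping[str, GenomeSequence],
    run_len: int = 4,
) -> bool:
    """True iff either flank's ``run_len`` adjacent reference bases are identical.

    Flanks truncated by a contig end cannot trigger; only complete
    windows are evaluated.
    """
    contig = genome[candidate.chrom]
    pos = candidate.pos
    if pos - run_len >= 1:
        left = contig.region(pos - run_len, pos - 1)
        if len(set(left)) == 1 and left[0] in BASES:
            return True
    if pos + run_len <= len(contig):
        right = contig.region(pos + 1, pos + run_len)
        if len(set(right)) == 1 and right[0] in BASES:
            return True
    return False


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def find_ssrs(
    sequence: str,
    *,
    chrom: str = "",
    region_start: int = 1,
    motif_min: int = 1,
    motif_max: int = 6,
    min_copies: int = 3,
    min_len: int = 9,
) -> list[SSRAnnotation]:
    """Find all maximal perfect tandem repeats in ``sequence``.

    A repeat qualifies if its motif is primitive (not itself a
    repetition), its length is in [motif_min, motif_max], it occurs in
    at least ``min_copies`` complete copies, and the full-copy span is
    at least ``min_len`` bp. The reported interval covers complete
    copies only. ``region_start`` is the 1-based genomic coordinate of
    ``sequence[0]``.
    """
    seq = sequence.upper()
    n = len(seq)
    out = []
    for start in range(n):
        for m in range(motif_min, motif_max + 1):
            if start + m * min_copies > n:
                break
            motif = seq[start : start + m]
            if not _is_primitive(motif):
                continue
            # left-maximality: the periodic run must not extend leftwards
            if start >= 1 and seq[start - 1] == seq[start + m - 1]:
                continue
            end = start + m
            while end < n and seq[end] == seq[end - m]:
                end += 1
            copies = (end - start) // m
            if copies >= min_copies and copies * m >= min_len:
                out.append(
                    SSRAnnotation(
                        chrom=chrom,
                        start=region_start + start,
                        end=region_start + start + copies * m - 1,
                        motif=motif,
                        copies=copies,
                    )
                )
    return out


def flag_ssr(
    candidate: CandidateSite, ssrs: Sequence[SSRAnnotation], offset: int = 3
) -> bool:
    """True iff the site falls within ``offset`` bp of an SSR interval."""
    return any(
        ssr.chrom == candidate.chrom
        and ssr.start - offset <= candidate.pos <= ssr.end + offset
        for ssr in ssrs
    )


def build_edited_consensus(
    candidate: CandidateSite,
    rna_obs: Iterable[AlignedObservation],
    genome: Mapping[str, GenomeSequence],
    length: int = 40,
) -> ConsensusSequence:
    """Majority consensus of the edited-allele-supporting reads around the site.

    The window spans ``length`` bases with the edited allele at 0-based
    index ``length // 2 - 1`` (index 19 of a 40-mer); it is truncated at
    contig ends. Per flank position the majority base among edited reads
    covering it wins, ties and uncovered positions fall back to the
    reference base.
    """
    contig = genome[candidate.chrom]
    half_left = length // 2 - 1
    start = max(1, candidate.pos - half_left)
    end = min(len(contig), candidate.pos + (length - half_left - 1))
    window_obs: dict[int, list[AlignedObservation]] = {}
    edited_ids = set()
    for o in rna_obs:
        if o.chrom != candidate.chrom or not start <= o.pos <= end:
            continue
        window_obs.setdefault(o.pos, []).append(o)
        if o.pos == candidate.pos and o.base == candidate.rna_allele:
            edited_ids.add(o.read_id)
    if not edited_ids:
        raise UsageError(
            f"no reads support the edited allele at {candidate.chrom}:{candidate.pos}"
        )
    bases = []
    for pos in range(start, end + 1):
        ref = contig.base_at(pos)
        if pos == candidate.pos:
            bases.append(candidate.rna_allele)
            continue
        tally: dict[str, int] = {}
        for o in window_obs.get(pos, ()):
            if o.read_id in edited_ids and o.base in BASES:
                tally[o.base] = tally.get(o.base, 0) + 1
        if not tally:
            bases.append(ref)
            continue
        best = max(tally.values())
        winners = {b for b, c in tally.items() if c == best}
        bases.append(ref if ref in winners or len(winners) > 1 else winners.pop())
    return ConsensusSequence(
        seq="".join(bases),
        center_index=candidate.pos - start,
        truncated=(end - start + 1) < length,
    )


def _matches_with_mismatches(pattern: str, text: str, k: int) -> bool:
    if k == 0:
        return pattern in text
    n, m = len(text), len(pattern)
    for i in range(n - m + 1):
        mismatches = 0
        for a, b in zip(pattern, text[i : i + m]):
            if a != b:
                mismatches += 1
                if mismatches > k:
                    break
        else:
            return True
    return False


def find_multimapping_match(
    consensus: ConsensusSequence,
    dna_reads: Iterable[RawRead],
    max_mismatches: int = 0,
) -> str | None:
    """Read id of the first raw DNA read containing the consensus, if any.

    Both the read and its reverse complement are searched.
    """
    pattern = consensus.seq
    for read in dna_reads:
        if _matches_with_mismatches(pattern, read.seq, max_mismatches):
            return read.read_id
        if _matches_with_mismatches(
            pattern, reverse_complement(read.seq), max_mismatches
        ):
            return read.read_id
    return None


def flag_multimapping(
    consensus: ConsensusSequence,
    dna_reads: Iterable[RawRead],
    max_mismatches: int = 0,
) -> bool:
    """True iff the edited-allele consensus occurs in any raw DNA read."""
    reads = dna_reads if isinstance(dna_reads, (list, tuple)) else list(dna_reads)
    if not reads:
        import logging

        logging.getLogger(__name__).warning(
            "multimapping filter called with no raw DNA reads; returning False"
        )
        return False
    return find_multimapping_match(consensus, reads, max_mismatches) is not None


@dataclass(slots=True)
class FilterContext:
    """Everything the six filters need for one sample.

    ``rna_observations`` indexes the sample's RNA observations by
    (chrom, pos); ``dna_reads`` are the sample's raw genomic reads
    (including unaligned ones). SSR annotations are computed from the
    genome on first use when not supplied.
    """

    genome: Mapping[str, GenomeSequence]
    gene_models: Sequence[GeneModel]
    rna_observations: Mapping[tuple[str, int], list[AlignedObservation]]
    dna_reads: Sequence[RawRead]
    ssrs: Sequence[SSRAnnotation] | None = None
    end_window: int = 10
    max_end_frac: float = 0.5
    delta_max: float = 0.5
    exon_range: tuple[int, int] = (1, 3)
    intron_range: tuple[int, int] = (3, 8)
    homopolymer_run: int = 4
    ssr_offset: int = 3
    consensus_length: int = 40
    max_mismatches: int = 0

    def ssr_annotations(self) -> Sequence[SSRAnnotation]:
        if self.ssrs is None:
            ssrs: list[SSRAnnotation] = []
            for name, contig in self.genome.items():
                ssrs.extend(find_ssrs(contig.seq, chrom=name))
            self.ssrs = ssrs
        return self.ssrs


def apply_filters(candidate: CandidateSite, context: FilterContext) -> BiasFlags:
    """Evaluate all six filters independently (no short-circuiting)."""
    site_obs = context.rna_observations.get((candidate.chrom, candidate.pos), [])
    extremity = flag_extremity_bias(
        candidate, site_obs, context.end_window, context.max_end_frac
    )
    delta = strand_delta(candidate)
    strand = flag_strand_bias(candidate, context.delta_max)
    splice = flag_splice_bias(
        candidate, context.gene_models, context.exon_range, context.intron_range
    )
    homopolymer = flag_homopolymer(candidate, context.genome, context.homopolymer_run)
    ssr = flag_ssr(candidate, context.ssr_annotations(), context.ssr_offset)

    window_obs: list[AlignedObservation] = []
    half_left = context.consensus_length // 2 - 1
    lo = candidate.pos - half_left
    hi = candidate.pos + (context.consensus_length - half_left - 1)
    for pos in range(lo, hi + 1):
        window_obs.extend(context.rna_observations.get((candidate.chrom, pos), ()))
    consensus = build_edited_consensus(
        candidate, window_obs, context.genome, context.consensus_length
    )
    match = find_multimapping_match(
        consensus, context.dna_reads, context.max_mismatches
    )

    edited = [o for o in site_obs if o.base == candidate.rna_allele]
    near_end = sum(1 for o in edited if o.end_distance() < context.end_window)
    diagnostics = {
        "extremity": near_end / len(edited) if edited else None,
        "strand": delta,
        "homopolymer": None,
        "splice": None,
        "ssr": None,
        "multimapping": match,
        "consensus": consensus.seq,
    }
    return BiasFlags(
        extremity=extremity,
        strand=strand,
        splice=splice,
        homopolymer=homopolymer,
        ssr=ssr,
        multimapping=match is not None,
        diagnostics=diagnostics,
    )
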