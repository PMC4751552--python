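import random

import pytest

from editscreen.errors import UsageError
from editscreen.filters import (
    BiasFlags,
    FilterContext,
    apply_filters,
    build_edited_consensus,
    find_multimapping_match,
    find_ssrs,
    flag_extremity_bias,
    flag_homopolymer,
    flag_multimapping,
    flag_splice_bias,
    flag_ssr,
    flag_strand_bias,
    reverse_complement,
    ConsensusSequence,
    SSRAnnotation,
)
from editscreen.io_formats import GeneModel, GenomeSequence, RawRead

from conftest import make_candidate, make_column, make_obs

# ---------------------------------------------------------------------------
# extremity


def _edited_obs(offsets, pos=100, base="G", read_length=101):
    return [
        make_obs(pos, base, read_offset=off, read_length=read_length, read_id=f"r{i}")
        for i, off in enumerate(offsets)
    ]


def test_extremity_central_observations_pass():
    cand = make_candidate()
    obs = _edited_obs([50] * 10)
    assert flag_extremity_bias(cand, obs) is False


def test_extremity_majority_near_ends_flagged():
    cand = make_candidate()
    obs = _edited_obs([3] * 4 + [97] * 4 + [50] * 2)  # 8/10 within 10bp of an end
    assert flag_extremity_bias(cand, obs) is True


def test_extremity_no_edited_obs_is_usage_error():
    cand = make_candidate()
    with pytest.raises(UsageError):
        flag_extremity_bias(cand, [])


def test_extremity_matches_brute_force_fraction():
    rng = random.Random(13)
    for _ in range(300):
        offsets = [rng.randint(0, 100) for _ in range(rng.randint(1, 30))]
        obs = _edited_obs(offsets)
        # independent recount
        frac = sum(1 for off in offsets if min(off, 100 - off) < 10) / len(offsets)
        cand = make_candidate()
        assert flag_extremity_bias(cand, obs) == (frac > 0.5)


# ---------------------------------------------------------------------------
# strand


def test_strand_balanced_not_flagged():
    # p_f = p_r = 0.4
    specs = [("A", "+")] * 6 + [("G", "+")] * 4 + [("A", "-")] * 6 + [("G", "-")] * 4
    cand = make_candidate(rna_obs_specs=specs)
    assert flag_strand_bias(cand) is False


def test_strand_marked_imbalance_flagged():
    specs = [("G", "+")] * 9 + [("A", "+")] * 1 + [("G", "-")] * 1 + [("A", "-")] * 9
    cand = make_candidate(rna_obs_specs=specs)
    assert flag_strand_bias(cand) is True  # delta = 0.8


def test_strand_single_strand_coverage_flagged():
    specs = [("A", "+")] * 14 + [("G", "+")] * 6
    cand = make_candidate(rna_obs_specs=specs)
    assert flag_strand_bias(cand) is True


# ---------------------------------------------------------------------------
# splice


@pytest.fixture()
def gene():
    return GeneModel(
        gene_id="g1",
        chrom="chr1",
        strand="+",
        gene_start=100,
        gene_end=400,
        exons=((100, 200), (301, 400)),
    )


@pytest.mark.parametrize(
    "pos,expected",
    [
        (200, True),  # last exon base, distance 1
        (198, True),  # exon distance 3
        (197, False),  # exon distance 4
        (201, False),  # intron distance 1 (not in 3..8)
        (202, False),  # intron distance 2
        (203, True),  # intron distance 3
        (205, True),  # intron distance 5
        (208, True),  # intron distance 8
        (210, False),  # intron distance 10
        (301, True),  # first base of downstream exon
        (299, False),  # intron distance 2 from right junction
        (298, True),  # intron distance 3 from right junction
        (150, False),  # mid-exon
    ],
)
def test_splice_zone_boundaries(gene, pos, expected):
    cand = make_candidate(pos=pos)
    assert flag_splice_bias(cand, [gene]) is expected


def test_splice_no_overlapping_gene_is_false(gene):
    cand = make_candidate(pos=5000)
    assert flag_splice_bias(cand, [gene]) is False


# ---------------------------------------------------------------------------
# homopolymer


def _genome(seq):
    return {"chr1": GenomeSequence(name="chr1", seq=seq)}


def test_homopolymer_left_flank():
    genome = _genome("CGAAAAGTCGT")  # site at pos 7 has AAAA at 3..6
    cand = make_candidate(pos=7)
    assert flag_homopolymer(cand, genome) is True


def test_homopolymer_right_flank():
    genome = _genome("CGCGCGATTTTCG")  # pos 7 followed by TTTT
    cand = make_candidate(pos=7)
    assert flag_homopolymer(cand, genome) is True


def test_homopolymer_mixed_context_passes():
    genome = _genome("ACGTACGTACGTACGT")
    cand = make_candidate(pos=8)
    assert flag_homopolymer(cand, genome) is False


def test_homopolymer_contig_end_evaluates_available_side():
    genome = _genome("AGTTTT")  # pos 2: only 1 left base, right = TTTT
    cand = make_candidate(pos=2)
    assert flag_homopolymer(cand, genome) is True
    genome2 = _genome("AGTCGA")
    assert flag_homopolymer(make_candidate(pos=2), genome2) is False


# ---------------------------------------------------------------------------
# SSR finder


def test_find_ssrs_simple_dinucleotide():
    ssrs = find_ssrs("ACACACACAC")
    assert len(ssrs) == 1
    assert ssrs[0].motif == "AC"
    assert ssrs[0].copies == 5
    assert (ssrs[0].start, ssrs[0].end) == (1, 10)


def test_find_ssrs_none_in_nonrepetitive():
    assert find_ssrs("ACGTACGA") == []


def test_find_ssrs_homopolymer_run():
    ssrs = find_ssrs("GGAAAAAAAAAGG")
    assert len(ssrs) == 1
    assert ssrs[0].motif == "A"
    assert ssrs[0].copies == 9


def _brute_force_ssrs(seq, motif_min=1, motif_max=6, min_copies=3, min_len=9):
    """Independent enumeration: try every (start, motif) and count whole copies
    by slice comparison."""
    found = set()
    n = len(seq)
    for i in range(n):
        for m in range(motif_min, motif_max + 1):
            motif = seq[i : i + m]
            if len(motif) < m:
                continue
            # primitive?
            if any(
                m % d == 0 and motif == motif[:d] * (m // d) for d in range(1, m)
            ):
                continue
            # left-maximal under period m?
            if i >= 1 and seq[i - 1] == seq[i + m - 1]:
                continue
            copies = 1
            while seq[i + copies * m : i + (copies + 1) * m] == motif:
                copies += 1
            if copies >= min_copies and copies * m >= min_len:
                found.add((i + 1, i + copies * m, motif, copies))
    return found


@pytest.mark.parametrize("n_strings", [2000])
def test_find_ssrs_equals_brute_force_on_random_strings(n_strings):
    rng = random.Random(17)
    for _ in range(n_strings):
        length = rng.randint(5, 50)
        # biased alphabet so repeats actually occur
        seq = "".join(rng.choice("AACCG") for _ in range(length))
        got = {(s.start, s.end, s.motif, s.copies) for s in find_ssrs(seq)}
        assert got == _brute_force_ssrs(seq)


def test_flag_ssr_offset_window():
    ssr = SSRAnnotation(chrom="chr1", start=100, end=111, motif="AC", copies=6)
    assert flag_ssr(make_candidate(pos=113), [ssr]) is True  # 2bp past end
    assert flag_ssr(make_candidate(pos=115), [ssr]) is False  # 4bp past end
    assert flag_ssr(make_candidate(pos=105), [ssr]) is True  # inside
    assert flag_ssr(make_candidate(pos=97), [ssr]) is True  # 3bp before start


# ---------------------------------------------------------------------------
# consensus + multimapping


def _window_reads(genome_seq, pos, rna_allele, n_reads, read_start, flank_snp=None):
    """Reads of length 60 starting at read_start, all carrying the edited allele."""
    obs = []
    for i in range(n_reads):
        rid = f"e{i}"
        for p in range(read_start, read_start + 60):
            base = genome_seq[p - 1]
            if p == pos:
                base = rna_allele
            if flank_snp and p == flank_snp[0]:
                base = flank_snp[1]
            obs.append(
                make_obs(
                    p, base, read_offset=p - read_start, read_length=60, read_id=rid
                )
            )
    return obs


@pytest.fixture()
def consensus_setup():
    rng = random.Random(23)
    seq = "".join(rng.choice("ACGT") for _ in range(200))
    seq = seq[:99] + "A" + seq[100:]  # ref A at pos 100
    genome = _genome(seq)
    cand = make_candidate(pos=100, dna_allele="A", rna_allele="G")
    return genome, cand, seq


def test_consensus_reference_flanks(consensus_setup):
    genome, cand, seq = consensus_setup
    obs = _window_reads(seq, 100, "G", 5, 70)
    cons = build_edited_consensus(cand, obs, genome)
    assert len(cons.seq) == 40
    assert cons.center_index == 19
    expected = seq[80:99] + "G" + seq[100:120]
    assert cons.seq == expected


def test_consensus_carries_shared_flank_snp(consensus_setup):
    genome, cand, seq = consensus_setup
    obs = _window_reads(seq, 100, "G", 5, 70, flank_snp=(90, "T"))
    cons = build_edited_consensus(cand, obs, genome)
    assert cons.seq[90 - 81] == "T"


def test_consensus_matches_per_column_majority_oracle(consensus_setup):
    genome, cand, seq = consensus_setup
    rng = random.Random(31)
    obs = []
    for i in range(12):
        rid = f"e{i}"
        start = rng.randint(55, 95)
        supports = rng.random() < 0.7
        for p in range(start, start + 60):
            base = seq[p - 1]
            if p == 100:
                base = "G" if supports else "A"
            elif rng.random() < 0.1:
                base = rng.choice("ACGT")
            obs.append(
                make_obs(p, base, read_offset=p - start, read_length=60, read_id=rid)
            )
    if not any(o.pos == 100 and o.base == "G" for o in obs):
        pytest.skip("no edited read drawn")
    cons = build_edited_consensus(cand, obs, genome)
    # independent per-column majority recount
    edited_ids = {o.read_id for o in obs if o.pos == 100 and o.base == "G"}
    for idx, p in enumerate(range(81, 121)):
        if p == 100:
            assert cons.seq[idx] == "G"
            continue
        tally = {}
        for o in obs:
            if o.pos == p and o.read_id in edited_ids:
                tally[o.base] = tally.get(o.base, 0) + 1
        ref = seq[p - 1]
        if not tally:
            assert cons.seq[idx] == ref
        else:
            best = max(tally.values())
            winners = {b for b, c in tally.items() if c == best}
            if ref in winners or len(winners) > 1:
                assert cons.seq[idx] == ref
            else:
                assert cons.seq[idx] == winners.pop()


def test_multimapping_exact_match_and_rc():
    cons = ConsensusSequence(seq="ACGTACGTACGTACGTACGT", center_index=10)
    reads = [RawRead("r1", "TTTT" + cons.seq + "GGGG")]
    assert flag_multimapping(cons, reads) is True
    rc_reads = [RawRead("r2", "TT" + reverse_complement(cons.seq) + "AA")]
    assert flag_multimapping(cons, rc_reads) is True
    assert flag_multimapping(cons, [RawRead("r3", "A" * 60)]) is False


def test_multimapping_empty_read_set_false():
    cons = ConsensusSequence(seq="ACGT", center_index=1)
    assert flag_multimapping(cons, []) is False


def test_multimapping_reports_matching_read():
    cons = ConsensusSequence(seq="ACGTTGCA", center_index=3)
    reads = [RawRead("r1", "G" * 30), RawRead("r2", "C" + cons.seq)]
    assert find_multimapping_match(cons, reads) == "r2"


# ---------------------------------------------------------------------------
# combined application


def _full_context(seq, rna_obs, dna_reads=(), genes=()):
    index = {}
    for o in rna_obs:
        index.setdefault((o.chrom, o.pos), []).append(o)
    return FilterContext(
        genome=_genome(seq),
        gene_models=list(genes),
        rna_observations=index,
        dna_reads=list(dna_reads),
    )


def _clean_setup():
    rng = random.Random(41)
    seq = "".join(rng.choice("ACGT") for _ in range(200))
    # scrub any accidental repeat context around pos 100
    seq = seq[:80] + "GATCGTTAGCATGCACTGAG" + "A" + "CTGAGATCCGTTAACGGATC" + seq[121:]
    obs = []
    for i in range(20):
        rid = f"r{i}"
        start = 60 + 2 * i
        strand = "+" if i % 2 == 0 else "-"
        edited = i % 3 == 0
        for p in range(start, start + 60):
            base = seq[p - 1]
            if p == 100 and edited:
                base = "G"
            obs.append(
                make_obs(
                    p,
                    base,
                    strand=strand,
                    read_offset=p - start,
                    read_length=60,
                    read_id=rid,
                )
            )
    specs = [
        (o.base, o.strand, o.read_offset, o.read_length, o.read_id)
        for o in obs
        if o.pos == 100
    ]
    cand = make_candidate(pos=100, dna_allele="A", rna_allele="G", rna_obs_specs=specs)
    return seq, obs, cand


def test_apply_filters_clean_candidate_all_false():
    seq, obs, cand = _clean_setup()
    context = _full_context(seq, obs)
    flags = apply_filters(cand, context)
    assert flags.unbiased
    assert flags.flagged_filters() == ()


def test_apply_filters_idempotent_and_order_independent():
    seq, obs, cand = _clean_setup()
    context = _full_context(seq, obs)
    first = apply_filters(cand, context)
    second = apply_filters(cand, context)
    assert first.as_dict() == second.as_dict()


def test_apply_filters_strand_only():
    seq, obs, cand = _clean_setup()
    # replace candidate counts with a strand-skewed profile
    specs = [("G", "+")] * 9 + [("A", "+")] * 1 + [("A", "-")] * 10
    skewed = make_candidate(pos=100, dna_allele="A", rna_allele="G", rna_obs_specs=specs)
    context = _full_context(seq, obs)
    flags = apply_filters(skewed, context)
    assert flags.strand is True
    assert flags.splice is False
    assert flags.homopolymer is False
    assert flags.ssr is False
    assert flags.multimapping is False
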