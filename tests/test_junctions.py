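"""Backsplice calling: k-mer index, caller vs truth and brute-force oracle,
linear spanning counts, RPM/CTL arithmetic."""

import numpy as np
import pytest

from circdigit import (
    BacksplicedJunction,
    annotate_linear_counts,
    build_kmer_index,
    build_toy_genome,
    call_backsplice_junctions,
    count_linear_spanning,
    ctl_ratio,
    reverse_complement,
    rpm,
    simulate_expression_truth,
    simulate_read_set,
)
from circdigit.genome import ToyGenome
from circdigit.junctions import KmerIndex
from circdigit.simulate import SimulatedReadSet

from oracles import oracle_call_backsplice


# ---- k-mer index -----------------------------------------------------------


def test_kmer_index_whole_genome_lookup():
    g = ToyGenome(chrom="c", sequence="ACGTACGT", gene_models=[])
    idx = build_kmer_index(g, 8)
    assert idx.lookup("ACGTACGT") == [("c", 0, "+")]


def test_kmer_index_reverse_complement_hit(genome3, index3):
    s, e = genome3.gene_models[0].exons[0]
    km = genome3.sequence[s : s + 20]
    hits = index3.lookup(reverse_complement(km))
    assert hits == [(genome3.chrom, s, "-")]


def test_kmer_index_round_trip(rng):
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    g = ToyGenome(chrom="r", sequence=seq, gene_models=[])
    idx = build_kmer_index(g, 20)
    for p in rng.integers(0, 980, size=50):
        p = int(p)
        assert (g.chrom, p, "+") in idx.lookup(seq[p : p + 20])


def test_kmer_index_invalid_k():
    with pytest.raises(ValueError):
        KmerIndex(0)
    with pytest.raises(ValueError):
        build_kmer_index(ToyGenome("c", "ACGT", []), 10)


# ---- RPM / CTL -------------------------------------------------------------


@pytest.mark.parametrize(
    "n,total,expected", [(5, 1_000_000, 5.0), (0, 123, 0.0), (7, 3_500_000, 2.0)]
)
def test_rpm(n, total, expected):
    assert rpm(n, total) == pytest.approx(expected)


def test_rpm_requires_positive_total():
    with pytest.raises(ValueError):
        rpm(5, 0)


@pytest.mark.parametrize(
    "args,expected",
    [((10, 10, 10), 1.0), ((15, 5, 15), 1.5), ((12, 0, 0), None), ((0, 3, 5), 0.0)],
)
def test_ctl_ratio(args, expected):
    got = ctl_ratio(*args)
    if expected is None:
        assert got is None  # the "no linear reads" undefined case
    else:
        assert got == pytest.approx(expected)


# ---- calling on simulated reads -------------------------------------------


def _truth_support(reads, circ_id):
    return sum(
        1
        for rid, label in reads.truth_labels.items()
        if label == "backsplice" and rid.split("|")[2] == circ_id
    )


def test_caller_recovers_single_circle(single_circle_world):
    genome, truth, reads = single_circle_world
    (circle,) = truth.circles
    idx = build_kmer_index(genome, 20)
    calls = call_backsplice_junctions(
        reads, genome, idx, anchor_len=20, min_overhang=20, min_support=5
    )
    assert len(calls) == 1
    (j,) = calls
    assert (j.acceptor_start, j.donor_end) == (circle.acceptor_start, circle.donor_end)
    assert j.strand == genome.gene_models[0].strand
    assert j.n_junction_reads == _truth_support(reads, circle.circ_id)
    assert j.rpm == pytest.approx(j.n_junction_reads / len(reads) * 1e6)


def test_min_support_above_count_empties_result(single_circle_world):
    genome, truth, reads = single_circle_world
    (circle,) = truth.circles
    n = _truth_support(reads, circle.circ_id)
    idx = build_kmer_index(genome, 20)
    calls = call_backsplice_junctions(
        reads, genome, idx, min_overhang=20, min_support=n + 1
    )
    assert calls == []


def test_linear_only_reads_yield_no_junctions(genome3, index3, truth3):
    silenced = type(truth3)(
        linear_abundance=dict(truth3.linear_abundance),
        circles=list(truth3.circles),
        circ_abundance={k: 0.0 for k in truth3.circ_abundance},
    )
    reads = simulate_read_set(genome3, silenced, 800, read_len=60, seed=4)
    assert call_backsplice_junctions(reads, genome3, index3, min_support=1) == []


def test_gt_ag_filter_is_a_noop_on_canonical_genomes(single_circle_world):
    """Toy genomes carry canonical signals at every exon edge, so requiring
    GT/AG must not change the calls."""
    genome, truth, reads = single_circle_world
    idx = build_kmer_index(genome, 20)
    kwargs = dict(anchor_len=20, min_overhang=20, min_support=5)
    with_flag = call_backsplice_junctions(
        reads, genome, idx, require_gt_ag=True, **kwargs
    )
    without = call_backsplice_junctions(
        reads, genome, idx, require_gt_ag=False, **kwargs
    )
    assert [(j.key, j.n_junction_reads) for j in with_flag] == [
        (j.key, j.n_junction_reads) for j in without
    ]


def test_support_threshold_monotonicity(single_circle_world):
    genome, truth, reads = single_circle_world
    idx = build_kmer_index(genome, 20)
    seen = None
    for support in (1, 5, 20, 200):
        calls = call_backsplice_junctions(
            reads, genome, idx, min_overhang=20, min_support=support
        )
        keys = {j.key for j in calls}
        if seen is not None:
            assert keys <= seen, "raising min_support must never add a junction"
        seen = keys


def test_mismatch_tolerance_monotonicity(single_circle_world):
    genome, truth, _ = single_circle_world
    reads = simulate_read_set(
        genome, truth, 1500, read_len=60, seed=77, error_rate=0.01, min_overhang=20
    )
    idx = build_kmer_index(genome, 20)
    keys0 = {
        j.key
        for j in call_backsplice_junctions(reads, genome, idx, max_mismatch=0, min_support=5)
    }
    keys1 = {
        j.key
        for j in call_backsplice_junctions(reads, genome, idx, max_mismatch=1, min_support=5)
    }
    assert keys0 <= keys1, "raising max_mismatch must never remove a junction"


def test_ctl_invariant_under_doubled_read_counts(single_circle_world):
    genome, truth, reads = single_circle_world
    doubled = SimulatedReadSet(
        reads=reads.reads + [(f"dup_{r[0]}", *r[1:]) for r in reads.reads],
        truth_labels={
            **reads.truth_labels,
            **{f"dup_{k}": v for k, v in reads.truth_labels.items()},
        },
    )
    idx = build_kmer_index(genome, 20)
    single = annotate_linear_counts(
        call_backsplice_junctions(reads, genome, idx, min_overhang=20, min_support=5),
        reads, genome, idx, min_overhang=20,
    )
    both = annotate_linear_counts(
        call_backsplice_junctions(doubled, genome, idx, min_overhang=20, min_support=5),
        doubled, genome, idx, min_overhang=20,
    )
    for a, b in zip(single, both):
        assert b.n_junction_reads == 2 * a.n_junction_reads
        assert b.ctl == pytest.approx(a.ctl)


# ---- linear spanning counts ------------------------------------------------


def test_linear_spanning_zero_when_host_silent(genome3, index3, truth3):
    only_circles = type(truth3)(
        linear_abundance={k: 0.0 for k in truth3.linear_abundance},
        circles=list(truth3.circles),
        circ_abundance={
            k: (v if truth3.circle(k).spliced_length >= 60 else 0.0)
            for k, v in truth3.circ_abundance.items()
        },
    )
    reads = simulate_read_set(genome3, only_circles, 400, read_len=60, seed=5)
    for c in truth3.circles:
        j = BacksplicedJunction(
            chrom=genome3.chrom, strand=genome3.gene(c.gene_id).strand,
            acceptor_start=c.acceptor_start, donor_end=c.donor_end,
        )
        assert count_linear_spanning(reads, genome3, index3, j) == (0, 0)


def test_linear_spanning_matches_closed_form(single_circle_world):
    """Donor/acceptor spanning counts are binomial with success probability
    (#usable read starts)/(#transcript positions)."""
    genome, truth, reads = single_circle_world
    (circle,) = truth.circles
    gene = genome.gene_models[0]
    idx = build_kmer_index(genome, 20)
    j = BacksplicedJunction(
        chrom=genome.chrom, strand=gene.strand,
        acceptor_start=circle.acceptor_start, donor_end=circle.donor_end,
    )
    nd, na = count_linear_spanning(reads, genome, idx, j, min_overhang=8)
    # transcript layout: three 100-nt exons; junction sites are the middle
    # exon's edges, i.e. transcript offsets 100 and 200 (mirrored for -)
    L, A, T = 60, 20, 300
    n_lin = sum(
        1
        for rid, label in reads.truth_labels.items()
        if label == "linear" and rid.split("|")[2] == gene.gene_id
    )
    # usable starts: splice breakpoint c = site - s within [A, L - A]
    n_starts = (L - A) - A + 1
    p = n_starts / (T - L + 1)
    sd = np.sqrt(n_lin * p * (1 - p))
    for observed in (nd, na):
        assert abs(observed - n_lin * p) <= 3 * sd


def test_read_ending_at_donor_counts_in_neither(single_circle_world):
    genome, truth, _ = single_circle_world
    (circle,) = truth.circles
    gene = genome.gene_models[0]
    idx = build_kmer_index(genome, 20)
    spliced = genome.linear_spliced_sequence(gene)
    # middle exon's donor edge sits at transcript offset 200 on '+', 100 on '-'
    don_offset = 200 if gene.strand == "+" else 100
    seq = spliced[don_offset - 60 : don_offset]
    reads = SimulatedReadSet(reads=[("edge|linear|manual", seq)],
                             truth_labels={"edge|linear|manual": "linear"})
    j = BacksplicedJunction(
        chrom=genome.chrom, strand=gene.strand,
        acceptor_start=circle.acceptor_start, donor_end=circle.donor_end,
    )
    assert count_linear_spanning(reads, genome, idx, j) == (0, 0)


# ---- oracle equivalence (small; the acceptance test scales this up) --------


@pytest.mark.parametrize("seed", [101, 102, 103])
def test_caller_matches_string_matching_oracle(seed):
    genome = build_toy_genome(seed, n_genes=3, exons_per_gene=(2, 4))
    truth = simulate_expression_truth(genome, seed + 1, circ_fraction=1.0)
    reads = simulate_read_set(
        genome, truth, 200, read_len=60, seed=seed + 2, min_overhang=20
    )
    idx = build_kmer_index(genome, 20)
    calls = call_backsplice_junctions(
        reads, genome, idx, anchor_len=20, min_overhang=20, min_support=5
    )
    expected = oracle_call_backsplice(genome, reads, min_support=5, overhang=20)
    assert {j.key: j.n_junction_reads for j in calls} == expected
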