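"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package internals: the junction
oracle enumerates exon-boundary pairs and tests reads by exact string
matching; the Fisher oracle enumerates all margin-preserving 2x2 tables in
integer arithmetic; the UPGMA oracle recomputes every inter-cluster average
distance from the full pairwise matrix at each merge.
"""

from __future__ import annotations

from math import comb

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_call_backsplice(genome, reads, min_support: int, overhang: int):
    """Brute-force backsplice calling by string matching.

    Enumerates every (acceptor_start, donor_end) exon-boundary pair within
    each gene and counts reads (in either orientation) that exactly equal
    donor-side context + acceptor-side context for some breakpoint offset
    with >= ``overhang`` nt on both sides. Returns
    {(chrom, strand, acceptor_start, donor_end): n_reads} for junctions with
    >= min_support supporting reads.
    """
    gseq = genome.sequence
    candidates = []
    for g in genome.gene_models:
        for i in range(len(g.exons)):
            for j in range(i, len(g.exons)):
                acc = g.exons[i][0]
                don = g.exons[j][1]
                candidates.append((g.strand, acc, don))
    support: dict[tuple, set] = {}
    for rid, seq in reads.sequences():
        L = len(seq)
        for strand, acc, don in candidates:
            hit = False
            for q in (seq, _rc(seq)):
                for x in range(overhang, L - overhang + 1):
                    if don - x < 0 or acc + (L - x) > len(gseq):
                        continue
                    if gseq[don - x : don] + gseq[acc : acc + (L - x)] == q:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                key = (genome.chrom, strand, acc, don)
                support.setdefault(key, set()).add(rid)
    return {k: len(v) for k, v in support.items() if len(v) >= min_support}


def oracle_fisher_two_tailed(a: int, b: int, c: int, d: int, slack: float = 1e-7) -> float:
    """Two-tailed Fisher p by exact enumeration over margin-preserving tables.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose point probability is <= that of the observed table (with a
    small relative slack for floating-point tie conventions). Pure integer
    arithmetic until the final division.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("empty table")
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    obs = weights[a]
    cutoff = obs + int(obs * slack)
    total = sum(w for w in weights.values() if w <= cutoff)
    return total / denom


def oracle_upgma_heights(dist: np.ndarray) -> list[float]:
    """Merge heights of UPGMA clustering, recomputed O(n^3) from scratch.

    At every step the pair of clusters with the smallest unweighted average
    of original pairwise distances is merged; returns the n-1 merge heights
    in merge order.
    """
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pairs = [dist[p, q] for p in clusters[i] for q in clusters[j]]
                h = float(np.mean(pairs))
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights
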