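"""Anchor-based backsplice junction calling and circular/linear statistics.

The caller follows the anchor-pair strategy of find_circ: from each read it
takes a head and a tail anchor of ``anchor_len`` nt, requires both to map
uniquely to the same chromosome and strand, and reports a backsplice when
the tail anchor lands genomically upstream of the head anchor (head-to-tail
order). Each anchor pair is extended toward the breakpoint allowing at most
``max_mismatch`` mismatches and requiring ``min_overhang`` nt on both sides;
ambiguous breakpoints are slid to the position consistent with canonical
GT..AG (plus strand) or CT..AC (minus strand, the genomic mirror image)
splice signals, falling back to the leftmost genomic breakpoint. Junctions
are aggregated by (chrom, strand, acceptor_start, donor_end); a read — and a
read pair sharing an id — contributes at most one count to any junction.

Quantities:

* RPM — junction-spanning reads per million total raw reads.
* CTL — junction-spanning reads divided by the average of the linear read
  counts spanning the splice donor and splice acceptor sites; undefined
  (``None``, serialized ``NA``) when both linear counts are zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .genome import ToyGenome, reverse_complement

logger = logging.getLogger(__name__)

UNDEFINED = None


class KmerIndex:
    """Exact k-mer -> genomic position index over both strands.

    Plus-strand k-mers are stored; minus-strand hits are resolved through the
    reverse complement at lookup time, so a stored position always yields the
    queried k-mer by substring extraction (reverse complemented for '-').
    """

    def __init__(self, k: int):
        if k <= 0:
            raise ValueError("k must be positive")
        self.k = k
        self._plus: dict[str, list[tuple[str, int]]] = {}

    def add_sequence(self, chrom: str, sequence: str) -> None:
        k = self.k
        for i in range(len(sequence) - k + 1):
            self._plus.setdefault(sequence[i : i + k], []).append((chrom, i))

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All (chrom, position, strand) occurrences of ``kmer``."""
        hits = [(c, p, "+") for c, p in self._plus.get(kmer, [])]
        rc = reverse_complement(kmer)
        if rc != kmer:
            hits += [(c, p, "-") for c, p in self._plus.get(rc, [])]
        return hits


def build_kmer_index(genome: ToyGenome, k: int) -> KmerIndex:
    if k > len(genome):
        raise ValueError("k exceeds genome length")
    index = KmerIndex(k)
    index.add_sequence(genome.chrom, genome.sequence)
    return index


@dataclass
class BacksplicedJunction:
    """A called circRNA backsplice junction with read support and statistics."""

    chrom: str
    strand: str
    acceptor_start: int  # 0-based genomic start of the circularized block
    donor_end: int  # half-open genomic end of the circularized block
    n_junction_reads: int = 0
    n_linear_donor: int = 0
    n_linear_acceptor: int = 0
    rpm: float = 0.0
    ctl: float | None = UNDEFINED
    read_ids: set = field(default_factory=set, repr=False)

    @property
    def name(self) -> str:
        return f"circ_{self.chrom}_{self.acceptor_start}_{self.donor_end}"

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.acceptor_start, self.donor_end)


def rpm(n_junction_reads: int, total_raw_reads: int) -> float:
    """Backsplice reads per million total raw reads."""
    if total_raw_reads <= 0:
        raise ValueError("total_raw_reads must be positive")
    return n_junction_reads / total_raw_reads * 1e6

def ctl_ratio(
    n_junction_reads: int, n_linear_donor: int, n_linear_acceptor: int
) -> float | None:
    """Circular-to-linear ratio; ``None`` when both linear counts are zero."""
    denom = (n_linear_donor + n_linear_acceptor) / 2
    if denom == 0:
        return UNDEFINED
    return n_junction_reads / denom


# ---- per-read alignment ----------------------------------------------------


def _mismatch_profiles(q: str, genome_seq: str, h: int, suffix_start: int):
    """Cumulative mismatch counts for prefix (vs genome at h) and suffix
    (vs genome ending at suffix_start + len(q)) alignments.

    pre[b] = mismatches of q[:b] vs genome[h:h+b]; suf[b] = mismatches of
    q[b:] vs genome[suffix_start+b : suffix_start+len(q)]. Out-of-bounds
    genome positions count as mismatches.
    """
    n = len(q)
    glen = len(genome_seq)
    pre = [0] * (n + 1)
    for j in range(n):
        gpos = h + j
        bad = gpos >= glen or q[j] != genome_seq[gpos]
        pre[j + 1] = pre[j] + (1 if bad else 0)
    suf = [0] * (n + 1)
    for j in range(n - 1, -1, -1):
        gpos = suffix_start + j
        bad = gpos < 0 or gpos >= glen or q[j] != genome_seq[gpos]
        suf[j] = suf[j + 1] + (1 if bad else 0)
    return pre, suf


def _splice_signal_strand(genome_seq: str, acc: int, don: int) -> str | None:
    """Gene strand implied by splice signals flanking a backsplice, or None."""
    if acc < 2 or don + 2 > len(genome_seq):
        return None
    before, after = genome_seq[acc - 2 : acc], genome_seq[don : don + 2]
    if before == "AG" and after == "GT":
        return "+"
    if before == "AC" and after == "CT":
        return "-"
    return None


@dataclass
class _ReadAlignment:
    kind: str  # "backsplice" or "linear"
    strand: str  # strand the junction/gene is assigned to
    # backsplice: breakpoint coordinates
    acceptor_start: int = -1
    donor_end: int = -1
    # linear: anchor-implied segment geometry on the + genome
    h: int = -1  # prefix alignment start
    t: int = -1  # tail-anchor start
    L: int = 0
    A: int = 0
    valid_bs: tuple[int, ...] = ()
    gap: int = -1
    q: str = ""


def _align_read(
    seq: str,
    genome: ToyGenome,
    index: KmerIndex,
    anchor_len: int,
    max_mismatch: int,
    min_overhang: int,
    require_gt_ag: bool,
) -> _ReadAlignment | None:
    """Classify one read (either mate) against the genome.

    Returns a backsplice alignment, a colinear (possibly spliced) linear
    alignment, or None when the anchors do not map uniquely/consistently.
    """
    A = anchor_len
    L = len(seq)
    h_hits = index.lookup(seq[:A])
    t_hits = index.lookup(seq[-A:])
    if len(h_hits) != 1 or len(t_hits) != 1:
        return None
    (hc, hp, hs), (tc, tp, ts) = h_hits[0], t_hits[0]
    if hc != tc or hs != ts:
        return None
    if hs == "-":
        # re-express the alignment on the + strand of the genome
        q = reverse_complement(seq)
        h, t = tp, hp
    else:
        q, h, t = seq, hp, tp
    gseq = genome.sequence
    if t == h:
        return None
    if t < h:
        # head-to-tail order: backsplice candidate; suffix aligns ending at t+A
        suffix_start = t + A - L
        pre, suf = _mismatch_profiles(q, gseq, h, suffix_start)
        # scan every consistent breakpoint first (a junction with repeated
        # sequence at its edges admits several equivalent b), pick the
        # splice-signal-consistent one (leftmost as fallback), and only then
        # enforce the overhang on the chosen breakpoint — otherwise an edge
        # read whose true breakpoint just misses the overhang window would be
        # misassigned to a shifted coordinate inside it
        valid = [
            b
            for b in range(1, L)
            if pre[b] + suf[b] <= max_mismatch and suffix_start + b >= 0
        ]
        if not valid:
            return None
        chosen = None
        strand = None
        for b in valid:  # ascending: leftmost-first
            s = _splice_signal_strand(gseq, suffix_start + b, h + b)
            if s is not None:
                chosen, strand = b, s
                break
        if chosen is None:
            if require_gt_ag:
                return None
            chosen, strand = valid[0], hs
        if min(chosen, L - chosen) < min_overhang:
            return None
        acc, don = suffix_start + chosen, h + chosen
        if acc < 0 or don <= acc:
            return None
        return _ReadAlignment(
            kind="backsplice", strand=strand, acceptor_start=acc, donor_end=don
        )
    # colinear candidate (t > h); gap between segments is constant in b
    gap = (t - h) - (L - A)
    if gap < 0:
        return None
    suffix_start = t + A - L
    pre, suf = _mismatch_profiles(q, gseq, h, suffix_start)
    if gap == 0:
        if pre[L] <= max_mismatch:
            return _ReadAlignment(
                kind="linear", strand=hs, h=h, t=t, L=L, A=A,
                valid_bs=tuple(range(0, L + 1)), gap=0, q=q,
            )
        return None
    valid = tuple(
        b for b in range(1, L) if pre[b] + suf[b] <= max_mismatch
    )
    if not valid:
        return None
    return _ReadAlignment(
        kind="linear", strand=hs, h=h, t=t, L=L, A=A, valid_bs=valid, gap=gap, q=q
    )


# ---- calling ---------------------------------------------------------------


def call_backsplice_junctions(
    reads,
    genome: ToyGenome,
    index: KmerIndex,
    anchor_len: int = 20,
    max_mismatch: int = 0,
    min_overhang: int = 8,
    require_gt_ag: bool = False,
    min_support: int = 5,
    total_raw_reads: int | None = None,
) -> list[BacksplicedJunction]:
    """Call backsplice junctions from a read set.

    ``reads`` is a :class:`~circdigit.simulate.SimulatedReadSet` or anything
    with a ``sequences()`` iterator of (read_id, sequence) pairs (mates share
    a read id and are processed independently; a fragment contributes at most
    one count per junction). Junctions with fewer than ``min_support``
    supporting reads are discarded; RPM is computed against
    ``total_raw_reads`` (default: the number of reads supplied).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    pairs = list(reads.sequences())
    n_total = total_raw_reads if total_raw_reads is not None else len(
        {rid for rid, _ in pairs}
    )
    if n_total <= 0:
        raise ValueError("total_raw_reads must be positive")
    junctions: dict[tuple, BacksplicedJunction] = {}
    n_short = 0
    for rid, seq in pairs:
        if len(seq) < 2 * anchor_len:
            n_short += 1
            continue
        aln = _align_read(
            seq, genome, index, anchor_len, max_mismatch, min_overhang, require_gt_ag
        )
        if aln is None or aln.kind != "backsplice":
            continue
        key = (genome.chrom, aln.strand, aln.acceptor_start, aln.donor_end)
        j = junctions.get(key)
        if j is None:
            j = BacksplicedJunction(
                chrom=genome.chrom,
                strand=aln.strand,
                acceptor_start=aln.acceptor_start,
                donor_end=aln.donor_end,
            )
            junctions[key] = j
        j.read_ids.add(rid)
    if n_short:
        logger.info("skipped %d reads shorter than 2 x anchor_len", n_short)
    out = []
    for j in sorted(junctions.values(), key=lambda x: x.key):
        j.n_junction_reads = len(j.read_ids)
        if j.n_junction_reads < min_support:
            continue
        j.rpm = rpm(j.n_junction_reads, n_total)
        j.ctl = ctl_ratio(j.n_junction_reads, j.n_linear_donor, j.n_linear_acceptor)
        out.append(j)
    return out


def count_linear_spanning(
    reads,
    genome: ToyGenome,
    index: KmerIndex,
    junction: BacksplicedJunction,
    anchor_len: int = 20,
    max_mismatch: int = 0,
    min_overhang: int = 8,
) -> tuple[int, int]:
    """Count linear reads spanning the donor and acceptor sites of a junction.

    A read spans the donor when it aligns colinearly across ``donor_end``
    into downstream sequence — either genomically (one aligned segment covers
    donor_end with ``min_overhang`` on both sides) or through a linear splice
    whose breakpoint falls exactly on donor_end — and likewise across
    ``acceptor_start`` from upstream. Backsplice-supporting reads are
    excluded. Returns ``(n_linear_donor, n_linear_acceptor)``.
    """
    don, acc = junction.donor_end, junction.acceptor_start
    if acc < 0 or don > len(genome):
        raise ValueError("junction coordinates outside genome")
    ov = min_overhang
    donor_ids: set[str] = set()
    acceptor_ids: set[str] = set()
    for rid, seq in reads.sequences():
        if len(seq) < 2 * anchor_len:
            continue
        aln = _align_read(
            seq, genome, index, anchor_len, max_mismatch, min_overhang, False
        )
        if aln is None or aln.kind != "linear":
            continue
        h, t, L, A = aln.h, aln.t, aln.L, aln.A
        if aln.gap == 0:
            segs = [(h, h + L)]
            splice_bs = ()
        else:
            splice_bs = aln.valid_bs
            segs = None  # segment extents depend on b; handled below
        for site, bucket, is_donor in ((don, donor_ids, True), (acc, acceptor_ids, False)):
            hit = False
            if aln.gap == 0:
                s, e = h, h + L
                hit = s <= site - ov and e >= site + ov
            else:
                for b in splice_bs:
                    s1, e1 = h, h + b
                    s2, e2 = t + A - L + b, t + A
                    # genomic continuation inside either segment
                    if (s1 <= site - ov and e1 >= site + ov) or (
                        s2 <= site - ov and e2 >= site + ov
                    ):
                        hit = True
                        break
                    # spliced continuation with the splice exactly at the site
                    if b >= ov and L - b >= ov:
                        if is_donor and e1 == site:
                            hit = True
                            break
                        if not is_donor and s2 == site:
                            hit = True
                            break
            if hit:
                bucket.add(rid)
    return len(donor_ids), len(acceptor_ids)


def annotate_linear_counts(
    junctions: list[BacksplicedJunction],
    reads,
    genome: ToyGenome,
    index: KmerIndex,
    anchor_len: int = 20,
    max_mismatch: int = 0,
    min_overhang: int = 8,
) -> list[BacksplicedJunction]:
    """Fill linear spanning counts and CTL ratios for called junctions."""
    for j in junctions:
        j.n_linear_donor, j.n_linear_acceptor = count_linear_spanning(
            reads, genome, index, j, anchor_len, max_mismatch, min_overhang
        )
        j.ctl = ctl_ratio(j.n_junction_reads, j.n_linear_donor, j.n_linear_acceptor)
    return junctions


# ---- serialization ---------------------------------------------------------

TSV_COLUMNS = (
    "chrom", "start", "end", "strand", "name", "n_junction_reads",
    "n_linear_donor", "n_linear_acceptor", "rpm", "ctl",
)


def write_junction_tsv(junctions: list[BacksplicedJunction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for j in junctions:
            ctl = "NA" if j.ctl is UNDEFINED else repr(j.ctl)
            fh.write(
                "\t".join(
                    [j.chrom, str(j.acceptor_start), str(j.donor_end), j.strand,
                     j.name, str(j.n_junction_reads), str(j.n_linear_donor),
                     str(j.n_linear_acceptor), repr(j.rpm), ctl]
                )
                + "\n"
            )


def write_junction_bed(junctions: list[BacksplicedJunction], path: str | Path) -> None:
    """BED6: score = junction read count."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                "\t".join(
                    [j.chrom, str(j.acceptor_start), str(j.donor_end), j.name,
                     str(j.n_junction_reads), j.strand]
                )
                + "\n"
            )


def read_junction_tsv(path: str | Path) -> list[BacksplicedJunction]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TSV_COLUMNS:
            raise ValueError(f"unexpected junction table header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                BacksplicedJunction(
                    chrom=f[0], strand=f[3], acceptor_start=int(f[1]),
                    donor_end=int(f[2]), n_junction_reads=int(f[5]),
                    n_linear_donor=int(f[6]), n_linear_acceptor=int(f[7]),
                    rpm=float(f[8]), ctl=None if f[9] == "NA" else float(f[9]),
                )
            )
    return out
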