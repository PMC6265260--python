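"""Toy genomes with spliced gene models for circRNA pipeline testing.

A :class:`ToyGenome` is a single synthetic chromosome carrying a handful of
non-overlapping multi-exon genes. Every exon is flanked by canonical splice
signals in genomic orientation (``AG|exon|GT`` for plus-strand genes,
``AC|exon|CT`` for minus-strand genes, the latter being the reverse
complement of GT..AG read on the transcribed strand), so that both linear
splice junctions and every possible exonic backsplice junction carry
canonical GU/AG signals.  Exonic 20-mers are unique genome-wide (counting
both strands), which makes 20-nt anchor mapping unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ANCHOR_UNIQUENESS_K = 20


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A spliced gene: ordered, non-overlapping exons on one strand.

    Coordinates are 0-based half-open genomic intervals sorted by start.
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if end - start < 1:
                raise ValueError("each exon must have length >= 1")
            if start <= prev_end and prev_end >= 0:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class CircleDef:
    """An exonic circle over a contiguous run of host-gene exons.

    ``acceptor_start``/``donor_end`` are the genomic edges of the circularized
    exon block (donor_end > acceptor_start regardless of strand); the
    backsplice covalently joins the transcript 3' end of the block to its
    transcript 5' end.
    """

    gene_id: str
    exon_indices: tuple[int, int]  # inclusive (first, last) index into host exons
    acceptor_start: int
    donor_end: int
    spliced_length: int

    def __post_init__(self):
        if self.donor_end <= self.acceptor_start:
            raise ValueError("donor_end must exceed acceptor_start")

    @property
    def circ_id(self) -> str:
        return f"circ_{self.gene_id}_{self.acceptor_start}_{self.donor_end}"


@dataclass
class ToyGenome:
    """One synthetic chromosome plus its gene models."""

    chrom: str
    sequence: str
    gene_models: list[GeneModel] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.gene_models:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def fetch(self, start: int, end: int) -> str:
        if start < 0 or end > len(self.sequence):
            raise IndexError(f"[{start}, {end}) outside genome of length {len(self)}")
        return self.sequence[start:end]

    # ---- spliced sequences -------------------------------------------------

    def linear_spliced_sequence(self, gene: GeneModel | str) -> str:
        """Mature linear transcript sequence (transcript orientation)."""
        if isinstance(gene, str):
            gene = self.gene(gene)
        seq = "".join(self.fetch(s, e) for s, e in gene.exons)
        return reverse_complement(seq) if gene.strand == "-" else seq

    def circ_spliced_sequence(self, circle: CircleDef) -> str:
        """Spliced circle sequence in transcript orientation.

        Concatenates the circularized exons in genomic order and reverse
        complements for minus-strand hosts; length equals
        ``circle.spliced_length``.
        """
        gene = self.gene(circle.gene_id)
        i, j = circle.exon_indices
        if i < 0 or j >= len(gene.exons):
            raise IndexError("circle exon indices outside host gene")
        seq = "".join(self.fetch(s, e) for s, e in gene.exons[i : j + 1])
        if len(seq) != circle.spliced_length:
            raise ValueError("circle spliced_length inconsistent with exons")
        return reverse_complement(seq) if gene.strand == "-" else seq

    # ---- serialization -----------------------------------------------------

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.sequence), width):
                fh.write(self.sequence[i : i + width] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        """GTF (1-based inclusive) with one transcript per gene."""
        with open(path, "w") as fh:
            for g in self.gene_models:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
                fh.write(
                    "\t".join(
                        [self.chrom, "circdigit", "transcript", str(g.start + 1),
                         str(g.end), ".", g.strand, ".", attrs]
                    )
                    + "\n"
                )
                for s, e in g.exons:
                    fh.write(
                        "\t".join(
                            [self.chrom, "circdigit", "exon", str(s + 1), str(e),
                             ".", g.strand, ".", attrs]
                        )
                        + "\n"
                    )

    def write_bed12(self, path: str | Path) -> None:
        """BED12 (0-based half-open) with blockSizes/blockStarts per gene."""
        with open(path, "w") as fh:
            for g in self.gene_models:
                sizes = ",".join(str(e - s) for s, e in g.exons)
                starts = ",".join(str(s - g.start) for s, e in g.exons)
                fh.write(
                    "\t".join(
                        [self.chrom, str(g.start), str(g.end), g.gene_id, "0",
                         g.strand, str(g.start), str(g.end), "0",
                         str(len(g.exons)), sizes, starts]
                    )
                    + "\n"
                )


def _exonic_kmers_unique(genome: ToyGenome, k: int) -> bool:
    """True if every exonic k-mer occurs exactly once genome-wide (both strands)."""
    seq = genome.sequence
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        counts[km] = counts.get(km, 0) + 1
    for g in genome.gene_models:
        for s, e in g.exons:
            for i in range(s, e - k + 1):
                km = seq[i : i + k]
                rc = reverse_complement(km)
                n = counts.get(km, 0) + (counts.get(rc, 0) if rc != km else 1)
                if n != 1:
                    return False
    return True


def build_toy_genome(
    seed: int,
    n_genes: int = 3,
    exons_per_gene: tuple[int, int] = (3, 5),
    exon_len: tuple[int, int] = (80, 120),
    intron_len: tuple[int, int] = (50, 100),
    *,
    chrom: str = "chrT",
    spacer: int = 60,
    max_attempts: int = 50,
) -> ToyGenome:
    """Build a random repeat-free toy genome.

    Deterministic for a fixed seed. Genes are laid out left to right with
    ``spacer`` nt of intergenic sequence; strands alternate +/-. Canonical
    splice-signal dinucleotides are written into the 2 nt flanking every exon.
    Regenerates (bounded by ``max_attempts``) until all exonic 20-mers are
    unique genome-wide on both strands, so anchor mapping is unambiguous.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for lo, hi in (exons_per_gene, exon_len, intron_len):
        if lo < 1 or hi < lo:
            raise ValueError("ranges must be positive with lo <= hi")
    if intron_len[0] < 4:
        raise ValueError("intron_len lower bound must be >= 4 to host splice signals")
    if spacer < 4:
        raise ValueError("spacer must be >= 4")

    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed, attempt))
        genes: list[GeneModel] = []
        cursor = spacer
        layout: list[tuple[str, list[tuple[int, int]]]] = []
        for gi in range(n_genes):
            n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
            strand = "+" if gi % 2 == 0 else "-"
            exons = []
            pos = cursor
            for ei in range(n_ex):
                elen = int(rng.integers(exon_len[0], exon_len[1] + 1))
                exons.append((pos, pos + elen))
                pos += elen
                if ei < n_ex - 1:
                    pos += int(rng.integers(intron_len[0], intron_len[1] + 1))
            layout.append((strand, exons))
            cursor = pos + spacer
        total = cursor
        bases = np.array(list("ACGT"))
        seq = list(rng.choice(bases, size=total))
        for gi, (strand, exons) in enumerate(layout):
            before, after = ("AG", "GT") if strand == "+" else ("AC", "CT")
            for s, e in exons:
                seq[s - 2] = before[0]
                seq[s - 1] = before[1]
                seq[e] = after[0]
                seq[e + 1] = after[1]
            genes.append(
                GeneModel(gene_id=f"gene{gi + 1}", strand=strand, exons=tuple(exons))
            )
        genome = ToyGenome(chrom=chrom, sequence="".join(seq), gene_models=genes)
        if _exonic_kmers_unique(genome, ANCHOR_UNIQUENESS_K):
            return genome
    raise RuntimeError(
        f"could not build a genome with unique exonic {ANCHOR_UNIQUENESS_K}-mers "
        f"in {max_attempts} attempts; enlarge exon/intron ranges"
    )


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA, returning (name, sequence)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from a BED12 file."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + sz) for o, sz in zip(starts, sizes))
            genes.append(GeneModel(gene_id=f[3], strand=f[5], exons=exons))
    return genes
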