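"""Junction-spanning probe target design for digital circRNA counting.

For each circle a 100-nt target region centered on the backsplice junction
is taken from the circle's spliced sequence (wrapping around the molecule
when the circle is shorter than the window) and split into two adjacent
50-nt halves — the capture and reporter probe target sequences. Because
reporter and capture probes must hybridize immediately adjacent to one
another to produce a signal, a target split exactly at the backsplice
boundary only yields adjacent binding on the circular transcript; on any
linear transcript the two halves are separated, so the junction-centered
sequence must not occur contiguously in the linear genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome import CircleDef, ToyGenome, reverse_complement
from .junctions import KmerIndex


@dataclass
class ProbePair:
    """A 100-nt junction target split into adjacent 50-nt probe targets."""

    circ_id: str
    target_100mer: str
    capture_target: str
    reporter_target: str
    junction_offset: int
    qc_flags: set[str] = field(default_factory=set)

    @property
    def capture_probe(self) -> str:
        """Actual capture oligo sequence (reverse complement of its target)."""
        return reverse_complement(self.capture_target)

    @property
    def reporter_probe(self) -> str:
        return reverse_complement(self.reporter_target)


def circ_spliced_sequence(genome: ToyGenome, circle: CircleDef) -> str:
    """Spliced circle sequence in transcript orientation (see ToyGenome)."""
    return genome.circ_spliced_sequence(circle)


def junction_target_sequence(spliced: str, window: int = 100) -> tuple[str, int]:
    """Junction-centered target from a spliced circle sequence.

    Returns ``(target, junction_offset)``: the last window/2 nt of the circle
    joined to its first window/2 nt. Circles shorter than the window wrap —
    the target is the junction-centered substring of the doubled sequence of
    length ``min(window, len(spliced))`` with the junction at ``len // 2``.
    """
    if window % 2:
        raise ValueError("window must be even")
    if not spliced:
        raise ValueError("spliced sequence must be nonempty")
    m = min(window, len(spliced))
    left = m // 2
    right = m - left
    target = (spliced[-left:] if left else "") + spliced[:right]
    return target, left


def split_probe_pair(target: str, junction_offset: int) -> ProbePair:
    """Split a junction target into adjacent capture/reporter halves.

    The split falls at the midpoint; when the junction is not centered
    (asymmetric window) the pair is flagged ``off_center_junction``.
    """
    if len(target) < 2:
        raise ValueError("target must be at least 2 nt")
    half = len(target) // 2
    flags = set()
    if junction_offset != half:
        flags.add("off_center_junction")
    if len(target) < 100:
        flags.add("wrapped_target")
    return ProbePair(
        circ_id="",
        target_100mer=target,
        capture_target=target[:half],
        reporter_target=target[half:],
        junction_offset=junction_offset,
        qc_flags=flags,
    )


def design_probe(genome: ToyGenome, circle: CircleDef, window: int = 100) -> ProbePair:
    """Design the junction probe pair for one circle."""
    spliced = circ_spliced_sequence(genome, circle)
    target, offset = junction_target_sequence(spliced, window)
    pair = split_probe_pair(target, offset)
    pair.circ_id = circle.circ_id
    return pair


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def probe_qc(
    pair: ProbePair,
    genome: ToyGenome,
    index: KmerIndex | None = None,
    gc_bounds: tuple[float, float] = (0.3, 0.7),
    max_homopolymer: int = 6,
) -> ProbePair:
    """Flag composition and specificity problems on a probe pair.

    Flags: ``gc_out_of_range`` (either half outside gc_bounds),
    ``homopolymer`` (any run longer than max_homopolymer), and
    ``junction_kmer_in_linear_genome`` when the 40-mer centered on the
    junction occurs contiguously in the genome or its reverse complement —
    which a true backsplice target on a repeat-free genome never does.
    """
    for half in (pair.capture_target, pair.reporter_target):
        if not gc_bounds[0] <= _gc_fraction(half) <= gc_bounds[1]:
            pair.qc_flags.add("gc_out_of_range")
    if _max_homopolymer(pair.target_100mer) > max_homopolymer:
        pair.qc_flags.add("homopolymer")
    off = pair.junction_offset
    lo, hi = max(0, off - 20), min(len(pair.target_100mer), off + 20)
    junction_kmer = pair.target_100mer[lo:hi]
    gseq = genome.sequence
    if junction_kmer and (
        junction_kmer in gseq or reverse_complement(junction_kmer) in gseq
    ):
        pair.qc_flags.add("junction_kmer_in_linear_genome")
    return pair


def design_linear_reference_probe(
    genome: ToyGenome,
    gene_id: str,
    window: int = 100,
    gc_bounds: tuple[float, float] = (0.3, 0.7),
    max_homopolymer: int = 6,
) -> ProbePair:
    """Pick a QC-passing 100-mer inside a linear gene's exonic sequence."""
    spliced = genome.linear_spliced_sequence(gene_id)
    if len(spliced) < window:
        raise ValueError(f"{gene_id} spliced sequence shorter than window")
    best = None
    for start in range(0, len(spliced) - window + 1):
        target = spliced[start : start + window]
        half = window // 2
        pair = ProbePair(
            circ_id=gene_id,
            target_100mer=target,
            capture_target=target[:half],
            reporter_target=target[half:],
            junction_offset=half,
        )
        for part in (pair.capture_target, pair.reporter_target):
            if not gc_bounds[0] <= _gc_fraction(part) <= gc_bounds[1]:
                pair.qc_flags.add("gc_out_of_range")
        if _max_homopolymer(target) > max_homopolymer:
            pair.qc_flags.add("homopolymer")
        if not pair.qc_flags:
            return pair
        if best is None:
            best = pair
    return best


def design_codeset(
    genome: ToyGenome,
    circles: list[CircleDef],
    reference_genes: list[str] = (),
    window: int = 100,
    index: KmerIndex | None = None,
    gc_bounds: tuple[float, float] = (0.3, 0.7),
    max_homopolymer: int = 6,
) -> list[ProbePair]:
    """Design the full codeset: one junction pair per circle plus linear
    reference-gene probes."""
    pairs = []
    for c in circles:
        pair = design_probe(genome, c, window)
        probe_qc(pair, genome, index, gc_bounds, max_homopolymer)
        pairs.append(pair)
    for gene_id in reference_genes:
        pairs.append(
            design_linear_reference_probe(genome, gene_id, window, gc_bounds, max_homopolymer)
        )
    return pairs


def write_codeset_tsv(pairs: list[ProbePair], path: str | Path) -> None:
    rows = [
        {
            "circ_id": p.circ_id,
            "target_100mer": p.target_100mer,
            "capture_target": p.capture_target,
            "reporter_target": p.reporter_target,
            "capture_probe_rc": p.capture_probe,
            "reporter_probe_rc": p.reporter_probe,
            "junction_offset": p.junction_offset,
            "flags": ";".join(sorted(p.qc_flags)),
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_target_fasta(pairs: list[ProbePair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.circ_id}\n{p.target_100mer}\n")
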