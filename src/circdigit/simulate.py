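"""Synthetic expression truth, sequencing reads and digital-count data.

This module generates every input the downstream analysis consumes, with the
statistical structure the pipeline assumes: log-normal linear/circular
abundances, reads sampled from spliced linear transcripts and circularized
spliced sequences (backsplice-spanning fragments arise from wrap-around),
optional rolling-circle concatemer artifacts, and nCounter-style lane count
matrices with negative/positive controls, candidate reference genes,
per-lane scale factors, and an RNase R treatment effect (circRNA enrichment,
linear depletion, a designated RNase-R-sensitive subset).

Truth labels are embedded in read names (``<id>|<label>|<template>``) so
caller precision/recall can be measured against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix
from .genome import CircleDef, ToyGenome, reverse_complement

HOUSEKEEPING_NAMES = ("ACTB", "PUM1", "SF3A1", "UBC", "GAPDH")
HOUSEKEEPING_BASE = (4000.0, 2500.0, 1500.0, 1000.0, 800.0)
READ_LABELS = ("linear", "backsplice", "concatemer")


@dataclass
class SyntheticTruth:
    """Ground-truth abundances and treatment design behind a simulation."""

    linear_abundance: dict[str, float]
    circles: list[CircleDef]
    circ_abundance: dict[str, float]
    lane_scale_factors: dict[str, float] = field(default_factory=dict)
    rnase_r_sensitive: set[str] = field(default_factory=set)

    def circle(self, circ_id: str) -> CircleDef:
        for c in self.circles:
            if c.circ_id == circ_id:
                return c
        raise KeyError(circ_id)

    def truth_ctl(self, circ_id: str) -> float:
        """Circular-to-linear abundance ratio implied by the truth."""
        c = self.circle(circ_id)
        return self.circ_abundance[circ_id] / self.linear_abundance[c.gene_id]

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for gene, ab in self.linear_abundance.items():
            rows.append(("linear", gene, ab, ""))
        for c in self.circles:
            rows.append(
                (
                    "circle",
                    c.circ_id,
                    self.circ_abundance[c.circ_id],
                    "sensitive" if c.circ_id in self.rnase_r_sensitive else "",
                )
            )
        pd.DataFrame(rows, columns=["kind", "id", "abundance", "flags"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class SimulatedReadSet:
    """Simulated reads plus per-read truth labels.

    ``reads`` holds ``(read_id, sequence)`` or ``(read_id, sequence, mate)``;
    ``truth_labels`` maps read id -> one of linear/backsplice/concatemer.
    """

    reads: list[tuple]
    truth_labels: dict[str, str]

    def __len__(self) -> int:
        return len(self.reads)

    def sequences(self):
        """Yield (read_id, sequence) for every mate."""
        for rec in self.reads:
            rid = rec[0]
            yield rid, rec[1]
            if len(rec) == 3:
                yield rid, rec[2]

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.reads:
                rid = rec[0]
                for mate_i, seq in enumerate(rec[1:], start=1):
                    name = rid if len(rec) == 2 else f"{rid}/{mate_i}"
                    fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> SimulatedReadSet:
    """Read a FASTQ written by :meth:`SimulatedReadSet.write_fastq`.

    Truth labels are recovered from read names when present (middle ``|``
    field); reads without labels get label ``linear``-agnostic ``""``.
    """
    from Bio import SeqIO

    reads: list[tuple] = []
    labels: dict[str, str] = {}
    by_id: dict[str, list[str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        rid = rec.id.rsplit("/", 1)[0] if rec.id[-2:-1] == "/" else rec.id
        if rid not in by_id:
            by_id[rid] = []
            order.append(rid)
        by_id[rid].append(str(rec.seq).upper())
        parts = rid.split("|")
        labels[rid] = parts[1] if len(parts) >= 2 else ""
    for rid in order:
        reads.append((rid, *by_id[rid]))
    return SimulatedReadSet(reads=reads, truth_labels=labels)


# ---- expression truth ------------------------------------------------------


def simulate_expression_truth(
    genome: ToyGenome,
    seed: int,
    circ_fraction: float = 0.5,
    lognormal_mu: float = 0.0,
    lognormal_sigma: float = 1.5,
    *,
    n_rnase_r_sensitive: int = 0,
) -> SyntheticTruth:
    """Draw log-normal linear/circular abundances and define exonic circles.

    A ``circ_fraction`` subset of genes hosts one circle each over a
    contiguous exon run (internal exons when the gene has >= 3, so that
    linear reads can span both backsplice sites; all exons otherwise).
    """
    if not genome.gene_models:
        raise ValueError("genome has no genes")
    if not 0 < circ_fraction <= 1:
        raise ValueError("circ_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = genome.gene_models
    linear = {
        g.gene_id: float(rng.lognormal(lognormal_mu, lognormal_sigma)) for g in genes
    }
    n_circ = max(1, int(round(circ_fraction * len(genes))))
    host_idx = sorted(rng.choice(len(genes), size=n_circ, replace=False).tolist())
    circles: list[CircleDef] = []
    circ_ab: dict[str, float] = {}
    for gi in host_idx:
        g = genes[gi]
        n_ex = len(g.exons)
        if n_ex >= 3:
            # internal exons only, so linear reads can span both sites
            lo_pool, hi_pool = 1, n_ex - 2
            i = int(rng.integers(lo_pool, hi_pool + 1))
            j = int(rng.integers(i, hi_pool + 1))
        else:
            i, j = 0, n_ex - 1  # short genes circularize whole
        block = g.exons[i : j + 1]
        circle = CircleDef(
            gene_id=g.gene_id,
            exon_indices=(i, j),
            acceptor_start=block[0][0],
            donor_end=block[-1][1],
            spliced_length=sum(e - s for s, e in block),
        )
        circles.append(circle)
        circ_ab[circle.circ_id] = float(rng.lognormal(lognormal_mu, lognormal_sigma))
    sensitive: set[str] = set()
    if n_rnase_r_sensitive:
        if n_rnase_r_sensitive > len(circles):
            raise ValueError("more sensitive circles requested than circles exist")
        picks = rng.choice(len(circles), size=n_rnase_r_sensitive, replace=False)
        sensitive = {circles[int(p)].circ_id for p in picks}
    return SyntheticTruth(
        linear_abundance=linear,
        circles=circles,
        circ_abundance=circ_ab,
        rnase_r_sensitive=sensitive,
    )


# ---- read simulation -------------------------------------------------------


def _junction_crossings(start: int, length: int, circumference: int) -> list[int]:
    """Offsets (within a fragment of ``length`` starting at ``start`` on the
    doubled circle) at which the backsplice boundary is crossed."""
    crossings = []
    c = circumference - start
    while c < length:
        if c > 0:
            crossings.append(c)
        c += circumference
    return crossings


def simulate_read_set(
    genome: ToyGenome,
    truth: SyntheticTruth,
    n_fragments: int,
    read_len: int = 100,
    seed: int = 0,
    error_rate: float = 0.0,
    concatemer_rate: float = 0.0,
    min_overhang: int = 8,
    *,
    paired: bool = False,
) -> SimulatedReadSet:
    """Sample ``n_fragments`` fragments from linear and circular transcripts.

    Fragment counts per template are multinomial in the truth abundances.
    Circle fragments are drawn from the wrap-around (doubled) spliced
    sequence; with probability ``concatemer_rate`` a fragment comes from a
    rolling-circle template longer than the circle itself and is labelled
    ``concatemer``. A read crossing the backsplice boundary with at least
    ``min_overhang`` nt on both sides is labelled ``backsplice``; everything
    else is ``linear``. Fragments are drawn from either strand with p = 0.5.
    """
    if read_len < 2 * min_overhang:
        raise ValueError("read_len must be >= 2 * min_overhang")
    if not (0 <= error_rate <= 1 and 0 <= concatemer_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    frag_len = 2 * read_len if paired else read_len

    templates = []  # (name, seq, weight, circumference or None)
    for g in genome.gene_models:
        ab = truth.linear_abundance[g.gene_id]
        if ab <= 0:
            continue
        seq = genome.linear_spliced_sequence(g)
        if len(seq) < frag_len:
            raise ValueError(
                f"linear transcript {g.gene_id} ({len(seq)} nt) shorter than "
                f"fragment length {frag_len}"
            )
        templates.append((g.gene_id, seq, ab, None))
    for c in truth.circles:
        ab = truth.circ_abundance[c.circ_id]
        if ab <= 0:
            continue
        if c.spliced_length < read_len and concatemer_rate == 0:
            raise ValueError(
                f"{c.circ_id}: spliced length {c.spliced_length} < read length "
                f"{read_len} with concatemer_rate=0"
            )
        templates.append((c.circ_id, genome.circ_spliced_sequence(c), ab, c.spliced_length))
    if not templates:
        raise ValueError("no expressed templates to sample from")

    rng = np.random.default_rng(seed)
    weights = np.array([t[2] for t in templates], dtype=float)
    counts = rng.multinomial(n_fragments, weights / weights.sum())

    bases = np.array(list("ACGT"))
    reads: list[tuple] = []
    labels: dict[str, str] = {}
    idx = 0
    for (name, seq, _ab, circumference), n_t in zip(templates, counts):
        for _ in range(int(n_t)):
            if circumference is None:
                start = int(rng.integers(0, len(seq) - frag_len + 1))
                frag = seq[start : start + frag_len]
                label = "linear"
            else:
                s = circumference
                is_concat = rng.random() < concatemer_rate
                if is_concat:
                    this_len = max(frag_len, s + int(rng.integers(1, s + 1)))
                else:
                    this_len = frag_len
                start = int(rng.integers(0, s))
                rolled = seq * (this_len // s + 2)
                frag = rolled[start : start + this_len]
                if this_len > s:
                    label = "concatemer"
                else:
                    span = [
                        c
                        for c in _junction_crossings(start, min(read_len, this_len), s)
                        if min_overhang <= c <= read_len - min_overhang
                    ]
                    label = "backsplice" if span else "linear"
            if rng.random() < 0.5:
                frag = reverse_complement(frag)
            if error_rate > 0:
                frag_arr = np.array(list(frag))
                hit = rng.random(len(frag_arr)) < error_rate
                if hit.any():
                    subs = rng.integers(1, 4, size=int(hit.sum()))
                    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
                    for pos, shift in zip(np.nonzero(hit)[0], subs):
                        frag_arr[pos] = bases[(lut[frag_arr[pos]] + shift) % 4]
                    frag = "".join(frag_arr)
            rid = f"r{idx:06d}|{label}|{name}"
            idx += 1
            if paired:
                mate1 = frag[:read_len]
                mate2 = reverse_complement(frag[-read_len:])
                reads.append((rid, mate1, mate2))
            else:
                reads.append((rid, frag[:read_len]))
            labels[rid] = label
    return SimulatedReadSet(reads=reads, truth_labels=labels)


# ---- nCounter count simulation ---------------------------------------------

DEFAULT_POS_LADDER = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)  # geometric, ratio 4


def simulate_nanostring_counts(
    truth: SyntheticTruth,
    n_lanes: int,
    seed: int,
    neg_mean: float = 2.0,
    pos_ladder: tuple[float, ...] = DEFAULT_POS_LADDER,
    pos_scale: float = 800.0,
    noise: float = 0.1,
    *,
    lane_scales: tuple[float, ...] | None = None,
    endogenous_scale: float = 200.0,
    hk_names: tuple[str, ...] = HOUSEKEEPING_NAMES,
    hk_base: tuple[float, ...] = HOUSEKEEPING_BASE,
    rcc_dir: str | Path | None = None,
) -> CountMatrix:
    """Simulate a raw nCounter lane matrix from the expression truth.

    count(target, lane) = round(lane_scale * expected * lognormal(sd=noise))
    + Poisson(neg_mean) background, with expected = endogenous_scale *
    circle abundance for Endogenous probes, a fixed base level for the five
    Housekeeping candidates, pos_scale * concentration for Positive spikes,
    and 0 for Negatives. Lane scale factors are drawn log-normally unless
    given, and recorded on ``truth.lane_scale_factors``. If ``rcc_dir`` is
    set, one RCC file per lane is written.
    """
    if n_lanes < 1:
        raise ValueError("n_lanes must be >= 1")
    if neg_mean < 0:
        raise ValueError("neg_mean must be >= 0")
    if len(pos_ladder) < 4 or any(
        b >= a for a, b in zip(pos_ladder, pos_ladder[1:])
    ):
        raise ValueError("pos_ladder must be strictly decreasing with >= 4 entries")
    if len(hk_base) != len(hk_names):
        raise ValueError("hk_base and hk_names lengths differ")
    rng = np.random.default_rng(seed)
    if lane_scales is None:
        scales = np.exp(rng.normal(0.0, 0.15, size=n_lanes))
    else:
        if len(lane_scales) != n_lanes:
            raise ValueError("lane_scales length must equal n_lanes")
        scales = np.asarray(lane_scales, dtype=float)
    lanes = [f"lane{i + 1:02d}" for i in range(n_lanes)]
    truth.lane_scale_factors = dict(zip(lanes, scales.tolist()))

    names: list[str] = []
    classes: list[str] = []
    expected: list[float] = []
    for c in truth.circles:
        names.append(c.circ_id)
        classes.append("Endogenous")
        expected.append(endogenous_scale * truth.circ_abundance[c.circ_id])
    for nm, base in zip(hk_names, hk_base):
        names.append(nm)
        classes.append("Housekeeping")
        expected.append(float(base))
    for i, conc in enumerate(pos_ladder):
        names.append(f"POS_{chr(ord('A') + i)}")
        classes.append("Positive")
        expected.append(pos_scale * conc)
    for i in range(6):
        names.append(f"NEG_{chr(ord('A') + i)}")
        classes.append("Negative")
        expected.append(0.0)

    exp_arr = np.array(expected)
    data = np.zeros((len(names), n_lanes))
    for li, scale in enumerate(scales):
        if noise > 0:
            factor = np.exp(rng.normal(0.0, noise, size=len(names)))
        else:
            factor = np.ones(len(names))
        lane_counts = np.round(scale * exp_arr * factor)
        background = rng.poisson(neg_mean, size=len(names)) if neg_mean > 0 else 0
        data[:, li] = lane_counts + background
    matrix = CountMatrix(
        pd.DataFrame(data, index=names, columns=lanes),
        pd.Series(classes, index=names),
        "raw",
    )
    if rcc_dir is not None:
        from .countmatrix import write_rcc

        write_rcc(matrix, rcc_dir)
    return matrix


def apply_rnase_r(
    matrix: CountMatrix,
    truth: SyntheticTruth,
    circ_enrichment: float = 6.0,
    linear_depletion: float = 4.0,
    sensitive_depletion: float = 4.0,
    seed: int = 0,
    *,
    resample: bool = True,
) -> CountMatrix:
    """Simulate RNase R treatment on a raw count matrix.

    Expected treated counts: mock x circ_enrichment for RNase-R-resistant
    circles, mock / linear_depletion for Housekeeping (linear) targets,
    mock / sensitive_depletion for circles in ``truth.rnase_r_sensitive``.
    Negative/Positive control expectations are untouched. Counts are Poisson
    resampled around the expectation unless ``resample=False``.
    """
    for v in (circ_enrichment, linear_depletion, sensitive_depletion):
        if v <= 0:
            raise ValueError("all RNase R factors must be > 0")
    matrix.require_stage("raw")
    rng = np.random.default_rng(seed)
    expected = matrix.counts.copy()
    for name in matrix.targets:
        cc = matrix.code_class[name]
        if cc == "Endogenous":
            if name in truth.rnase_r_sensitive:
                expected.loc[name] /= sensitive_depletion
            else:
                expected.loc[name] *= circ_enrichment
        elif cc == "Housekeeping":
            expected.loc[name] /= linear_depletion
    if resample:
        treated = rng.poisson(expected.values).astype(float)
    else:
        treated = np.round(expected.values)
    out = matrix.copy_with(
        pd.DataFrame(treated, index=matrix.targets, columns=matrix.samples), "raw"
    )
    return out


# ---- RNA-quality metric ----------------------------------------------------


def dv200(fragment_lengths, counts=None) -> float:
    """Fraction of RNA fragments longer than 200 nt.

    ``fragment_lengths`` is an array of lengths, optionally weighted by
    ``counts`` (an empirical length distribution). Returns a value in [0, 1].
    """
    lengths = np.asarray(fragment_lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("at least one fragment is required")
    if counts is None:
        weights = np.ones_like(lengths)
    else:
        weights = np.asarray(counts, dtype=float)
        if weights.shape != lengths.shape:
            raise ValueError("counts must match fragment_lengths in shape")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total fragment count must be positive")
    return float(weights[lengths > 200].sum() / total)
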