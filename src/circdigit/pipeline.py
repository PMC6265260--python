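"""End-to-end pipeline: simulate -> call -> design -> normalize -> enrich ->
compare -> cluster, with validated config, per-stage seeding and a manifest.

A single global seed is expanded into independent per-stage seeds by stable
hashing, so changing one stage's parameters never perturbs another stage's
randomness. Every run writes a JSON manifest recording the config, the
per-stage outputs and their SHA-256 checksums; reruns with the same seed and
config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .countmatrix import CountMatrix, load_rcc_dir, write_rcc
from .genome import build_toy_genome
from .junctions import (
    annotate_linear_counts,
    build_kmer_index,
    call_backsplice_junctions,
    rpm as rpm_of,
    write_junction_bed,
    write_junction_tsv,
)
from .nanostring import (
    enrichment_summary,
    enrichment_to_frame,
    normalize_cascade,
    reference_gene_normalize,
)
from .probes import design_codeset, write_codeset_tsv, write_target_fasta
from .simulate import (
    apply_rnase_r,
    simulate_expression_truth,
    simulate_nanostring_counts,
    simulate_read_set,
)
from .stats import dichotomize_and_crosstab, fit_simple_regression, pearson_average_linkage, zscore_rows

STAGE_ORDER = ("simulate", "call", "design", "normalize", "enrich", "compare", "cluster")


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


# ---- config ----------------------------------------------------------------


@dataclass
class SimulateConfig:
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_len: tuple[int, int] = (80, 120)
    intron_len: tuple[int, int] = (50, 100)
    circ_fraction: float = 0.8
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.2
    n_rnase_r_sensitive: int = 1
    n_fragments: int = 30000
    read_len: int = 100
    error_rate: float = 0.0
    concatemer_rate: float = 0.02
    min_overhang: int = 8
    n_lanes: int = 3
    noise: float = 0.1
    neg_mean: float = 2.0


@dataclass
class CallConfig:
    anchor_len: int = 20
    max_mismatch: int = 0
    min_overhang: int = 8
    require_gt_ag: bool = False
    min_support: int = 5


@dataclass
class DesignConfig:
    window: int = 100
    gc_bounds: tuple[float, float] = (0.3, 0.7)
    max_homopolymer: int = 6


@dataclass
class NormalizeConfig:
    n_refs: int = 4
    stability_method: str = "cv_log"
    background_method: str = "mean_neg"
    zero_policy: float = 0.5


@dataclass
class EnrichConfig:
    circ_enrichment: float = 6.0
    linear_depletion: float = 4.0
    sensitive_depletion: float = 4.0
    expressed_min: float = 20.0
    use_normalized: bool = True


@dataclass
class CompareConfig:
    cutoff_nanostring: float = 20.0
    cutoff_junction_reads: float = 2.0  # RPM cutoff is this / total reads x 1e6
    exclude: tuple[str, ...] = ()
    log_scale: bool = False


@dataclass
class ClusterConfig:
    axis: str = "samples"


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "circdigit_run"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    call: CallConfig = field(default_factory=CallConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    normalize: NormalizeConfig = field(default_factory=NormalizeConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _dataclass_from_dict(cls, data, path="")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return _tuples_to_lists(dataclasses.asdict(self))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _dataclass_from_dict(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = path or "top level"
        raise ValueError(f"unknown config key(s) at {where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.default_factory, type) and dataclasses.is_dataclass(f.default_factory)
        ):
            sub_cls = f.default_factory
            kwargs[name] = _dataclass_from_dict(sub_cls, value, f"{path}{name}.")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


# ---- pipeline --------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on synthetic data; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "circdigit",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
    }

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "seed": derive_stage_seed(config.seed, stage),
                "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
            }
        )

    # -- simulate
    sim = config.simulate
    seed_sim = derive_stage_seed(config.seed, "simulate")
    genome = build_toy_genome(
        seed_sim,
        n_genes=sim.n_genes,
        exons_per_gene=sim.exons_per_gene,
        exon_len=sim.exon_len,
        intron_len=sim.intron_len,
    )
    truth = simulate_expression_truth(
        genome,
        seed_sim + 1,
        circ_fraction=sim.circ_fraction,
        lognormal_mu=sim.lognormal_mu,
        lognormal_sigma=sim.lognormal_sigma,
        n_rnase_r_sensitive=sim.n_rnase_r_sensitive,
    )
    reads = simulate_read_set(
        genome,
        truth,
        n_fragments=sim.n_fragments,
        read_len=sim.read_len,
        seed=seed_sim + 2,
        error_rate=sim.error_rate,
        concatemer_rate=sim.concatemer_rate,
        min_overhang=sim.min_overhang,
    )
    mock = simulate_nanostring_counts(
        truth, sim.n_lanes, seed_sim + 3, neg_mean=sim.neg_mean, noise=sim.noise
    )
    enr = config.enrich
    treated = apply_rnase_r(
        mock,
        truth,
        circ_enrichment=enr.circ_enrichment,
        linear_depletion=enr.linear_depletion,
        sensitive_depletion=enr.sensitive_depletion,
        seed=seed_sim + 4,
    )
    fasta = out / "genome.fa"
    gtf = out / "genes.gtf"
    bed = out / "genes.bed12"
    fastq = out / "reads.fq"
    truth_tsv = out / "truth.tsv"
    genome.write_fasta(fasta)
    genome.write_gtf(gtf)
    genome.write_bed12(bed)
    reads.write_fastq(fastq)
    truth.to_tsv(truth_tsv)
    mock_dir = out / "rcc_mock"
    treated_dir = out / "rcc_treated"
    mock_paths = write_rcc(mock, mock_dir)
    treated_paths = write_rcc(treated, treated_dir)
    record("simulate", [fasta, gtf, bed, fastq, truth_tsv, *mock_paths, *treated_paths])

    # -- call
    callc = config.call
    index = build_kmer_index(genome, callc.anchor_len)
    junctions = call_backsplice_junctions(
        reads,
        genome,
        index,
        anchor_len=callc.anchor_len,
        max_mismatch=callc.max_mismatch,
        min_overhang=callc.min_overhang,
        require_gt_ag=callc.require_gt_ag,
        min_support=callc.min_support,
        total_raw_reads=len(reads),
    )
    annotate_linear_counts(
        junctions, reads, genome, index,
        anchor_len=callc.anchor_len,
        max_mismatch=callc.max_mismatch,
        min_overhang=callc.min_overhang,
    )
    jt = out / "junctions.tsv"
    jb = out / "junctions.bed"
    write_junction_tsv(junctions, jt)
    write_junction_bed(junctions, jb)
    record("call", [jt, jb])

    # -- design
    des = config.design
    codeset = design_codeset(
        genome,
        truth.circles,
        reference_genes=[],
        window=des.window,
        index=index,
        gc_bounds=des.gc_bounds,
        max_homopolymer=des.max_homopolymer,
    )
    ct = out / "codeset.tsv"
    cf = out / "targets.fa"
    write_codeset_tsv(codeset, ct)
    write_target_fasta(codeset, cf)
    record("design", [ct, cf])

    # -- normalize (reload the written RCC lanes: exercises the interchange)
    norm = config.normalize
    mock_raw = load_rcc_dir(mock_dir)
    normalized, refs = normalize_cascade(
        mock_raw,
        n_refs=norm.n_refs,
        stability_method=norm.stability_method,
        background_method=norm.background_method,
        zero_policy=norm.zero_policy,
    )
    nt = out / "normalized.tsv"
    normalized.to_tsv(nt)
    (out / "reference_genes.txt").write_text("\n".join(refs) + "\n")
    record("normalize", [nt, out / "reference_genes.txt"])

    # -- enrich (paired lane 1 mock vs treated)
    treated_raw = load_rcc_dir(treated_dir)
    lane = mock_raw.samples[0]

    def single(m: CountMatrix) -> CountMatrix:
        return CountMatrix(m.counts[[lane]], m.code_class.copy(), m.stage)

    mock_lane_raw = single(mock_raw)
    treated_lane_raw = single(treated_raw)
    mock_lane_norm, _ = normalize_cascade(
        mock_lane_raw, reference_candidates=refs, n_refs=len(refs),
        background_method=norm.background_method, zero_policy=norm.zero_policy,
    )
    treated_lane_norm, _ = normalize_cascade(
        treated_lane_raw, reference_candidates=refs, n_refs=len(refs),
        background_method=norm.background_method, zero_policy=norm.zero_policy,
    )
    records, averages = enrichment_summary(
        mock_lane_norm,
        treated_lane_norm,
        mock_lane_raw,
        treated_lane_raw,
        expressed_min=enr.expressed_min,
        use_normalized=enr.use_normalized,
    )
    et = out / "enrichment.tsv"
    enrichment_to_frame(records).to_csv(et, sep="\t", index=False)
    ea = out / "enrichment_class_averages.json"
    ea.write_text(json.dumps(averages, indent=2, sort_keys=True) + "\n")
    record("enrich", [et, ea])

    # -- compare (NanoString normalized counts vs RNA-seq RPM per circle)
    cmp_cfg = config.compare
    by_coord = {(j.acceptor_start, j.donor_end): j for j in junctions}
    rows = []
    for c in truth.circles:
        if c.circ_id in cmp_cfg.exclude:
            continue
        j = by_coord.get((c.acceptor_start, c.donor_end))
        rows.append(
            {
                "circ_id": c.circ_id,
                "nanostring": float(
                    normalized.counts.loc[c.circ_id].mean()
                ),
                "rpm": j.rpm if j is not None else 0.0,
                "n_junction_reads": j.n_junction_reads if j is not None else 0,
            }
        )
    cmp_df = pd.DataFrame(rows)
    xs = cmp_df["rpm"].to_numpy()
    ys = cmp_df["nanostring"].to_numpy()
    if cmp_cfg.log_scale:
        xs, ys = np.log10(xs + 1), np.log10(ys + 1)
    fit = fit_simple_regression(xs, ys)
    cutoff_rpm = rpm_of(int(cmp_cfg.cutoff_junction_reads), len(reads))
    tab, ns_only, seq_only = dichotomize_and_crosstab(
        cmp_df["nanostring"], cmp_cfg.cutoff_nanostring,
        cmp_df["rpm"], cutoff_rpm,
        labels=list(cmp_df["circ_id"]),
    )
    comparison = {
        "regression": dataclasses.asdict(fit),
        "contingency": {"a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
                        "p_two_tailed": tab.p_two_tailed},
        "cutoffs": {"nanostring": cmp_cfg.cutoff_nanostring, "rpm": cutoff_rpm},
        "nanostring_only": ns_only,
        "rnaseq_only": seq_only,
    }
    cpj = out / "comparison.json"
    cpv = out / "comparison_values.tsv"
    cmp_df.to_csv(cpv, sep="\t", index=False)
    cpj.write_text(json.dumps(comparison, indent=2, sort_keys=True) + "\n")
    record("compare", [cpj, cpv])

    # -- cluster
    endo = normalized.class_counts("Endogenous")
    z, flagged = zscore_rows(endo)
    dend = pearson_average_linkage(z, axis=config.cluster.axis)
    zt = out / "zscores.tsv"
    nwk = out / "clustering.nwk"
    z.to_csv(zt, sep="\t")
    nwk.write_text(dend.to_newick() + "\n")
    record("cluster", [zt, nwk])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
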