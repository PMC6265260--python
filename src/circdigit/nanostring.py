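"""nCounter-style normalization cascade and RNase R enrichment analysis.

The cascade runs in a fixed order on a raw :class:`CountMatrix`:

1. background subtraction — per lane, the mean of the negative-control
   counts is subtracted from every biological target (floored at zero);
2. positive-control normalization — each lane is scaled by
   (mean over lanes of the per-lane geometric mean of positive controls) /
   (this lane's positive geometric mean), removing lane-to-lane technical
   yield differences;
3. reference-gene (content) normalization — same construction on the
   geometric mean of the chosen stable linear reference genes.

The output of step 3 is the "normalized count" used everywhere downstream.

RNase R validation compares a mock-treated and an RNase-R-treated lane. The
signed fold change is treated/mock when the target is enriched and
-(mock/treated) when it is depleted, so a value of +6 means sixfold
enrichment and -4 fourfold depletion; resistant circRNAs are expected
around +6 and linear transcripts around -4 under the default treatment
strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix

UNDEFINED = None

FACTOR_QC_BAND = (0.3, 3.0)


def geometric_mean(values, zero_policy: float | str = 0.5) -> float:
    """Geometric mean with an explicit zero policy.

    ``zero_policy`` is either a pseudocount replacing zeros (default 0.5) or
    the string ``"exclude"`` to drop them; raises if nothing remains.
    """
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("values must be nonnegative")
    if zero_policy == "exclude":
        arr = arr[arr > 0]
    else:
        arr = np.where(arr == 0, float(zero_policy), arr)
    if arr.size == 0:
        raise ValueError("no values left after zero policy")
    return float(np.exp(np.mean(np.log(arr))))


def background_subtract(matrix: CountMatrix, method: str = "mean_neg") -> CountMatrix:
    """Subtract the per-lane negative-control background from biological targets.

    ``method``: ``mean_neg`` (mean of negatives, as used throughout) or
    ``mean_neg_2sd`` (mean + 2 SD, a common stricter alternative). Counts are
    floored at 0; Negative/Positive rows are retained unmodified for audit.
    """
    matrix.require_stage("raw")
    negatives = matrix.class_counts("Negative")
    if negatives.empty:
        raise ValueError("matrix has no Negative targets")
    if method == "mean_neg":
        background = negatives.mean(axis=0)
    elif method == "mean_neg_2sd":
        background = negatives.mean(axis=0) + 2 * negatives.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown background method {method!r}")
    counts = matrix.counts.copy()
    bio = matrix.code_class.isin(["Endogenous", "Housekeeping"])
    counts.loc[bio] = (counts.loc[bio] - background).clip(lower=0)
    return matrix.copy_with(counts, "background_subtracted")


def positive_control_normalize(matrix: CountMatrix, zero_policy: float | str = 0.5) -> CountMatrix:
    """Scale lanes so positive-control geometric means agree.

    Lane factor = (arithmetic mean across lanes of per-lane positive
    geometric means) / (this lane's positive geometric mean). Endogenous,
    Housekeeping and Positive counts are scaled (so post-normalization
    positive geomeans are equal); Negatives stay raw for audit. Factors
    outside the conventional [0.3, 3] QC band are flagged with a warning.
    """
    matrix.require_stage("background_subtracted")
    pos = matrix.class_counts("Positive")
    if len(pos) < 2:
        raise ValueError("need >= 2 Positive targets")
    geomeans = pos.apply(lambda col: geometric_mean(col, zero_policy), axis=0)
    if (geomeans == 0).any():
        raise ValueError("a lane's positive-control geometric mean is zero")
    factors = geomeans.mean() / geomeans
    outside = factors[(factors < FACTOR_QC_BAND[0]) | (factors > FACTOR_QC_BAND[1])]
    if not outside.empty:
        warnings.warn(
            f"positive-control factors outside QC band {FACTOR_QC_BAND}: "
            f"{outside.to_dict()}"
        )
    counts = matrix.counts.copy()
    scaled = matrix.code_class.isin(["Endogenous", "Housekeeping", "Positive"])
    counts.loc[scaled] = counts.loc[scaled] * factors
    out = matrix.copy_with(counts, "positive_normalized")
    out.norm_factors["positive"] = factors
    return out


def select_stable_references(
    matrix: CountMatrix,
    candidates: list[str],
    k: int = 4,
    method: str = "cv_log",
    zero_policy: float | str = 0.5,
) -> list[str]:
    """Rank candidate reference genes by cross-lane stability, return top k.

    ``cv_log`` ranks by the standard deviation of log2 counts across lanes
    (ties broken by name). ``genorm_pairwise`` iteratively removes the gene
    with the highest mean pairwise log-ratio variation (the geNorm M
    statistic) until k remain.
    """
    hk = set(matrix.class_targets("Housekeeping"))
    unknown = [c for c in candidates if c not in hk]
    if unknown:
        raise ValueError(f"candidates not among Housekeeping targets: {unknown}")
    if k > len(candidates):
        raise ValueError("k exceeds the number of candidates")
    if len(matrix.samples) < 2:
        raise ValueError("need >= 2 lanes to assess stability")
    sub = matrix.counts.loc[list(candidates)]
    pseudo = 0.5 if zero_policy == "exclude" else float(zero_policy)
    logs = np.log2(sub.where(sub > 0, pseudo))
    if method == "cv_log":
        sd = logs.std(axis=1, ddof=1)
        order = sorted(candidates, key=lambda c: (sd[c], c))
        return order[:k]
    if method == "genorm_pairwise":
        remaining = list(candidates)
        removed = []
        while len(remaining) > k:
            m_stats = {}
            for g in remaining:
                vs = [
                    float((logs.loc[g] - logs.loc[other]).std(ddof=1))
                    for other in remaining
                    if other != g
                ]
                m_stats[g] = float(np.mean(vs))
            worst = max(remaining, key=lambda g: (m_stats[g], g))
            remaining.remove(worst)
            removed.append(worst)
        return sorted(remaining, key=lambda c: c)
    raise ValueError(f"unknown stability method {method!r}")


def reference_gene_normalize(
    matrix: CountMatrix, refs: list[str], zero_policy: float | str = 0.5
) -> CountMatrix:
    """Content normalization against stable linear reference genes.

    Lane factor = (mean across lanes of the per-lane geometric mean of the
    reference genes) / (this lane's reference geometric mean); Endogenous and
    Housekeeping counts are scaled. Output carries the
    ``reference_normalized`` stage tag — the "normalized counts" used by all
    downstream comparisons.
    """
    matrix.require_stage("positive_normalized")
    if not refs:
        raise ValueError("refs must be nonempty")
    missing = [r for r in refs if r not in matrix.counts.index]
    if missing:
        raise ValueError(f"reference genes absent from matrix: {missing}")
    sub = matrix.counts.loc[list(refs)]
    geomeans = sub.apply(lambda col: geometric_mean(col, zero_policy), axis=0)
    if (geomeans == 0).any():
        raise ValueError("a lane's reference-gene geometric mean is zero")
    factors = geomeans.mean() / geomeans
    counts = matrix.counts.copy()
    bio = matrix.code_class.isin(["Endogenous", "Housekeeping"])
    counts.loc[bio] = counts.loc[bio] * factors
    out = matrix.copy_with(counts, "reference_normalized")
    out.norm_factors["reference"] = factors
    return out


def normalize_cascade(
    matrix: CountMatrix,
    reference_candidates: list[str] | None = None,
    n_refs: int = 4,
    stability_method: str = "cv_log",
    background_method: str = "mean_neg",
    zero_policy: float | str = 0.5,
) -> tuple[CountMatrix, list[str]]:
    """Run the full cascade; returns the normalized matrix and chosen refs."""
    stage1 = background_subtract(matrix, background_method)
    stage2 = positive_control_normalize(stage1, zero_policy)
    candidates = reference_candidates or stage2.class_targets("Housekeeping")
    if len(matrix.samples) >= 2 and n_refs < len(candidates):
        refs = select_stable_references(
            stage2, candidates, n_refs, stability_method, zero_policy
        )
    else:
        refs = list(candidates)[: max(n_refs, 1)]
    stage3 = reference_gene_normalize(stage2, refs, zero_policy)
    return stage3, refs


# ---- RNase R enrichment ----------------------------------------------------


def signed_fold_change(treated: float, mock: float) -> float | None:
    """Signed fold change between treated and mock counts.

    treated > mock -> treated/mock; treated < mock -> -(mock/treated);
    equal -> +1.0. Undefined (None) when either side is zero while the other
    is positive, or both are zero.
    """
    if treated < 0 or mock < 0:
        raise ValueError("counts must be nonnegative")
    if treated == mock:
        if treated == 0:
            return UNDEFINED
        return 1.0
    if treated == 0 or mock == 0:
        return UNDEFINED
    if treated > mock:
        return treated / mock
    return -(mock / treated)


@dataclass
class EnrichmentRecord:
    """Mock vs RNase-R-treated counts for one target."""

    target: str
    code_class: str
    mock: float
    treated: float
    raw_mock: float
    raw_treated: float
    signed_fc: float | None
    enriched_2x: bool
    enriched_50ct: bool
    expressed: bool


def enrichment_summary(
    mock_matrix: CountMatrix,
    treated_matrix: CountMatrix,
    raw_mock: CountMatrix,
    raw_treated: CountMatrix,
    expressed_min: float = 20.0,
    use_normalized: bool = True,
) -> tuple[list[EnrichmentRecord], dict[str, float]]:
    """Per-target RNase R enrichment records and per-class average fold changes.

    Inputs are paired single-lane matrices (normalized and raw scales for
    mock and treated). ``enriched_2x`` means treated > 2 x mock on the
    analysis scale; ``enriched_50ct`` means a raw-count increase > 50. Class
    averages are means of signed fold changes over *expressed* targets
    (mock >= ``expressed_min`` on the analysis scale) in the Endogenous and
    Housekeeping classes — under RNase R the circRNA average is expected
    positive (~ the enrichment factor) and the linear average negative.
    """
    for m in (mock_matrix, treated_matrix, raw_mock, raw_treated):
        if len(m.samples) != 1:
            raise ValueError("enrichment expects single-lane matrices")
    targets = mock_matrix.targets
    for m in (treated_matrix, raw_mock, raw_treated):
        if m.targets != targets:
            raise ValueError("matrices do not share an identical target set")
    records = []
    for name in targets:
        cc = mock_matrix.code_class[name]
        if cc not in ("Endogenous", "Housekeeping"):
            continue
        mock_n = float(mock_matrix.counts.loc[name].iloc[0])
        treat_n = float(treated_matrix.counts.loc[name].iloc[0])
        mock_r = float(raw_mock.counts.loc[name].iloc[0])
        treat_r = float(raw_treated.counts.loc[name].iloc[0])
        mock_v, treat_v = (mock_n, treat_n) if use_normalized else (mock_r, treat_r)
        fc = signed_fold_change(treat_v, mock_v)
        records.append(
            EnrichmentRecord(
                target=name,
                code_class=cc,
                mock=mock_v,
                treated=treat_v,
                raw_mock=mock_r,
                raw_treated=treat_r,
                signed_fc=fc,
                enriched_2x=treat_v > 2 * mock_v,
                enriched_50ct=(treat_r - mock_r) > 50,
                expressed=mock_v >= expressed_min,
            )
        )
    averages: dict[str, float] = {}
    for cc in ("Endogenous", "Housekeeping"):
        fcs = [
            r.signed_fc
            for r in records
            if r.code_class == cc and r.expressed and r.signed_fc is not None
        ]
        if fcs:
            averages[cc] = float(np.mean(fcs))
    return records, averages


def enrichment_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target": r.target,
                "code_class": r.code_class,
                "mock": r.mock,
                "treated": r.treated,
                "raw_mock": r.raw_mock,
                "raw_treated": r.raw_treated,
                "signed_fc": np.nan if r.signed_fc is None else r.signed_fc,
                "enriched_2x": r.enriched_2x,
                "enriched_50ct": r.enriched_50ct,
                "expressed": r.expressed,
            }
            for r in records
        ]
    )
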