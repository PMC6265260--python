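"""Normalization cascade, RCC parsing, reference selection, RNase R records."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circdigit import (
    apply_rnase_r,
    background_subtract,
    enrichment_summary,
    geometric_mean,
    normalize_cascade,
    positive_control_normalize,
    reference_gene_normalize,
    select_stable_references,
    signed_fold_change,
    simulate_expression_truth,
    simulate_nanostring_counts,
)
from circdigit.countmatrix import CountMatrix, load_rcc_dir, parse_rcc, write_rcc


def _matrix(rows: dict, classes: dict, lanes=("L1", "L2"), stage="raw"):
    df = pd.DataFrame(rows, index=lanes).T
    return CountMatrix(df, pd.Series(classes), stage)


# ---- geometric mean --------------------------------------------------------


@pytest.mark.parametrize(
    "values,policy,expected",
    [((2, 8), 0.5, 4.0), ((5,), 0.5, 5.0), ((0, 8), 0.5, 2.0), ((0, 8), "exclude", 8.0)],
)
def test_geometric_mean(values, policy, expected):
    assert geometric_mean(values, policy) == pytest.approx(expected)


def test_geometric_mean_empty_after_policy_raises():
    with pytest.raises(ValueError):
        geometric_mean([0, 0], "exclude")


# ---- RCC -------------------------------------------------------------------


def test_rcc_round_trip(tmp_path, genome3):
    truth = simulate_expression_truth(genome3, 7, circ_fraction=1.0)
    m = simulate_nanostring_counts(truth, 2, seed=5)
    write_rcc(m, tmp_path)
    back = load_rcc_dir(tmp_path)
    assert back.samples == m.samples and back.targets == m.targets
    np.testing.assert_array_equal(back.counts.values, m.counts.values)
    assert (back.code_class == m.code_class).all()


def test_rcc_negative_count_names_line(tmp_path):
    p = tmp_path / "bad.rcc"
    p.write_text(
        "<Header>\nFileVersion,1.7\n</Header>\n"
        "<Code_Summary>\nCodeClass,Name,Accession,Count\n"
        "Endogenous,circA,syn,-3\n</Code_Summary>\n"
    )
    with pytest.raises(ValueError, match=r":6:.*negative"):
        parse_rcc(p)


def test_rcc_missing_code_summary(tmp_path):
    p = tmp_path / "empty.rcc"
    p.write_text("<Header>\nFileVersion,1.7\n</Header>\n")
    with pytest.raises(ValueError, match="Code_Summary"):
        parse_rcc(p)


def test_rcc_two_lane_merge(tmp_path, genome3):
    truth = simulate_expression_truth(genome3, 7, circ_fraction=1.0)
    m = simulate_nanostring_counts(truth, 2, seed=6)
    write_rcc(m, tmp_path)
    merged = load_rcc_dir(tmp_path)
    assert len(merged.samples) == 2
    assert merged.targets == m.targets


# ---- background subtraction ------------------------------------------------


def test_background_subtracts_mean_of_negatives():
    m = _matrix(
        {"circA": (110, 110), "NEG_A": (10, 10), "NEG_B": (10, 10), "POS_A": (50, 50)},
        {"circA": "Endogenous", "NEG_A": "Negative", "NEG_B": "Negative",
         "POS_A": "Positive"},
    )
    out = background_subtract(m)
    assert out.stage == "background_subtracted"
    assert (out.counts.loc["circA"] == 100).all()
    # controls retained unmodified for audit
    assert (out.counts.loc["NEG_A"] == 10).all()
    assert (out.counts.loc["POS_A"] == 50).all()


def test_background_floors_at_zero_and_zero_negatives_are_identity():
    m = _matrix(
        {"circA": (5, 5), "NEG_A": (10, 10)},
        {"circA": "Endogenous", "NEG_A": "Negative"},
    )
    assert (background_subtract(m).counts.loc["circA"] == 0).all()
    m2 = _matrix(
        {"circA": (7, 9), "NEG_A": (0, 0)},
        {"circA": "Endogenous", "NEG_A": "Negative"},
    )
    assert (background_subtract(m2).counts.loc["circA"] == (7, 9)).all()


def test_background_requires_negatives_and_raw_stage():
    no_neg = _matrix({"circA": (1, 1)}, {"circA": "Endogenous"})
    with pytest.raises(ValueError, match="Negative"):
        background_subtract(no_neg)
    m = _matrix(
        {"circA": (5, 5), "NEG_A": (1, 1)},
        {"circA": "Endogenous", "NEG_A": "Negative"},
    )
    staged = background_subtract(m)
    with pytest.raises(ValueError, match="stage"):
        background_subtract(staged)


# ---- positive-control normalization ----------------------------------------


def _pos_matrix(geo1, geo2):
    # two positives whose geometric mean is the requested value per lane
    return _matrix(
        {
            "POS_A": (geo1 * 2, geo2 * 2),
            "POS_B": (geo1 / 2, geo2 / 2),
            "NEG_A": (0, 0),
            "circA": (100, 100),
        },
        {"POS_A": "Positive", "POS_B": "Positive", "NEG_A": "Negative",
         "circA": "Endogenous"},
        stage="background_subtracted",
    )


def test_positive_factors_and_equalized_geomeans():
    out = positive_control_normalize(_pos_matrix(100, 200))
    np.testing.assert_allclose(out.norm_factors["positive"].values, [1.5, 0.75])
    pos = out.class_counts("Positive")
    geo = np.exp(np.log(pos).mean(axis=0))
    np.testing.assert_allclose(geo.values, [150.0, 150.0])


def test_single_lane_positive_factor_is_one():
    m = _matrix(
        {"POS_A": (200,), "POS_B": (50,), "circA": (10,)},
        {"POS_A": "Positive", "POS_B": "Positive", "circA": "Endogenous"},
        lanes=("L1",),
        stage="background_subtracted",
    )
    out = positive_control_normalize(m)
    assert out.norm_factors["positive"].iloc[0] == pytest.approx(1.0)


def test_true_lane_scales_recovered(genome3):
    truth = simulate_expression_truth(genome3, 7, circ_fraction=1.0)
    m = simulate_nanostring_counts(
        truth, 3, seed=8, neg_mean=0.0, noise=0.0, lane_scales=(1.0, 2.0, 4.0)
    )
    out = positive_control_normalize(background_subtract(m))
    factors = out.norm_factors["positive"].values
    np.testing.assert_allclose(factors / factors[0], [1.0, 0.5, 0.25], rtol=1e-9)


# ---- reference-gene selection and normalization ----------------------------


def _hk_matrix(noisy_gene="HK5"):
    lanes = ("L1", "L2", "L3", "L4")
    rows = {f"HK{i}": (100.0, 102.0, 98.0, 101.0) for i in range(1, 6)}
    rows[noisy_gene] = (20.0, 400.0, 50.0, 800.0)
    rows["POS_A"] = (10.0,) * 4
    rows["POS_B"] = (10.0,) * 4
    classes = {f"HK{i}": "Housekeeping" for i in range(1, 6)}
    classes.update({"POS_A": "Positive", "POS_B": "Positive"})
    return _matrix(rows, classes, lanes=lanes, stage="positive_normalized")


@pytest.mark.parametrize("method", ["cv_log", "genorm_pairwise"])
def test_unstable_candidate_excluded(method):
    m = _hk_matrix()
    chosen = select_stable_references(m, [f"HK{i}" for i in range(1, 6)], 4, method)
    assert "HK5" not in chosen and len(chosen) == 4


def test_reference_selection_ties_and_bounds():
    m = _matrix(
        {f"HK{i}": (100.0, 100.0) for i in range(1, 6)}
        | {"POS_A": (1.0, 1.0), "POS_B": (1.0, 1.0)},
        {f"HK{i}": "Housekeeping" for i in range(1, 6)}
        | {"POS_A": "Positive", "POS_B": "Positive"},
        stage="positive_normalized",
    )
    cands = [f"HK{i}" for i in range(1, 6)]
    assert select_stable_references(m, cands, 3) == ["HK1", "HK2", "HK3"]
    assert sorted(select_stable_references(m, cands, 5)) == cands
    with pytest.raises(ValueError):
        select_stable_references(m, cands, 6)


def test_reference_normalization_doubles_low_lane():
    m = _matrix(
        {"HK1": (50.0, 100.0), "circA": (30.0, 30.0)},
        {"HK1": "Housekeeping", "circA": "Endogenous"},
        stage="positive_normalized",
    )
    out = reference_gene_normalize(m, ["HK1"])
    assert out.stage == "reference_normalized"
    # global mean geomean = 75; lane L1 factor 1.5, L2 factor 0.75
    np.testing.assert_allclose(out.counts.loc["circA"].values, [45.0, 22.5])


def test_reference_normalization_identity_when_refs_constant():
    m = _matrix(
        {"HK1": (80.0, 80.0), "circA": (30.0, 60.0)},
        {"HK1": "Housekeeping", "circA": "Endogenous"},
        stage="positive_normalized",
    )
    out = reference_gene_normalize(m, ["HK1"])
    np.testing.assert_allclose(out.counts.loc["circA"].values, [30.0, 60.0])


def test_cascade_invariant_to_global_lane_scaling(genome3):
    """Tripling one lane's raw counts leaves the reference-normalized
    endogenous profile unchanged up to the cascade's single global gain
    constant: every entry moves by one and the same factor."""
    truth = simulate_expression_truth(genome3, 7, circ_fraction=1.0)
    m = simulate_nanostring_counts(truth, 3, seed=9, noise=0.1)
    scaled_counts = m.counts.copy()
    scaled_counts["lane02"] *= 3
    scaled = CountMatrix(scaled_counts, m.code_class.copy(), "raw")
    norm_a, _ = normalize_cascade(m)
    norm_b, _ = normalize_cascade(scaled)
    endo = norm_a.class_targets("Endogenous")
    a = norm_a.counts.loc[endo].values
    b = norm_b.counts.loc[endo].values
    ratio = b[a > 0] / a[a > 0]
    np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-9)
    # within the rescaled run, the tripled lane is fully corrected: its
    # normalized counts agree with the other lanes as before
    rel_a = norm_a.counts.loc[endo, "lane02"] / norm_a.counts.loc[endo, "lane01"]
    rel_b = norm_b.counts.loc[endo, "lane02"] / norm_b.counts.loc[endo, "lane01"]
    np.testing.assert_allclose(rel_a.values, rel_b.values, rtol=1e-9)


def test_cascade_recovers_truth_abundances(genome3):
    truth = simulate_expression_truth(genome3, 7, circ_fraction=1.0)
    m = simulate_nanostring_counts(truth, 3, seed=10, noise=0.1)
    norm, refs = normalize_cascade(m)
    assert len(refs) == 4
    endo = norm.class_counts("Endogenous").mean(axis=1)
    ab = pd.Series(truth.circ_abundance).loc[endo.index]
    r = np.corrcoef(endo.values, ab.values)[0, 1]
    assert r**2 > 0.95


def test_stage_machine_rejects_out_of_order_calls(genome3):
    truth = simulate_expression_truth(genome3, 7, circ_fraction=1.0)
    m = simulate_nanostring_counts(truth, 2, seed=11)
    with pytest.raises(ValueError, match="stage"):
        positive_control_normalize(m)  # skips background subtraction
    with pytest.raises(ValueError, match="stage"):
        reference_gene_normalize(background_subtract(m), ["ACTB"])


# ---- signed fold change ----------------------------------------------------


@pytest.mark.parametrize(
    "treated,mock,expected",
    [(20, 10, 2.0), (10, 20, -2.0), (7, 7, 1.0), (0, 5, None), (5, 0, None), (0, 0, None)],
)
def test_signed_fold_change(treated, mock, expected):
    got = signed_fold_change(treated, mock)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected)


@settings(derandomize=True, max_examples=100)
@given(
    a=st.floats(min_value=0.01, max_value=1e6),
    b=st.floats(min_value=0.01, max_value=1e6),
)
def test_signed_fold_change_antisymmetric_and_at_least_one(a, b):
    fa, fb = signed_fold_change(a, b), signed_fold_change(b, a)
    assert abs(fa) >= 1 and abs(fb) >= 1
    if a != b:
        assert fa == pytest.approx(-fb)


# ---- enrichment summary ----------------------------------------------------


def test_enrichment_classification(genome3):
    truth = simulate_expression_truth(
        genome3, 7, circ_fraction=1.0, n_rnase_r_sensitive=1
    )
    mock = simulate_nanostring_counts(
        truth, 1, seed=12, neg_mean=0.0, noise=0.0, lane_scales=(1.0,)
    )
    treated = apply_rnase_r(mock, truth, seed=13, resample=False)
    records, averages = enrichment_summary(mock, treated, mock, treated)
    by_name = {r.target: r for r in records}
    for c in truth.circles:
        rec = by_name[c.circ_id]
        if not rec.expressed:
            continue
        if c.circ_id in truth.rnase_r_sensitive:
            assert not rec.enriched_2x and rec.signed_fc < 0
        else:
            assert rec.enriched_2x and rec.signed_fc == pytest.approx(6.0, rel=0.02)
    for r in records:
        if r.code_class == "Housekeeping":
            assert not r.enriched_2x and r.signed_fc < 0
    assert averages["Housekeeping"] == pytest.approx(-4.0, rel=0.05)


def test_enrichment_50_count_rule_uses_raw_scale():
    lanes = ("L1",)
    classes = {"circA": "Endogenous", "circB": "Endogenous", "HK1": "Housekeeping"}
    mock = _matrix({"circA": (100,), "circB": (10,), "HK1": (400,)}, classes, lanes)
    treated = _matrix({"circA": (160,), "circB": (45,), "HK1": (100,)}, classes, lanes)
    records, _ = enrichment_summary(mock, treated, mock, treated, expressed_min=5)
    by_name = {r.target: r for r in records}
    assert by_name["circA"].enriched_50ct  # +60 raw counts
    assert not by_name["circA"].enriched_2x  # only 1.6x
    assert by_name["circB"].enriched_2x  # 4.5x
    assert not by_name["circB"].enriched_50ct  # +35 raw counts
    assert not by_name["HK1"].enriched_2x


def test_enrichment_rejects_mismatched_targets():
    lanes = ("L1",)
    a = _matrix({"circA": (1,)}, {"circA": "Endogenous"}, lanes)
    b = _matrix({"circB": (1,)}, {"circB": "Endogenous"}, lanes)
    with pytest.raises(ValueError, match="target set"):
        enrichment_summary(a, b, a, b)
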