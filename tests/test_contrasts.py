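"""Contrast parsing, the four strategies, merging and FDR control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lfqdea.contrasts import (ContrastError, ContrastResults, adjust_fdr,
                              contrasts_missing, estimate_variance_prior,
                              linear_model_contrasts, merge_contrasts,
                              moderate, parse_contrast,
                              parse_linear_expression, ropeca)
from lfqdea.data import AnalysisConfig, QuantTable
from lfqdea.model import ProteinLinearModel, build_design

from conftest import make_two_group_table


# ------------------------------------------------------------------ parsing

def test_parse_linear_expression_differences_and_scaling():
    assert parse_linear_expression("e - d") == {"e": 1.0, "d": -1.0}
    assert parse_linear_expression("0.5*(a + b) - c") == \
        {"a": 0.5, "b": 0.5, "c": -1.0}
    assert parse_linear_expression("a - a") == {"a": 0.0}
    with pytest.raises(ContrastError):
        parse_linear_expression("a * b")
    with pytest.raises(ContrastError):
        parse_linear_expression("a - 2")


def _five_group_design():
    rows = [(f"{g}{r}", g) for g in "abcde" for r in range(1, 5)]
    ann = pd.DataFrame(rows, columns=["sample", "group"])
    return build_design(ann, AnalysisConfig(), "group")


def test_parse_contrast_weights_under_treatment_coding():
    design = _five_group_design()
    spec = parse_contrast("e - d", design)
    assert spec.c["group:e"] == 1.0
    assert spec.c["group:d"] == -1.0
    assert spec.c["Intercept"] == 0.0
    assert spec.is_difference
    with pytest.raises(ContrastError, match="unknown"):
        parse_contrast("z - a", design)


def test_contrast_reproduces_cell_mean_difference_noiseless():
    """On a zero-noise fixture c'beta equals the requested difference of
    group means, including the reference level and interaction cells."""
    means = {"a": 10.0, "b": 11.0, "c": 9.0, "d": 13.0, "e": 14.5}
    rows = [(f"P", f"{g}{r}", g, means[g]) for g in means for r in range(1, 4)]
    df = pd.DataFrame(rows, columns=["protein", "sample", "group", "abundance"])
    cfg = AnalysisConfig(response_col="abundance", log_transformed=True)
    res = ProteinLinearModel(QuantTable(df, cfg), "group").fit()
    for expr, want in (("e - d", 1.5), ("b - a", 1.0), ("a - c", 1.0),
                       ("0.5*(d + e) - a", 3.75)):
        out = res.contrasts([expr]).frame
        assert out.loc[0, "diff"] == pytest.approx(want, abs=1e-10)


def test_interaction_contrast_difference_of_differences():
    cells = {("a", "x"): 10.0, ("a", "y"): 12.0,
             ("b", "x"): 11.0, ("b", "y"): 16.0}
    rows = []
    for (f1, f2), m in cells.items():
        for r in range(1, 4):
            rows.append(("P", f"{f1}{f2}{r}", f1, f2, m))
    df = pd.DataFrame(rows, columns=["protein", "sample", "f1", "f2",
                                     "abundance"])
    cfg = AnalysisConfig(group_cols=("f1", "f2"), response_col="abundance",
                         log_transformed=True)
    res = ProteinLinearModel(QuantTable(df, cfg), "f1 * f2").fit()
    out = res.contrasts(["(b:y - b:x) - (a:y - a:x)"]).frame
    assert out.loc[0, "diff"] == pytest.approx((16 - 11) - (12 - 10), abs=1e-10)


# ------------------------------------------------------- plain vs t-test

def test_plain_contrast_equals_pooled_two_sample_t_test():
    """diff, se, df and p agree with the textbook pooled t-test to 1e-10."""
    rng = np.random.default_rng(17)
    table = make_two_group_table(n_proteins=30, delta=0.4, sigma=0.6, seed=17)
    res = ProteinLinearModel(table, "group").fit()
    out = res.contrasts(["trt - ctrl"]).frame.set_index("protein")
    data = table.data
    for prot, sub in data.groupby("protein"):
        a = sub.loc[sub["group"] == "trt", "abundance"].to_numpy()
        b = sub.loc[sub["group"] == "ctrl", "abundance"].to_numpy()
        t, p = sps.ttest_ind(a, b, equal_var=True)
        sp2 = (((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
               / (len(a) + len(b) - 2))
        se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        row = out.loc[prot]
        assert row["diff"] == pytest.approx(a.mean() - b.mean(), abs=1e-10)
        assert row["se"] == pytest.approx(se, abs=1e-10)
        assert row["df"] == len(a) + len(b) - 2
        assert row["statistic"] == pytest.approx(t, abs=1e-10)
        assert row["p_value"] == pytest.approx(p, abs=1e-10)


def test_plain_contrast_zero_noise_and_zero_vector():
    table = make_two_group_table(n_proteins=2, delta=2.0, sigma=0.0)
    res = ProteinLinearModel(table, "group").fit()
    out = res.contrasts(["trt - ctrl"]).frame
    np.testing.assert_allclose(out["diff"], 2.0, atol=1e-12)
    assert (out["p_value"] < 1e-50).all()  # underflow-safe near t = inf
    zero = res.contrasts(["trt - trt"]).frame
    np.testing.assert_allclose(zero["diff"], 0.0)
    assert (zero["p_value"] == 1.0).all()


def test_plain_contrast_skips_inestimable_proteins():
    table = make_two_group_table(n_proteins=3, seed=4)
    df = table.data[~((table.data["protein"] == "P000")
                      & (table.data["group"] == "trt"))]
    res = ProteinLinearModel(
        QuantTable(df, table.config, annotation=table.annotation), "group").fit()
    out = res.contrasts(["trt - ctrl"]).frame
    assert "P000" not in set(out["protein"])
    assert {"P001", "P002"} <= set(out["protein"])


# ----------------------------------------------------------- moderation

def test_posterior_limits_of_variance_shrinkage():
    from lfqdea.contrasts import ModerationParams
    s2 = np.array([0.5, 2.0, 1.0])
    df = np.array([4.0, 4.0, 4.0])
    inf_prior = ModerationParams(d0=np.inf, s02=1.3)
    np.testing.assert_allclose(inf_prior.posterior(s2, df), 1.3)
    none_prior = ModerationParams(d0=0.0, s02=1.3)
    np.testing.assert_allclose(none_prior.posterior(s2, df), s2)
    mid = ModerationParams(d0=4.0, s02=1.0).posterior(s2, df)
    assert ((mid >= np.minimum(s2, 1.0)) & (mid <= np.maximum(s2, 1.0))).all()


def test_variance_prior_recovery_from_simulated_variances():
    """5000 variances from a scaled inverse chi-square prior with known
    (d0, s0^2): moment matching recovers d0 within 20%, s0^2 within 10%."""
    rng = np.random.default_rng(23)
    d0_true, s02_true, df = 6.0, 0.04, 6
    n = 5000
    sigma2 = d0_true * s02_true / rng.chisquare(d0_true, size=n)
    s2 = sigma2 * rng.chisquare(df, size=n) / df
    params = estimate_variance_prior(s2, np.full(n, df))
    assert abs(params.d0 - d0_true) / d0_true < 0.2
    assert abs(params.s02 - s02_true) / s02_true < 0.1


def test_moderation_identical_variances_gives_infinite_prior():
    table = make_two_group_table(n_proteins=12, sigma=0.0, delta=1.0)
    res = ProteinLinearModel(table, "group").fit()
    plain = res.contrasts(["trt - ctrl"])
    mod = moderate(plain)
    assert np.isinf(mod.moderation.d0)
    assert mod.moderation.s02 == pytest.approx(0.0, abs=1e-12)


def test_moderation_preserves_sign_and_ordering():
    table = make_two_group_table(n_proteins=40, delta=0.3, sigma=0.5, seed=8)
    res = ProteinLinearModel(table, "group").fit()
    plain = res.contrasts(["trt - ctrl"])
    mod = moderate(plain)
    t0 = plain.frame["statistic"].to_numpy()
    t1 = mod.frame["statistic"].to_numpy()
    assert (np.sign(t0) == np.sign(t1)).all()
    # equal df everywhere: |t| order preserved up to the common shrinkage
    order0 = np.argsort(np.abs(t0))
    # moderated |t| need not be monotone in plain |t| when sigma varies;
    # but p-value order matches |t| order within the moderated set
    p = mod.frame["p_value"].to_numpy()
    assert (np.argsort(p) == np.argsort(-np.abs(t1))).all() or \
        np.allclose(np.sort(p), p[np.argsort(-np.abs(t1))])
    assert mod.frame["method"].eq("moderated").all()
    assert (mod.frame["df"] > plain.frame["df"]).all()


# ------------------------------------------------------- missing / LOD

def _missing_fixture():
    """Protein observed in group a (4 obs) but absent from group b."""
    rows = [("P1", f"a{i}", "a", 18.0 + d) for i, d in
            zip(range(1, 5), (-0.5, 0.0, 0.0, 0.5))]
    rows += [("P2", f"a{i}", "a", 20.0) for i in range(1, 5)]
    rows += [("P2", f"b{i}", "b", 21.0) for i in range(1, 5)]
    df = pd.DataFrame(rows, columns=["protein", "sample", "group", "abundance"])
    cfg = AnalysisConfig(response_col="abundance", log_transformed=True)
    ann = pd.DataFrame({"sample": [f"{g}{i}" for g in "ab" for i in range(1, 5)],
                        "group": [g for g in "ab" for _ in range(4)]})
    return QuantTable(df, cfg, annotation=ann)


def test_missing_contrast_substitutes_lod_for_empty_group():
    table = _missing_fixture()
    out = contrasts_missing(table, ["a - b"], lod=15.0).frame.set_index("protein")
    row = out.loc["P1"]
    s_p = table.data.query("protein == 'P1'")["abundance"].std(ddof=1)
    assert row["diff"] == pytest.approx(18.0 - 15.0, abs=1e-12)
    assert row["se"] == pytest.approx(s_p * np.sqrt(1 / 4 + 1 / 1), abs=1e-12)
    assert row["df"] == 3  # 4 observations, 1 observed group
    assert bool(row["lod_substituted"])


def test_missing_contrast_matches_plain_diff_when_both_groups_observed():
    table = _missing_fixture()
    out = contrasts_missing(table, ["a - b"], lod=15.0).frame.set_index("protein")
    row = out.loc["P2"]
    assert row["diff"] == pytest.approx(-1.0, abs=1e-12)
    assert not bool(row["lod_substituted"])
    assert row["df"] == 6


def test_missing_contrast_clamps_means_below_lod():
    # observed mean 14 < A_LOD 15 and the other group empty -> diff 0
    rows = [("P1", f"a{i}", "a", 14.0 + d) for i, d in
            zip(range(1, 5), (-0.2, 0.0, 0.0, 0.2))]
    df = pd.DataFrame(rows, columns=["protein", "sample", "group", "abundance"])
    cfg = AnalysisConfig(response_col="abundance", log_transformed=True)
    ann = pd.DataFrame({"sample": [f"{g}{i}" for g in "ab" for i in range(1, 5)],
                        "group": [g for g in "ab" for _ in range(4)]})
    table = QuantTable(df, cfg, annotation=ann)
    out = contrasts_missing(table, ["a - b"], lod=15.0).frame
    assert out.loc[0, "diff"] == pytest.approx(0.0, abs=1e-12)
    assert bool(out.loc[0, "lod_substituted"])


def test_missing_contrast_falls_back_to_median_pooled_variance():
    # P1 has a single observation in a (no within-group variance anywhere);
    # its variance comes from the other proteins' median pooled variance
    rows = [("P1", "a1", "a", 18.0)]
    for prot, s in (("P2", 0.5), ("P3", 1.0), ("P4", 2.0)):
        for g, m in (("a", 20.0), ("b", 21.0)):
            for i, d in zip(range(1, 4), (-s, 0.0, s)):
                rows.append((prot, f"{g}{i}", g, m + d))
    df = pd.DataFrame(rows, columns=["protein", "sample", "group", "abundance"])
    cfg = AnalysisConfig(response_col="abundance", log_transformed=True)
    ann = df[["sample", "group"]].drop_duplicates()
    table = QuantTable(df, cfg, annotation=ann)
    out = contrasts_missing(table, ["a - b"], lod=15.0).frame.set_index("protein")
    med_pooled = np.median([0.5 ** 2, 1.0 ** 2, 2.0 ** 2])
    row = out.loc["P1"]
    assert row["sigma"] ** 2 == pytest.approx(med_pooled, abs=1e-12)
    assert row["se"] == pytest.approx(np.sqrt(med_pooled) * np.sqrt(1 + 1),
                                      abs=1e-12)


# ------------------------------------------------------------- ropeca

def _peptide_results(protein, ps, diffs, ts=None):
    ts = ts if ts is not None else [1.0] * len(ps)
    frame = pd.DataFrame({
        "protein": protein, "peptide": [f"pep{i}" for i in range(len(ps))],
        "contrast": "c1", "diff": diffs, "se": 0.1, "df": 6.0,
        "statistic": ts, "p_value": ps, "method": "plain",
        "n_per_group": "", "lod_substituted": False,
    })
    return ContrastResults(frame)


def test_ropeca_single_peptide_is_identity():
    out = ropeca(_peptide_results("P", [0.04], [1.0])).frame
    assert out.loc[0, "p_value"] == pytest.approx(0.04, abs=1e-12)
    assert out.loc[0, "df"] == 1


def test_ropeca_null_peptides_give_probability_one():
    out = ropeca(_peptide_results("P", [1.0] * 5, [0.5] * 5)).frame
    assert out.loc[0, "p_value"] == pytest.approx(1.0, abs=1e-12)


def test_ropeca_beta_cdf_oracle():
    """d=5 with one-sided values {0.01,0.02,0.03,0.4,0.6}: the median is
    0.03 and the protein value is 2*BetaCDF(0.03; 3, 3)."""
    # choose two-sided p and signs so the one-sided values come out right:
    # p/2 for positive diffs: 0.02,0.04,0.06 -> 0.01,0.02,0.03
    # 1 - p/2 for negative: p=1.2? not valid; use positive diffs with
    # p=0.8 -> 0.4 and p=1.0-> 0.5 is not 0.6, so take a negative diff
    # with p = 0.8 -> 1 - 0.4 = 0.6
    ps = [0.02, 0.04, 0.06, 0.8, 0.8]
    diffs = [1.0, 1.0, 1.0, 1.0, -1.0]
    out = ropeca(_peptide_results("P", ps, diffs)).frame
    q = sps.beta.cdf(0.03, 3, 3)
    assert out.loc[0, "p_value"] == pytest.approx(2 * min(q, 1 - q), abs=1e-12)
    assert out.loc[0, "df"] == 5
    assert out.loc[0, "diff"] == pytest.approx(1.0)


def test_ropeca_even_d_uses_upper_median():
    ps = [0.02, 0.04, 0.06, 0.8]
    diffs = [1.0, 1.0, 1.0, 1.0]
    out = ropeca(_peptide_results("P", ps, diffs)).frame
    i = 3  # ceil((4+1)/2)
    q = sps.beta.cdf(0.03, i, 4 - i + 1)
    assert out.loc[0, "p_value"] == pytest.approx(2 * min(q, 1 - q), abs=1e-12)


# ---------------------------------------------------- merge and FDR

def test_merge_prefers_first_and_unions():
    f1 = pd.DataFrame({"protein": ["P1", "P2"], "contrast": "c", "diff": [1.0, 2.0],
                       "p_value": [0.1, 0.2], "method": "moderated"})
    f2 = pd.DataFrame({"protein": ["P2", "P3"], "contrast": "c", "diff": [9.0, 3.0],
                       "p_value": [0.9, 0.3], "method": "missing"})
    merged = merge_contrasts(ContrastResults(f1), ContrastResults(f2)).frame
    assert len(merged) == 3
    assert merged.set_index("protein").loc["P2", "diff"] == 2.0
    assert merged.set_index("protein").loc["P3", "method"] == "missing"


def test_bh_adjustment_hand_computed():
    frame = pd.DataFrame({"protein": ["P1", "P2", "P3"], "contrast": "c",
                          "diff": 1.0, "p_value": [0.01, 0.02, 0.04],
                          "method": "plain"})
    out = adjust_fdr(ContrastResults(frame)).frame
    np.testing.assert_allclose(sorted(out["FDR"]), [0.03, 0.03, 0.04])
    single = adjust_fdr(ContrastResults(frame.iloc[[0]].copy())).frame
    assert single.loc[0, "FDR"] == 0.01
    equal = frame.copy()
    equal["p_value"] = 0.07
    out_eq = adjust_fdr(ContrastResults(equal)).frame
    np.testing.assert_allclose(out_eq["FDR"], 0.07)


def test_bh_is_applied_within_each_contrast_separately():
    frame = pd.DataFrame({
        "protein": ["P1", "P2", "P1", "P2"],
        "contrast": ["c1", "c1", "c2", "c2"],
        "diff": 1.0, "p_value": [0.01, 0.04, 0.5, 0.9], "method": "plain"})
    out = adjust_fdr(ContrastResults(frame)).frame
    c1 = out[out["contrast"] == "c1"].sort_values("p_value")["FDR"].to_numpy()
    np.testing.assert_allclose(c1, [0.02, 0.04])
    c2 = out[out["contrast"] == "c2"].sort_values("p_value")["FDR"].to_numpy()
    np.testing.assert_allclose(c2, [0.9, 0.9])


def test_merged_results_round_trip_tsv(tmp_path, two_group_table):
    res = ProteinLinearModel(two_group_table, "group").fit()
    out = adjust_fdr(moderate(res.contrasts(["trt - ctrl"])))
    path = tmp_path / "contrasts.tsv"
    out.to_tsv(path)
    back = ContrastResults.from_tsv(path)
    np.testing.assert_allclose(back.frame["diff"], out.frame["diff"])
    assert list(back.frame["method"]) == list(out.frame["method"])
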