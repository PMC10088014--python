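"""Design matrices, per-protein OLS, pooled variance, LOD estimation."""

import numpy as np
import pandas as pd
import pytest

from lfqdea.data import AnalysisConfig, QuantTable
from lfqdea.model import (DesignError, ProteinLinearModel, build_design,
                          estimate_lod, fit_protein, pooled_variance)

from conftest import make_two_group_table


def annotation_one_factor(levels, reps):
    rows = [(f"{g}{r+1}", g) for g in levels for r in range(reps)]
    return pd.DataFrame(rows, columns=["sample", "group"])


def test_design_one_factor_five_levels_rank():
    ann = annotation_one_factor("abcde", 4)
    cfg = AnalysisConfig()
    design = build_design(ann, cfg, formula="group")
    assert design.matrix.shape == (20, 5)
    assert np.linalg.matrix_rank(design.matrix.to_numpy()) == 5
    assert design.terms == ["Intercept", "group:b", "group:c", "group:d",
                            "group:e"]
    assert design.cells == list("abcde")


def test_design_single_level_is_intercept_only():
    ann = annotation_one_factor("a", 3)
    design = build_design(ann, AnalysisConfig(), formula="group")
    assert design.terms == ["Intercept"]


def test_design_two_factor_interaction():
    rows = [(f"s{i}", f1, f2) for i, (f1, f2) in enumerate(
        [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")] * 2)]
    ann = pd.DataFrame(rows, columns=["sample", "f1", "f2"])
    cfg = AnalysisConfig(group_cols=("f1", "f2"))
    design = build_design(ann, cfg, formula="f1 * f2")
    assert design.matrix.shape[1] == 4
    assert "f1:b×f2:y" in design.terms
    assert np.linalg.matrix_rank(design.matrix.to_numpy()) == 4
    assert design.cells == ["a:x", "a:y", "b:x", "b:y"]


def test_design_unknown_factor_errors():
    ann = annotation_one_factor("ab", 2)
    with pytest.raises(DesignError, match="unknown factor"):
        build_design(ann, AnalysisConfig(), formula="treatment")


def test_fit_recovers_exact_shift_with_zero_noise():
    table = make_two_group_table(n_proteins=1, delta=1.5, sigma=0.0)
    design = build_design(table.annotation, table.config, "group")
    y = table.data.set_index("sample")["abundance"]
    fit = fit_protein(y, design, analyte="P000")
    assert fit.beta["group:trt"] == pytest.approx(1.5, abs=1e-12)
    assert fit.sigma == pytest.approx(0.0, abs=1e-12)
    assert fit.df == 6
    assert fit.fully_estimable


def test_fit_flags_inestimable_when_group_unobserved():
    table = make_two_group_table(n_proteins=1)
    design = build_design(table.annotation, table.config, "group")
    sub = table.data[table.data["group"] == "ctrl"]
    fit = fit_protein(sub.set_index("sample")["abundance"], design)
    assert not bool(fit.estimable["group:trt"])
    assert fit.group_n["trt"] == 0
    # the ctrl-group mean (= Intercept under treatment coding) is estimable
    e_int = np.eye(2)[0]
    assert fit.is_estimable(e_int)
    assert not fit.is_estimable(np.array([0.0, 1.0]))


def test_fit_matches_normal_equations_oracle():
    """Brute-force (X'X)^-1 X'y on a random unbalanced one-factor fixture."""
    rng = np.random.default_rng(5)
    ann = annotation_one_factor("abc", 4)
    cfg = AnalysisConfig(response_col="abundance", log_transformed=True)
    design = build_design(ann, cfg, "group")
    # unbalanced: drop two samples
    samples = [s for s in ann["sample"] if s not in ("a2", "c4")]
    y = pd.Series(rng.normal(20, 1, len(samples)), index=samples)
    fit = fit_protein(y, design)
    X = design.matrix.loc[samples].to_numpy()
    yv = y.to_numpy()
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ yv
    np.testing.assert_allclose(fit.beta.to_numpy(), beta, atol=1e-10)
    resid = yv - X @ beta
    df = len(yv) - X.shape[1]
    np.testing.assert_allclose(fit.sigma, np.sqrt(resid @ resid / df),
                               atol=1e-10)
    np.testing.assert_allclose(fit.cov_unscaled.to_numpy(), xtx_inv,
                               atol=1e-10)


def test_fit_invariant_to_record_order():
    table = make_two_group_table(n_proteins=1, sigma=0.8, seed=9)
    design = build_design(table.annotation, table.config, "group")
    y = table.data.set_index("sample")["abundance"]
    f1 = fit_protein(y, design)
    f2 = fit_protein(y.sample(frac=1.0, random_state=1), design)
    pd.testing.assert_series_equal(f1.beta, f2.beta)
    assert f1.sigma == f2.sigma


def test_balanced_contrast_variance_identity():
    """For a balanced one-factor design, c'(X'X)^-1 c for a two-group
    difference equals 1/n_a + 1/n_b."""
    ann = annotation_one_factor("abcde", 4)
    design = build_design(ann, AnalysisConfig(), "group")
    from lfqdea.contrasts import parse_contrast
    spec = parse_contrast("e - d", design)
    ck = spec.c.to_numpy()
    X = design.matrix.to_numpy()
    cvc = ck @ np.linalg.inv(X.T @ X) @ ck
    assert cvc == pytest.approx(1 / 4 + 1 / 4, abs=1e-10)


def test_pooled_variance_formula_and_two_group_equivalence():
    table = make_two_group_table(n_proteins=1, sigma=0.7, seed=2)
    design = build_design(table.annotation, table.config, "group")
    y = table.data.set_index("sample")["abundance"]
    fit = fit_protein(y, design)
    pv = pooled_variance(fit)
    a = y[[s for s in y.index if s.startswith("ctrl")]].to_numpy()
    b = y[[s for s in y.index if s.startswith("trt")]].to_numpy()
    classic = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
        / (len(a) + len(b) - 2)
    assert pv.s2 == pytest.approx(classic, abs=1e-12)
    assert pv.n == 8 and pv.n_groups == 2 and pv.defined


def test_pooled_variance_weighted_example():
    # groups (n, s) = (4, 1.0), (2, 2.0) -> s_p^2 = (3*1 + 1*4)/4 = 1.75
    fit_stub = type("F", (), {})()
    fit_stub.group_n = pd.Series({"a": 4, "b": 2})
    fit_stub.group_sd = pd.Series({"a": 1.0, "b": 2.0})
    pv = pooled_variance(fit_stub)
    assert pv.s2 == pytest.approx(1.75, abs=1e-12)


def test_pooled_variance_single_usable_group():
    fit_stub = type("F", (), {})()
    fit_stub.group_n = pd.Series({"a": 3, "b": 1})
    fit_stub.group_sd = pd.Series({"a": 0.5, "b": np.nan})
    pv = pooled_variance(fit_stub)
    assert pv.s2 == pytest.approx(0.25, abs=1e-12)
    fit_stub.group_n = pd.Series({"a": 1, "b": 1})
    assert not pooled_variance(fit_stub).defined


def _lod_table(cell_values):
    """Protein-level log2 table; cell_values: protein -> {group: [values]}."""
    rows = []
    for prot, groups in cell_values.items():
        for g, vals in groups.items():
            for i, v in enumerate(vals):
                rows.append((prot, f"{g}{i+1}", g, v))
    df = pd.DataFrame(rows, columns=["protein", "sample", "group", "abundance"])
    cfg = AnalysisConfig(response_col="abundance", log_transformed=True)
    return QuantTable(df, cfg)


def test_estimate_lod_median_of_singleton_cells():
    table = _lod_table({
        "P1": {"a": [10.0], "b": [20.0, 21.0]},
        "P2": {"a": [12.0], "b": [19.0, 20.0]},
        "P3": {"a": [14.0], "b": [18.0, 18.5]},
    })
    lod = estimate_lod(table)
    assert lod.a_lod == 12.0
    assert lod.n_cells == 3


def test_estimate_lod_errors_without_singletons():
    table = _lod_table({"P1": {"a": [10.0, 11.0], "b": [20.0, 21.0]}})
    with pytest.raises(ValueError, match="explicitly"):
        estimate_lod(table)


def test_estimate_lod_tracks_simulated_censoring_threshold():
    from lfqdea.preprocess import log2_transform
    from lfqdea.aggregate import median_polish
    from lfqdea.simulate import SimParams, simulate_experiment
    # one peptide per protein so the protein abundance scale coincides with
    # the scale on which censoring acts (multi-peptide rollup shifts the
    # protein-level detection boundary down by the peptide-offset spread)
    sim = simulate_experiment(SimParams(n_background=600, n_spike=0,
                                        base_mean=17.0,
                                        peptides_per_protein_mean=1.0,
                                        seed=13))
    protein = median_polish(log2_transform(sim.table))
    lod = estimate_lod(protein)
    assert lod.n_cells > 50
    assert abs(lod.a_lod - sim.params.lod) < 1.0


def test_model_results_summary_and_sigma_frame(two_group_table):
    res = ProteinLinearModel(two_group_table, formula="group").fit()
    assert len(res) == 10
    sf = res.sigma_frame()
    assert set(sf.columns) == {"analyte", "sigma2", "df", "n_obs"}
    assert (sf["df"] == 6).all()
    text = res.summary()
    assert "formula" in text and "group" in text
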