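import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from palgraph.biomarker_eval import (
    SUBGROUPS,
    bh_fdr,
    consistency_matrix,
    correlate_binary,
    cox_fit,
    grade_discrimination,
    group_activation_profile,
    km_logrank,
    kruskal_wallis,
    median_split,
    patient_average,
    roc_auc,
    run_comparison_grid,
    welch_t_test,
)
from palgraph.expression import ExpressionMatrix

from .conftest import exp_matrix, make_pathway


# ---------------------------------------------------------------------------
# Scalar tests
# ---------------------------------------------------------------------------


def test_welch_identical_groups():
    assert welch_t_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)


def test_welch_hand_example():
    t, p = welch_t_test([1, 2, 3, 4], [3, 4, 5, 6])
    assert round(t, 2) == -2.19


def test_welch_location_invariance():
    t0, _ = welch_t_test([1, 2, 3, 4], [3, 4, 5, 6])
    t1, _ = welch_t_test([11, 12, 13, 14], [13, 14, 15, 16])
    assert t1 == pytest.approx(t0)


def test_welch_degenerate_equal_constants():
    assert welch_t_test([2, 2, 2], [2, 2]) == (0.0, 1.0)


def test_auc_perfect_and_ties():
    assert roc_auc([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0
    assert roc_auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5


def test_auc_pair_counting_example():
    assert roc_auc([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc([1, 2], [1, 1])


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.integers(-1000, 1000).map(lambda v: v / 10.0), min_size=4, max_size=30, unique=True),
    st.data(),
)
def test_auc_invariant_under_monotone_transform(scores, data):
    labels = data.draw(st.lists(st.sampled_from([0, 1]), min_size=len(scores), max_size=len(scores)))
    if len(set(labels)) < 2:
        labels[0], labels[-1] = 0, 1
    base = roc_auc(scores, labels)
    transformed = [np.exp(s / 50) + 3 for s in scores]
    assert roc_auc(transformed, labels) == pytest.approx(base)


def test_median_split_even():
    labels = median_split([1, 2, 3, 4])
    assert list(labels) == ["low", "low", "high", "high"]


def test_median_split_ties_go_low():
    labels = median_split([1, 2, 2, 5])
    assert list(labels) == ["low", "low", "low", "high"]


def test_median_split_all_equal_has_no_high():
    assert (median_split([3, 3, 3]) == "high").sum() == 0


def test_logrank_identical_groups():
    _, chi2, p = km_logrank([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_worked_example():
    curves, chi2, p = km_logrank([1, 2], [1, 1], [3, 4], [1, 1])
    assert chi2 == pytest.approx(2.88, abs=0.005)
    assert p == pytest.approx(0.090, abs=0.0005)
    # product-limit curves step down to 0 (no censoring)
    assert curves["A"]["survival"].iloc[-1] == 0.0


def test_logrank_symmetric_in_labels():
    _, chi2a, _ = km_logrank([1, 2], [1, 1], [3, 4], [1, 1])
    _, chi2b, _ = km_logrank([3, 4], [1, 1], [1, 2], [1, 1])
    assert chi2a == pytest.approx(chi2b)


def test_logrank_requires_events():
    with pytest.raises(ValueError, match="event"):
        km_logrank([1, 2], [0, 0], [3, 4], [0, 0])


def test_logrank_null_pvalues_uniform():
    rng = np.random.default_rng(3)
    ps = []
    for _ in range(1000):
        a, b = rng.exponential(1, 40), rng.exponential(1, 40)
        _, _, p = km_logrank(a, np.ones(40), b, np.ones(40))
        ps.append(p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def _bh_oracle(pvals):
    n = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        q[i] = running
    return q


def test_bh_examples():
    assert bh_fdr([0.2]) == pytest.approx([0.2])
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert bh_fdr([]).size == 0


def test_bh_permutation_equivariance():
    p = np.array([0.3, 0.01, 0.7, 0.04, 0.04])
    perm = np.array([4, 2, 0, 1, 3])
    np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))


def test_bh_matches_step_up_oracle():
    rng = np.random.default_rng(4)
    for _ in range(50):
        p = rng.random(int(rng.integers(1, 21)))
        np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), atol=1e-12)


def test_kruskal_examples():
    h0, p0 = kruskal_wallis([1, 2, 3], [1, 2, 3])
    assert h0 == pytest.approx(0.0, abs=1e-12) and p0 == pytest.approx(1.0)
    h, _ = kruskal_wallis([1, 2, 3], [4, 5, 6])
    assert round(h, 3) == 3.857
    h2, _ = kruskal_wallis([11, 12, 13], [14, 15, 16])
    assert h2 == pytest.approx(h)
    assert kruskal_wallis([5, 5], [5, 5]) == (0.0, 1.0)


def test_correlate_binary():
    assert correlate_binary([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(0.894, abs=5e-4)
    r = correlate_binary([1, 2, 3, 4], [1, 1, 0, 0])
    assert r == pytest.approx(-0.894, abs=5e-4)
    with pytest.raises(ValueError, match="constant"):
        correlate_binary([2, 2, 2, 2], [0, 0, 1, 1])
    rng = np.random.default_rng(5)
    assert abs(correlate_binary(rng.normal(size=2000), rng.integers(0, 2, 2000))) < 0.08


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------


def _two_group_exp(rng, n, hr):
    group = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / np.where(group == 1, hr, 1.0))
    return pd.DataFrame({"group": group.astype(float)}), t, np.ones(n, int)


def test_cox_null_recovery():
    rng = np.random.default_rng(10)
    cov, t, e = _two_group_exp(rng, 500, 1.0)
    fit = cox_fit(cov, t, e).iloc[0]
    assert abs(fit["beta"]) < 0.2
    assert fit["ci_low"] < 1.0 < fit["ci_high"]


def test_cox_recovers_true_hazard_ratio():
    rng = np.random.default_rng(11)
    cov, t, e = _two_group_exp(rng, 1000, 2.0)
    fit = cox_fit(cov, t, e).iloc[0]
    assert 1.7 <= fit["hr"] <= 2.35


def test_cox_bias_small_across_effect_sizes():
    rng = np.random.default_rng(12)
    for hr in (1.5, 2.0, 3.0):
        errs = []
        for _ in range(20):
            cov, t, e = _two_group_exp(rng, 2000, hr)
            errs.append(cox_fit(cov, t, e)["beta"].iloc[0] - np.log(hr))
        assert abs(np.mean(errs)) < 0.05


def test_cox_multivariate_matches_univariate_for_independent_covariates():
    rng = np.random.default_rng(13)
    n = 1500
    x1 = rng.integers(0, 2, n).astype(float)
    x2 = rng.normal(size=n)
    t = rng.exponential(1.0 / np.exp(0.5 * x1 + 0.3 * x2))
    e = np.ones(n, int)
    multi = cox_fit(pd.DataFrame({"x1": x1, "x2": x2}), t, e).set_index("covariate")
    for name, x in (("x1", x1), ("x2", x2)):
        uni = cox_fit(pd.DataFrame({name: x}), t, e).iloc[0]
        se = (np.log(multi.loc[name, "ci_high"]) - np.log(multi.loc[name, "hr"])) / 1.96
        assert abs(uni["beta"] - multi.loc[name, "beta"]) < se


def test_cox_rejects_bad_inputs():
    with pytest.raises(ValueError, match="constant"):
        cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), [1, 2, 3], [1, 1, 1])
    with pytest.raises(ValueError, match="events"):
        cox_fit(pd.DataFrame({"x": [1.0, 0.0, 1.0]}), [1, 2, 3], [0, 0, 0])


# ---------------------------------------------------------------------------
# Grade discrimination
# ---------------------------------------------------------------------------


def _clinical(n, grades, seed=0, os_time=None, os_event=None):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "patient_id": [f"s{i}" for i in range(n)],
            "grade": grades,
            "os_time": rng.exponential(300, n) if os_time is None else os_time,
            "os_event": rng.integers(0, 2, n) if os_event is None else os_event,
            "pfs_time": rng.exponential(150, n),
            "pfs_event": rng.integers(0, 2, n),
            "idh": rng.choice(["mut", "wt"], n),
            "codel_1p19q": rng.choice(["codel", "non-codel"], n),
            "mgmt": rng.choice(["methylated", "unmethylated"], n),
            "age": rng.normal(50, 10, n),
            "subtype": rng.choice(["mesenchymal", "classical", "proneural"], n),
        }
    )


def test_grade_discrimination_null_auc():
    rng = np.random.default_rng(20)
    n = 400
    clin = _clinical(n, ["LGG"] * 200 + ["GBM"] * 200)
    scores = pd.DataFrame({"b": rng.normal(size=n)}, index=clin["sample_id"])
    out = grade_discrimination([("d", scores, clin)])
    assert abs(out["auc"].iloc[0] - 0.5) < 0.08


def test_grade_discrimination_pal_beats_noisy_single_gene(strong_effect_cohort):
    scores, clinical, _ = strong_effect_cohort
    out = grade_discrimination([("sim", scores, clinical)]).set_index("biomarker")
    assert out.loc["PAL2", "auc"] > 0.9
    assert out.loc["PAL2", "auc"] > out.loc["FREM2_expr", "auc"]
    assert (out["p"] < 0.05).all()


def test_single_grade_dataset_skipped(caplog):
    clin = _clinical(10, ["GBM"] * 10)
    scores = pd.DataFrame({"b": np.arange(10.0)}, index=clin["sample_id"])
    with caplog.at_level("WARNING"):
        out = grade_discrimination([("d", scores, clin)])
    assert out.empty


# ---------------------------------------------------------------------------
# Comparison grid
# ---------------------------------------------------------------------------


def _grid_dataset(n=120, seed=30):
    rng = np.random.default_rng(seed)
    clin = _clinical(n, rng.choice(["LGG", "GBM"], n), seed=seed)
    scores = pd.DataFrame(
        {b: rng.normal(size=n) for b in ["EXPR", "PAL1", "PAL2", "PAL3"]},
        index=pd.Index(clin["sample_id"], name="sample_id"),
    )
    return "d", scores, clin


def test_grid_cell_enumeration_matches_brute_force():
    label, scores, clin = _grid_dataset()
    grid = run_comparison_grid([(label, scores, clin)], fit_cox=False)
    # brute-force enumeration of eligible cells
    expected = 0
    c = clin.set_index("sample_id")
    for grade in ("LGG", "GBM"):
        graded = c[c["grade"] == grade]
        for ep in ("os", "pfs"):
            surv = graded.dropna(subset=[f"{ep}_time", f"{ep}_event"])
            for name, mask in SUBGROUPS.items():
                cell = surv[mask(surv)]
                if len(cell) >= 10 and cell[f"{ep}_event"].sum() > 0:
                    expected += 1
    assert grid.n_cells() == expected
    # every evaluated cell contains all four biomarkers
    per_cell = grid.to_frame().groupby(["grade", "endpoint", "subgroup"]).size()
    assert (per_cell == 4).all()


def test_grid_small_subgroups_excluded():
    label, scores, clin = _grid_dataset(n=40, seed=31)
    # force a 9-sample subgroup: exactly 9 IDH-mut LGG samples
    clin["idh"] = "wt"
    lgg_idx = clin.index[clin["grade"] == "LGG"][:9]
    clin.loc[lgg_idx, "idh"] = "mut"
    grid = run_comparison_grid([(label, scores, clin)], fit_cox=False)
    cells = {(r.grade, r.subgroup) for r in grid.results}
    assert ("LGG", "IDH_mut") not in cells
    assert any(
        s["subgroup"] == "IDH_mut" and s["grade"] == "LGG" and "< 10" in s["reason"]
        for s in grid.skipped
    )


def test_grid_q_values_within_cell():
    label, scores, clin = _grid_dataset()
    grid = run_comparison_grid([(label, scores, clin)], fit_cox=False)
    df = grid.to_frame()
    for _, cell in df.groupby(["dataset", "grade", "endpoint", "subgroup"]):
        np.testing.assert_allclose(np.sort(cell["q"]), np.sort(_bh_oracle(cell["logrank_p"].values)))
        assert (cell["q"] >= cell["logrank_p"] - 1e-12).all()


def test_grid_global_fdr_scope():
    label, scores, clin = _grid_dataset()
    grid = run_comparison_grid([(label, scores, clin)], fdr_scope="global", fit_cox=False)
    df = grid.to_frame()
    np.testing.assert_allclose(np.sort(df["q"]), np.sort(_bh_oracle(df["logrank_p"].values)))


def test_grid_summary_and_consistency_matrix():
    label, scores, clin = _grid_dataset()
    grid = run_comparison_grid([(label, scores, clin)], fit_cox=True)
    summary = grid.summary().set_index("biomarker")
    assert set(summary.index) == {"EXPR", "PAL1", "PAL2", "PAL3"}
    assert (summary["n_comparisons"] == grid.n_cells()).all()
    cm = consistency_matrix(grid, "PAL2")
    assert set(np.unique(cm.values)) <= {"+", "-", "N/A"}
    # HRs populated for most cells
    df = grid.to_frame()
    assert df["hr"].notna().mean() > 0.8


def test_grid_recovers_planted_hazard_direction(strong_effect_cohort):
    """High PAL carries the planted excess hazard: every per-grade 'all' cell
    estimates HR > 1 for PAL2 (within-grade splits see the planted effect
    diluted by the grade-level activity difference, so direction — not
    per-cell significance — is the planted property)."""
    scores, clinical, _ = strong_effect_cohort
    grid = run_comparison_grid([("sim", scores, clinical)])
    df = grid.to_frame()
    cells = df[(df["biomarker"] == "PAL2") & (df["subgroup"] == "all")]
    assert len(cells) == 4  # two grades x OS/PFS
    assert (cells["hr"] > 1.0).all()


# ---------------------------------------------------------------------------
# Patient averaging and activation profiles
# ---------------------------------------------------------------------------


def test_patient_average_basic():
    m = exp_matrix({"G1": {"a1": 2.0, "a2": 4.0, "b1": 10.0}}, "normalized")
    clin = pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "b1"],
            "patient_id": ["A", "A", "B"],
            "grade": ["GBM", "GBM", "GBM"],
        }
    )
    avg, collapsed = patient_average(m, clin)
    assert avg.values.loc["G1", "A"] == 3.0
    assert avg.values.loc["G1", "B"] == 10.0
    assert len(collapsed) == 2


def test_patient_average_collapses_39_samples_to_16_patients():
    rng = np.random.default_rng(40)
    # 12 patients with 2-3 samples plus 4 single-sample patients = 39 samples
    per_patient = [3] * 11 + [2] + [1, 1, 1, 1]
    assert sum(per_patient) == 39
    sids, pids = [], []
    for pi, k in enumerate(per_patient):
        for r in range(k):
            sids.append(f"P{pi}S{r}")
            pids.append(f"P{pi}")
    m = ExpressionMatrix(
        values=pd.DataFrame(rng.integers(1, 100, (5, 39)).astype(float),
                            index=[f"G{i}" for i in range(5)], columns=sids),
        layer="normalized",
    )
    clin = pd.DataFrame({"sample_id": sids, "patient_id": pids, "grade": "GBM"})
    avg, collapsed = patient_average(m, clin)
    assert avg.values.shape[1] == 16
    assert len(collapsed) == 16


def test_patient_average_conflicting_fields_error():
    m = exp_matrix({"G1": {"a1": 2.0, "a2": 4.0}}, "normalized")
    clin = pd.DataFrame(
        {"sample_id": ["a1", "a2"], "patient_id": ["A", "A"], "grade": ["GBM", "LGG"]}
    )
    with pytest.raises(ValueError, match="conflicting"):
        patient_average(m, clin)


def _profile_inputs(gene_values):
    cnr = exp_matrix(gene_values, "cnr")
    pal = pd.DataFrame({"sample_id": ["s1", "s2", "s3", "s4"], "pathway": "p", "pal": [1, 2, 3, 4]})
    return cnr, pal


def test_activation_profile_identical_groups_zero():
    cnr, pal = _profile_inputs({"A": {"s1": 2.0, "s2": 2.0, "s3": 2.0, "s4": 2.0}})
    p = make_pathway("p", {"n1": {"A"}}, [])
    out = group_activation_profile(cnr, pal, p)
    assert out["log_ratio_low_vs_high"].iloc[0] == pytest.approx(0.0)


def test_activation_profile_doubled_in_high_group():
    cnr, pal = _profile_inputs({"A": {"s1": 1.0, "s2": 1.0, "s3": 2.0, "s4": 2.0}})
    p = make_pathway("p", {"n1": {"A"}}, [])
    out = group_activation_profile(cnr, pal, p)
    assert out["log_ratio_low_vs_high"].iloc[0] == pytest.approx(-np.log10(2))


def test_activation_profile_opposite_members_cancel():
    cnr, pal = _profile_inputs(
        {
            "A": {"s1": 1.0, "s2": 1.0, "s3": 2.0, "s4": 2.0},
            "B": {"s1": 2.0, "s2": 2.0, "s3": 1.0, "s4": 1.0},
        }
    )
    p = make_pathway("p", {"n1": {"A", "B"}}, [])
    out = group_activation_profile(cnr, pal, p)
    assert out["log_ratio_low_vs_high"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_activation_profile_unmeasured_node_is_nan():
    cnr, pal = _profile_inputs({"A": {"s1": 1.0, "s2": 1.0, "s3": 2.0, "s4": 2.0}})
    p = make_pathway("p", {"n1": {"A"}, "n2": {"ZZ"}}, [])
    out = group_activation_profile(cnr, pal, p).set_index("node_id")
    assert np.isnan(out.loc["n2", "log_ratio_low_vs_high"])
    assert out.loc["n2", "n_genes_measured"] == 0
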