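"""Nested F-tests, dimorphism classification, effect sizes, KO summaries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols

from dimet import (
    classify_dimorphism,
    nested_f_test,
    study_preset,
    simulate_cohort,
    standardized_fold_change,
    summarize_ko,
    test_line as run_line_tests,
)
from dimet.dimorphism import CATEGORIES, _design

from conftest import make_meta, make_table


def _two_by_two(rng, n_per_cell=5, effects=(0.0, 0.0, 0.0)):
    """Balanced 2x2 genotype x sex layout with optional effects."""
    geno = np.repeat([0, 1], 2 * n_per_cell)
    sex = np.tile(np.repeat([0, 1], n_per_cell), 2)
    g_eff, s_eff, i_eff = effects
    y = (rng.normal(10, 1, geno.size) + g_eff * geno + s_eff * sex
         + i_eff * geno * sex)
    ones = np.ones_like(y)
    X_full = np.column_stack([ones, geno, sex, geno * sex])
    X_int_null = np.column_stack([ones, geno, sex])
    X_geno_null = np.column_stack([ones, sex])
    return y, geno, sex, X_full, X_int_null, X_geno_null


def test_identical_group_means_give_p_near_one():
    # every genotype-sex cell holds the same values: no genotype information
    y = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 4)
    geno = np.repeat([0, 1], 10)
    sex = np.tile(np.repeat([0, 1], 5), 2)
    ones = np.ones_like(y)
    X_full = np.column_stack([ones, geno, sex, geno * sex])
    X_null = np.column_stack([ones, sex])
    f, p = nested_f_test(X_full, X_null, y)
    assert f == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("seed", range(6))
def test_interaction_p_matches_classical_anova(seed):
    rng = np.random.default_rng(seed)
    y, geno, sex, X_full, X_int_null, _ = _two_by_two(
        rng, effects=(1.0, 0.5, 0.8))
    _, p = nested_f_test(X_full, X_int_null, y)
    df = pd.DataFrame({"y": y, "g": geno, "s": sex})
    fit = ols("y ~ C(g) * C(s)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    assert p == pytest.approx(table.loc["C(g):C(s)", "PR(>F)"], rel=1e-8)


def test_location_invariance():
    rng = np.random.default_rng(9)
    y, _, _, X_full, X_int_null, _ = _two_by_two(rng)
    f1, _ = nested_f_test(X_full, X_int_null, y)
    f2, _ = nested_f_test(X_full, X_int_null, y + 1234.5)
    assert f1 == pytest.approx(f2, rel=1e-9)


def test_nested_f_matches_brute_force_projection():
    """The lstsq-based F equals the hat-matrix projection computed from
    explicit pseudoinverses on random small designs."""
    rng = np.random.default_rng(77)
    from scipy import stats as sps
    for _ in range(100):
        n = int(rng.integers(8, 30))
        Xn = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        Xf = np.column_stack([Xn, rng.normal(size=(n, 2))])
        y = rng.normal(size=n)
        f, p = nested_f_test(Xf, Xn, y)
        H1 = Xf @ np.linalg.pinv(Xf)
        H0 = Xn @ np.linalg.pinv(Xn)
        rss1 = y @ (np.eye(n) - H1) @ y
        rss0 = y @ (np.eye(n) - H0) @ y
        d_extra = np.linalg.matrix_rank(Xf) - np.linalg.matrix_rank(Xn)
        d_res = n - np.linalg.matrix_rank(Xf)
        f_ref = ((rss0 - rss1) / d_extra) / (rss1 / d_res)
        assert f == pytest.approx(f_ref, rel=1e-8)
        assert p == pytest.approx(sps.f.sf(f_ref, d_extra, d_res), rel=1e-8)


def test_rank_deficient_design_raises():
    y = np.arange(6.0)
    ones = np.ones(6)
    geno = np.array([1, 1, 1, 0, 0, 0.0])
    sex = np.array([0, 0, 0, 1, 1, 1.0])   # sex aliases genotype
    X_full = np.column_stack([ones, geno, sex, geno * sex])
    X_null = np.column_stack([ones, sex])
    with pytest.raises(ValueError):
        nested_f_test(X_full, X_null, y)


CLASSIFY_CASES = [
    # (p_g, p_i, p_f, p_m, sign_f, sign_m, expected)
    (0.50, 0.30, 0.5, 0.5, 1, 1, "ns"),
    (0.01, 0.30, 0.5, 0.5, 1, 1, "genotype-no-sex-difference"),
    (0.01, 0.01, 0.01, 0.60, 1, 1, "female-only"),
    (0.01, 0.01, 0.60, 0.01, 1, 1, "male-only"),
    (0.01, 0.01, 0.01, 0.01, 1, -1, "opposite-direction"),
    (0.01, 0.01, 0.01, 0.01, 1, 1, "different-effect-size"),
    (0.20, 0.01, 0.60, 0.60, 1, 1, "interaction-only"),
]


@pytest.mark.parametrize("pg,pi,pf,pm,sf,sm,expected", CLASSIFY_CASES)
def test_classification_decision_tree(pg, pi, pf, pm, sf, sm, expected):
    assert classify_dimorphism(pg, pi, pf, pm, sf, sm, alpha=0.05) == expected


def test_classification_genotype_gate_option():
    # interaction significant but genotype test not: gated runs fall back
    assert classify_dimorphism(0.20, 0.01, 0.01, 0.60, 1, 1,
                               gate_on_genotype=True) == "interaction-only"
    assert classify_dimorphism(0.01, 0.01, 0.01, 0.60, 1, 1,
                               gate_on_genotype=True) == "female-only"


def _planted_line_cohort(archetype, n_features=200, seed=0, fc=(1.0, 2.0)):
    fids = [f"met_{i:04d}" for i in range(n_features)]
    cfg = study_preset(
        seed=seed, n_features=n_features, n_ko_lines=1, n_phenotypes=2,
        sex_affected_fraction=0.0, missing_rate=0.0, n_high_missing=0,
        n_high_rsd=0, n_internal_standards=0, batch_effect=1.0,
        ko_log2fc_range=fc,
        archetype_map={"KO01": {f: archetype for f in fids}})
    return simulate_cohort(cfg)


def test_planted_equal_effects_classified_as_no_sex_difference():
    table, meta, annot, _, _ = _planted_line_cohort("both-sexes-equal", seed=21)
    res = run_line_tests(table, meta, "KO01")
    counts = res["category"].value_counts()
    assert counts.get("genotype-no-sex-difference", 0) > 0.5 * len(res)


def test_planted_null_is_mostly_ns():
    table, meta, annot, _, _ = _planted_line_cohort("null", seed=22)
    res = run_line_tests(table, meta, "KO01")
    assert (res["category"] == "ns").mean() > 0.85


def test_planted_opposite_direction_recovery():
    table, meta, annot, _, _ = _planted_line_cohort(
        "opposite-direction", seed=23, fc=(2.0, 2.0))
    res = run_line_tests(table, meta, "KO01")
    assert (res["category"] == "opposite-direction").mean() > 0.5


def test_categories_partition_all_pairs(small_clean):
    prep, meta, annot, truth = small_clean
    res = run_line_tests(prep["table"], meta, meta.ko_lines()[0])
    assert res["category"].isin(CATEGORIES).all()
    assert not res["category"].isna().any()


def test_line_with_missing_sex_is_skipped_with_warning():
    rows = [(f"w{i}", "FM"[i % 2], "WT", "study") for i in range(8)]
    rows += [(f"k{i}", "F", "KO1", "study") for i in range(3)]   # no KO males
    meta = make_meta(rows)
    rng = np.random.default_rng(1)
    table = make_table(rng.lognormal(3, 0.4, size=(11, 4)),
                       sample_ids=[r[0] for r in rows])
    with pytest.warns(UserWarning, match="rank-deficient"):
        res = run_line_tests(table, meta, "KO1")
    assert len(res) == 0


def test_standardized_fold_change_trivials():
    rows = [(f"w{i}", "FM"[i % 2], "WT", "study") for i in range(8)]
    rows += [(f"k{i}", "FM"[i % 2], "KO1", "study") for i in range(6)]
    meta = make_meta(rows)
    vals = np.ones((14, 1))
    vals[8:, 0] = 3.0
    table = make_table(vals, sample_ids=[r[0] for r in rows])
    fc = standardized_fold_change(table, meta, "KO1", "f0")
    assert (fc["standardized_fc"] == 3.0).all()
    vals2 = np.full((14, 1), 2.5)
    table2 = make_table(vals2, sample_ids=[r[0] for r in rows])
    fc2 = standardized_fold_change(table2, meta, "KO1", "f0")
    assert (fc2["standardized_fc"] == 1.0).all()
    assert (fc2["spread"] == 0.0).all()


def test_propagated_spread_matches_bootstrap():
    rng = np.random.default_rng(4)
    rows = [(f"w{i}", "F", "WT", "study") for i in range(20)]
    rows += [(f"k{i}", "F", "KO1", "study") for i in range(10)]
    rows += [("wm", "M", "WT", "study"), ("wm2", "M", "WT", "study"),
             ("km", "M", "KO1", "study"), ("km2", "M", "KO1", "study")]
    meta = make_meta(rows)
    yw = rng.lognormal(2, 0.3, 20)
    yk = rng.lognormal(2.5, 0.3, 10)
    vals = np.r_[yw, yk, rng.lognormal(2, 0.3, 4)][:, None]
    table = make_table(vals, sample_ids=[r[0] for r in rows])
    fc = standardized_fold_change(table, meta, "KO1", "f0")
    spread = fc.set_index("sex").loc["F", "spread"]
    boots = []
    for _ in range(500):
        bw = rng.choice(yw, 20, replace=True)
        bk = rng.choice(yk, 10, replace=True)
        boots.append(bk.mean() / bw.mean())
    assert spread == pytest.approx(np.std(boots, ddof=1), rel=0.2)


def test_summarize_all_ns():
    res = pd.DataFrame({
        "ko_line": ["L1"] * 4, "feature_id": list("abcd"),
        "p_genotype": [0.5] * 4, "p_interaction": [0.6] * 4,
        "p_female": [0.7] * 4, "p_male": [0.8] * 4,
        "fc_female": [1.0] * 4, "fc_male": [1.0] * 4,
        "category": ["ns"] * 4})
    s = summarize_ko(res)
    assert s["global"]["pct_significant"] == 0.0


def test_summarize_category_fractions_sum_to_one(small_clean):
    prep, meta, annot, truth = small_clean
    from dimet import test_all_lines
    res = test_all_lines(prep["table"], meta)
    s = summarize_ko(res)["global"]
    if s["n_significant"]:
        total = sum(s[f"frac_{c}"] for c in CATEGORIES if c != "ns")
        assert total == pytest.approx(1.0)
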