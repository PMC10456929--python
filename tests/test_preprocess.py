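"""QC statistics, quoted filter boundaries, imputation rules, batch scaling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dimet import (
    PhenotypeTable,
    ValidationError,
    compute_qc_stats,
    filter_features,
    impute_half_min,
    impute_phenotype_min,
    median_batch_normalize,
)
from dimet.preprocess import QCStats

from conftest import make_meta, make_table


def _qc_meta(n_qc, n_study):
    rows = [(f"q{i}", "F", "pooled_plasma", "QC") for i in range(n_qc)]
    rows += [(f"s{i}", "F" if i % 2 else "M", "WT", "study") for i in range(n_study)]
    return make_meta(rows)


def test_rsd_of_constant_qc_is_zero():
    meta = _qc_meta(3, 2)
    table = make_table([[10.0], [10.0], [10.0], [5.0], [6.0]],
                       sample_ids=["q0", "q1", "q2", "s0", "s1"])
    qc = compute_qc_stats(table, meta)
    assert qc.frame.loc["f0", "rsd_qc"] == 0.0


def test_rsd_hand_calculation():
    # sd([1,3], n-1) = sqrt(2), mean 2 -> RSD = 70.71%
    meta = _qc_meta(2, 2)
    table = make_table([[1.0], [3.0], [4.0], [4.0]],
                       sample_ids=["q0", "q1", "s0", "s1"])
    qc = compute_qc_stats(table, meta)
    assert qc.frame.loc["f0", "rsd_qc"] == pytest.approx(70.7107, abs=1e-3)


def test_rsd_undefined_with_single_qc_value():
    meta = _qc_meta(1, 2)
    table = make_table([[1.0], [4.0], [4.0]], sample_ids=["q0", "s0", "s1"])
    qc = compute_qc_stats(table, meta)
    assert np.isnan(qc.frame.loc["f0", "rsd_qc"])


def test_missing_fraction_on_study_rows_only():
    meta = _qc_meta(2, 10)
    vals = [[1.0], [1.0]] + [[np.nan]] * 7 + [[2.0]] * 3
    table = make_table(vals, sample_ids=["q0", "q1"] + [f"s{i}" for i in range(10)])
    qc = compute_qc_stats(table, meta)
    assert qc.frame.loc["f0", "missing_fraction"] == pytest.approx(0.7)
    assert qc.frame.loc["f0", "prevalence"] == pytest.approx(0.3)


def _stats_frame(rsd, missing):
    return QCStats(pd.DataFrame({
        "rsd_qc": rsd, "missing_fraction": missing,
        "prevalence": [1 - m for m in missing],
    }, index=[f"f{j}" for j in range(len(rsd))]))


@pytest.mark.parametrize("rsd,missing,kept", [
    (50.0, 0.0, True),    # RSD exactly 50% is retained (rule is strict >)
    (50.01, 0.0, False),
    (10.0, 0.70, False),  # missing exactly 70% removed ("at least 70%")
    (10.0, 0.699, True),
    (10.0, 0.30, True),   # prevalence 0.70 > 0.30
])
def test_filter_boundaries(rsd, missing, kept):
    table = make_table([[1.0], [2.0]])
    out, log = filter_features(table, _stats_frame([rsd], [missing]))
    assert (len(out.feature_ids) == 1) is kept


def test_prevalence_exactly_030_removed():
    # detected in exactly 30% of samples is NOT "more than 30%"
    table = make_table([[1.0], [2.0]])
    out, log = filter_features(table, _stats_frame([10.0], [0.70]))
    assert out.feature_ids == []
    assert "prevalence" in log["removed_because"].iloc[0] or \
           "missing" in log["removed_because"].iloc[0]


def test_internal_standard_removed_by_flag(small_cohort, small_clean):
    table, meta, annot, _, _ = small_cohort
    prep = small_clean[0]
    istd = annot.frame.index[annot.frame["is_internal_standard"]]
    assert len(istd) > 0
    assert not set(istd) & set(prep["table"].feature_ids)
    logged = prep["removal_log"]
    flagged = logged[logged["removed_because"].str.contains("internal_standard")]
    assert set(flagged["feature_id"]) >= set(istd)


def test_filter_order_independence():
    rng = np.random.default_rng(42)
    n = 60
    stats = _stats_frame(list(rng.uniform(0, 100, n)), list(rng.uniform(0, 1, n)))
    table = make_table(rng.lognormal(1, 1, size=(3, n)))
    rules = [dict(rsd_max=50.0, missing_max=2.0, prevalence_min=-1.0),
             dict(rsd_max=np.inf, missing_max=0.70, prevalence_min=-1.0),
             dict(rsd_max=np.inf, missing_max=2.0, prevalence_min=0.30)]
    results = set()
    for perm in itertools.permutations(rules):
        t = table
        for rule in perm:
            t, _ = filter_features(t, QCStats(stats.frame.loc[t.feature_ids]), **rule)
        results.add(tuple(t.feature_ids))
    assert len(results) == 1


def test_half_min_imputation_rule():
    meta = make_meta([("a1", "F", "WT", "study"), ("a2", "M", "WT", "study"),
                      ("a3", "F", "WT", "study")])
    table = make_table([[2.0], [4.0], [np.nan]], sample_ids=["a1", "a2", "a3"])
    out = impute_half_min(table, meta)
    assert out.data.loc["a3", "f0"] == 1.0


def test_half_min_is_group_wise_not_global():
    meta = make_meta([("w1", "F", "WT", "study"), ("w2", "M", "WT", "study"),
                      ("k1", "F", "KO1", "study"), ("k2", "M", "KO1", "study")])
    table = make_table([[2.0], [np.nan], [8.0], [np.nan]],
                       sample_ids=["w1", "w2", "k1", "k2"])
    out = impute_half_min(table, meta)
    assert out.data.loc["w2", "f0"] == 1.0
    assert out.data.loc["k2", "f0"] == 4.0


def test_imputation_leaves_no_missing_and_preserves_observed(small_cohort):
    table, meta, annot, _, _ = small_cohort
    out = impute_half_min(table, meta)
    study = meta.study_samples().index
    assert not out.data.loc[study].isna().any().any()
    obs = table.data.notna()
    pd.testing.assert_frame_equal(out.data[obs], table.data[obs])


def test_imputed_values_below_group_minimum():
    meta = make_meta([(f"s{i}", "F", "WT", "study") for i in range(5)])
    vals = [[3.0], [7.0], [np.nan], [np.nan], [5.0]]
    table = make_table(vals, sample_ids=[f"s{i}" for i in range(5)])
    out = impute_half_min(table, meta)
    assert (out.data["f0"].dropna() <= 7.0).all()
    assert out.data.loc["s2", "f0"] <= 3.0


def test_feature_with_no_observed_values_rejected():
    meta = make_meta([("s0", "F", "WT", "study"), ("s1", "M", "WT", "study")])
    table = make_table([[np.nan], [np.nan]])
    with pytest.raises(ValidationError):
        impute_half_min(table, meta)


def test_phenotype_dropped_when_sex_group_mostly_missing():
    rows = [(f"f{i}", "F", "WT", "study") for i in range(10)]
    rows += [(f"m{i}", "M", "WT", "study") for i in range(10)]
    meta = make_meta(rows)
    vals = np.ones((20, 1))
    vals[:8, 0] = np.nan    # 8 of 10 females missing
    pheno = PhenotypeTable(pd.DataFrame(vals, index=[r[0] for r in rows],
                                        columns=["p0"]))
    out, dropped = impute_phenotype_min(pheno, meta)
    assert dropped == ["p0"]
    assert out.data.shape[1] == 0


def test_phenotype_group_minimum_imputation():
    meta = make_meta([("s0", "F", "WT", "study"), ("s1", "M", "WT", "study"),
                      ("s2", "F", "WT", "study")])
    pheno = PhenotypeTable(pd.DataFrame(
        {"p0": [5.0, 7.0, np.nan]}, index=["s0", "s1", "s2"]))
    out, dropped = impute_phenotype_min(pheno, meta)
    assert dropped == []
    assert out.data.loc["s2", "p0"] == 5.0   # full minimum, not half


def test_phenotype_identity_when_complete():
    meta = make_meta([("s0", "F", "WT", "study"), ("s1", "M", "WT", "study")])
    pheno = PhenotypeTable(pd.DataFrame({"p0": [1.0, 2.0]}, index=["s0", "s1"]))
    out, dropped = impute_phenotype_min(pheno, meta)
    pd.testing.assert_frame_equal(out.data, pheno.data)


def test_batch_normalize_single_batch_identity():
    meta = make_meta([(f"s{i}", "F", "WT", "study", "B1") for i in range(4)])
    table = make_table(np.arange(1.0, 9.0).reshape(4, 2), platform="HILIC")
    out = median_batch_normalize(table, meta, min_batch_obs=1)
    np.testing.assert_allclose(out.data.to_numpy(), table.data.to_numpy())


def test_batch_normalize_equalizes_doubled_batch():
    rows = [(f"a{i}", "F", "WT", "study", "B1") for i in range(5)]
    rows += [(f"b{i}", "F", "WT", "study", "B2") for i in range(5)]
    meta = make_meta(rows)
    rng = np.random.default_rng(0)
    base = rng.lognormal(3, 0.4, size=(5, 6))
    vals = np.vstack([base, base * 2.0])
    table = make_table(vals, sample_ids=[r[0] for r in rows], platform="HILIC")
    out = median_batch_normalize(table, meta)
    med_a = out.data.iloc[:5].median(axis=0)
    med_b = out.data.iloc[5:].median(axis=0)
    np.testing.assert_allclose(med_a.to_numpy(), med_b.to_numpy(), rtol=1e-9)


def test_batch_normalize_random_data_median_ratio():
    rng = np.random.default_rng(17)
    rows = [(f"a{i}", "F", "WT", "study", "B1") for i in range(20)]
    rows += [(f"b{i}", "M", "WT", "study", "B2") for i in range(20)]
    meta = make_meta(rows)
    vals = rng.lognormal(5, 0.6, size=(40, 30))
    vals[20:] *= rng.uniform(1.2, 1.8)
    table = make_table(vals, sample_ids=[r[0] for r in rows], platform="HILIC")
    out = median_batch_normalize(table, meta)
    ratio = (out.data.iloc[:20].median(axis=0) /
             out.data.iloc[20:].median(axis=0))
    assert ((ratio > 0.99) & (ratio < 1.01)).all()


def test_batch_normalize_scale_equivariance():
    rows = [(f"a{i}", "F", "WT", "study", f"B{1 + i % 2}") for i in range(10)]
    meta = make_meta(rows)
    rng = np.random.default_rng(3)
    vals = rng.lognormal(2, 0.5, size=(10, 4))
    t1 = make_table(vals, sample_ids=[r[0] for r in rows], platform="HILIC")
    t2 = make_table(vals * 7.5, sample_ids=[r[0] for r in rows], platform="HILIC")
    o1 = median_batch_normalize(t1, meta)
    o2 = median_batch_normalize(t2, meta)
    np.testing.assert_allclose(o2.data.to_numpy(), 7.5 * o1.data.to_numpy(),
                               rtol=1e-9)


def test_non_listed_platform_untouched():
    rows = [(f"a{i}", "F", "WT", "study", f"B{1 + i % 2}") for i in range(6)]
    meta = make_meta(rows)
    vals = np.arange(1.0, 13.0).reshape(6, 2)
    table = make_table(vals, sample_ids=[r[0] for r in rows], platform="GC")
    out = median_batch_normalize(table, meta, platforms=("HILIC",))
    pd.testing.assert_frame_equal(out.data, table.data)
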