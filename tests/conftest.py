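import numpy as np
import pandas as pd
import pytest

from dimet import AbundanceTable, SampleMeta, study_preset, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced study-shaped cohort shared by read-only tests."""
    cfg = study_preset(seed=7, n_features=120, n_phenotypes=12,
                       n_high_missing=4, n_high_rsd=4, n_internal_standards=2)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_clean(small_cohort):
    from dimet import preprocess_cohort
    table, meta, annot, pheno, truth = small_cohort
    prep = preprocess_cohort(table, meta, annot, pheno)
    return prep, meta, annot, truth


def make_table(values, sample_ids=None, feature_ids=None, platform="GC"):
    """Small AbundanceTable from a nested list; NaN allowed."""
    arr = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(arr.shape[0])]
    feature_ids = feature_ids or [f"f{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=sample_ids, columns=feature_ids)
    plat = pd.Series(platform, index=feature_ids)
    return AbundanceTable(df, plat)


def make_meta(rows):
    """SampleMeta from (sample_id, sex, genotype, role[, batch, weight]) tuples."""
    recs = []
    for r in rows:
        sid, sex, geno, role = r[:4]
        batch = r[4] if len(r) > 4 else "B1"
        weight = r[5] if len(r) > 5 else np.nan
        zyg = "wt" if geno == "WT" else ("na" if role != "study" else "hom")
        recs.append({"sample_id": sid, "sex": sex, "genotype": geno,
                     "zygosity": zyg, "role": role, "batch": batch,
                     "body_weight": weight})
    return SampleMeta(pd.DataFrame(recs).set_index("sample_id"))
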