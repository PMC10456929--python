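"""Generate a knockout-cohort simulation and inspect its planted truth.

The preset mirrors a phenomics screen: 40 wildtype mice (20 per sex),
30 KO lines with three mice per sex, ~800 metabolite features on five MS
platforms, pooled-plasma QC replicates, and MNAR missingness.
"""

from dimet import study_preset, simulate_cohort

cfg = study_preset(seed=42, n_features=200, n_phenotypes=20)
table, meta, annot, pheno, truth = simulate_cohort(cfg)

study = meta.study_samples()
print(f"samples: {len(meta.sample_ids)} total "
      f"({len(study)} study, {len(meta.qc_samples())} QC)")
counts = {k: int(v) for k, v in table.platform.value_counts().items()}
print(f"features: {len(table.feature_ids)} across platforms {counts}")
print(f"missing cells in study rows: "
      f"{table.data.loc[study.index].isna().to_numpy().mean():.1%}")
print("\nplanted KO archetypes (rows of the truth table):")
print(truth.frame["archetype"].value_counts().to_string())
# Each row records the exact log2 effect planted per sex for one
# (feature, KO line) pair; recovery tests compare the classifier against it.
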