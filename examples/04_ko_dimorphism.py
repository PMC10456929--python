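"""Test one knockout line and classify its sexually dimorphic changes.

The genotype effect compares Y ~ Genotype + Sex + Genotype:Sex against
Y ~ Sex; the interaction effect compares the same full model against
Y ~ Genotype + Sex.  Significant interactions are sub-classified by the
per-sex KO-vs-WT contrasts into female-only, male-only,
opposite-direction or different-effect-size changes.
"""

from dimet import (
    study_preset,
    preprocess_cohort,
    simulate_cohort,
    standardized_fold_change,
    summarize_ko,
    test_all_lines,
)

table, meta, annot, pheno, truth = simulate_cohort(study_preset(seed=42, n_features=200))
clean = preprocess_cohort(table, meta, annot)["table"]

res = test_all_lines(clean, meta)
s = summarize_ko(res)["global"]
print(f"{s['n_significant']} of {s['n_tests']} (line, metabolite) tests "
      f"significant ({s['pct_significant']}%); "
      f"{s['pct_dimorphic_among_significant']}% of those sexually dimorphic")
print("\ncategory decomposition of significant changes:")
for cat in ("genotype-no-sex-difference", "female-only", "male-only",
            "opposite-direction", "different-effect-size", "interaction-only"):
    print(f"  {cat:28s} {s['n_' + cat]:5d}  ({100 * s['frac_' + cat]:.1f}%)")

hit = res[res["category"] == "opposite-direction"].nsmallest(1, "p_interaction")
if len(hit):
    row = hit.iloc[0]
    fc = standardized_fold_change(clean, meta, row["ko_line"], row["feature_id"])
    print(f"\nexample opposite-direction hit: {row['feature_id']} in {row['ko_line']}")
    print(fc[["sex", "standardized_fc", "spread"]].to_string(index=False))
# standardized_fc is the KO mean over the sex-matched WT mean; 1.0 = no change.
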