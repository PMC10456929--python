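"""Knockout-line testing and sexual-dimorphism classification.

For each KO line the six mutant mice are compared against the full shared
wildtype pool with nested ordinary-least-squares models:

* genotype effect:   Y ~ Genotype + Sex + Genotype:Sex   vs   Y ~ Sex
* interaction:       Y ~ Genotype + Sex + Genotype:Sex   vs   Y ~ Genotype + Sex

plus per-sex two-group KO-vs-WT contrasts.  Significant changes are then
labelled by a decision tree: a genotype effect without interaction is
``genotype-no-sex-difference``; an interaction is sub-classified by which
per-sex contrasts reach significance and whether their directions agree
(``female-only``, ``male-only``, ``opposite-direction``,
``different-effect-size``), with ``interaction-only`` reserved for an
interaction that neither per-sex contrast individually supports.  No
multiplicity correction is applied across metabolites here by default —
enrichment across chemical clusters carries the FDR control instead — but
``fdr=True`` adds BH q-values per test family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import bh_fdr, nested_f_test, two_group_test
from .tables import AbundanceTable, SampleMeta, ValidationError, WT_GENOTYPE

CATEGORIES = (
    "ns", "genotype-no-sex-difference", "female-only", "male-only",
    "opposite-direction", "different-effect-size", "interaction-only",
)

DIMORPHIC_CATEGORIES = (
    "female-only", "male-only", "opposite-direction",
    "different-effect-size", "interaction-only",
)


def classify_dimorphism(p_genotype: float, p_interaction: float,
                        p_female: float, p_male: float,
                        sign_female: float, sign_male: float,
                        alpha: float = 0.05,
                        gate_on_genotype: bool = False) -> str:
    """Label one (line, feature) pair by the dimorphism decision tree.

    With ``gate_on_genotype=True`` the interaction sub-classification also
    requires the genotype test itself to be significant; pairs failing the
    gate fall back to ``interaction-only``.
    """
    sig_i = p_interaction < alpha
    sig_g = p_genotype < alpha
    if not sig_i:
        return "genotype-no-sex-difference" if sig_g else "ns"
    if gate_on_genotype and not sig_g:
        return "interaction-only"
    sig_f = p_female < alpha
    sig_m = p_male < alpha
    if sig_f and not sig_m:
        return "female-only"
    if sig_m and not sig_f:
        return "male-only"
    if sig_f and sig_m:
        return "opposite-direction" if sign_female * sign_male < 0 \
            else "different-effect-size"
    return "interaction-only"


def _design(meta_frame: pd.DataFrame, ko_line: str):
    geno = (meta_frame["genotype"] == ko_line).astype(float).to_numpy()
    sex_m = (meta_frame["sex"] == "M").astype(float).to_numpy()
    ones = np.ones_like(geno)
    X_full = np.column_stack([ones, geno, sex_m, geno * sex_m])
    X_null_geno = np.column_stack([ones, sex_m])
    X_null_int = np.column_stack([ones, geno, sex_m])
    return X_full, X_null_geno, X_null_int


def test_line(table: AbundanceTable, meta: SampleMeta, ko_line: str,
              alpha: float = 0.05, welch: bool = False,
              gate_on_genotype: bool = False,
              fdr: bool = False) -> pd.DataFrame:
    """Run all tests for one KO line against the shared WT pool.

    Returns one row per feature with p_genotype, p_interaction, p_female,
    p_male, natural-scale fold-changes (KO mean over sex-matched WT mean)
    and the dimorphism category.  A line missing one sex entirely makes the
    interaction design rank-deficient; the line is then skipped with a
    warning and an empty frame is returned.
    """
    study = meta.study_samples()
    if ko_line not in set(study["genotype"]):
        raise ValidationError(f"unknown KO line {ko_line!r}")
    sub = study[study["genotype"].isin([ko_line, WT_GENOTYPE])]
    Y = table.data.loc[sub.index].to_numpy()
    X_full, X_null_geno, X_null_int = _design(sub, ko_line)
    try:
        f_g, p_g = nested_f_test(X_full, X_null_geno, Y)
        f_i, p_i = nested_f_test(X_full, X_null_int, Y)
    except ValueError as exc:
        warnings.warn(f"line {ko_line}: rank-deficient design ({exc}); skipped",
                      stacklevel=2)
        return pd.DataFrame(columns=[
            "ko_line", "feature_id", "p_genotype", "p_interaction",
            "p_female", "p_male", "fc_female", "fc_male", "category"])

    out = {"ko_line": ko_line, "feature_id": table.feature_ids,
           "p_genotype": p_g, "p_interaction": p_i}
    signs, fcs = {}, {}
    for sex in ("F", "M"):
        sx = sub[sub["sex"] == sex]
        is_ko = (sx["genotype"] == ko_line).to_numpy()
        Ys = table.data.loc[sx.index].to_numpy()
        est, _, p = two_group_test(Ys, is_ko, welch=welch)
        mean_ko = Ys[is_ko].mean(axis=0)
        mean_wt = Ys[~is_ko].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(mean_wt > 0, mean_ko / mean_wt, np.nan)
        out[f"p_{'female' if sex == 'F' else 'male'}"] = p
        fcs[sex] = fc
        signs[sex] = np.sign(est)
    out["fc_female"] = fcs["F"]
    out["fc_male"] = fcs["M"]
    df = pd.DataFrame(out)
    if fdr:
        for col in ("p_genotype", "p_interaction", "p_female", "p_male"):
            df[f"q_{col[2:]}"] = bh_fdr(df[col])
    df["category"] = [
        classify_dimorphism(pg, pi, pf, pm, sf, sm, alpha=alpha,
                            gate_on_genotype=gate_on_genotype)
        for pg, pi, pf, pm, sf, sm in zip(
            df["p_genotype"], df["p_interaction"],
            df["p_female"], df["p_male"], signs["F"], signs["M"])
    ]
    return df


def test_all_lines(table: AbundanceTable, meta: SampleMeta,
                   alpha: float = 0.05, **kwargs) -> pd.DataFrame:
    """Concatenate :func:`test_line` over every KO line in the metadata."""
    frames = [test_line(table, meta, line, alpha=alpha, **kwargs)
              for line in meta.ko_lines()]
    if not frames:
        raise ValidationError("no KO lines in metadata")
    return pd.concat(frames, ignore_index=True)


def standardized_fold_change(table: AbundanceTable, meta: SampleMeta,
                             ko_line: str, feature: str) -> pd.DataFrame:
    """KO arithmetic mean over the sex-matched WT mean, with an sd band.

    The spread is the first-order (delta-method) standard deviation of the
    ratio of the two group means:
    ``fc * sqrt(se_KO^2/mean_KO^2 + se_WT^2/mean_WT^2)`` with ``se`` the
    standard errors of the group means.
    """
    study = meta.study_samples()
    rows = []
    for sex in ("F", "M"):
        ko = study[(study["genotype"] == ko_line) & (study["sex"] == sex)]
        wt = study[(study["genotype"] == WT_GENOTYPE) & (study["sex"] == sex)]
        if len(wt) == 0:
            raise ValidationError(f"no WT {sex} reference samples")
        yk = table.data.loc[ko.index, feature].to_numpy()
        yw = table.data.loc[wt.index, feature].to_numpy()
        mk, mw = yk.mean(), yw.mean()
        if mw <= 0:
            raise ValidationError("non-positive WT reference mean")
        fc = mk / mw
        se_k2 = yk.var(ddof=1) / len(yk) if len(yk) > 1 else 0.0
        se_w2 = yw.var(ddof=1) / len(yw) if len(yw) > 1 else 0.0
        spread = abs(fc) * np.sqrt(se_k2 / mk ** 2 + se_w2 / mw ** 2) \
            if mk != 0 else np.sqrt(se_k2) / mw
        rows.append({"ko_line": ko_line, "feature_id": feature, "sex": sex,
                     "standardized_fc": fc, "spread": spread,
                     "n_ko": len(yk), "n_wt": len(yw)})
    return pd.DataFrame(rows)


def summarize_ko(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Global and per-line decomposition of KO test outcomes.

    ``significant`` means the genotype or the interaction test reached
    alpha; among significant pairs the category fractions sum to one, and
    ``dimorphic`` pools every category except
    ``genotype-no-sex-difference``.
    """
    if len(results) == 0:
        raise ValidationError("empty KO result set")
    res = results.copy()
    res["significant"] = (res["p_genotype"] < alpha) | (res["p_interaction"] < alpha)

    def _decompose(df: pd.DataFrame) -> dict:
        n = len(df)
        sig = df[df["significant"]]
        out = {
            "n_tests": n,
            "n_significant": len(sig),
            "pct_significant": round(100.0 * len(sig) / n, 1) if n else 0.0,
        }
        for cat in CATEGORIES:
            if cat == "ns":
                continue
            k = int((sig["category"] == cat).sum())
            out[f"n_{cat}"] = k
            out[f"frac_{cat}"] = k / len(sig) if len(sig) else 0.0
        n_dim = int(sig["category"].isin(DIMORPHIC_CATEGORIES).sum())
        out["n_dimorphic"] = n_dim
        out["pct_dimorphic_among_significant"] = (
            round(100.0 * n_dim / len(sig), 1) if len(sig) else 0.0)
        return out

    per_line = pd.DataFrame([
        {"ko_line": line, **_decompose(grp)}
        for line, grp in res.groupby("ko_line", sort=True)
    ])
    return {"global": _decompose(res), "per_line": per_line, "alpha": alpha}
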