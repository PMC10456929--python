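"""Per-sex metabolite-phenotype association in wildtype mice.

Each (metabolite, phenotype) pair is tested separately in females and in
males with Spearman rank correlation on pairwise-complete observations.
Pairs with 14 or fewer points in either sex are skipped (n >= 15 strict).
A pair is then categorised by which sexes reach significance and whether
the correlation signs agree:

``both-same-direction`` / ``both-opposite-direction`` / ``female-only`` /
``male-only`` / ``ns``.

Cluster-level summaries reuse the KS enrichment machinery per
(phenotype, sex), signing each cell by the median rho of its significant
members, which yields a long-format table ready for a red/blue heatmap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import DEFAULT_MIN_SIZE, enrich_clusters
from .stats import spearman, spearman_matrix
from .tables import AbundanceTable, PhenotypeTable, SampleMeta, ValidationError

MIN_POINTS = 15  # "more than 14 data points", strict

CORR_CATEGORIES = ("ns", "female-only", "male-only",
                   "both-same-direction", "both-opposite-direction")


def _categorize(p_f, p_m, rho_f, rho_m, alpha):
    sig_f = p_f < alpha
    sig_m = p_m < alpha
    if sig_f and sig_m:
        return ("both-same-direction" if np.sign(rho_f) == np.sign(rho_m)
                else "both-opposite-direction")
    if sig_f:
        return "female-only"
    if sig_m:
        return "male-only"
    return "ns"


def _sex_correlations(X: pd.DataFrame, P: pd.DataFrame, min_n: int):
    """Spearman rho/p/n for all (feature, phenotype) pairs within one sex.

    Vectorises the complete-data case per phenotype; features with missing
    values fall back to the scalar routine on pairwise-complete rows.
    Returns (rho, p, n) DataFrames of shape features x phenotypes; pairs
    with n < min_n or a constant vector get NaN rho/p.
    """
    feats, phenos = list(X.columns), list(P.columns)
    rho = pd.DataFrame(np.nan, index=feats, columns=phenos)
    pvl = pd.DataFrame(np.nan, index=feats, columns=phenos)
    cnt = pd.DataFrame(0, index=feats, columns=phenos, dtype=int)
    x_complete = X.notna().all(axis=0)
    for pid in phenos:
        pv = P[pid]
        valid = pv.notna()
        Xv = X.loc[valid]
        yv = pv[valid].to_numpy()
        full = [f for f in feats if x_complete[f] or Xv[f].notna().all()]
        n_full = int(valid.sum())
        if full and n_full >= min_n and np.unique(yv).size > 1:
            r, p = spearman_matrix(Xv[full].to_numpy(), yv[:, None])
            r, p = r[:, 0], p[:, 0]
            const = Xv[full].nunique().to_numpy() < 2
            r[const] = np.nan
            p[const] = np.nan
            rho.loc[full, pid] = r
            pvl.loc[full, pid] = p
            cnt.loc[full, pid] = n_full
        elif full:
            cnt.loc[full, pid] = n_full
        rest = [f for f in feats if f not in set(full)]
        for f in rest:
            both = valid & X[f].notna()
            n = int(both.sum())
            cnt.loc[f, pid] = n
            if n < min_n:
                continue
            r, p = spearman(X.loc[both, f].to_numpy(), pv[both].to_numpy())
            rho.loc[f, pid] = r
            pvl.loc[f, pid] = p
    return rho, pvl, cnt


def spearman_by_sex(table: AbundanceTable, pheno: PhenotypeTable,
                    meta: SampleMeta, alpha: float = 0.05,
                    min_n: int = MIN_POINTS) -> pd.DataFrame:
    """All-pairs per-sex Spearman correlations in WT mice.

    Returns one row per retained (feature, phenotype) pair with rho/p/n per
    sex and the dimorphism category; pairs skipped by the sample-size rule
    or a constant vector are counted in ``result.attrs['n_skipped']``.
    """
    wt = meta.wt_samples()
    if len(wt) == 0:
        raise ValidationError("no wildtype study samples")
    common = wt.index.intersection(pheno.data.index)
    parts = {}
    for sex in ("F", "M"):
        ids = wt.index[wt["sex"] == sex].intersection(common)
        parts[sex] = _sex_correlations(
            table.data.loc[ids], pheno.data.loc[ids], min_n)
    rho_f, p_f, n_f = parts["F"]
    rho_m, p_m, n_m = parts["M"]
    rows = []
    n_skipped = 0
    for fid in table.feature_ids:
        for pid in pheno.phenotype_ids:
            rf, pf = rho_f.at[fid, pid], p_f.at[fid, pid]
            rm, pm = rho_m.at[fid, pid], p_m.at[fid, pid]
            if np.isnan(rf) or np.isnan(rm):
                n_skipped += 1
                continue
            rows.append({
                "feature_id": fid, "phenotype_id": pid,
                "rho_F": rf, "p_F": pf, "n_F": int(n_f.at[fid, pid]),
                "rho_M": rm, "p_M": pm, "n_M": int(n_m.at[fid, pid]),
                "category": _categorize(pf, pm, rf, rm, alpha),
            })
    out = pd.DataFrame(rows, columns=[
        "feature_id", "phenotype_id", "rho_F", "p_F", "n_F",
        "rho_M", "p_M", "n_M", "category"])
    out.attrs["n_skipped"] = n_skipped
    return out


def categorize_summary(results: pd.DataFrame) -> dict:
    """Counts and one-decimal percentages of the correlation categories.

    ``n_significant`` is the union over sexes (every non-ns pair); the four
    dimorphism categories partition it exactly.
    """
    n = len(results)
    counts = results["category"].value_counts()
    n_sig = int(n - counts.get("ns", 0))

    def pct(k, denom):
        return round(100.0 * k / denom, 1) if denom else 0.0

    out = {"n_tested": n, "n_significant": n_sig,
           "pct_significant": pct(n_sig, n)}
    for cat in CORR_CATEGORIES:
        if cat == "ns":
            continue
        k = int(counts.get(cat, 0))
        out[f"n_{cat}"] = k
        out[f"pct_{cat}"] = pct(k, n)
        out[f"pct_{cat}_of_significant"] = pct(k, n_sig)
    return out


def cluster_phenotype_matrix(results: pd.DataFrame, clusters: pd.Series,
                             alpha: float = 0.05,
                             min_size: int = DEFAULT_MIN_SIZE) -> pd.DataFrame:
    """Cluster-level association map over (phenotype, sex) slices.

    For every phenotype and sex, the member correlation p-values of each
    chemical cluster are tested for enrichment; the cell value is
    ``sign(median rho of significant members) * -log10(ks_p)``.  Output is
    long-format with exactly |phenotypes| x |clusters >= min_size| x 2
    rows.
    """
    cl = clusters.dropna()
    sizes = cl[cl.index.isin(results["feature_id"].unique())].value_counts()
    tested_clusters = sorted(sizes.index[sizes >= min_size].astype(str))
    rows = []
    for pid, grp in results.groupby("phenotype_id", sort=True):
        g = grp.set_index("feature_id")
        for sex, pcol, rcol in (("F", "p_F", "rho_F"), ("M", "p_M", "rho_M")):
            enr = enrich_clusters(g[pcol], np.sign(g[rcol]), cl,
                                  alpha=alpha, min_size=min_size)
            enr = enr.set_index("cluster")
            for cluster in tested_clusters:
                if cluster in enr.index:
                    e = enr.loc[cluster]
                    val = float(e["direction_score"]) or 1.0
                    rows.append({
                        "phenotype_id": pid, "sex": sex, "cluster": cluster,
                        "size": int(e["size"]), "ks_p": float(e["ks_p"]),
                        "q_value": float(e["q_value"]),
                        "signed_neg_log10_p": float(np.sign(val) * e["neg_log10_p"]),
                        "significant": bool(e["significant"]),
                    })
                else:   # too few members with a p-value in this slice
                    rows.append({
                        "phenotype_id": pid, "sex": sex, "cluster": cluster,
                        "size": 0, "ks_p": np.nan, "q_value": np.nan,
                        "signed_neg_log10_p": 0.0, "significant": False,
                    })
    return pd.DataFrame(rows)
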