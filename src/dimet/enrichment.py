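"""Chemical-cluster enrichment by a one-sided Kolmogorov-Smirnov test.

Metabolites are grouped into non-overlapping chemical clusters (supplied
as annotation — cluster derivation from structure or ontology is outside
this package).  For each cluster the member p-values from any upstream
test are compared against Uniform(0,1) with a one-sided KS statistic
(D+ — sensitive to an excess of small p-values), and Benjamini-Hochberg
FDR is applied across clusters.  This is set-level inference: individual
metabolite tests stay uncorrected, the multiplicity control lives here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr
from .tables import ValidationError

DEFAULT_MIN_SIZE = 3


def ks_uniform_pvalue(p_members) -> tuple[float, float]:
    """One-sided KS test of a p-value sample against Uniform(0,1).

    Returns ``(D_plus, p)`` where D+ = sup_x (ECDF(x) - x); large D+ means
    the members concentrate at small p-values.
    """
    x = np.asarray(p_members, dtype=float)
    res = sps.ks_1samp(x, sps.uniform.cdf, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def enrich_clusters(member_p: pd.Series, member_direction: pd.Series,
                    clusters: pd.Series, alpha: float = 0.05,
                    min_size: int = DEFAULT_MIN_SIZE) -> pd.DataFrame:
    """Cluster-level enrichment of per-feature p-values.

    ``member_p``, ``member_direction`` and ``clusters`` are aligned by
    feature id; features with no cluster label or no p-value are ignored.
    Clusters smaller than ``min_size`` are excluded (listed in
    ``result.attrs['skipped_clusters']``).  Output columns: cluster, size,
    ks_p, q_value, altered_fraction (members with p < alpha),
    increased_fraction (among altered, fraction with positive direction),
    direction_score (median direction of altered members, else of all),
    neg_log10_p, and the key compound (member with the smallest p).
    """
    bad = member_p.dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValidationError("member p-values must lie in [0, 1]")
    df = pd.DataFrame({
        "p": member_p,
        "direction": member_direction.reindex(member_p.index),
        "cluster": clusters.reindex(member_p.index),
    }).dropna(subset=["p", "cluster"])
    rows, skipped = [], []
    for cl, grp in df.groupby("cluster", sort=True):
        if len(grp) < min_size:
            skipped.append(str(cl))
            continue
        d_plus, ks_p = ks_uniform_pvalue(grp["p"].to_numpy())
        altered = grp[grp["p"] < alpha]
        n_alt = len(altered)
        inc = float((altered["direction"] > 0).mean()) if n_alt else np.nan
        score_src = altered if n_alt else grp
        rows.append({
            "cluster": str(cl),
            "size": len(grp),
            "ks_statistic": d_plus,
            "ks_p": ks_p,
            "altered_fraction": n_alt / len(grp),
            "increased_fraction": inc,
            "direction_score": float(np.median(score_src["direction"])),
            "key_compound": grp["p"].idxmin(),
        })
    out = pd.DataFrame(rows, columns=[
        "cluster", "size", "ks_statistic", "ks_p", "altered_fraction",
        "increased_fraction", "direction_score", "key_compound"])
    if len(out):
        out["q_value"] = bh_fdr(out["ks_p"])
        out["neg_log10_p"] = -np.log10(np.maximum(out["ks_p"], 1e-300))
        out["significant"] = (out["ks_p"] < alpha) | (out["q_value"] < alpha)
    else:
        for col in ("q_value", "neg_log10_p", "significant"):
            out[col] = []
    out.attrs["skipped_clusters"] = skipped
    return out
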