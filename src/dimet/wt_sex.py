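"""Sex-difference testing in wildtype mice.

Each metabolite (or continuous phenotype) is fit with a linear model
``Y ~ Sex`` — optionally ``Y ~ Sex + Weight`` — and the two-sided Wald
p-value of the sex coefficient is reported.  ``variance_mode='per-sex'``
(the default) runs two-step feasible generalised least squares with a
separate residual variance per sex, the natural heteroskedasticity for a
two-group comparison; ``'pooled'`` is ordinary least squares, identical to
the pooled-variance t-test.  Fold-changes are ratios of arithmetic means on
the natural scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import bh_fdr
from .tables import AbundanceTable, SampleMeta, ValidationError

VARIANCE_MODES = ("pooled", "per-sex")


def fit_sex_model(y, meta_frame: pd.DataFrame, adjust_weight: bool = False,
                  variance_mode: str = "per-sex") -> dict:
    """Fit the sex model for one response vector.

    ``meta_frame`` must be the metadata rows (same order as ``y``) of the
    samples being modelled, with ``sex`` and, if ``adjust_weight``,
    ``body_weight`` columns.  Returns a dict with ``estimate`` (mean M - F,
    adjusted if a covariate is present), ``log2_fc`` (log2 of the ratio of
    arithmetic means M/F), ``p_value``, and group means.
    """
    if variance_mode not in VARIANCE_MODES:
        raise ValidationError(f"variance_mode must be one of {VARIANCE_MODES}")
    y = np.asarray(y, dtype=float)
    # un-imputed inputs may still carry missing cells: pairwise deletion
    keep = np.isfinite(y)
    if not keep.all():
        y = y[keep]
        meta_frame = meta_frame.loc[keep]
    sex = meta_frame["sex"].to_numpy()
    is_m = sex == "M"
    if is_m.sum() < 2 or (~is_m).sum() < 2:
        raise ValidationError("need at least 2 samples of each sex")
    cols = {"const": np.ones_like(y), "sex_M": is_m.astype(float)}
    if adjust_weight:
        w = meta_frame["body_weight"].to_numpy(dtype=float)
        if np.isnan(w).any():
            raise ValidationError("body weight missing for weight-adjusted model")
        cols["body_weight"] = w
    X = pd.DataFrame(cols, index=meta_frame.index)

    mean_m = float(y[is_m].mean())
    mean_f = float(y[~is_m].mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = float(np.log2(mean_m / mean_f)) if mean_f > 0 and mean_m > 0 else np.nan

    if np.ptp(y) == 0.0:
        warnings.warn("response has zero variance; p set to 1", stacklevel=2)
        return {"estimate": 0.0, "log2_fc": 0.0 if mean_f > 0 else np.nan,
                "p_value": 1.0, "mean_F": mean_f, "mean_M": mean_m}

    ols = sm.OLS(y, X).fit()
    if variance_mode == "pooled":
        res = ols
    else:
        resid = ols.resid
        s2 = np.empty_like(y)
        for grp, mask in (("M", is_m), ("F", ~is_m)):
            v = float(np.var(resid[mask], ddof=1))
            if v <= 0:   # a degenerate group: fall back to pooled variance
                v = float(np.var(resid, ddof=1))
            s2[mask] = v
        res = sm.WLS(y, X, weights=1.0 / s2).fit()
    return {
        "estimate": float(res.params["sex_M"]),
        "log2_fc": log2_fc,
        "p_value": float(res.pvalues["sex_M"]),
        "mean_F": mean_f,
        "mean_M": mean_m,
    }


def sex_scan(table: AbundanceTable, meta: SampleMeta,
             adjust_weight: bool = False, variance_mode: str = "per-sex",
             alpha: float = 0.05, use_fdr: bool = False) -> pd.DataFrame:
    """Test every feature for a WT sex effect; BH q-values across features.

    Returns one row per feature: estimate, log2_fc (M over F), p_value,
    q_value, direction at the chosen threshold, and (when requested) the
    weight-adjusted p in ``p_weight_adjusted``.
    """
    wt = meta.wt_samples()
    if len(wt) == 0:
        raise ValidationError("no wildtype study samples")
    data = table.data.loc[wt.index]
    rows = []
    n_unfit = 0
    for fid in table.feature_ids:
        try:
            fit = fit_sex_model(data[fid].to_numpy(), wt, adjust_weight=False,
                                variance_mode=variance_mode)
        except ValidationError:
            # e.g. a near-empty feature on an un-imputed matrix
            n_unfit += 1
            fit = {"estimate": np.nan, "log2_fc": np.nan, "p_value": np.nan,
                   "mean_F": np.nan, "mean_M": np.nan}
        row = {"feature_id": fid, **fit}
        if adjust_weight:
            try:
                row["p_weight_adjusted"] = fit_sex_model(
                    data[fid].to_numpy(), wt, adjust_weight=True,
                    variance_mode=variance_mode)["p_value"]
            except ValidationError:
                row["p_weight_adjusted"] = np.nan
        rows.append(row)
    if n_unfit:
        warnings.warn(f"{n_unfit} features could not be fit and got NaN results",
                      stacklevel=2)
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"])
    crit = out["q_value"] if use_fdr else out["p_value"]
    out["direction"] = np.where(
        crit < alpha,
        np.where(out["estimate"] > 0, "higher-in-M", "higher-in-F"),
        "ns")
    return out


def summarize_sex_effects(results: pd.DataFrame, alpha: float = 0.05,
                          use_fdr: bool = False) -> dict:
    """Counts and one-decimal percentages of sex-effect directions.

    Direction is recomputed from the estimate sign and the chosen
    significance column, so the same result table can be summarised at
    p < alpha or FDR < alpha.
    """
    n = len(results)
    crit = results["q_value"] if use_fdr else results["p_value"]
    sig = crit < alpha
    higher_m = int((sig & (results["estimate"] > 0)).sum())
    higher_f = int((sig & (results["estimate"] < 0)).sum())

    def pct(k: int) -> float:
        return round(100.0 * k / n, 1) if n else 0.0

    return {
        "n_features": n,
        "n_significant": int(sig.sum()),
        "pct_significant": pct(int(sig.sum())),
        "n_higher_in_M": higher_m,
        "pct_higher_in_M": pct(higher_m),
        "n_higher_in_F": higher_f,
        "pct_higher_in_F": pct(higher_f),
        "n_ns": n - int(sig.sum()),
        "alpha": alpha,
        "criterion": "fdr" if use_fdr else "p",
    }
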