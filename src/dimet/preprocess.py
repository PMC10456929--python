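"""Feature QC, filtering, imputation and batch normalisation.

The filter rules follow the wording of the processing protocol exactly:

* drop features whose QC relative standard deviation exceeds 50% (strictly
  greater — RSD = 50.0% is kept);
* drop features missing in at least 70% of study samples (0.70 exactly is
  dropped);
* keep only features detected in more than 30% of study samples (0.30
  exactly is dropped);
* drop deuterated internal standards by annotation flag.

Missing metabolite values are replaced by half the minimum observed value
within the sample's genotype group (below-detection assumption); missing
phenotype values by the full group minimum, after discarding phenotypes
with >70% missing in either sex group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import (
    AbundanceTable,
    FeatureAnnotation,
    PhenotypeTable,
    SampleMeta,
    ValidationError,
)

DEFAULT_RSD_MAX = 50.0        # percent, strict
DEFAULT_MISSING_MAX = 0.70    # inclusive ("at least 70%")
DEFAULT_PREVALENCE_MIN = 0.30  # strict ("more than 30%")


@dataclass
class QCStats:
    """Per-feature technical QC metrics.

    ``rsd_qc`` is sd/mean x 100 over QC samples (sample sd, n-1), NaN when
    fewer than two QC values exist; ``missing_fraction`` and ``prevalence``
    are computed over study samples only and sum to 1.
    """

    frame: pd.DataFrame  # indexed by feature_id: rsd_qc, missing_fraction, prevalence


def compute_qc_stats(table: AbundanceTable, meta: SampleMeta) -> QCStats:
    qc_ids = list(meta.qc_samples().index)
    study_ids = list(meta.study_samples().index)
    qc = table.data.loc[qc_ids] if qc_ids else table.data.iloc[0:0]
    study = table.data.loc[study_ids]

    n_qc = qc.notna().sum(axis=0)
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = (sd / mean) * 100.0
    rsd = rsd.where(n_qc >= 2)

    missing = study.isna().mean(axis=0)
    frame = pd.DataFrame({
        "rsd_qc": rsd,
        "missing_fraction": missing,
        "prevalence": 1.0 - missing,
    })
    return QCStats(frame)


def filter_features(table: AbundanceTable, qc: QCStats,
                    annot: FeatureAnnotation | None = None,
                    rsd_max: float = DEFAULT_RSD_MAX,
                    missing_max: float = DEFAULT_MISSING_MAX,
                    prevalence_min: float = DEFAULT_PREVALENCE_MIN):
    """Apply the QC filter rules; returns ``(filtered_table, removal_log)``.

    The removal log is a DataFrame with one row per dropped feature naming
    every rule it triggered.  The rules commute — the retained set does not
    depend on application order.
    """
    stats = qc.frame
    reasons: dict[str, list[str]] = {}

    def _flag(fid: str, why: str) -> None:
        reasons.setdefault(fid, []).append(why)

    for fid in table.feature_ids:
        if annot is not None and fid in annot.frame.index and \
                bool(annot.frame.loc[fid, "is_internal_standard"]):
            _flag(fid, "internal_standard")
        row = stats.loc[fid]
        if pd.notna(row["rsd_qc"]) and row["rsd_qc"] > rsd_max:
            _flag(fid, f"rsd>{rsd_max:g}")
        if row["missing_fraction"] >= missing_max:
            _flag(fid, f"missing>={missing_max:g}")
        if not row["prevalence"] > prevalence_min:
            _flag(fid, f"prevalence<={prevalence_min:g}")

    keep = [f for f in table.feature_ids if f not in reasons]
    log = pd.DataFrame(
        [(fid, ";".join(why)) for fid, why in reasons.items()],
        columns=["feature_id", "removed_because"],
    ).sort_values("feature_id", kind="mergesort").reset_index(drop=True)
    return table.subset_features(keep), log


def impute_half_min(table: AbundanceTable, meta: SampleMeta) -> AbundanceTable:
    """Replace missing study values by half the genotype-group minimum.

    For feature f and genotype group g, every missing cell becomes
    0.5 x min of the observed values of f within g; a group with no
    observed value falls back to 0.5 x the global observed minimum of f.
    A feature with no observed value anywhere is an error (it should have
    been removed by the prevalence filter).  Non-missing cells are never
    touched; QC/blank rows are left as-is.
    """
    data = table.data.copy()
    study = meta.study_samples()
    study_data = data.loc[study.index]
    global_min = study_data.min(axis=0)
    if study_data.isna().all(axis=0).any():
        dead = study_data.columns[study_data.isna().all(axis=0)].tolist()
        raise ValidationError(f"features with no observed values: {dead[:5]}")
    for genotype, grp in study.groupby("genotype", sort=False):
        block = data.loc[grp.index]
        if not block.isna().any().any():
            continue
        gmin = block.min(axis=0)
        fill = 0.5 * gmin.fillna(global_min)
        data.loc[grp.index] = block.fillna(fill)
    return AbundanceTable(data, table.platform)


def impute_phenotype_min(pheno: PhenotypeTable, meta: SampleMeta,
                         missing_max: float = 0.70):
    """Drop phenotypes with >70% missing in a sex group; impute the rest.

    Remaining missing values are replaced by the minimum observed value in
    the sample's genotype group (the full minimum, not half), falling back
    to the global phenotype minimum for an entirely-missing group.
    Returns ``(PhenotypeTable, dropped_ids)``.
    """
    study = meta.study_samples()
    data = pheno.data.loc[pheno.data.index.intersection(study.index)].copy()
    dropped = []
    for sex, grp in study.loc[data.index].groupby("sex"):
        frac = data.loc[grp.index].isna().mean(axis=0)
        dropped.extend(frac.index[frac > missing_max].tolist())
    dropped = sorted(set(dropped))
    data = data.drop(columns=dropped)
    global_min = data.min(axis=0)
    for genotype, grp in study.loc[data.index].groupby("genotype", sort=False):
        block = data.loc[grp.index]
        if not block.isna().any().any():
            continue
        fill = block.min(axis=0).fillna(global_min)
        data.loc[grp.index] = block.fillna(fill)
    return PhenotypeTable(data), dropped


def median_batch_normalize(table: AbundanceTable, meta: SampleMeta,
                           platforms=("HILIC",),
                           min_batch_obs: int = 3) -> AbundanceTable:
    """Divide each value by its batch median, rescaled by the grand median.

    Correction is per feature: x / median_batch(f) * median_all(f), so
    units are preserved and a single batch is a no-op.  When a feature has
    fewer than ``min_batch_obs`` observed values in a batch, the batch's
    global median ratio (across all features of the platform) is used
    instead.  Only features on the listed platforms are touched.
    """
    data = table.data.copy()
    study = meta.study_samples()
    feats = [f for f in table.feature_ids if table.platform[f] in set(platforms)]
    if not feats:
        return AbundanceTable(data, table.platform)
    block = data.loc[study.index, feats]
    grand_med = block.median(axis=0)
    batch_labels = study["batch"]
    global_grand = np.nanmedian(block.to_numpy())
    for batch, grp in study.groupby("batch", sort=False):
        sub = block.loc[grp.index]
        med = sub.median(axis=0)
        n_obs = sub.notna().sum(axis=0)
        global_ratio = np.nanmedian(sub.to_numpy()) / global_grand
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = med / grand_med
        factor = factor.where((n_obs >= min_batch_obs) & (med > 0), global_ratio)
        data.loc[grp.index, feats] = sub / factor.to_numpy()[None, :]
    return AbundanceTable(data, table.platform)


def preprocess_cohort(table: AbundanceTable, meta: SampleMeta,
               annot: FeatureAnnotation | None = None,
               pheno: PhenotypeTable | None = None,
               rsd_max: float = DEFAULT_RSD_MAX,
               missing_max: float = DEFAULT_MISSING_MAX,
               prevalence_min: float = DEFAULT_PREVALENCE_MIN,
               normalize_platforms=("HILIC",)):
    """Full processing chain: QC stats -> filters -> imputation -> batch scaling.

    Returns a dict with keys ``table``, ``qc``, ``removal_log``, ``pheno``,
    ``pheno_dropped`` and the stage-by-stage feature counts under
    ``attrition``.
    """
    qc = compute_qc_stats(table, meta)
    n0 = len(table.feature_ids)
    filtered, log = filter_features(table, qc, annot, rsd_max=rsd_max,
                                    missing_max=missing_max,
                                    prevalence_min=prevalence_min)
    n1 = len(filtered.feature_ids)
    imputed = impute_half_min(filtered, meta)
    normed = median_batch_normalize(imputed, meta, platforms=normalize_platforms)
    out_pheno, dropped = (None, [])
    if pheno is not None:
        out_pheno, dropped = impute_phenotype_min(pheno, meta)
    return {
        "table": normed,
        "qc": qc,
        "removal_log": log,
        "pheno": out_pheno,
        "pheno_dropped": dropped,
        "attrition": {"input_features": n0, "post_filter_features": n1},
    }
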