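"""Core domain types for the dimorphism pipeline.

All tabular state is carried by pandas objects with explicit invariants:
abundance and phenotype matrices are samples x features frames of
non-negative floats with NaN as the single missing marker, and sample
metadata is one row per sample keyed by ``sample_id``.  Every analysis
stage consumes and returns these types, so validation lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLATFORMS = ("GC", "HILIC", "CSH-lipidomics", "bile-steroids", "oxylipins")

SEXES = ("F", "M")
ROLES = ("study", "QC", "blank")
ZYGOSITIES = ("het", "hom", "wt", "na")

#: genotype label reserved for wildtype control mice
WT_GENOTYPE = "WT"

_SEX_ALIASES = {
    "f": "F", "female": "F", "fem": "F",
    "m": "M", "male": "M",
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def normalize_sex(token: str) -> str:
    """Map common sex spellings (``female``, ``M``, ...) to ``F``/``M``."""
    key = str(token).strip().lower()
    if key not in _SEX_ALIASES:
        raise ValidationError(f"unknown sex token {token!r}")
    return _SEX_ALIASES[key]


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class AbundanceTable:
    """Samples x metabolite-features matrix with per-feature platform labels.

    ``data`` holds non-negative abundances on the natural intensity scale;
    NaN marks a missing (below-detection) measurement.  ``platform`` is a
    per-feature Series aligned to ``data.columns``.
    """

    data: pd.DataFrame
    platform: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "feature ids")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        bad = np.isfinite(vals) & (vals < 0)
        if bad.any():
            raise ValidationError("negative abundance values present")
        if np.isinf(vals).any():
            raise ValidationError("non-finite abundance values present")
        self.platform = self.platform.reindex(self.data.columns)
        if self.platform.isna().any():
            missing = self.platform[self.platform.isna()].index.tolist()
            raise ValidationError(f"features without platform label: {missing[:5]}")
        unknown = set(self.platform.unique()) - set(PLATFORMS)
        if unknown:
            raise ValidationError(f"unknown platform labels: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)].copy(), self.platform)

    def subset_features(self, feature_ids) -> "AbundanceTable":
        keep = list(feature_ids)
        return AbundanceTable(self.data[keep].copy(), self.platform.loc[keep])


@dataclass
class SampleMeta:
    """Per-sample design factors: sex, genotype, zygosity, role, batch, weight.

    Only ``role == 'study'`` samples enter statistics; QC and blank rows are
    used for technical QC alone.  ``WT`` is the reserved wildtype genotype.
    """

    frame: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("sex", "genotype", "zygosity", "role", "batch")

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "sample ids")
        self.frame.index = self.frame.index.astype(str)
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValidationError(f"sample metadata lacks column {col!r}")
        if "body_weight" not in self.frame.columns:
            self.frame["body_weight"] = np.nan
        self.frame["sex"] = [
            normalize_sex(s) if pd.notna(s) and str(s).strip() != "" else s
            for s in self.frame["sex"]
        ]
        bad_role = set(self.frame["role"]) - set(ROLES)
        if bad_role:
            raise ValidationError(f"unknown role tokens: {sorted(bad_role)}")
        bad_zyg = set(self.frame["zygosity"]) - set(ZYGOSITIES)
        if bad_zyg:
            raise ValidationError(f"unknown zygosity tokens: {sorted(bad_zyg)}")
        study = self.frame[self.frame["role"] == "study"]
        if study["sex"].isna().any() or (study["sex"] == "").any():
            raise ValidationError("study samples with undefined sex")
        if study["genotype"].isna().any():
            raise ValidationError("study samples with undefined genotype")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def study_samples(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "study"]

    def qc_samples(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "QC"]

    def wt_samples(self) -> pd.DataFrame:
        st = self.study_samples()
        return st[st["genotype"] == WT_GENOTYPE]

    def ko_lines(self) -> list[str]:
        st = self.study_samples()
        lines = sorted(set(st["genotype"]) - {WT_GENOTYPE})
        return lines


@dataclass
class FeatureAnnotation:
    """Per-feature display name, chemical cluster label and optional flags.

    Cluster labels must partition annotated features (non-overlapping by
    construction since each feature carries one label); features without a
    cluster are excluded from enrichment only, never from testing.
    """

    frame: pd.DataFrame  # indexed by feature_id

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "feature ids")
        self.frame.index = self.frame.index.astype(str)
        if "name" not in self.frame.columns:
            self.frame["name"] = self.frame.index
        if "chemical_cluster" not in self.frame.columns:
            self.frame["chemical_cluster"] = pd.NA
        if "is_internal_standard" not in self.frame.columns:
            self.frame["is_internal_standard"] = False
        self.frame["is_internal_standard"] = (
            self.frame["is_internal_standard"]
            .map({True: True, False: False, "True": True, "False": False,
                  "true": True, "false": False, 1: True, 0: False,
                  "1": True, "0": False})
            .fillna(False)
            .astype(bool)
        )

    def clusters(self, feature_ids=None) -> pd.Series:
        s = self.frame["chemical_cluster"]
        if feature_ids is not None:
            s = s.reindex(list(feature_ids))
        return s


@dataclass
class PhenotypeTable:
    """Samples x continuous-phenotypes matrix; NaN marks missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "phenotype ids")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data = self.data.astype(float)

    @property
    def phenotype_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class TruthTable:
    """Ground truth of planted effects, one row per (feature, KO line).

    Columns: ``feature_id``, ``ko_line``, ``archetype``,
    ``effect_female_log2``, ``effect_male_log2``, ``sex_effect_log2``.
    Archetype semantics: male-only implies a zero female effect,
    opposite-direction implies effects of equal magnitude and opposite
    sign, and so on; :func:`validate` enforces these.
    """

    frame: pd.DataFrame

    ARCHETYPES = (
        "null", "both-sexes-equal", "female-only", "male-only",
        "opposite-direction", "different-effect-size",
    )

    def validate(self) -> None:
        f = self.frame
        bad = set(f["archetype"]) - set(self.ARCHETYPES)
        if bad:
            raise ValidationError(f"unknown archetypes: {sorted(bad)}")
        ef = f["effect_female_log2"].to_numpy()
        em = f["effect_male_log2"].to_numpy()
        a = f["archetype"].to_numpy()
        checks = {
            "null": (ef == 0) & (em == 0),
            "both-sexes-equal": (ef == em) & (ef != 0),
            "female-only": (ef != 0) & (em == 0),
            "male-only": (ef == 0) & (em != 0),
            "opposite-direction": (ef == -em) & (ef != 0),
            "different-effect-size": (ef * em > 0) & (ef != em),
        }
        for name, ok in checks.items():
            mask = a == name
            if mask.any() and not ok[mask].all():
                raise ValidationError(f"effects inconsistent with archetype {name!r}")


def validate_cohort(table: AbundanceTable, meta: SampleMeta) -> None:
    """Cross-check abundance matrix against metadata; silent drops are errors."""
    mat = set(table.sample_ids)
    met = set(meta.sample_ids)
    only_mat = mat - met
    if only_mat:
        raise ValidationError(
            f"samples in abundance data without metadata: {sorted(only_mat)[:5]}"
        )
    only_met = met - mat
    if only_met:
        raise ValidationError(
            f"samples in metadata missing from abundance data: {sorted(only_met)[:5]}"
        )
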