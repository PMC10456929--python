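"""Synthetic knockout-cohort generator with planted ground truth.

Emulates the study design the pipeline targets: 40 wildtype mice (20 per
sex), 30 knockout lines with six mice each (3 per sex), ~800 metabolite
features spread over five MS platforms, pooled-plasma QC replicates, and a
continuous-phenotype panel.  Abundances are lognormal so planted log2
effects are exact fold-changes; missingness is missing-not-at-random
(below-detection), which is what makes half-minimum imputation well-posed.

Each (feature, KO line) pair may carry one planted archetype:

======================  =============================================
archetype               per-sex log2 effect (female, male)
======================  =============================================
null                    (0, 0)
both-sexes-equal        (d, d)
female-only             (d, 0)
male-only               (0, d)
opposite-direction      (d, -d)
different-effect-size   (d, 2d)   — same sign, doubled in males
======================  =============================================

with |d| drawn from ``ko_log2fc_range`` and a random sign.  The planted
map is returned as a :class:`~dimet.tables.TruthTable` for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables import (
    AbundanceTable,
    FeatureAnnotation,
    PhenotypeTable,
    SampleMeta,
    TruthTable,
    ValidationError,
    WT_GENOTYPE,
)

# per-platform compound shares mirroring the five-assay panel
# (primary metabolites, biogenic amines, complex lipids, bile acids/steroids,
# oxylipins)
DEFAULT_PLATFORM_PROPORTIONS = {
    "GC": 0.131,
    "HILIC": 0.220,
    "CSH-lipidomics": 0.545,
    "bile-steroids": 0.041,
    "oxylipins": 0.063,
}

DIMORPHIC_ARCHETYPES = (
    "female-only", "male-only", "opposite-direction", "different-effect-size",
)

PHENO_PATTERNS = ("female-only", "male-only", "both-same", "both-opposite")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-shaped preset."""

    n_wt_per_sex: int = 20
    n_ko_lines: int = 30
    n_ko_per_sex: int = 3
    n_features: int = 800
    platform_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_PLATFORM_PROPORTIONS))
    # lognormal abundance model (log2 scale)
    base_log2_mean: float = 16.0
    base_log2_sd: float = 2.0
    feature_log2_sd_range: tuple = (0.3, 0.8)
    # wildtype sex effects
    sex_affected_fraction: float = 0.55
    sex_log2fc_range: tuple = (0.2, 2.0)   # up to 4-fold
    sex_male_higher_prob: float = 0.75
    sex_effect_by_cluster: bool = True
    # knockout effects
    ko_affected_fraction: float = 0.30
    ko_dimorphic_fraction: float = 1.0 / 3.0
    ko_log2fc_range: tuple = (1.0, 2.0)
    archetype_map: dict | None = None   # {line: {feature_id: archetype}}
    # missingness
    missing_rate: float = 0.05
    mnar_quantile: float = 0.3
    mnar_weight: float = 4.0
    # QC replicates and pathological features exercised by the filters
    n_qc: int = 22
    qc_rsd_percent: float = 10.0
    n_high_missing: int = 10
    high_missing_fraction: float = 0.85
    n_high_rsd: int = 10
    high_rsd_percent: float = 80.0
    n_internal_standards: int = 5
    # annotation / batches
    cluster_mean_size: int = 20
    n_batches: int = 2
    batch_effect: float = 1.3   # multiplicative shift on HILIC batch 2
    # phenotypes
    n_phenotypes: int = 208
    n_pheno_drivers: int = 2
    pheno_pattern_probs: dict = field(default_factory=lambda: {
        "female-only": 0.40, "male-only": 0.40,
        "both-same": 0.12, "both-opposite": 0.08,
    })
    pheno_noise_ratio: float = 1.0
    pheno_missing_rate: float = 0.03
    n_pheno_high_missing: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_wt_per_sex", "n_ko_lines", "n_ko_per_sex", "n_features"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("sex_affected_fraction", "ko_affected_fraction",
                     "ko_dimorphic_fraction", "missing_rate", "mnar_quantile",
                     "sex_male_higher_prob", "pheno_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.missing_rate >= 1.0:
            raise ValidationError("missing_rate must be < 1")
        if abs(sum(self.platform_proportions.values()) - 1.0) > 1e-6:
            raise ValidationError("platform proportions must sum to 1")


def study_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-shaped default configuration."""
    return replace(SimulationConfig(seed=seed), **overrides)


def null_config(seed: int = 0, n_features: int = 800, **overrides) -> SimulationConfig:
    """A fully null cohort: no planted sex, genotype or phenotype effects."""
    cfg = SimulationConfig(
        seed=seed, n_features=n_features,
        sex_affected_fraction=0.0, ko_affected_fraction=0.0,
        missing_rate=0.0, n_high_missing=0, n_high_rsd=0,
        n_internal_standards=0, batch_effect=1.0,
        pheno_pattern_probs={}, pheno_missing_rate=0.0,
        n_pheno_high_missing=0,
    )
    return replace(cfg, **overrides)


def _spawn(seed: int, n: int):
    """Deterministic per-stage RNGs derived from a single run seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _feature_layout(cfg: SimulationConfig, rng) -> pd.DataFrame:
    platforms = list(cfg.platform_proportions)
    counts = np.floor(np.array([cfg.platform_proportions[p] for p in platforms])
                      * cfg.n_features).astype(int)
    counts[0] += cfg.n_features - counts.sum()
    rows = []
    for plat, cnt in zip(platforms, counts):
        n_clusters = max(1, round(cnt / cfg.cluster_mean_size))
        assign = rng.integers(0, n_clusters, size=cnt)
        for j in range(cnt):
            rows.append((plat, f"{plat}_cluster{assign[j]:02d}"))
    feat = pd.DataFrame(rows, columns=["platform", "chemical_cluster"])
    feat.index = [f"met_{i:04d}" for i in range(len(feat))]
    feat["is_internal_standard"] = False
    # deuterated internal standards ride along and must be filtered out
    for k in range(cfg.n_internal_standards):
        feat.loc[f"istd_d{k}"] = [platforms[k % len(platforms)], pd.NA, True]
    return feat


def _sample_layout(cfg: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    for sex in ("F", "M"):
        for i in range(cfg.n_wt_per_sex):
            rows.append((f"WT_{sex}{i:02d}", sex, WT_GENOTYPE, "wt", "study"))
    zyg_pool = ["het"] * 17 + ["hom"] * 13
    for li in range(cfg.n_ko_lines):
        line = f"KO{li + 1:02d}"
        zyg = zyg_pool[li % len(zyg_pool)]
        for sex in ("F", "M"):
            for i in range(cfg.n_ko_per_sex):
                rows.append((f"{line}_{sex}{i}", sex, line, zyg, "study"))
    for q in range(cfg.n_qc):
        rows.append((f"QC_{q:02d}", "F", "pooled_plasma", "na", "QC"))
    df = pd.DataFrame(rows, columns=["sample_id", "sex", "genotype",
                                     "zygosity", "role"]).set_index("sample_id")
    df["batch"] = [f"B{1 + (i % cfg.n_batches)}" for i in range(len(df))]
    weight = np.where(df["sex"] == "M",
                      rng.normal(30.0, 2.0, len(df)),
                      rng.normal(24.0, 1.5, len(df)))
    df["body_weight"] = np.where(df["role"] == "study", np.round(weight, 2), np.nan)
    return df


def _plant_sex_effects(cfg: SimulationConfig, feat: pd.DataFrame, rng) -> pd.Series:
    """Per-feature wildtype sex effect on the log2 scale (M minus F)."""
    fids = feat.index[~feat["is_internal_standard"]]
    n = len(fids)
    target = round(cfg.sex_affected_fraction * n)
    effect = pd.Series(0.0, index=feat.index)
    if target == 0:
        return effect
    if cfg.sex_effect_by_cluster:
        clusters = feat.loc[fids, "chemical_cluster"]
        order = list(pd.unique(clusters))
        rng.shuffle(order)
        chosen: list = []
        for cl in order:
            members = list(clusters.index[clusters == cl])
            if len(chosen) + len(members) > target and chosen:
                members = members[: target - len(chosen)]
            chosen.extend(members)
            if len(chosen) >= target:
                break
        # one dominant direction per cluster makes enrichment detectable
        for cl in pd.unique(clusters.loc[chosen]):
            members = [f for f in chosen if clusters.get(f) == cl]
            sign = 1.0 if rng.random() < cfg.sex_male_higher_prob else -1.0
            mag = rng.uniform(*cfg.sex_log2fc_range, size=len(members))
            effect.loc[members] = sign * mag
    else:
        chosen = list(rng.choice(fids, size=target, replace=False))
        sign = np.where(rng.random(target) < cfg.sex_male_higher_prob, 1.0, -1.0)
        effect.loc[chosen] = sign * rng.uniform(*cfg.sex_log2fc_range, size=target)
    return effect


def _archetype_effects(archetype: str, d: float) -> tuple[float, float]:
    if archetype == "null":
        return 0.0, 0.0
    if archetype == "both-sexes-equal":
        return d, d
    if archetype == "female-only":
        return d, 0.0
    if archetype == "male-only":
        return 0.0, d
    if archetype == "opposite-direction":
        return d, -d
    if archetype == "different-effect-size":
        return d, 2.0 * d
    raise ValidationError(f"unknown archetype {archetype!r}")


def _plant_ko_effects(cfg: SimulationConfig, feat: pd.DataFrame,
                      lines: list[str], sex_effect: pd.Series, rng):
    """Assign archetypes per (line, feature); returns truth rows and effect maps."""
    fids = [f for f in feat.index if not feat.loc[f, "is_internal_standard"]]
    if cfg.archetype_map is not None:
        unknown = set(cfg.archetype_map) - set(lines)
        if unknown:
            raise ValidationError(f"archetype map references unknown lines: {sorted(unknown)}")
    truth_rows = []
    eff_f = {line: pd.Series(0.0, index=feat.index) for line in lines}
    eff_m = {line: pd.Series(0.0, index=feat.index) for line in lines}
    n_affected = round(cfg.ko_affected_fraction * len(fids))
    n_dim = round(cfg.ko_dimorphic_fraction * n_affected)
    for line in lines:
        explicit = (cfg.archetype_map or {}).get(line)
        if explicit is not None:
            assignment = dict(explicit)
        else:
            chosen = rng.choice(fids, size=n_affected, replace=False)
            assignment = {}
            per_kind = n_dim // len(DIMORPHIC_ARCHETYPES)
            idx = 0
            for kind in DIMORPHIC_ARCHETYPES:
                for f in chosen[idx:idx + per_kind]:
                    assignment[f] = kind
                idx += per_kind
            for f in chosen[idx:]:
                assignment[f] = "both-sexes-equal"
        for f, kind in assignment.items():
            if kind == "null":
                continue
            d = rng.uniform(*cfg.ko_log2fc_range) * (1.0 if rng.random() < 0.5 else -1.0)
            ef, em = _archetype_effects(kind, d)
            eff_f[line].loc[f] = ef
            eff_m[line].loc[f] = em
            truth_rows.append((f, line, kind, ef, em, float(sex_effect.get(f, 0.0))))
    truth = pd.DataFrame(truth_rows, columns=[
        "feature_id", "ko_line", "archetype",
        "effect_female_log2", "effect_male_log2", "sex_effect_log2"])
    return truth, eff_f, eff_m


def _rsd_to_log2_sd(rsd_percent: float) -> float:
    """Lognormal sigma (log2) giving a given coefficient of variation."""
    cv = rsd_percent / 100.0
    return math.sqrt(math.log(1.0 + cv * cv)) / math.log(2)


def inject_missingness(table: AbundanceTable, rate: float,
                       mnar_quantile: float, seed: int,
                       weight: float = 4.0) -> AbundanceTable:
    """Blank out cells preferentially where abundance is low (MNAR).

    Cells below each feature's ``mnar_quantile`` quantile are ``weight``
    times as likely to go missing; the realised overall missing fraction
    equals ``round(rate * n_cells) / n_cells``.  ``rate`` must be < 1.
    """
    if not 0.0 <= rate < 1.0:
        raise ValidationError("missingness rate must lie in [0, 1)")
    data = table.data.copy()
    if rate == 0.0:
        return AbundanceTable(data, table.platform)
    rng = np.random.default_rng(seed)
    vals = data.to_numpy()
    thresh = np.nanquantile(vals, mnar_quantile, axis=0)
    w = np.where(vals <= thresh[None, :], weight, 1.0).ravel()
    observed = np.isfinite(vals).ravel()
    w[~observed] = 0.0
    k = round(rate * vals.size)
    # weighted sampling without replacement via the exponential-race trick
    keys = rng.exponential(1.0, size=w.size)
    with np.errstate(divide="ignore"):
        keys = np.where(w > 0, keys / w, np.inf)
    drop = np.argsort(keys, kind="mergesort")[:k]
    flat = vals.ravel()
    flat[drop] = np.nan
    data.iloc[:, :] = flat.reshape(vals.shape)
    return AbundanceTable(data, table.platform)


def simulate_cohort(config: SimulationConfig):
    """Generate one full cohort.

    Returns ``(AbundanceTable, SampleMeta, FeatureAnnotation,
    PhenotypeTable, TruthTable)``, fully reproducible from
    ``config.seed``.
    """
    cfg = config
    cfg.validate()
    (rng_layout, rng_sex, rng_ko, rng_ab, rng_qc, rng_miss,
     rng_pheno, rng_weird) = _spawn(cfg.seed, 8)

    feat = _feature_layout(cfg, rng_layout)
    samples = _sample_layout(cfg, rng_layout)
    meta = SampleMeta(samples.copy())
    lines = [f"KO{i + 1:02d}" for i in range(cfg.n_ko_lines)]

    sex_effect = _plant_sex_effects(cfg, feat, rng_sex)
    truth_frame, eff_f, eff_m = _plant_ko_effects(cfg, feat, lines, sex_effect, rng_ko)

    mu = rng_ab.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=len(feat))
    sigma = rng_ab.uniform(*cfg.feature_log2_sd_range, size=len(feat))
    mu = pd.Series(mu, index=feat.index)
    sigma = pd.Series(sigma, index=feat.index)

    study = samples[samples["role"] == "study"]
    log2 = pd.DataFrame(
        rng_ab.normal(0.0, 1.0, size=(len(study), len(feat))) * sigma.to_numpy()[None, :],
        index=study.index, columns=feat.index)
    log2 += mu.to_numpy()[None, :]
    is_m = (study["sex"] == "M").to_numpy()
    log2.loc[is_m, :] += sex_effect.to_numpy()[None, :]
    for line in lines:
        in_line = study["genotype"] == line
        lf = in_line & (study["sex"] == "F")
        lm = in_line & (study["sex"] == "M")
        log2.loc[lf.to_numpy(), :] += eff_f[line].to_numpy()[None, :]
        log2.loc[lm.to_numpy(), :] += eff_m[line].to_numpy()[None, :]

    # QC replicates: pooled plasma at the grand feature mean, technical noise only
    qc_idx = samples.index[samples["role"] == "QC"]
    qc_sd = np.full(len(feat), _rsd_to_log2_sd(cfg.qc_rsd_percent))
    high_rsd = rng_weird.choice(
        [f for f in feat.index if not feat.loc[f, "is_internal_standard"]],
        size=cfg.n_high_rsd, replace=False) if cfg.n_high_rsd else np.array([], dtype=object)
    qc_sd[feat.index.get_indexer(high_rsd)] = _rsd_to_log2_sd(cfg.high_rsd_percent)
    qc_log2 = pd.DataFrame(
        rng_qc.normal(0.0, 1.0, size=(len(qc_idx), len(feat))) * qc_sd[None, :],
        index=qc_idx, columns=feat.index)
    qc_log2 += (mu + 0.5 * sex_effect).to_numpy()[None, :]

    log2_all = pd.concat([log2, qc_log2]).loc[samples.index]
    values = np.exp2(log2_all)
    # multiplicative batch shift on the HILIC platform (later undone by
    # median batch normalisation)
    if cfg.batch_effect != 1.0:
        hilic = (feat["platform"] == "HILIC").to_numpy()
        shifted = (samples["batch"] != "B1").to_numpy()
        values.loc[shifted, hilic] *= cfg.batch_effect

    table = AbundanceTable(values, feat["platform"])
    if cfg.missing_rate > 0:
        study_part = table.subset_samples(study.index)
        study_part = inject_missingness(
            study_part, cfg.missing_rate, cfg.mnar_quantile,
            seed=int(rng_miss.integers(2 ** 31)), weight=cfg.mnar_weight)
        values.loc[study.index] = study_part.data
    # features the missingness filter must catch
    if cfg.n_high_missing:
        eligible = [f for f in feat.index
                    if not feat.loc[f, "is_internal_standard"] and f not in set(high_rsd)]
        hm = rng_weird.choice(eligible, size=cfg.n_high_missing, replace=False)
        for f in hm:
            kill = rng_weird.random(len(study)) < cfg.high_missing_fraction
            values.loc[study.index[kill], f] = np.nan
    table = AbundanceTable(values, feat["platform"])

    pheno, pheno_drivers = _simulate_phenotypes(cfg, log2, study, rng_pheno)
    annot = FeatureAnnotation(feat)
    truth = TruthTable(truth_frame)
    truth.validate()
    truth.pheno_drivers = pheno_drivers
    return table, meta, annot, pheno, truth


def _simulate_phenotypes(cfg: SimulationConfig, log2: pd.DataFrame,
                         study: pd.DataFrame, rng):
    """Continuous phenotypes as sex-specific linear readouts of driver features."""
    fids = [c for c in log2.columns if not c.startswith("istd")]
    pheno_ids = [f"pheno_{i:03d}" for i in range(cfg.n_phenotypes)]
    patterns = list(cfg.pheno_pattern_probs)
    probs = np.array([cfg.pheno_pattern_probs[p] for p in patterns], dtype=float)
    null_prob = max(0.0, 1.0 - probs.sum())
    patterns.append("null")
    probs = np.append(probs, null_prob)
    probs /= probs.sum()
    is_m = (study["sex"] == "M").to_numpy()
    data = np.empty((len(study), cfg.n_phenotypes))
    rows = []
    for j, pid in enumerate(pheno_ids):
        pattern = rng.choice(patterns, p=probs)
        drivers = rng.choice(fids, size=cfg.n_pheno_drivers, replace=False)
        beta = rng.uniform(0.5, 1.5, size=cfg.n_pheno_drivers)
        bf, bm = {
            "female-only": (beta, 0.0 * beta),
            "male-only": (0.0 * beta, beta),
            "both-same": (beta, beta),
            "both-opposite": (beta, -beta),
            "null": (0.0 * beta, 0.0 * beta),
        }[pattern]
        X = log2[drivers].to_numpy()
        Xc = X - X.mean(axis=0, keepdims=True)
        signal = np.where(is_m, Xc @ bm, Xc @ bf)
        scale = signal.std() if signal.std() > 0 else 1.0
        noise_sd = cfg.pheno_noise_ratio * scale if pattern != "null" else 1.0
        data[:, j] = 50.0 + signal + rng.normal(0.0, noise_sd, size=len(study))
        rows.append((pid, pattern, ";".join(drivers)))
    df = pd.DataFrame(data, index=study.index, columns=pheno_ids)
    if cfg.pheno_missing_rate > 0:
        mask = rng.random(df.shape) < cfg.pheno_missing_rate
        df = df.mask(mask)
    # a few phenotypes nearly absent in females, exercising the drop rule
    for j in range(cfg.n_pheno_high_missing):
        pid = pheno_ids[j]
        females = study.index[~is_m]
        kill = rng.random(len(females)) < 0.85
        df.loc[females[kill], pid] = np.nan
    drivers = pd.DataFrame(rows, columns=["phenotype_id", "pattern", "drivers"])
    return PhenotypeTable(df), drivers
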