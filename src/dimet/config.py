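"""Run configuration: one serialisable document driving every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml


@dataclass
class RunConfig:
    """Thresholds, flags, seed and paths for a pipeline run.

    The document is echoed verbatim into every output directory so any
    result file is traceable to the exact settings that produced it.
    """

    # significance and filters
    alpha: float = 0.05
    rsd_max: float = 50.0
    missing_max: float = 0.70
    prevalence_min: float = 0.30
    min_cluster_size: int = 3
    min_corr_n: int = 15
    # flags
    fdr: bool = False
    adjust_weight: bool = False
    variance_mode: str = "per-sex"   # 'pooled' | 'per-sex'
    welch: bool = False
    gate_on_genotype: bool = False
    gc_noise_floor: bool = False
    normalize_platforms: tuple = ("HILIC",)
    # simulation / reproducibility
    seed: int = 0
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    # paths (used when simulate is False)
    abundance_path: str | None = None
    meta_path: str | None = None
    annotation_path: str | None = None
    phenotype_path: str | None = None

    def to_yaml(self, path=None) -> str:
        doc = asdict(self)
        doc["normalize_platforms"] = list(self.normalize_platforms)
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        try:
            with open(path_or_text) as fh:
                doc = yaml.safe_load(fh)
        except (OSError, TypeError):
            doc = yaml.safe_load(path_or_text)
        if "normalize_platforms" in doc:
            doc["normalize_platforms"] = tuple(doc["normalize_platforms"])
        return cls(**doc)

    def with_overrides(self, **kw) -> "RunConfig":
        return replace(self, **kw)
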