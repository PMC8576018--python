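"""Pipeline thresholds, collected in one place and loadable from YAML."""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every threshold of the analysis, with the defaults used throughout.

    Units: detection_threshold / p_adj_max / dmr_sig_p / dmr_fisher_p_max
    are p-values; delta_min and dmr_delta_min are beta-scale fractions;
    dmr_max_gap is bp; clip_eps a beta fraction.
    """

    detection_threshold: float = 0.01
    detection_rule: str = "any"       # 'any' sample failing drops the probe
    clip_eps: float = 0.001
    control_ratio: int = 5
    max_age_gap: float = 10.0
    pca_components: int = 2
    pca_z_cut: float = 3.0
    delta_min: float = 0.10
    p_adj_max: float = 0.001
    adjust_method: str = "fdr_bh"
    auc_min: float = 0.9
    r_max: float = 0.8
    corr_rule: str = "both"           # redundancy must show in both groups
    corr_scale: str = "beta"          # scale for the correlation filter
    dmr_sig_p: float = 0.01
    dmr_min_cpgs: int = 5
    dmr_max_gap: int = 1000
    dmr_delta_min: float = 0.10
    dmr_fisher_p_max: float = 0.01
    dmr_window_mode: str = "chain"
    svm_c: float = 1.0
    train_frac: float = 0.75
    band_negative: float = 0.2
    band_positive: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
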