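"""Pipeline configuration.

Every analysis parameter is a named key with the published study value as
default, so a config file only needs the entries that differ.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # inputs (paths; ignored when the simulate stage generates data)
    abundance: str | None = None
    metadata: str | None = None
    cognition: str | None = None
    gene_sets: str | None = None
    cell_markers: str | None = None
    reference_assignment: str | None = None
    target_abundance: str | None = None
    target_metadata: str | None = None

    # stages to run, in pipeline order
    stages: list[str] = field(default_factory=lambda: ["preprocess", "network"])
    out_dir: str = "results"
    seed: int = 0

    # preprocessing
    outlier_cutoff: float = 3.0           # SD of Z-transformed connectivity
    outlier_iterate: bool = True
    n_boot: int = 1000                    # bootstrap regression iterations
    control_set: str = "all_controls"     # which controls feed the covariate model

    # network construction
    power: int = 12                       # signed soft-threshold exponent
    correlation: str = "bicor"
    tom_denom: str = "mean"
    deep_split: int = 4
    min_module_size: int = 30
    merge_cut_height: float = 0.07
    pam_stage: bool = True
    pam_respects_dendro: bool = True
    kme_p_threshold: float = 0.05         # reassignment significance (unadjusted)
    kme_max_iter: int = 30

    # annotation / association
    hub_percentile: float = 0.80
    fdr_level: float = 0.05
    anova_adjust: str = "residualize"     # how age/sex enter group comparisons

    # preservation / replication
    n_perm: int = 500
    missing_threshold: float = 0.75

    # simulation (defaults = the synthetic study conditions)
    sim_n_proteins: int = 800
    sim_n_samples: int = 140
    sim_n_modules: int = 8
    sim_loading_range: tuple[float, float] = (0.6, 0.9)
    sim_noise_sd: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "sim_loading_range" in data:
            data["sim_loading_range"] = tuple(data["sim_loading_range"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["sim_loading_range"] = list(data["sim_loading_range"])
        with open(Path(path), "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
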