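"""YAML run configuration.

A run configuration is a flat mapping of stage parameters; unknown keys
are rejected so typos fail loudly.  Every threshold actually applied is
logged by the stage that applies it.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import yaml

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters for a pipeline run, loadable from YAML."""

    seed: int = 0
    # signature
    top_n_markers: int = 60
    min_fold_change: float = 1.5
    replicates_per_subtype: int = 3
    # deconvolution
    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    quantile_normalize: bool = True
    standardize: bool = True
    # enrichment
    gsea_weight: float = 1.0
    n_permutations: int = 1000
    fdr_threshold: float = 0.05
    # genomics
    snv_min_frequency: float = 0.02
    cnv_gain_threshold: int = 4
    cnv_loss_threshold: int = 1
    rna_nonzero_fraction: float = 0.97
    cnv_min_fraction: float = 0.03
    association_alpha: float = 0.05
    sift_polyphen_rule: str = "and"
    n_orthogonal: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "nu_grid" in data:
            data["nu_grid"] = tuple(data["nu_grid"])
        cfg = cls(**data)
        log.info("loaded configuration: %s", asdict(cfg))
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
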