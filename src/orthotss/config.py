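"""Pipeline-wide thresholds.

Defaults are the operational values of the comparative dRNA-seq protocol:
read mapping filters (20 nt minimum read length after poly-A/T clipping, 80%
aligned fraction, at most 4 mismatches, no gaps, e-value 1e-4), TSS
clustering distances (30 bp within a condition, 35 bp across conditions),
the 1000 nt UTR window for genic classification, the 30% identity floor for
orthologs, the 35-column criterion for positional TSS orthology, and the 5%
extreme-fold-change candidate fraction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

CONDITION_BRANCHLESS = "branchless"
CONDITION_TRUE_BRANCHING = "true_branching"
CONDITIONS = (CONDITION_BRANCHLESS, CONDITION_TRUE_BRANCHING)

TEX_PLUS = "plus"
TEX_MINUS = "minus"


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class PipelineConfig:
    # read clipping / mapping filters
    min_read_len: int = 20
    min_aln_frac: float = 0.8
    max_mismatches: int = 4
    max_evalue: float = 1e-4
    # TSS calling (documented stand-in caller) and clustering
    min_step: float = 5.0
    min_enrich: float = 2.0
    cluster_distance: int = 30
    unify_window: int = 35
    # classification
    utr_threshold: int = 1000
    pribnow_window: tuple[int, int] = (1, 20)
    # orthology
    min_global_identity: float = 30.0
    ortho_max_evalue: float = 1e-10  # honoured when ingesting external tabular hits
    calibration_shuffles: int = 300
    # comparative TSS matching
    max_col_dist: int = 35
    locus_flank: int = 35
    # differential screening
    candidate_fraction: float = 0.05
    combine_statistic: str = "sum"  # one of: sum, min, product

    def validate(self) -> "PipelineConfig":
        if not 0.0 < self.min_aln_frac <= 1.0:
            raise ConfigError("min_aln_frac must be in (0, 1]")
        if not 0.0 < self.candidate_fraction <= 1.0:
            raise ConfigError("candidate_fraction must be in (0, 1]")
        if self.combine_statistic not in ("sum", "min", "product"):
            raise ConfigError(f"unknown combine_statistic {self.combine_statistic!r}")
        if self.min_read_len < 1 or self.cluster_distance < 0 or self.unify_window < 0:
            raise ConfigError("length/distance parameters must be positive")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pribnow_window" in raw:
            raw["pribnow_window"] = tuple(raw["pribnow_window"])
        return cls(**raw).validate()
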