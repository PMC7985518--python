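"""Pipeline configuration: validated load/save of YAML run descriptions."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a pipeline config."""


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run.

    Input paths default to empty strings so a config can be built
    incrementally; :func:`tfcascade.pipeline.run_pipeline` validates that
    the paths it needs exist.
    """

    # inputs
    genes_gtf: str = ""
    peaks_bed: str = ""
    genome_fasta: str = ""
    motifs: str = ""
    open_chromatin: dict = field(default_factory=dict)   # {"control": path, "treated": path}
    rem_table: str | None = None
    deg_tables: dict = field(default_factory=dict)       # {timepoint: path}
    tf_genes: str | None = None                          # TSV tf_name \t gene_id
    outdir: str = "cascade_out"
    # window / decay
    half_width: int = 25_000
    decay_constant: float = 5_000.0
    # TRAP constants
    trap_lambda: float = 0.7
    trap_r0_slope: float = 0.584
    trap_r0_intercept: float = -5.66
    pseudocount: float = 1.0
    # affinity threshold calibration
    threshold_p_value: float = 0.05
    n_random_sequences: int = 1_000
    # classification
    root_tf: str = "VDR"
    k_methods: int = 1
    padj_cutoff: float = 0.05
    early_timepoints: list = field(default_factory=lambda: ["2.5h", "4h"])
    late_timepoints: list = field(default_factory=lambda: ["24h"])
    # regression
    epsilon: float = 1e-3
    l1_ratio: float = 0.1
    penalty_grid: list = field(
        default_factory=lambda: [1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0]
    )
    n_outer_folds: int = 6
    n_inner_folds: int = 6
    restrict_to_secondary: bool = True
    feature_kind: str = "ratio"
    # network: absolute score threshold, or "calibrated" for the per-TF
    # random-sequence thresholds
    network_edge_threshold: Any = 0.1
    variant_agg: str = "max"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ConfigError(f"half_width must be > 0, got {self.half_width}")
        if self.decay_constant <= 0:
            raise ConfigError(
                f"decay_constant must be > 0, got {self.decay_constant}"
            )
        if self.trap_lambda <= 0 or self.pseudocount <= 0 or self.epsilon <= 0:
            raise ConfigError("trap_lambda, pseudocount and epsilon must be > 0")
        if not 0.0 < self.threshold_p_value < 1.0:
            raise ConfigError("threshold_p_value must be in (0, 1)")
        if not 0.0 < self.padj_cutoff <= 1.0:
            raise ConfigError("padj_cutoff must be in (0, 1]")
        if self.k_methods not in (1, 2, 3):
            raise ConfigError(f"k_methods must be 1, 2 or 3, got {self.k_methods}")
        if self.n_random_sequences < 100:
            raise ConfigError("n_random_sequences must be >= 100")
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ConfigError("fold counts must be >= 2")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ConfigError("l1_ratio must be in [0, 1]")
        if self.feature_kind not in ("ratio", "difference"):
            raise ConfigError(f"unknown feature_kind {self.feature_kind!r}")
        if self.variant_agg not in ("max", "sum", "mean"):
            raise ConfigError(f"unknown variant_agg {self.variant_agg!r}")
        if any(c <= 0 for c in self.penalty_grid):
            raise ConfigError("penalty_grid values must be > 0")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        if self.network_edge_threshold != "calibrated":
            try:
                self.network_edge_threshold = float(self.network_edge_threshold)
            except (TypeError, ValueError) as exc:
                raise ConfigError(
                    "network_edge_threshold must be a number or 'calibrated'"
                ) from exc

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML (or JSON) pipeline config; empty file means all defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
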