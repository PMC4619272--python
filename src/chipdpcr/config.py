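"""Run configuration with lossless YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .chip_model import DEFAULT_MIN_VALID_PARTITIONS, DEFAULT_QUALITY_THRESHOLD
from .exceptions import SchemaError
from .poisson_quant import DEFAULT_PARTITION_VOLUME_UL


@dataclass(frozen=True)
class RunConfig:
    """All tunables of an analysis run.

    Defaults encode the validated operating point of the assay: quality
    cut 0.5, QC floor of 10,000 valid partitions, 0.809 nL wells, 95 %
    intervals, cel-miR-39 as the VIC spike-in, automatic per-channel
    fluorescence thresholds, and project-wide normalization scope.
    """

    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
    min_valid_partitions: int = DEFAULT_MIN_VALID_PARTITIONS
    partition_volume: float = DEFAULT_PARTITION_VOLUME_UL
    confidence_level: float = 0.95
    spike_assay: str = "cel-mir-39"
    fam_threshold: float | None = None  # None = automatic
    vic_threshold: float | None = None
    ci_method: str = "delta"  # "delta" | "binomial"
    normalization_scope: str = "project"  # "project" | "per-sample"
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.quality_threshold <= 1:
            raise ValueError("quality_threshold must lie in [0, 1]")
        if self.min_valid_partitions < 0:
            raise ValueError("min_valid_partitions must be >= 0")
        if self.partition_volume <= 0:
            raise ValueError("partition_volume must be > 0")
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must lie in (0, 1)")
        if self.ci_method not in ("delta", "binomial"):
            raise ValueError("ci_method must be 'delta' or 'binomial'")
        if self.normalization_scope not in ("project", "per-sample"):
            raise ValueError("normalization_scope must be 'project' or 'per-sample'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError(f"config file {path} is not a YAML mapping")
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        """Short stable digest identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
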