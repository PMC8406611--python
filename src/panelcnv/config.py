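"""Pipeline configuration: one validated record of every tunable threshold."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import InputError
from .coverage import DEFAULT_MIN_MAPQ
from .pooling import DEFAULT_MIN_NORMAL_DEPTH
from .qc import (
    DEFAULT_DEVIATION_CUTOFF_PCT,
    DEFAULT_MAX_POOL_CV_PCT,
    DEFAULT_RUNWISE_DELTA_THRESHOLD,
)
from .reporting import (
    DEFAULT_DEL_THRESHOLD,
    DEFAULT_DUP_THRESHOLD,
    DEFAULT_MIN_CONSECUTIVE,
    MOSAIC_DEL_THRESHOLD,
    MOSAIC_MIN_CONSECUTIVE,
)
from .scoring import DEFAULT_FLOOR_SCORE, DEFAULT_MIN_POOL_DEPTH
from .windows import DEFAULT_SLIDE_LEN, DEFAULT_WINDOW_LEN

logger = logging.getLogger("panelcnv")


@dataclass
class PipelineConfig:
    window_len: int = DEFAULT_WINDOW_LEN
    slide_len: int = DEFAULT_SLIDE_LEN
    pool_size: int | None = None  # K; required where pools are built
    min_normal_depth: float = DEFAULT_MIN_NORMAL_DEPTH
    deviation_cutoff_pct: float = DEFAULT_DEVIATION_CUTOFF_PCT
    max_pool_cv_pct: float = DEFAULT_MAX_POOL_CV_PCT
    runwise_delta_threshold: float = DEFAULT_RUNWISE_DELTA_THRESHOLD
    min_pool_depth: float = DEFAULT_MIN_POOL_DEPTH
    floor_score: float = DEFAULT_FLOOR_SCORE
    del_threshold: float = DEFAULT_DEL_THRESHOLD
    dup_threshold: float = DEFAULT_DUP_THRESHOLD
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE
    mosaic_del_threshold: float = MOSAIC_DEL_THRESHOLD
    mosaic_min_consecutive: int = MOSAIC_MIN_CONSECUTIVE
    min_mapq: int = DEFAULT_MIN_MAPQ
    count_duplicates: bool = False

    def validate(self) -> "PipelineConfig":
        if self.slide_len < 1 or self.slide_len > self.window_len:
            raise InputError(
                f"need 1 <= slide_len <= window_len, got {self.slide_len}, {self.window_len}"
            )
        if self.pool_size is not None and self.pool_size < 2:
            raise InputError(f"pool_size must be >= 2, got {self.pool_size}")
        if not self.del_threshold < 0 < self.dup_threshold:
            raise InputError("need del_threshold < 0 < dup_threshold")
        if self.min_pool_depth < 0 or self.min_normal_depth < 0:
            raise InputError("depth cutoffs must be >= 0")
        if self.min_consecutive < 1 or self.mosaic_min_consecutive < 1:
            raise InputError("min_consecutive values must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; keyword overrides (CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"{path}: unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data).validate()

    def resolved(self, **overrides) -> "PipelineConfig":
        cfg = dataclasses.replace(
            self, **{k: v for k, v in overrides.items() if v is not None}
        ).validate()
        logger.info("resolved config: %s", dataclasses.asdict(cfg))
        return cfg
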