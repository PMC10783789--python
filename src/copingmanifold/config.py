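"""Analysis configuration and seeded RNG plumbing.

A single flat :class:`AnalysisConfig` collects every numeric default used
anywhere in the pipeline, so that a run is fully described by one YAML/JSON
file plus a master seed.  Child RNG streams for independent stages are derived
from the master seed with :func:`child_rng`, keyed by stable string/int labels
(e.g. ``("animal", 2, "day", 3, "behavior")``), so adding a stage never
perturbs the streams of existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

logger = logging.getLogger("copingmanifold")


@dataclass
class AnalysisConfig:
    """Numeric defaults for every pipeline stage.

    Units are given per field; thresholds are dimensionless unless noted.
    """

    # trace conditioning
    detrend_window_s: float = 30.0      # running-percentile window (seconds)
    detrend_percentile: float = 10.0    # percentile removed as slow baseline
    transient_k: float = 2.0            # SD threshold on frame-to-frame rise
    smooth_sigma_s: float = 0.25        # Gaussian kernel sigma before embedding
    n_quantiles: int = 100              # quantile-transformer resolution
    zscore_joint: bool = True           # z-score baseline+TS jointly

    # per-neuron scoring
    selectivity_threshold: float = 0.2
    movement_threshold: float = 0.2
    peth_window_s: float = 0.5

    # regression / decoding
    folds: int = 10
    logistic_c_context: float = 0.1
    logistic_c_coping: float = 0.01
    svc_c: float = 1.0
    ridge_alpha: float = 50.0
    n_population_predictors: int = 50
    ev_surrogates: int = 1000
    surrogate_shift_min_s: float = 20.0
    surrogate_shift_max_s: float = 120.0
    ev_alpha_percentile: float = 95.0
    decode_surrogates: int = 20
    contiguous_folds: bool = True       # temporal-block CV (False: shuffled frames)
    standardize_global: bool = False    # fit scaler on all frames, not train only

    # manifold
    embedding_method: str = "isomap"
    embedding_dims: int = 5
    isomap_neighbors: int = 500
    spectral_neighbors: int = 1000
    fit_fraction: float = 0.6
    template_digits: int = 20
    flow_bins: int = 15
    turn_target_rate_hz: float = 2.67
    rotation_reps: int = 100

    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.detrend_window_s <= 0 or self.transient_k <= 0:
            raise ValueError("thresholds must be positive")
        if self.selectivity_threshold <= 0 or self.movement_threshold <= 0:
            raise ValueError("classification thresholds must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.embedding_dims < 2:
            raise ValueError("embedding_dims must be >= 2")
        if not 0 < self.fit_fraction <= 1:
            raise ValueError("fit_fraction must be in (0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def log_resolved(self) -> None:
        logger.info("resolved config: %s", json.dumps(self.to_dict(), sort_keys=True))
        logger.info("master seed: %d", self.seed)


def _key_to_int(key: Any) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode())


def child_rng(master_seed: int, *keys: Any) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from the master seed.

    Keys may be strings or integers; the mapping is stable across runs and
    platforms (CRC32 of the string form).
    """
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
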