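"""Pipeline configuration: every numeric threshold in one validated record.

Defaults reflect the published analysis conditions for a high-GC
actinobacterial genome: 100-bp peak clustering, sub-clustering at positional
standard deviation 25, a minimum raw peak count of 4, a Z-score cut of 6, a
40-nt upstream folding window evaluated at 30 degC with a -23 kcal/mol
structured/unstructured split, a 3-uridine cut over the 8-nt tract downstream
of the stem, 300-bp read-through flanks, and 200-bp / 5% / raw-5 sliding-window
criteria for transcription-unit assembly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Optional

import yaml

from .model import ConfigError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cluster_gap: int = 100
    subcluster_sd: float = 25.0
    min_peak_count: float = 4.0
    zscore_min: float = 6.0
    zscore_flank: int = 50
    knn_window_halfwidth: int = 10
    downstream_assoc_window: int = 500
    premature_offset: int = 70
    fold_window: int = 40
    fold_temperature: float = 30.0
    hs_threshold: float = -23.0
    utract_window: int = 8
    utract_min_u: int = 3
    readthrough_flank: int = 300
    readthrough_cutoff: float = 0.5
    tu_window: int = 200
    tu_frac: float = 0.05
    tu_min_raw: float = 5.0
    tss_offset: int = 100
    tep_offset: int = 100
    short_pair_cutoff: int = 200
    max_tu_span: int = 20000
    lenient_window_filter: bool = False
    bitep_max_overlap: int = 60
    random_n: int = 10000
    rpf_median_default: float = 18.75
    rpf_rna_log_ratio_default: float = 0.74
    knn_k: int = 5
    cv_fraction: float = 0.5
    cv_reps: int = 1000
    replicate_tolerance: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bad = []
        for key in (
            "cluster_gap",
            "knn_window_halfwidth",
            "downstream_assoc_window",
            "fold_window",
            "utract_window",
            "readthrough_flank",
            "tu_window",
            "short_pair_cutoff",
            "max_tu_span",
            "zscore_flank",
        ):
            if getattr(self, key) <= 0:
                bad.append(key)
        if not 0 < self.tu_frac < 1:
            bad.append("tu_frac")
        if not 0 < self.cv_fraction < 1:
            bad.append("cv_fraction")
        if self.hs_threshold >= 0:
            bad.append("hs_threshold")
        if self.subcluster_sd <= 0:
            bad.append("subcluster_sd")
        if self.min_peak_count < 0:
            bad.append("min_peak_count")
        if self.knn_k < 1:
            bad.append("knn_k")
        if self.cv_reps < 0:
            bad.append("cv_reps")
        if bad:
            raise ConfigError(f"invalid configuration values for: {', '.join(bad)}")

    def replace(self, **overrides) -> "PipelineConfig":
        return dataclasses.replace(self, **overrides)


def load_config(path: Optional[str] = None, **overrides) -> PipelineConfig:
    """Build a config from defaults, an optional flat YAML file, and overrides.

    YAML keys may use dashes or underscores. Unknown keys raise a
    :class:`~termscape.model.ConfigError`.
    """
    values = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a flat mapping")
        values.update({str(k).replace("-", "_"): v for k, v in loaded.items()})
    values.update(overrides)

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = PipelineConfig(**values)
    log.info("pipeline configuration: %s", cfg)
    return cfg
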