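"""Pipeline configuration: one structured object, loadable from YAML.

A fully specified config plus the seed determines every output byte of a
pipeline run (manifests carry checksums so this is checkable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields, is_dataclass
from pathlib import Path

import yaml

from .crackle_features import DetectionSettings
from .preprocessing import FilterSettings
from .spectral_features import SpectralSettings
from .synthetic_data import CohortSpec


@dataclass
class AudioSynthSpec:
    """Audio-fixture parameters: protocol timing plus crackle placement."""

    n_patients: int = 2
    fs: float = 44100.0
    n_breaths: int = 8
    t_insp_s: float = 2.0
    t_exp_s: float = 2.0
    snr_db: float = 20.0
    sites: tuple[str, ...] = ("left_posterior_base", "right_posterior_base")
    #: fine crackles inserted per inspiration, one entry per patient
    #: (cycled when n_patients exceeds the list)
    crackles_per_insp: tuple[int, ...] = (12, 5)
    f0_range_hz: tuple[float, float] = (300.0, 700.0)
    tau_range_ms: tuple[float, float] = (3.0, 8.0)
    min_separation_ms: float = 25.0


@dataclass
class ModelSpec:
    """Regression / ROC plan for the analysis stage."""

    outcome: str = "honeycombing"
    #: candidate name -> OR unit scale (e.g. F99 odds per 100 Hz)
    candidates: dict = field(default_factory=lambda: {
        "timing_early": 1.0, "count_per_insp": 5.0, "f99_hz": 100.0,
        "f95_hz": 100.0, "f50_hz": 100.0, "tcd_ms": 1.0, "ldw_ms": 1.0})
    #: terms kept in the multivariate model regardless of screening
    forced_terms: dict = field(default_factory=lambda: {
        "ldw_ms": 1.0, "age_y": 1.0})
    representatives: tuple[str, ...] = ("f99_hz",)
    p_enter: float = 0.05
    corr_threshold: float = 0.7
    roc_variables: tuple[str, ...] = ("count_per_insp", "f99_hz")


@dataclass
class PipelineConfig:
    seed: int = 0
    multichannel: str = "reject"
    count_fine_only: bool = True
    onset_rule: str = "mean_first"
    filter: FilterSettings = field(default_factory=FilterSettings)
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    spectral: SpectralSettings = field(default_factory=SpectralSettings)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    audio: AudioSynthSpec = field(default_factory=AudioSynthSpec)
    model: ModelSpec = field(default_factory=ModelSpec)


def _build(cls, data: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        typ = f.type if isinstance(f.type, type) else None
        if isinstance(val, dict) and f.name in _NESTED:
            kwargs[f.name] = _build(_NESTED[f.name], val)
        elif isinstance(val, list):
            kwargs[f.name] = tuple(val)
        else:
            kwargs[f.name] = val
    return cls(**kwargs)


_NESTED = {
    "filter": FilterSettings,
    "detection": DetectionSettings,
    "spectral": SpectralSettings,
    "cohort": CohortSpec,
    "audio": AudioSynthSpec,
    "model": ModelSpec,
}


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unspecified fields keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(PipelineConfig, data)


def _to_plain(obj):
    import numpy as np
    if is_dataclass(obj):
        obj = asdict(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)
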