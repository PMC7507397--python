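"""Hierarchical run configuration with strict key validation.

Defaults mirror the canonical design: 10 Hz acquisition, 22 channels per
participant, 30/150/30/150/30 s blocks, the 3.2-12.8 s analysis band,
FDR q = .05, and group sizes 17/16/10.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import constants
from .coherence import BandSpec, WaveletParams
from .errors import ConfigError
from .preprocessing import ArtifactParams
from .signal_synthesis import AcquisitionConfig, CouplingSpec, NoiseSpec, ProbeLayout

__all__ = ["RunConfig", "load_config"]


def _build(cls, data: Mapping[str, Any], path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys under '{path}': {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list) and f.name in _SET_FIELDS:
                v = frozenset(v)
            elif isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


_SET_FIELDS = {"coupled_channels", "active_segments", "roi_channels"}


@dataclass(frozen=True)
class TaskConfig:
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(constants.DEFAULT_GROUP_SIZES)
    )
    tie_rule: str = "leq"


@dataclass(frozen=True)
class StatsConfig:
    fdr_q: float = 0.05
    ibs_tail: str = "one"


@dataclass(frozen=True)
class GcaConfig:
    channel: int | str = "auto"  # "auto" = top FDR-passing channel of the delayed group
    max_order: int = 20
    order: int | None = None
    group: str = "delayed"


@dataclass(frozen=True)
class PipelineConfig:
    snr_threshold: float = 2.0
    inject_artifacts: bool = True
    save_recordings: bool = False
    recording_format: str = "tsv"  # or "snirf"
    baseline_segments: tuple[str, ...] = constants.REST_BASELINE_SEGMENTS
    single_precision: bool = False


@dataclass(frozen=True)
class RunConfig:
    master_seed: int = 0
    output_dir: str = "results"
    task: TaskConfig = field(default_factory=TaskConfig)
    layout: ProbeLayout = field(default_factory=ProbeLayout)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    artifacts: ArtifactParams = field(default_factory=ArtifactParams)
    wavelet: WaveletParams = field(default_factory=WaveletParams)
    band: BandSpec = field(default_factory=BandSpec)
    gca: GcaConfig = field(default_factory=GcaConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    _SECTIONS = {
        "task": TaskConfig,
        "layout": ProbeLayout,
        "acquisition": AcquisitionConfig,
        "coupling": CouplingSpec,
        "noise": NoiseSpec,
        "artifacts": ArtifactParams,
        "wavelet": WaveletParams,
        "band": BandSpec,
        "gca": GcaConfig,
        "stats": StatsConfig,
        "pipeline": PipelineConfig,
    }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any] | None) -> "RunConfig":
        data = dict(data or {})
        unknown = set(data) - set(cls._SECTIONS) - {"master_seed", "output_dir"}
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        if "master_seed" in data:
            kwargs["master_seed"] = int(data["master_seed"])
        if "output_dir" in data:
            kwargs["output_dir"] = str(data["output_dir"])
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                sub = data[name]
                if not isinstance(sub, Mapping):
                    raise ConfigError(f"config section '{name}' must be a mapping")
                kwargs[name] = _build(section_cls, sub, name)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def _clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, frozenset):
                return sorted(obj)
            if isinstance(obj, tuple):
                return list(obj)
            if hasattr(obj, "tolist"):
                return obj.tolist()
            return obj

        out = {"master_seed": self.master_seed, "output_dir": self.output_dir}
        for name in self._SECTIONS:
            out[name] = _clean(getattr(self, name))
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def dump_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data)
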