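"""Pipeline configuration: one serializable object every stage reads from."""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .synthetic import GroupParams, default_group_params


@dataclass
class PipelineConfig:
    """All tunable parameters of the simulate -> report pipeline.

    Serializes round-trip identically to/from YAML; :func:`validate_config`
    checks cross-field constraints (band ordering, Nyquist, filter cutoff
    below the lower band edge).
    """

    seed: int = 0
    fs_accel: float = 148.1
    fs_pen: float = 100.0
    filter_order: int = 4
    filter_cutoff: float = 0.5
    psd_window: str = "hann"
    psd_segment_s: float = 4.0
    psd_overlap: float = 0.5
    band_low: tuple[float, float] = (0.5, 4.0)
    band_high: tuple[float, float] = (4.0, 12.0)
    clock_offset: float = 0.0
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    site: str = "S2"
    groups: list[GroupParams] = field(default_factory=default_group_params)


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Validate ranges and cross-field constraints; returns the config.

    Raises :class:`ConfigError` with a message naming the offending key.
    """
    if not isinstance(config.seed, (int,)) or isinstance(config.seed, bool):
        raise ConfigError("seed: must be an integer")
    for key in ("fs_accel", "fs_pen", "psd_segment_s", "svm_c"):
        if getattr(config, key) <= 0:
            raise ConfigError(f"{key}: must be positive")
    if config.filter_order < 1:
        raise ConfigError("filter_order: must be >= 1")
    for key in ("band_low", "band_high"):
        f1, f2 = getattr(config, key)
        if not (0 <= f1 < f2):
            raise ConfigError(f"{key}: band edges must satisfy 0 <= f1 < f2")
    nyquist = config.fs_accel / 2.0
    if config.band_high[1] > nyquist:
        raise ConfigError(
            f"band_high: upper edge {config.band_high[1]} Hz exceeds the "
            f"Nyquist frequency {nyquist:.2f} Hz"
        )
    if config.band_low[1] > config.band_high[0]:
        raise ConfigError("band_low: must not overlap band_high")
    if not (0 < config.filter_cutoff <= config.band_low[0]):
        raise ConfigError(
            "filter_cutoff: must lie in (0, lower band edge]"
        )
    if not (0 <= config.psd_overlap < 1):
        raise ConfigError("psd_overlap: must lie in [0, 1)")
    if not config.groups:
        raise ConfigError("groups: at least one group is required")
    return config


def config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["band_low"] = list(config.band_low)
    d["band_high"] = list(config.band_high)
    d["groups"] = [
        {**dataclasses.asdict(g),
         "mean_ratio_per_site": list(g.mean_ratio_per_site),
         "sd_ratio_per_site": list(g.sd_ratio_per_site)}
        for g in config.groups
    ]
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "seed" not in d:
        warnings.warn("config has no seed; defaulting to 0", stacklevel=2)
        d["seed"] = 0
    if "groups" in d:
        d["groups"] = [
            GroupParams(
                group_label=g["group_label"],
                n_subjects=int(g["n_subjects"]),
                mean_ratio_per_site=tuple(g["mean_ratio_per_site"]),
                sd_ratio_per_site=tuple(g["sd_ratio_per_site"]),
                mean_task_time=float(g["mean_task_time"]),
                sd_task_time=float(g["sd_task_time"]),
                mean_ftm=g.get("mean_ftm"),
                sd_ftm=float(g.get("sd_ftm") or 0.0),
            )
            for g in d["groups"]
        ]
    for key in ("band_low", "band_high"):
        if key in d:
            d[key] = tuple(float(v) for v in d[key])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return validate_config(config_from_dict(data))


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
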