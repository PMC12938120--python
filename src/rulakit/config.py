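"""Pipeline configuration: defaults, YAML overrides, provenance export.

The effective configuration is the per-module defaults overlaid with a YAML
file of the form::

    stabilizer:
      mode: angles
      alpha:
        trunk: 0.8
        arm_left: 0.7
    kinematics:
      trunk_correction: 10.0
    rula:
      forearm_neutral: [50, 110]
    alerts:
      threshold: 5
      refractory: 2.0
    analytics:
      baseline_s: 3.0

Every value is validated by the owning module's dataclass at load time, and
the effective configuration is embedded in every report for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .alerts import AlertConfig
from .analytics import AnalyticsConfig
from .kinematics import KinematicsConfig
from .rula import RulaConfig
from .stabilizer import FilterConfig


@dataclass
class PipelineConfig:
    stabilizer: FilterConfig = field(default_factory=FilterConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    rula: RulaConfig = field(default_factory=RulaConfig)
    alerts: AlertConfig = field(default_factory=AlertConfig)
    analytics: AnalyticsConfig = field(default_factory=AnalyticsConfig)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        return cls.from_dict(overrides)

    @classmethod
    def from_dict(cls, overrides: dict) -> "PipelineConfig":
        cfg = cls()
        unknown = set(overrides) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")

        def apply(block_name: str, obj, mapping: dict):
            kw = {}
            valid_names = {f.name for f in fields(obj)}
            for key, val in mapping.items():
                # stabilizer block spells its coefficient map 'alpha'
                attr = "alpha_by_channel" if (block_name == "stabilizer" and key == "alpha") else key
                if attr not in valid_names:
                    raise ValueError(f"unknown key {block_name}.{key}")
                current = getattr(obj, attr)
                if isinstance(current, dict) and isinstance(val, dict):
                    merged = dict(current)
                    merged.update(val)
                    kw[attr] = merged
                elif isinstance(current, tuple) and isinstance(val, (list, tuple)):
                    kw[attr] = tuple(val)
                else:
                    kw[attr] = val
            return replace(obj, **kw)

        for f in fields(cls):
            if f.name in overrides:
                block = overrides[f.name]
                if not isinstance(block, dict):
                    raise ValueError(f"config section {f.name!r} must be a mapping")
                setattr(cfg, f.name, apply(f.name, getattr(cfg, f.name), block))
        return cfg

    def to_dict(self) -> dict:
        def plain(obj):
            out = {}
            for f in fields(obj):
                v = getattr(obj, f.name)
                out[f.name] = list(v) if isinstance(v, tuple) else v
            return out

        return {
            "stabilizer": plain(self.stabilizer),
            "kinematics": plain(self.kinematics),
            "rula": plain(self.rula),
            "alerts": plain(self.alerts),
            "analytics": plain(self.analytics),
        }
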