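"""Run configuration: every tunable threshold with its validated default.

Defaults are the published operating point: rotation 65 deg, 5 s minimum
crossing, SDVM_1 = 0.01 g, SDVM_2 = 0.004 g, MinLieT = 20 min, back
inclination 45 deg, valid days require strictly more than 8 h of wear on
both sensors.  A YAML file and/or keyword overrides may change any key;
``resolved()`` returns the flat dict a run actually used, for provenance
sidecars.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

DEFAULTS: dict = {
    "sample_rate_hz": 25.0,
    "features": {"lp_hz": 5.0, "window_s": 2.0},
    "sed": {"inc_deg": 45.0, "sdvm_g": 0.1, "bridge_s": 10.0, "min_bout_s": 5.0},
    "lying": {
        "rot_deg": 65.0,
        "min_cross_s": 5.0,
        "sdvm1_g": 0.01,
        "sdvm2_g": 0.004,
        "min_lie_min": 20.0,
        "rot_ref_s": 10.0,
    },
    "reference": {"inc_back_deg": 45.0},
    "sync": {"chunk_s": 600.0, "max_lag_s": 120.0},
    "nonwear": {"sd_g": 0.003, "min_min": 120.0},
    "validday": {"min_wear_h": 8.0},
}


def _deep_update(base: dict, overrides: dict) -> dict:
    for k, v in overrides.items():
        if k not in base:
            raise KeyError(f"unknown config key {k!r}")
        if isinstance(base[k], dict):
            if not isinstance(v, dict):
                raise ValueError(f"config section {k!r} must be a mapping")
            _deep_update(base[k], v)
        else:
            base[k] = type(base[k])(v) if base[k] is not None else v
    return base


@dataclass
class RunConfig:
    values: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        cfg = cls()
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
            _deep_update(cfg.values, data)
        if overrides:
            _deep_update(cfg.values, overrides)
        return cfg

    def __getitem__(self, key):
        return self.values[key]

    def resolved(self) -> dict:
        return copy.deepcopy(self.values)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=False)

    def lying_params(self):
        from .lying import LyingParams

        ly = self.values["lying"]
        return LyingParams(
            rot_threshold=ly["rot_deg"],
            min_cross=ly["min_cross_s"],
            sdvm1=ly["sdvm1_g"],
            sdvm2=ly["sdvm2_g"],
            min_lie=ly["min_lie_min"],
            rot_ref_s=ly["rot_ref_s"],
        )
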