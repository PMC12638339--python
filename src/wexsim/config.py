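"""Run configuration: protocol-table defaults, YAML loading, validation and
unit normalization (durations in ms in config files, seconds internally)."""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "validate_config", "load_config", "config_hash"]

# Config-file representation of the protocol table (ms / Hz / degrees).
_DEFAULT_CONFIG: dict = {
    "protocols": {
        "bssfp": {"kind": "RECT", "rf_duration_ms": 0.3, "tr_ms": 2.47, "te_ms": None},
        "fiss": {
            "kind": "RECT",
            "rf_duration_ms": 0.3,
            "tr_ms": 2.47,
            "te_ms": None,
            "readouts_per_module": 4,
            "spoil_increment_deg": 117.0,
        },
        "borr": {
            "kind": "BORR",
            "tau_ms": 1.3,
            "f_rf_hz": 500.0,
            "dphi2_deg": 180.0,
            "tr_ms": 4.9,
            "te_ms": None,
            "gap_ms": 0.0,
        },
        "libre": {"kind": "LIBRE", "tau_ms": 1.3, "f_rf_hz": 540.0, "tr_ms": 4.9, "te_ms": None, "gap_ms": 0.0},
        "libor": {
            "kind": "LIBOR",
            "tau_ms": 1.3,
            "f_rf_hz": 270.0,
            "dphi2_deg": 290.0,
            "tr_ms": 4.9,
            "te_ms": None,
            "gap_ms": 0.1,
        },
    },
    "nominal_alpha_deg": 50.0,
    "n_excitations": 1000,
    "grids": {
        "delta_f_hz": {"lo": -800.0, "hi": 800.0, "step": 10.0},
        "alpha_deg": {"half_range": 20.0, "step": 5.0},
        "phase_deg": {"lo": 0.0, "hi": 360.0, "step": 10.0},
    },
    "tissues": {
        "water": {"t1_ms": 1390.0, "t2_ms": 300.0, "shift_hz": 0.0},
        "fat": {"t1_ms": 290.0, "t2_ms": 80.0, "shift_hz": -220.0},
    },
    "phantom": {
        "canvas_n": 96,
        "vial_radius": 9,
        "noise_sd": 0.01,
        "b0_offset_hz": 0.0,
    },
    "seed": 0,
}


@dataclass
class RunConfig:
    """Validated, unit-normalized run configuration."""

    raw: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.raw[key]

    def protocol(self, name: str) -> dict:
        return self.raw["protocols"][name]


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ValueError(f"unknown configuration key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"{where} must be a mapping")
            out[key] = _merge(base[key], val, where)
        else:
            out[key] = val
    return out


def validate_config(config: dict | None) -> RunConfig:
    """Merge user config onto the table defaults, check and normalize.

    Rejects unknown keys, verifies te < tr and tau > 0, and checks fat
    fractions and grids. Scalar durations stay in the config's ms units in
    ``raw``; accessors in the reporting layer convert to seconds.
    """
    merged = _merge(_DEFAULT_CONFIG, config or {})
    for name, proto in merged["protocols"].items():
        tr = float(proto["tr_ms"])
        if tr <= 0:
            raise ValueError(f"protocol {name}: tr must be > 0")
        te = proto.get("te_ms")
        if te is not None and not (0 < float(te) < tr):
            raise ValueError(f"protocol {name}: require 0 < te < tr")
        tau = proto.get("tau_ms", proto.get("rf_duration_ms"))
        if tau is None or float(tau) <= 0:
            raise ValueError(f"protocol {name}: pulse duration must be > 0")
        if float(tau) * (1 if proto["kind"] == "RECT" else 2) >= tr:
            raise ValueError(f"protocol {name}: pulse does not fit in TR")
    g = merged["grids"]["delta_f_hz"]
    if g["hi"] <= g["lo"] or g["step"] <= 0:
        raise ValueError("invalid delta_f grid")
    if not (0 < merged["nominal_alpha_deg"] <= 90):
        raise ValueError("nominal_alpha_deg must be in (0, 90]")
    if merged["phantom"]["noise_sd"] < 0:
        raise ValueError("phantom noise_sd must be >= 0")
    return RunConfig(raw=merged)


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; an empty/missing file gives defaults."""
    data = None
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    return validate_config(data)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the normalized configuration (provenance)."""
    payload = json.dumps(config.raw, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
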