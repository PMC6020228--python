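"""Run configuration: thresholds, segment definitions, seeds.

A config file is flat YAML key/value (one nested mapping, ``segments``, is
allowed for residue ranges).  Unknown keys are rejected so typos fail loudly
instead of silently running with defaults.  CLI flags override config
values; every result file echoes the effective configuration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError
from .fluctuations import (DEFAULT_ANTICORR_THRESHOLD,
                           DEFAULT_EQUILIBRATION_FRACTION, DEFAULT_SEGMENTS)
from .geometry import DEFAULT_MIN_DWELL, DEFAULT_OPENING_THRESHOLD
from .rin import DEFAULT_DMAX, DEFAULT_DMIN, DEFAULT_Z_THRESHOLD


@dataclass
class RunConfig:
    segments: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS))
    anticorr_threshold: float = DEFAULT_ANTICORR_THRESHOLD
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION
    dmin: float = DEFAULT_DMIN
    dmax: float = DEFAULT_DMAX
    z_threshold: float = DEFAULT_Z_THRESHOLD
    opening_threshold: float = DEFAULT_OPENING_THRESHOLD
    min_dwell: int = DEFAULT_MIN_DWELL
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segments"] = {k: list(v) for k, v in self.segments.items()}
        return d


_SCALAR_KEYS = {
    "anticorr_threshold": float,
    "equilibration_fraction": float,
    "dmin": float,
    "dmax": float,
    "z_threshold": float,
    "opening_threshold": float,
    "min_dwell": int,
    "seed": int,
    "output_dir": str,
}


def load_config(source) -> RunConfig:
    """Parse a config file (path, stream, or YAML text) into a RunConfig."""
    if hasattr(source, "read"):
        text = source.read()
    elif "\n" in source or ":" in source:
        text = source
    else:
        text = open(source).read()
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config: {exc}") from None
    if not isinstance(raw, dict):
        raise ConfigError("config must be a key/value mapping")
    cfg = RunConfig()
    for key, value in raw.items():
        if key == "segments":
            if not isinstance(value, dict):
                raise ConfigError("segments must map names to [lo, hi] ranges")
            segs = {}
            for name, rng in value.items():
                try:
                    lo, hi = int(rng[0]), int(rng[1])
                except (TypeError, ValueError, IndexError):
                    raise ConfigError(f"segment {name!r}: range must be [lo, hi]") from None
                if hi < lo:
                    raise ConfigError(f"segment {name!r}: empty range {lo}–{hi}")
                segs[str(name)] = (lo, hi)
            cfg.segments = segs
        elif key in _SCALAR_KEYS:
            try:
                setattr(cfg, key, _SCALAR_KEYS[key](value))
            except (TypeError, ValueError):
                raise ConfigError(f"config key {key!r}: bad value {value!r}") from None
        else:
            raise ConfigError(f"unknown config key {key!r}")
    return cfg
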