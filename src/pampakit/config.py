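"""Plain key-value configuration for plate geometry and tolerances.

Config files are flat YAML mappings, e.g.::

    acceptor_volume_cm3: 0.2
    donor_volume_cm3: 0.3
    filter_area_cm2: 0.2826
    steady_state_lag_s: 1140

Precedence is CLI option > config file > package default.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .plate import SandwichGeometry

__all__ = ["load_config", "geometry_from_config"]

_GEOMETRY_KEYS = (
    "acceptor_volume_cm3",
    "donor_volume_cm3",
    "filter_area_cm2",
    "steady_state_lag_s",
)


def load_config(path: str | Path | None) -> dict:
    """Read a flat key-value config file; None or empty file give {}."""
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return data


def geometry_from_config(config: dict, **overrides: float | None) -> SandwichGeometry:
    """Build a geometry from defaults, config values and explicit overrides."""
    kwargs = {}
    for key in _GEOMETRY_KEYS:
        if overrides.get(key) is not None:
            kwargs[key] = float(overrides[key])
        elif key in config:
            kwargs[key] = float(config[key])
    return SandwichGeometry(**kwargs)
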