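"""TOML serialization of model and protocol configurations.

Model configs round-trip through a flat TOML layout: one ``[cable]`` table,
one ``[model]`` table for the scalar knobs, and one ``[cells.<name>]`` table
per input neuron. Protocol configs name a builder from
:mod:`t5rf.stimuli` plus its keyword arguments.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict
from pathlib import Path

from . import stimuli
from .model import CableParams, CellTypeSpec, HexArray, ModelConfig, default_config
from .stimuli import InvalidConfigError

__all__ = ["model_config_to_toml", "model_config_from_toml", "protocol_from_toml"]


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return f'"{v}"'


def _table(name: str, mapping: dict) -> str:
    lines = [f"[{name}]"]
    lines += [f"{k} = {_fmt(v)}" for k, v in mapping.items()]
    return "\n".join(lines) + "\n"


def model_config_to_toml(config: ModelConfig, path) -> None:
    parts = [_table("model", dict(
        IE_ratio=config.IE_ratio, ie_mode=config.ie_mode, dt=config.dt,
        dt_ln=config.dt_ln, variant_name=config.variant_name,
        hex_spacing=config.hex_array.spacing,
        pd_direction=config.hex_array.pd_direction,
    ))]
    parts.append(_table("cable", asdict(config.cable)))
    for cell in config.cell_types:
        parts.append(_table(f"cells.{cell.name}",
                            {k: v for k, v in asdict(cell).items() if k != "name"}))
    Path(path).write_text("\n".join(parts))


def model_config_from_toml(path) -> ModelConfig:
    with open(path, "rb") as f:
        data = tomllib.load(f)
    m = data.get("model", {})
    hex_array = HexArray(spacing=m.pop("hex_spacing", 5.0),
                         pd_direction=m.pop("pd_direction", 0.0))
    cable = CableParams(**data.get("cable", {}))
    cells = tuple(
        CellTypeSpec(name=name, **spec) for name, spec in data.get("cells", {}).items()
    )
    if not cells:
        cells = default_config(m.get("variant_name", "all_rectified")).cell_types
    return ModelConfig(cell_types=cells, cable=cable, hex_array=hex_array, **m)


_BUILDERS = {
    "bars": stimuli.build_bar_protocol,
    "ternary_noise": stimuli.build_ternary_noise,
    "gratings": stimuli.build_grating_protocol,
    "flashes": stimuli.build_flash_protocol,
}


def protocol_from_toml(path) -> stimuli.StimulusTrace:
    """Render the stimulus protocol described by a TOML config.

    Layout: a ``[screen]`` table (ScreenGeometry fields) and a ``[protocol]``
    table with ``kind`` in {bars, ternary_noise, gratings, flashes} plus the
    builder's keyword arguments.
    """
    with open(path, "rb") as f:
        data = tomllib.load(f)
    geom = stimuli.ScreenGeometry(**data.get("screen", {}))
    proto = dict(data.get("protocol", {}))
    kind = proto.pop("kind", None)
    if kind not in _BUILDERS:
        raise InvalidConfigError(f"unknown protocol kind {kind!r}")
    return _BUILDERS[kind](geom, **proto)
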