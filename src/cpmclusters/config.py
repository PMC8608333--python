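"""TOML run configurations.

A configuration is a nested dict with sections ``[lattice]``, ``[tumor]``,
``[types.E]`` / ``[types.H]`` (and optionally H1/H2), ``[contact]``,
``[motility]`` and ``[run]``; see :data:`cpmclusters.runner.BASE_PARAMS` for
the full key set and defaults.  Reading uses the standard library TOML
parser; writing covers the scalar/list/nested-table subset these configs
use.
"""

from __future__ import annotations

import tomllib
from pathlib import Path


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def dump_config(params: dict, path) -> None:
    Path(path).write_text(dumps(params))


def dumps(params: dict, _prefix: str = "") -> str:
    lines = []
    tables = []
    for key, val in params.items():
        if isinstance(val, dict):
            tables.append((key, val))
        elif val is None:
            continue  # TOML has no null; absent keys fall back to defaults
        else:
            lines.append(f"{key} = {_format(val)}")
    text = "\n".join(lines)
    for key, val in tables:
        name = f"{_prefix}{key}"
        text += f"\n\n[{name}]\n" if text else f"[{name}]\n"
        text += dumps(val, _prefix=name + ".")
    return text


def _format(val) -> str:
    if isinstance(val, bool):
        return "true" if val else "false"
    if isinstance(val, str):
        return f'"{val}"'
    if isinstance(val, (list, tuple)):
        return "[" + ", ".join(_format(v) for v in val) + "]"
    return repr(val)
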