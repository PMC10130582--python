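"""Flat key=value text configuration files.

One ``key = value`` pair per line; ``#`` starts a comment; all values parse
as decimal floats. Unknown keys are rejected so that typos never silently
fall back to defaults.
"""

from __future__ import annotations

from pathlib import Path


def write_flat_config(path, values: dict[str, float], header: str = "") -> None:
    lines = []
    if header:
        lines.append(f"# {header}")
    for key, value in values.items():
        lines.append(f"{key} = {value!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_flat_config(path, known_keys: set[str]) -> dict[str, float]:
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, text = line.partition("=")
        key = key.strip()
        if key not in known_keys:
            raise ValueError(
                f"{path}:{lineno}: unknown key {key!r}; known keys: {sorted(known_keys)}"
            )
        if key in values:
            raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
        try:
            values[key] = float(text.strip())
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: bad numeric value for {key!r}") from err
    return values
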