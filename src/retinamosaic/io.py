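"""Pattern CSV input/output and config handling.

Patterns are stored as plain CSV: one lattice row per line of
comma-separated 0/1 values, optionally preceded by a ``#``-prefixed metadata
line recording the dimensions and orientation.  Patterns are tiny (at most a
few thousand cells), so a diffable text format is the right trade-off.
All indices in files and logs are 0-based.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .pattern import RetinaPattern

__all__ = ["read_pattern", "write_pattern", "load_config"]

PathLike = Union[str, Path]


def write_pattern(pattern: RetinaPattern, path: PathLike, header: bool = True) -> None:
    """Write a pattern to CSV, with an optional metadata comment line."""
    path = Path(path)
    lines = []
    if header:
        lines.append(f"# rows={pattern.n_rows} cols={pattern.n_cols} origin=posterior")
    for i in range(pattern.n_rows):
        lines.append(",".join(str(int(v)) for v in pattern.cells[i]))
    path.write_text("\n".join(lines) + "\n")


def read_pattern(path: PathLike) -> RetinaPattern:
    """Read a binary pattern from CSV.

    Raises ``ValueError`` with distinct messages for an empty file, ragged
    rows and non-binary cell values.
    """
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        values = []
        for tok in line.split(","):
            tok = tok.strip()
            if tok not in ("0", "1"):
                raise ValueError(
                    f"non-binary cell value {tok!r} at line {lineno} of {path}"
                )
            values.append(int(tok))
        rows.append(values)
    if not rows:
        raise ValueError(f"empty pattern file: {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(
            f"ragged rows in {path}: row lengths {sorted(lengths)} differ"
        )
    return RetinaPattern(np.array(rows, dtype=np.uint8))


def load_config(
    path: Optional[PathLike],
    allowed: Sequence[str],
    overrides: Optional[Mapping[str, object]] = None,
) -> dict:
    """Load a flat YAML config, rejecting unknown keys, and merge overrides.

    Command-line values in ``overrides`` that are not None take precedence
    over the file.
    """
    config: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a flat key-value mapping")
        unknown = sorted(set(loaded) - set(allowed))
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {unknown}")
        config.update(loaded)
    if overrides:
        for key, value in overrides.items():
            if value is not None:
                config[key] = value
    return config
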