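"""Configuration handling and tabular serialization for the CLI toolchain."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = ["RunConfig", "load_config", "write_results", "read_results",
           "read_series"]


@dataclass(frozen=True)
class RunConfig:
    """Validated run parameters; defaults follow the recommended settings
    (50 rings, delay 1, 2500-sample windows with step 500)."""

    rings: int = 50
    delay: int = 1
    width: int = 2500
    step: int = 500
    hurst: float = 0.5
    hurst_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))
    length: int = 20000
    replicates: int = 30
    seed: int = 0
    stage_order: tuple[int, ...] = (0, 5, 2, 3, 4)
    filter_mode: str = "butter"

    def __post_init__(self) -> None:
        if self.rings < 1:
            raise ValueError(f"rings must be >= 1, got {self.rings}")
        if self.delay < 1:
            raise ValueError(f"delay must be >= 1, got {self.delay}")
        if self.width < 1 or self.step < 1:
            raise ValueError("width and step must be >= 1")
        if not 0.0 < self.hurst <= 1.0:
            raise ValueError(f"hurst must be in (0, 1], got {self.hurst}")
        if any(not 0.0 < h <= 1.0 for h in self.hurst_grid):
            raise ValueError("hurst_grid values must be in (0, 1]")
        if self.length < 2:
            raise ValueError(f"length must be >= 2, got {self.length}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.filter_mode not in ("butter", "harmonic"):
            raise ValueError(f"filter_mode must be butter or harmonic, "
                             f"got {self.filter_mode}")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Merge defaults < YAML file < explicit overrides into a RunConfig.

    Unknown keys are rejected with the offending name; tuple-valued fields
    accept lists.  ``overrides`` entries that are None are ignored, so CLI
    flags left at their unset default do not mask file values.
    """
    known = {f.name for f in fields(RunConfig)}
    merged: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        merged.update(loaded)
    for k, v in (overrides or {}).items():
        if v is not None:
            merged[k] = v
    unknown = set(merged) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("hurst_grid", "stage_order"):
        if key in merged:
            merged[key] = tuple(merged[key])
    return RunConfig(**merged)


def read_series(path: str | Path, column: str | int | None = None) -> np.ndarray:
    """Read a univariate series from a single-column text/CSV file.

    With a header and several columns, ``column`` selects by name or index;
    a bare numeric column needs no header.
    """
    with Path(path).open() as fh:
        first = fh.readline()
    has_header = any(c.isalpha() for c in first.replace("e", "").replace("E", ""))
    df = pd.read_csv(path, header=0 if has_header else None,
                     float_precision="round_trip")
    if column is None:
        if df.shape[1] != 1:
            raise ValueError(f"{path} has {df.shape[1]} columns; pass column=")
        col = df.iloc[:, 0]
    elif isinstance(column, int):
        col = df.iloc[:, column]
    else:
        col = df[column]
    return col.to_numpy(dtype=float)


def write_results(rows: Sequence[Mapping[str, Any]] | pd.DataFrame,
                  path: str | Path,
                  columns: Sequence[str] | None = None) -> Path:
    """Write result rows as CSV with a deterministic column order.

    Floats are rendered with 17 significant digits so a write-read-write
    round trip is byte-identical.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if columns is not None:
        df = df.loc[:, list(columns)]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results` losslessly."""
    return pd.read_csv(path, float_precision="round_trip")
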