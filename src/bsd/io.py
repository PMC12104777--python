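"""Reading and writing spectra tables and configuration files.

Spectra are delimited text (TSV/CSV) with a header row: ``frequency_hz``
followed by one column per series (subject/condition/channel).
Configuration is YAML (JSON is valid YAML and therefore accepted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, DataFormatError
from .model import FrequencyGrid

__all__ = ["SpectraTable", "read_spectra", "write_spectra", "load_config", "dump_json"]

FREQ_COLUMN = "frequency_hz"


@dataclass
class SpectraTable:
    """A frequency grid plus named spectral series."""

    grid: FrequencyGrid
    series: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.grid)
        for name, col in self.series.items():
            col = np.asarray(col, dtype=float)
            if col.size != n:
                raise DataFormatError(
                    f"series {name!r} has {col.size} rows, grid has {n}"
                )
            self.series[name] = col

    @property
    def names(self) -> list[str]:
        return list(self.series)

    def to_frame(self) -> pd.DataFrame:
        data = {FREQ_COLUMN: self.grid.freqs}
        data.update(self.series)
        return pd.DataFrame(data)


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_spectra(path, delimiter: str | None = None, metadata: dict | None = None) -> SpectraTable:
    """Read a spectra table, validating the header and the frequency column."""
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as e:  # ragged rows, parse failures
        raise DataFormatError(f"{path}: cannot parse table: {e}") from e
    if FREQ_COLUMN not in df.columns:
        raise DataFormatError(
            f"{path}: missing required header column {FREQ_COLUMN!r} "
            f"(found {list(df.columns)})"
        )
    freqs = df[FREQ_COLUMN].to_numpy(dtype=float)
    diffs = np.diff(freqs)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        # offending entry is freqs[bad[0]+1]; +2 more for the header line
        # and 1-based file line numbering
        raise DataFormatError(
            f"{path}: frequency column is not strictly increasing at data row "
            f"{int(bad[0]) + 3} (value {freqs[bad[0] + 1]})"
        )
    if np.any(freqs <= 0):
        row = int(np.nonzero(freqs <= 0)[0][0]) + 2
        raise DataFormatError(f"{path}: non-positive frequency at data row {row}")
    series = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != FREQ_COLUMN}
    if not series:
        raise DataFormatError(f"{path}: no spectral series columns found")
    return SpectraTable(grid=FrequencyGrid(freqs), series=series, metadata=metadata or {})


def write_spectra(table: SpectraTable, path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    table.to_frame().to_csv(path, sep=sep, index=False)


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration file into a dict."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: invalid YAML: {e}") from e
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
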