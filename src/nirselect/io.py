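"""Readers and writers for spectra, responses and result tables.

Conventions: comma-separated CSV, "." decimal, UTF-8, samples in rows.  The
predictor file carries a mandatory header row of wavelength labels (parsed
as numbers when possible); the response file is a single column with
header.  Result tables are written as TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DimensionError

__all__ = ["SpectraDataset", "read_spectra", "write_spectra", "write_tsv"]


@dataclass
class SpectraDataset:
    """An n x m predictor matrix with wavelength labels and a response."""

    X: np.ndarray
    y: np.ndarray
    wavelengths: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise DimensionError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise DimensionError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]}"
            )
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("missing or non-finite values are not allowed")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths)
            if self.wavelengths.shape[0] != self.X.shape[1]:
                raise DimensionError(
                    "wavelength label count differs from column count"
                )
            if len(set(map(str, self.wavelengths))) != len(self.wavelengths):
                raise ValueError("duplicate wavelength labels")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]


def _parse_labels(columns) -> np.ndarray:
    try:
        return np.asarray([float(c) for c in columns])
    except (TypeError, ValueError):
        return np.asarray([str(c) for c in columns], dtype=object)


def read_spectra(x_path, y_path, transpose: bool = False) -> SpectraDataset:
    """Load predictors and response from CSV files.

    ``transpose=True`` handles wavelength-major exports (wavelengths in
    rows) from instrument software.
    """
    x_df = pd.read_csv(x_path, float_precision="round_trip")
    if transpose:
        x_df = x_df.set_index(x_df.columns[0]).T.reset_index(drop=True)
    y_df = pd.read_csv(y_path, float_precision="round_trip")
    if y_df.shape[1] != 1:
        raise ValueError(f"{y_path}: response file must have a single column")
    if x_df.shape[0] != y_df.shape[0]:
        raise DimensionError(
            f"row-count mismatch: X has {x_df.shape[0]} rows, "
            f"y has {y_df.shape[0]}"
        )
    try:
        X = x_df.to_numpy(dtype=float)
        y = y_df.iloc[:, 0].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in input: {exc}") from exc
    return SpectraDataset(X=X, y=y, wavelengths=_parse_labels(x_df.columns))


def write_spectra(data: SpectraDataset, x_path, y_path) -> None:
    """Write a dataset back to the CSV layout read_spectra expects."""
    labels = (
        data.wavelengths
        if data.wavelengths is not None
        else np.arange(data.n_wavelengths)
    )
    # %.17g guarantees float64 values survive the text round-trip exactly
    pd.DataFrame(data.X, columns=[str(w) for w in labels]).to_csv(
        x_path, index=False, float_format="%.17g"
    )
    pd.DataFrame({"response": data.y}).to_csv(
        y_path, index=False, float_format="%.17g"
    )


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
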