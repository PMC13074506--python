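"""Tabular exchange format for spectra plus chemistry.

A :class:`SampleTable` is a thin wrapper around a wide pandas ``DataFrame``
with one row per (sample, physical state): identifier columns, measured
chemistry (% dry weight), and one reflectance column per wavelength, named
``R400`` .. ``R889``.  The CSV dialect is plain UTF-8, comma separated,
``.`` decimal, header required.  Missing values are not permitted anywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .grid import SEASONS, STATES, check_grid

META_COLUMNS = ["sample_id", "season", "state", "polyphenols", "catechins"]
_R_COLUMN = re.compile(r"^R(\d+)$")


def reflectance_columns(wavelengths: np.ndarray) -> list[str]:
    return [f"R{int(w)}" for w in np.asarray(wavelengths)]


@dataclass
class Violation:
    """A single validation failure: which row, which rule, and why."""

    row: object  # sample_id or positional index
    rule: str
    message: str


class SampleTable:
    """Ordered collection of sample records sharing one wavelength grid."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in META_COLUMNS if c not in frame.columns]
        if missing:
            raise ParseError(f"missing required columns: {missing}")
        wl = self._wavelengths_from_columns(frame.columns)
        if wl.size == 0:
            raise ParseError("no reflectance columns (R<wavelength>) found")
        check_grid(wl)
        cols = META_COLUMNS + reflectance_columns(wl)
        self.frame = frame.loc[:, cols].reset_index(drop=True)
        self._wavelengths = wl

    @staticmethod
    def _wavelengths_from_columns(columns) -> np.ndarray:
        wl = [int(m.group(1)) for c in columns if (m := _R_COLUMN.match(str(c)))]
        return np.asarray(sorted(wl))

    # ---- accessors -------------------------------------------------------
    @property
    def wavelengths(self) -> np.ndarray:
        return self._wavelengths

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def reflectance(self) -> np.ndarray:
        """(n_rows, n_bands) float array of reflectance values."""
        return self.frame[reflectance_columns(self._wavelengths)].to_numpy(float)

    def chemistry(self, indicator: str) -> np.ndarray:
        if indicator not in ("polyphenols", "catechins"):
            raise ValueError(f"unknown indicator: {indicator!r}")
        return self.frame[indicator].to_numpy(float)

    def subset(self, mask) -> "SampleTable":
        return SampleTable(self.frame.loc[mask].reset_index(drop=True))

    def select(self, season: str | None = None, state: str | None = None) -> "SampleTable":
        mask = pd.Series(True, index=self.frame.index)
        if season is not None:
            mask &= self.frame["season"] == season
        if state is not None:
            mask &= self.frame["state"] == state
        return self.subset(mask)

    def equals(self, other: "SampleTable") -> bool:
        return self.frame.equals(other.frame)

    def __len__(self) -> int:
        return len(self.frame)


def write_sample_table(table: SampleTable, path) -> None:
    """Write *table* as CSV with a deterministic column order.

    Floats are serialized with shortest round-trip repr, so write -> read
    preserves every numeric value exactly and re-writing is byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False, lineterminator="\n")


def read_sample_table(path, expected_grid: np.ndarray | None = None) -> SampleTable:
    """Read and validate a sample-table CSV.

    Raises :class:`ParseError` for missing columns, non-numeric reflectance
    or a grid mismatch; a failed read never yields a partial table.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    table = SampleTable(frame)
    numeric = META_COLUMNS[3:] + reflectance_columns(table.wavelengths) if len(table.frame) else []
    for col in numeric:
        if not pd.api.types.is_numeric_dtype(table.frame[col]):
            bad = table.frame[pd.to_numeric(table.frame[col], errors="coerce").isna()]
            row = bad["sample_id"].iloc[0] if len(bad) else "?"
            raise ParseError(f"non-numeric value in column {col!r} (row {row})")
        if table.frame[col].isna().any():
            row = table.frame.loc[table.frame[col].isna(), "sample_id"].iloc[0]
            raise ParseError(f"missing value in column {col!r} (row {row})")
    if expected_grid is not None and not np.array_equal(table.wavelengths, expected_grid):
        raise ParseError(
            f"wavelength grid mismatch: file covers "
            f"{table.wavelengths[0]}-{table.wavelengths[-1]} nm, expected "
            f"{expected_grid[0]}-{expected_grid[-1]} nm"
        )
    return table


def validate_table(table: SampleTable) -> list[Violation]:
    """Check every table invariant; violations are returned, not raised."""
    v: list[Violation] = []
    f = table.frame
    refl = table.reflectance
    ids = f["sample_id"].astype(str)

    dup = f.duplicated(subset=["sample_id", "state"], keep=False)
    for sid in sorted(set(ids[dup])):
        v.append(Violation(sid, "unique_id_state", "(sample_id, state) pair duplicated"))
    for i, season in enumerate(f["season"]):
        if season not in SEASONS:
            v.append(Violation(ids.iloc[i], "season_vocabulary", f"unknown season {season!r}"))
    for i, state in enumerate(f["state"]):
        if state not in STATES:
            v.append(Violation(ids.iloc[i], "state_vocabulary", f"unknown state {state!r}"))
    for col in ("polyphenols", "catechins"):
        bad = ~((f[col] > 0) & (f[col] < 100))
        for sid in ids[bad]:
            v.append(Violation(sid, "chemistry_range", f"{col} outside (0, 100)"))
    finite = np.isfinite(refl).all(axis=1)
    in_range = ((refl >= 0.0) & (refl <= 1.0)).all(axis=1)
    for i in np.nonzero(~finite)[0]:
        v.append(Violation(ids.iloc[i], "reflectance_finite", "non-finite reflectance"))
    for i in np.nonzero(finite & ~in_range)[0]:
        v.append(Violation(ids.iloc[i], "reflectance_range", "reflectance outside [0, 1]"))
    return v
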