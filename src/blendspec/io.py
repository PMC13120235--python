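"""Containers and CSV interchange for IR spectra and blend compositions.

The two in-memory objects used throughout the package are :class:`SpectraSet`
(a uniform wavenumber grid plus an ``n_samples x n_channels`` absorbance
matrix) and :class:`CompositionTable` (per-sample variety percentages that sum
to 100).  Both round-trip losslessly through plain CSV files:

* spectra CSV: ``sample_id,<wavenumber>,<wavenumber>,...`` with one row per
  sample, wavenumbers in cm^-1;
* composition CSV: ``sample_id,RT2,RT3,...`` with percentages per variety.

Grids are always stored ascending; the instrument convention of displaying IR
spectra with decreasing wavenumber is purely a presentation concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Certified reference variety codes: flue-cured (RT2), oriental (RT3),
#: burley (RT4), dark air-cured (RT5, RT9) and dark fire-cured (RT10).
DEFAULT_VARIETIES = ("RT2", "RT3", "RT4", "RT5", "RT9", "RT10")

_GRID_RTOL = 1e-9
_ROWSUM_ATOL = 1e-6


class SpectraFormatError(ValueError):
    """A CSV file does not follow the expected spectra/composition layout."""


class ValidationError(ValueError):
    """A container violates one of its structural invariants."""


def _as_str_list(ids: Sequence) -> list[str]:
    return [str(i) for i in ids]


@dataclass(eq=False)
class SpectraSet:
    """A set of spectra sharing one uniform, strictly ascending wavenumber grid.

    Parameters
    ----------
    grid
        Wavenumbers in cm^-1, strictly increasing with constant spacing
        (relative tolerance 1e-9).
    absorbance
        Matrix of shape ``(n_samples, n_channels)`` in absorbance units.
    sample_ids
        Unique sample identifiers, one per row.
    meta
        Free-form metadata (e.g. the seed of a simulation run).
    """

    grid: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.sample_ids = _as_str_list(self.sample_ids)
        if self.grid.ndim != 1:
            raise ValidationError("grid must be one-dimensional")
        if self.absorbance.ndim != 2:
            raise ValidationError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if p != self.grid.size:
            raise ValidationError(
                f"absorbance has {p} channels but grid has {self.grid.size}"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} spectra"
            )
        if len(set(self.sample_ids)) != n:
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.grid.size >= 2:
            d = np.diff(self.grid)
            if np.any(d <= 0):
                raise ValidationError("grid must be strictly increasing")
            if np.any(np.abs(d - d[0]) > _GRID_RTOL * abs(d[0])):
                raise ValidationError("grid spacing is not uniform")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    @property
    def spacing(self) -> float:
        """Grid step in cm^-1 (undefined for single-channel sets)."""
        if self.grid.size < 2:
            raise ValidationError("spacing undefined for < 2 channels")
        return float(self.grid[1] - self.grid[0])

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.grid.copy(),
            self.absorbance.copy(),
            list(self.sample_ids),
            dict(self.meta),
        )

    def select(self, indices) -> "SpectraSet":
        """Row subset (by integer indices or boolean mask), order preserved."""
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectraSet(
            self.grid,
            self.absorbance[idx],
            [self.sample_ids[i] for i in idx],
            dict(self.meta),
        )


@dataclass(eq=False)
class CompositionTable:
    """Per-sample variety percentages; every row sums to 100.

    Proportions are stored exactly (e.g. ``100/3`` for a ternary blend) and
    only rounded to one decimal for display.
    """

    sample_ids: list[str]
    varieties: tuple
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _as_str_list(self.sample_ids)
        self.varieties = tuple(str(v) for v in self.varieties)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 2:
            raise ValidationError("proportions must be a 2-D matrix")
        n, k = self.proportions.shape
        if k != len(self.varieties):
            raise ValidationError(
                f"{k} proportion columns for {len(self.varieties)} varieties"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in composition table")
        neg = np.flatnonzero((self.proportions < 0).any(axis=1))
        if neg.size:
            raise ValidationError(
                f"negative proportion for sample {self.sample_ids[neg[0]]!r}"
            )
        sums = self.proportions.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 100.0) > _ROWSUM_ATOL)
        if bad.size:
            i = bad[0]
            raise ValidationError(
                f"proportions of sample {self.sample_ids[i]!r} sum to "
                f"{sums[i]!r}, expected 100"
            )

    @property
    def n_samples(self) -> int:
        return self.proportions.shape[0]

    def proportion_of(self, variety: str) -> np.ndarray:
        """Percentage vector of one variety across all samples."""
        try:
            j = self.varieties.index(variety)
        except ValueError:
            raise KeyError(f"unknown variety {variety!r}") from None
        return self.proportions[:, j]

    def select(self, indices) -> "CompositionTable":
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CompositionTable(
            [self.sample_ids[i] for i in idx],
            self.varieties,
            self.proportions[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=self.sample_ids, columns=list(self.varieties)
        )


# ----------------------------------------------------------------------
# CSV interchange (17 significant digits: lossless float round trip)

def _fmt17(x: float) -> str:
    return format(float(x), ".17g")


def read_spectra_csv(path) -> SpectraSet:
    """Read a wide-format spectra CSV (first column sample id).

    Column headers after the first must parse as wavenumbers; columns are
    reordered so the stored grid is ascending.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise SpectraFormatError(f"{path}: need a sample-id column plus channels")
    ids = df.iloc[:, 0].astype(str).tolist()
    raw_cols = list(df.columns[1:])
    grid = np.empty(len(raw_cols))
    for j, c in enumerate(raw_cols):
        try:
            grid[j] = float(c)
        except (TypeError, ValueError):
            raise SpectraFormatError(
                f"{path}: column header {c!r} is not a wavenumber"
            ) from None
    order = np.argsort(grid, kind="stable")
    values = df.iloc[:, 1:].to_numpy(dtype=float)[:, order]
    return SpectraSet(grid[order], values, ids)


def write_spectra_csv(s: SpectraSet, path) -> None:
    """Write a :class:`SpectraSet` readable back bit-exactly."""
    path = Path(path)
    header = ["sample_id"] + [_fmt17(v) for v in s.grid]
    lines = [",".join(header)]
    for i in range(s.n_samples):
        lines.append(
            ",".join([s.sample_ids[i]] + [_fmt17(v) for v in s.absorbance[i]])
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_composition_csv(path) -> CompositionTable:
    """Read a composition CSV (sample id + one percentage column per variety)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise SpectraFormatError(f"{path}: need a sample-id column plus varieties")
    ids = df.iloc[:, 0].astype(str).tolist()
    varieties = tuple(str(c) for c in df.columns[1:])
    props = df.iloc[:, 1:].to_numpy(dtype=float)
    return CompositionTable(ids, varieties, props)


def write_composition_csv(t: CompositionTable, path) -> None:
    path = Path(path)
    header = ["sample_id"] + list(t.varieties)
    lines = [",".join(header)]
    for i in range(t.n_samples):
        lines.append(
            ",".join([t.sample_ids[i]] + [_fmt17(v) for v in t.proportions[i]])
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def cut_region(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Restrict to channels with ``lo <= wavenumber <= hi`` (both inclusive).

    Used to retain the 650-2000 cm^-1 fingerprint region of mid-IR spectra;
    sample rows are never reordered or renamed.
    """
    if not lo < hi:
        raise ValidationError(f"invalid region: lo={lo} must be < hi={hi}")
    mask = (s.grid >= lo) & (s.grid <= hi)
    if not mask.any():
        raise ValidationError(f"no channels in region ({lo}, {hi})")
    return SpectraSet(
        s.grid[mask], s.absorbance[:, mask], list(s.sample_ids), dict(s.meta)
    )
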