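"""Reading, writing and harmonizing spectral tables.

Spectra are tabulated either *wide* (one row per sample, one column per
wavenumber, metadata columns first) or *long* (``sample_id, wavenumber,
value`` triples with a companion metadata table).  Internally every axis is
canonicalized to strictly increasing wavenumber (FTIR instruments export
4000 -> 650 cm^-1; Raman exports ascend), so downstream region-of-interest
cropping and peak bookkeeping never deal with orientation.

The in-memory containers are plain dataclasses over numpy arrays:

``Spectrum``
    one wavenumber axis + intensity vector + acquisition metadata.
``SpectraSet``
    a stack of spectra sharing one axis — the ``X`` matrix that the
    chemometrics layer standardizes and decomposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "Spectrum",
    "SpectraSet",
    "SpectraFormatError",
    "SpectraParseError",
    "read_spectra",
    "write_spectra",
    "harmonize_axis",
]

MODALITIES = ("raman", "ftir_alive", "ftir_dried")
PLANTS = ("basil", "mint", "other")
TREATMENTS = ("control", "cu", "fe", "zn", "other")

#: metadata columns of the wide dialect, in file order (after sample_id)
META_COLUMNS = ("plant", "treatment", "timepoint_h", "replicate_id", "acquisition_index")


class SpectraFormatError(ValueError):
    """Structural problem in a spectral table (columns, duplicates, emptiness)."""


class SpectraParseError(ValueError):
    """A cell failed to parse; the message reports row and column."""


@dataclass(frozen=True)
class SampleMeta:
    """Acquisition metadata of one spectrum.

    ``acquisition_index`` records measurement order and must be unique within
    a :class:`SpectraSet`; the sampling-design variogram lags over it.
    """

    plant: str = "other"
    treatment: str = "control"
    timepoint_h: float = 0.0
    replicate_id: str = ""
    acquisition_index: int = 0

    def __post_init__(self) -> None:
        if self.plant not in PLANTS:
            raise ValueError(f"unknown plant {self.plant!r}; expected one of {PLANTS}")
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        if self.timepoint_h < 0:
            raise ValueError("timepoint_h must be non-negative")
        if self.acquisition_index < 0:
            raise ValueError("acquisition_index must be non-negative")


@dataclass
class Spectrum:
    """One spectrum on a strictly increasing wavenumber axis."""

    axis: np.ndarray
    values: np.ndarray
    modality: str = "raman"
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis.ndim != 1 or self.values.ndim != 1:
            raise ValueError("axis and values must be 1-D")
        if self.axis.size != self.values.size:
            raise ValueError(
                f"axis length {self.axis.size} != values length {self.values.size}"
            )
        if self.axis.size == 0:
            raise ValueError("empty spectrum")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        # canonicalize: descending instrument axes are flipped on entry
        if self.axis.size > 1 and self.axis[0] > self.axis[-1]:
            self.axis = self.axis[::-1].copy()
            self.values = self.values[::-1].copy()
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly monotonic")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")

    def replace_values(self, values: np.ndarray) -> "Spectrum":
        """New spectrum with the same axis/metadata and different intensities."""
        return Spectrum(self.axis.copy(), np.asarray(values, float), self.modality, self.meta)


@dataclass
class SpectraSet:
    """Samples x wavenumbers intensity matrix on a shared axis."""

    axis: np.ndarray
    matrix: np.ndarray
    metas: list[SampleMeta]
    modality: str = "raman"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x wavenumbers)")
        if self.matrix.shape[0] < 1:
            raise ValueError("SpectraSet needs at least one sample")
        if self.matrix.shape[1] != self.axis.size:
            raise ValueError("matrix column count does not match axis length")
        if self.axis.size > 1 and self.axis[0] > self.axis[-1]:
            self.axis = self.axis[::-1].copy()
            self.matrix = self.matrix[:, ::-1].copy()
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains missing or non-finite values")
        if len(self.metas) != self.matrix.shape[0]:
            raise ValueError("one SampleMeta per row required")
        idx = [m.acquisition_index for m in self.metas]
        if len(set(idx)) != len(idx):
            raise ValueError("acquisition_index values must be unique within a set")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.sample_ids is None:
            self.sample_ids = [f"s{m.acquisition_index}" for m in self.metas]
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise ValueError("one sample_id per row required")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.axis.size

    def spectra(self) -> Iterable[Spectrum]:
        for row, meta in zip(self.matrix, self.metas):
            yield Spectrum(self.axis.copy(), row.copy(), self.modality, meta)

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis.copy(), self.matrix[i].copy(), self.modality, self.metas[i])

    def with_matrix(self, matrix: np.ndarray, axis: np.ndarray | None = None) -> "SpectraSet":
        return SpectraSet(
            self.axis.copy() if axis is None else np.asarray(axis, float),
            np.asarray(matrix, float),
            list(self.metas),
            self.modality,
            list(self.sample_ids),
        )

    def subset(self, rows: Sequence[int]) -> "SpectraSet":
        rows = list(rows)
        return SpectraSet(
            self.axis.copy(),
            self.matrix[rows].copy(),
            [self.metas[i] for i in rows],
            self.modality,
            [self.sample_ids[i] for i in rows],
        )


def _meta_to_row(meta: SampleMeta) -> dict:
    return {c: getattr(meta, c) for c in META_COLUMNS}


def _meta_from_row(row: pd.Series, where: str) -> SampleMeta:
    try:
        return SampleMeta(
            plant=str(row["plant"]),
            treatment=str(row["treatment"]),
            timepoint_h=float(row["timepoint_h"]),
            replicate_id=str(row["replicate_id"]),
            acquisition_index=int(row["acquisition_index"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SpectraParseError(f"bad metadata in {where}: {exc}") from exc


def _default_meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.csv")


def read_spectra(
    path: str | Path,
    dialect: str = "wide",
    modality: str = "raman",
    meta_path: str | Path | None = None,
) -> SpectraSet:
    """Read a delimited-text spectral table into a :class:`SpectraSet`.

    Parameters
    ----------
    path:
        CSV file.  ``wide``: header ``sample_id,<meta...>,<wn1>,<wn2>,...``.
        ``long``: header ``sample_id,wavenumber,value`` with a companion
        metadata CSV (``meta_path``, default ``<path stem>.meta.csv``).
    dialect:
        ``"wide"`` or ``"long"``.
    modality:
        instrument modality tag for the returned set.

    Descending instrument axes are flipped to ascending on ingestion.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if path.stat().st_size == 0:
        raise SpectraFormatError(f"{path} is empty")

    if dialect == "wide":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")
        if len(set(header)) != len(header):
            dups = sorted({c for c in header if header.count(c) > 1})
            raise SpectraFormatError(f"{path}: duplicate columns {dups}")
        try:
            df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
        except pd.errors.EmptyDataError as exc:
            raise SpectraFormatError(f"{path} is empty") from exc
        expected = ["sample_id", *META_COLUMNS]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise SpectraFormatError(f"{path}: missing columns {missing}")
        wn_cols = [c for c in df.columns if c not in expected]
        if not wn_cols:
            raise SpectraFormatError(f"{path}: no wavenumber columns")
        try:
            axis = np.array([float(c) for c in wn_cols])
        except ValueError as exc:
            raise SpectraFormatError(f"{path}: non-numeric wavenumber column: {exc}") from exc
        if np.unique(axis).size != axis.size:
            raise SpectraFormatError(f"{path}: duplicate wavenumber columns")
        values = np.empty((len(df), axis.size))
        for j, c in enumerate(wn_cols):
            col = pd.to_numeric(df[c], errors="coerce")
            bad = np.nonzero(col.isna().to_numpy())[0]
            if bad.size:
                raise SpectraParseError(
                    f"{path}: non-numeric value at data row {bad[0]}, column {c!r}"
                )
            values[:, j] = col.to_numpy(float)
        metas = [_meta_from_row(row, f"{path} row {i}") for i, row in df.iterrows()]
        ids = [str(s) for s in df["sample_id"]]
        return SpectraSet(axis, values, metas, modality, ids)

    # long dialect
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SpectraFormatError(f"{path} is empty") from exc
    for c in ("sample_id", "wavenumber", "value"):
        if c not in df.columns:
            raise SpectraFormatError(f"{path}: long dialect needs column {c!r}")
    mpath = Path(meta_path) if meta_path is not None else _default_meta_path(path)
    if not mpath.exists():
        raise SpectraFormatError(f"long dialect metadata table not found: {mpath}")
    mdf = pd.read_csv(mpath, keep_default_na=False).set_index("sample_id", drop=False)
    for c in ("wavenumber", "value"):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = np.nonzero(col.isna().to_numpy())[0]
        if bad.size:
            raise SpectraParseError(
                f"{path}: non-numeric value at data row {bad[0]}, column {c!r}"
            )
        df[c] = col
    pivot = df.pivot_table(index="sample_id", columns="wavenumber", values="value", sort=True)
    if pivot.isna().any().any():
        raise SpectraFormatError(f"{path}: samples do not share a complete wavenumber grid")
    ids = [str(s) for s in pivot.index]
    metas = []
    for sid in ids:
        if sid not in mdf.index:
            raise SpectraFormatError(f"{mpath}: no metadata row for sample {sid!r}")
        metas.append(_meta_from_row(mdf.loc[sid], f"{mpath} sample {sid}"))
    order = np.argsort([m.acquisition_index for m in metas])
    axis = pivot.columns.to_numpy(float)
    mat = pivot.to_numpy(float)
    return SpectraSet(
        axis,
        mat[order],
        [metas[i] for i in order],
        modality,
        [ids[i] for i in order],
    )


def write_spectra(
    sset: SpectraSet,
    path: str | Path,
    dialect: str = "wide",
    meta_path: str | Path | None = None,
) -> Path:
    """Write a :class:`SpectraSet` as CSV; ``read_spectra`` round-trips it.

    Values are written with ``repr`` precision so the round-trip is exact in
    float64.
    """
    path = Path(path)
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if sset.n_wavenumbers == 0:
        raise SpectraFormatError("cannot write a set with zero wavenumbers")

    if dialect == "wide":
        cols = {"sample_id": sset.sample_ids}
        for c in META_COLUMNS:
            cols[c] = [getattr(m, c) for m in sset.metas]
        for j, wn in enumerate(sset.axis):
            cols[repr(float(wn))] = sset.matrix[:, j]
        df = pd.DataFrame(cols)
        df.to_csv(path, index=False, float_format="%.17g")
        return path

    rows = {
        "sample_id": np.repeat(sset.sample_ids, sset.n_wavenumbers),
        "wavenumber": np.tile(sset.axis, sset.n_samples),
        "value": sset.matrix.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    mpath = Path(meta_path) if meta_path is not None else _default_meta_path(path)
    mrows = [{"sample_id": sid, **_meta_to_row(m)} for sid, m in zip(sset.sample_ids, sset.metas)]
    pd.DataFrame(mrows).to_csv(mpath, index=False)
    return path


def harmonize_axis(
    sets: Sequence[SpectraSet],
    target_axis: np.ndarray,
    method: str = "linear_interp",
) -> SpectraSet:
    """Merge sets onto one wavenumber grid by linear interpolation.

    ``target_axis`` must lie inside every input set's range; the merged set
    keeps each input's metadata (acquisition indices must remain unique
    across inputs).  When a set is already on the target grid its values
    pass through unchanged, so the operation is idempotent.
    """
    if method != "linear_interp":
        raise ValueError(f"unknown method {method!r}")
    if not sets:
        raise ValueError("no sets to harmonize")
    target = np.asarray(target_axis, dtype=float)
    if target.ndim != 1 or target.size == 0:
        raise ValueError("target_axis must be a non-empty 1-D array")
    if target.size > 1 and not np.all(np.diff(target) > 0):
        raise ValueError("target_axis must be strictly increasing")

    blocks, metas, ids = [], [], []
    for k, s in enumerate(sets):
        lo, hi = s.axis[0], s.axis[-1]
        if target[0] < lo or target[-1] > hi:
            raise ValueError(
                f"target axis [{target[0]}, {target[-1]}] outside range "
                f"[{lo}, {hi}] of set {k}"
            )
        if target.size == s.axis.size and np.array_equal(target, s.axis):
            blocks.append(s.matrix.copy())
        else:
            blocks.append(
                np.vstack([np.interp(target, s.axis, row) for row in s.matrix])
            )
        metas.extend(s.metas)
        ids.extend(s.sample_ids)
    return SpectraSet(target, np.vstack(blocks), metas, sets[0].modality, ids)
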