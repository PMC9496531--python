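"""Reading, validating, grouping and writing absorbance spectra and tables.

Spectra are two-column (wavenumber, absorbance) CSV files as exported by FTIR
instrument software. Grids may be stored ascending or descending in the file;
internally every :class:`Spectrum` is held with strictly ascending wavenumbers
so that interval bounds ``(low, high)`` are unambiguous everywhere downstream.

Replicate grouping is driven by an explicit manifest CSV
(``file,sample_id,replicate_id``) rather than filename parsing.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    InvalidSpectrumError,
    GridError,
    SchemaError,
    SpectrumParseError,
)

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_table_csv",
    "read_calibration_table",
    "read_ms_table",
    "read_manifest",
    "write_report",
]

#: Physically admissible wavenumber range (cm^-1) for mid/near-IR absorbance data.
WAVENUMBER_RANGE = (0.0, 10000.0)


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace on a strictly ascending wavenumber grid.

    Parameters
    ----------
    wavenumbers
        Grid in cm^-1. Accepted ascending or descending; stored ascending.
    absorbance
        Dimensionless absorbance, same length as ``wavenumbers``.
    sample_id, replicate_id
        Provenance labels; empty strings when unknown.
    baseline_corrected
        True once the anchored global baseline has been subtracted (or when a
        synthetic spectrum is generated directly on the blank baseline).
    was_descending
        Records whether the source file stored the grid high-to-low.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""
    replicate_id: str = ""
    baseline_corrected: bool = False
    was_descending: bool = field(default=False, compare=False)

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.size != a.size:
            raise InvalidSpectrumError(
                "wavenumbers and absorbance must be 1-D arrays of equal length"
            )
        if w.size < 2:
            raise InvalidSpectrumError(
                f"a spectrum needs at least 2 points, got {w.size}"
            )
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(a)):
            raise InvalidSpectrumError("non-finite wavenumber or absorbance value")
        lo, hi = WAVENUMBER_RANGE
        if w.min() < lo or w.max() > hi:
            raise InvalidSpectrumError(
                f"wavenumbers must lie within [{lo:g}, {hi:g}] cm^-1"
            )
        d = np.diff(w)
        descending = False
        if np.all(d > 0):
            pass
        elif np.all(d < 0):
            descending = True
            w = w[::-1].copy()
            a = a[::-1].copy()
        else:
            raise GridError("wavenumber grid is not strictly monotone")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)
        if descending:
            object.__setattr__(self, "was_descending", True)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.absorbance, other.absorbance)
            and self.sample_id == other.sample_id
            and self.replicate_id == other.replicate_id
            and self.baseline_corrected == other.baseline_corrected
        )

    @property
    def span(self) -> tuple[float, float]:
        """(min, max) wavenumber of the grid."""
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def with_absorbance(self, absorbance: np.ndarray, **changes) -> "Spectrum":
        """Return a copy with new absorbance values (and optional field changes)."""
        return replace(self, absorbance=np.asarray(absorbance, dtype=float), **changes)


@dataclass
class SpectrumSet:
    """A collection of spectra with sample/replicate grouping."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def add(self, spectrum: Spectrum) -> None:
        self.spectra.append(spectrum)

    def groups(self) -> dict[str, list[Spectrum]]:
        """Mapping sample_id -> replicate spectra, keys sorted."""
        out: dict[str, list[Spectrum]] = {}
        for s in self.spectra:
            out.setdefault(s.sample_id, []).append(s)
        return {k: out[k] for k in sorted(out)}

    def sample_ids(self) -> list[str]:
        return sorted({s.sample_id for s in self.spectra})


def _detect_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        for cand in ("\t", ";", ","):
            if cand in sample:
                return cand
        return ","


def read_spectrum_csv(
    path,
    *,
    sample_id: str = "",
    replicate_id: str = "",
    delimiter: str | None = None,
) -> Spectrum:
    """Read a two-column wavenumber/absorbance CSV into a :class:`Spectrum`.

    The delimiter (comma, semicolon or tab) is auto-detected unless given, and
    a single non-numeric header line is tolerated. Non-numeric cells elsewhere
    raise :class:`SpectrumParseError` naming the 1-based line number.
    """
    with open(path, "r", newline="", encoding="utf-8-sig") as fh:
        text = fh.read()
    if not text.strip():
        raise InvalidSpectrumError(f"{path}: empty spectrum file")
    if delimiter is None:
        delimiter = _detect_delimiter(text[:2048])

    wavenumbers: list[float] = []
    absorbance: list[float] = []
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    for lineno, row in enumerate(reader, start=1):
        cells = [c.strip() for c in row if c.strip() != ""]
        if not cells:
            continue
        if len(cells) < 2:
            raise SpectrumParseError(
                f"{path}: line {lineno}: expected 2 columns, got {len(cells)}",
                line_number=lineno,
            )
        try:
            w, a = float(cells[0]), float(cells[1])
        except ValueError:
            if lineno == 1 and not wavenumbers:
                continue  # header line
            raise SpectrumParseError(
                f"{path}: line {lineno}: non-numeric value in {cells[:2]!r}",
                line_number=lineno,
            ) from None
        wavenumbers.append(w)
        absorbance.append(a)

    if len(wavenumbers) < 2:
        raise InvalidSpectrumError(
            f"{path}: fewer than 2 data points ({len(wavenumbers)})"
        )
    return Spectrum(
        np.array(wavenumbers), np.array(absorbance),
        sample_id=sample_id, replicate_id=replicate_id,
    )


def write_spectrum_csv(spectrum: Spectrum, path, *, header: bool = True) -> None:
    """Write a spectrum as two-column CSV (ascending grid, 12 significant digits)."""
    df = pd.DataFrame(
        {"wavenumber": spectrum.wavenumbers, "absorbance": spectrum.absorbance}
    )
    df.to_csv(path, index=False, header=header, float_format="%.12g")


def read_table_csv(
    path,
    *,
    id_column: str,
    value_column: str,
    allow_duplicate_ids: bool = True,
    non_negative: bool = False,
) -> pd.DataFrame:
    """Read a generic (id, value) table with schema checks.

    Returns a DataFrame with the two requested columns, value coerced to float.
    """
    df = pd.read_csv(path)
    for col in (id_column, value_column):
        if col not in df.columns:
            raise SchemaError(
                f"{path}: missing required column {col!r}; found {list(df.columns)}"
            )
    out = df[[id_column, value_column]].copy()
    try:
        out[value_column] = out[value_column].astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-numeric value in column {value_column!r}") from exc
    if not allow_duplicate_ids and out[id_column].duplicated().any():
        dups = sorted(out.loc[out[id_column].duplicated(), id_column].unique())
        raise DomainError(f"{path}: duplicate ids not allowed: {dups}")
    if non_negative and (out[value_column] < 0).any():
        bad = out.loc[out[value_column] < 0, value_column].iloc[0]
        raise DomainError(f"{path}: negative value {bad!r} in column {value_column!r}")
    return out


def read_calibration_table(path, *, file_column: str = "file",
                           mass_column: str = "mass_ng") -> pd.DataFrame:
    """Calibration table: spectrum file (or precomputed AUC) vs. known mass in ng.

    Duplicate files/ids are allowed (replicate calibration points); negative
    masses are rejected.
    """
    return read_table_csv(
        path, id_column=file_column, value_column=mass_column,
        allow_duplicate_ids=True, non_negative=True,
    )


def read_ms_table(path, *, id_column: str = "sample_id",
                  value_column: str = "total_intensity") -> pd.DataFrame:
    """MS total-intensity table; one row per sample (duplicates rejected)."""
    return read_table_csv(
        path, id_column=id_column, value_column=value_column,
        allow_duplicate_ids=False, non_negative=True,
    )


def read_manifest(path) -> pd.DataFrame:
    """Sample manifest mapping spectrum files to sample/replicate ids.

    An optional boolean ``baseline_corrected`` column records whether the
    files hold already-corrected spectra (CSV itself carries no flags).
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"file", "sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: manifest missing columns {sorted(missing)}")
    if "replicate_id" not in df.columns:
        df["replicate_id"] = ""
    cols = ["file", "sample_id", "replicate_id"]
    if "baseline_corrected" in df.columns:
        df["baseline_corrected"] = (
            df["baseline_corrected"].str.strip().str.lower().isin(("true", "1", "yes"))
        )
        cols.append("baseline_corrected")
    return df[cols]


def write_report(records, path) -> None:
    """Write QC/quantification records to CSV with a deterministic column order.

    ``records`` is a non-empty DataFrame or list of dicts. Floats are written
    with 12 significant digits so the file round-trips through
    :func:`read_table_csv` within formatting precision.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        raise DomainError("refusing to write an empty report")
    df.to_csv(path, index=False, float_format="%.12g")
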