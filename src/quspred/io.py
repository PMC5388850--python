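"""On-disk formats: RF frame archives, label tables, feature tables.

RF frames are stored as a single-file NumPy ``.npz`` archive with named
arrays — ``rf`` (axial samples x scan lines) plus the scalars ``fs_hz``,
``pitch_mm``, ``c_m_s`` and ``axial_origin_mm``.  Label and feature tables
are plain CSV with the column dictionaries documented below.
"""

from __future__ import annotations

import os
import zipfile
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import FormatError, RFFrame

_RF_REQUIRED = ("rf", "fs_hz", "pitch_mm", "c_m_s")

#: Columns every label table must provide.
LABEL_COLUMNS = (
    "patient_id",
    "response_gp",
    "response_ci",
    "er",
    "pr",
    "her2",
    "rfs_months",
    "event",
)


def write_rf(frame: RFFrame, path: str | os.PathLike) -> None:
    """Write an RF frame to a named-array archive (uncompressed ``.npz``)."""
    np.savez(
        path,
        rf=frame.samples,
        fs_hz=np.float64(frame.sampling_rate_hz),
        pitch_mm=np.float64(frame.line_pitch_mm),
        c_m_s=np.float64(frame.speed_of_sound_m_s),
        axial_origin_mm=np.float64(frame.axial_origin_mm),
    )


def read_rf(path: str | os.PathLike) -> RFFrame:
    """Read an RF frame archive, validating the documented layout."""
    try:
        with np.load(path) as archive:
            missing = [k for k in _RF_REQUIRED if k not in archive.files]
            if missing:
                raise FormatError(f"RF archive {path} missing field(s): {', '.join(missing)}")
            origin = float(archive["axial_origin_mm"]) if "axial_origin_mm" in archive.files else 0.0
            return RFFrame(
                samples=archive["rf"],
                sampling_rate_hz=float(archive["fs_hz"]),
                line_pitch_mm=float(archive["pitch_mm"]),
                speed_of_sound_m_s=float(archive["c_m_s"]),
                axial_origin_mm=origin,
            )
    except (OSError, ValueError, zipfile.BadZipFile) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"cannot read RF archive {path}: {exc}") from exc


def _normalize_categorical(series: pd.Series, allowed: Iterable[str], column: str) -> pd.Series:
    lowered = series.astype(str).str.strip().str.lower()
    bad = ~lowered.isin(list(allowed))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"column {column!r}, row {row}: unknown value {series.iloc[row]!r} "
            f"(expected one of {sorted(allowed)})"
        )
    return lowered


def _normalize_marker(series: pd.Series, column: str) -> pd.Series:
    """ER/PR/HER2 status: 0/1, or NA for unavailable assays."""
    as_str = series.astype(str).str.strip().str.lower()
    na = as_str.isin(["na", "nan", "", "none"]) | series.isna()
    out = pd.Series(np.nan, index=series.index, dtype=float)
    valid = ~na
    if valid.any():
        numeric = pd.to_numeric(as_str[valid], errors="coerce")
        bad = numeric.isna() | ~numeric.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"column {column!r}: marker values must be 0, 1 or NA")
        out[valid] = numeric
    return out


def read_labels(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a per-patient label table.

    Expected CSV columns: ``patient_id``; ``response_gp`` in {good, poor};
    ``response_ci`` in {complete, incomplete}; ``er``, ``pr``, ``her2`` in
    {0, 1, NA}; ``rfs_months`` >= 0; ``event`` in {0, 1}.  Categorical
    values are case-insensitive and normalized to lower case.
    """
    table = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"label table missing column(s): {', '.join(missing)}")
    if table["patient_id"].duplicated().any():
        dup = table.loc[table["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient_id {dup!r}")
    table = table.copy()
    table["response_gp"] = _normalize_categorical(table["response_gp"], {"good", "poor"}, "response_gp")
    table["response_ci"] = _normalize_categorical(
        table["response_ci"], {"complete", "incomplete"}, "response_ci"
    )
    for marker in ("er", "pr", "her2"):
        table[marker] = _normalize_marker(table[marker], marker)
    months = pd.to_numeric(table["rfs_months"], errors="coerce")
    if months.isna().any() or (months < 0).any():
        row = int(np.flatnonzero((months.isna() | (months < 0)).to_numpy())[0])
        raise ValueError(f"column 'rfs_months', row {row}: must be a number >= 0")
    table["rfs_months"] = months
    event = pd.to_numeric(table["event"], errors="coerce")
    if event.isna().any() or ~event.isin([0, 1]).all():
        raise ValueError("column 'event' must be 0 or 1")
    table["event"] = event.astype(int)
    return table


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a patients x features table to CSV (index = patient_id)."""
    table.to_csv(path, index_label="patient_id")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    table = pd.read_csv(path, index_col="patient_id")
    if table.index.duplicated().any():
        raise ValueError("duplicate patient_id in feature table")
    return table
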