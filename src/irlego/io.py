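"""Readers and writers for the pipeline's table, spectrum and field formats.

Tables travel as TSV/CSV with a header (delimiter auto-detected), spectra
as two-column text (wavelength_nm, intensity), calibrations and estimates
as JSON, and 3D temperature fields as .npy arrays with a JSON sidecar
recording grids, units and ambient temperature.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .heat import TemperatureField
from .thermometry import EmissionSpectrum

__all__ = [
    "SchemaError",
    "read_table",
    "read_cohort",
    "write_cohort",
    "read_spectrum",
    "write_spectrum",
    "write_field",
    "read_field",
    "COHORT_SCHEMA",
]


class SchemaError(ValueError):
    """A table failed schema validation; the message names column and row."""


def _detect_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_table(
    path,
    schema: Mapping[str, Callable[[object], bool]],
    required: bool = True,
) -> pd.DataFrame:
    """Read a delimited table and validate it column by column.

    ``schema`` maps column names to per-cell validators returning True for
    acceptable values.  Missing columns and failing cells raise
    :class:`SchemaError` naming the column and the (1-based, header
    excluded) row of the first offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    for col, check in schema.items():
        if col not in df.columns:
            if required:
                raise SchemaError(f"missing required column {col!r} in {path}")
            continue
        for i, value in enumerate(df[col]):
            if not check(value):
                raise SchemaError(
                    f"invalid value {value!r} in column {col!r} at row {i + 1} of {path}"
                )
    return df


def _nonneg_int(v) -> bool:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return False
    return f == int(f) and f >= 0


COHORT_SCHEMA: dict[str, Callable[[object], bool]] = {
    "id": lambda v: isinstance(v, str) and len(v) > 0 or not pd.isna(v),
    "group": lambda v: v in ("labeled", "control"),
    "t_count": _nonneg_int,
    "m_count": _nonneg_int,
}


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table (id, group, t_count, m_count)."""
    df = read_table(path, COHORT_SCHEMA)
    df["t_count"] = df["t_count"].astype(int)
    df["m_count"] = df["m_count"].astype(int)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_spectrum(path, label: str | None = None) -> EmissionSpectrum:
    """Read a two-column (wavelength_nm, intensity) spectrum file."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    if not {"wavelength_nm", "intensity"} <= set(df.columns):
        raise SchemaError(f"{path} must have columns wavelength_nm and intensity")
    return EmissionSpectrum(
        df["wavelength_nm"].to_numpy(float),
        df["intensity"].to_numpy(float),
        label=label or path.stem,
    )


def write_spectrum(spectrum: EmissionSpectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
    ).to_csv(path, sep="\t", index=False)


def write_field(field: TemperatureField, path_stem) -> tuple[Path, Path]:
    """Write a temperature field as <stem>.npy plus a <stem>.json sidecar."""
    stem = Path(path_stem)
    npy_path = stem.with_suffix(".npy")
    json_path = stem.with_suffix(".json")
    np.save(npy_path, field.temperature)
    sidecar = {
        "units": {"coordinates": "um", "temperature": "degC", "time": "s"},
        "x": field.x.tolist(),
        "y": field.y.tolist(),
        "z": field.z.tolist(),
        "time": field.time,
        "ambient": field.ambient,
        "focal_position": list(field.focal_position),
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh)
    return npy_path, json_path


def read_field(path_stem) -> TemperatureField:
    stem = Path(path_stem)
    temperature = np.load(stem.with_suffix(".npy"))
    with open(stem.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return TemperatureField(
        np.asarray(meta["x"], float),
        np.asarray(meta["y"], float),
        np.asarray(meta["z"], float),
        temperature,
        meta["time"],
        meta["ambient"],
        tuple(meta["focal_position"]),
    )
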