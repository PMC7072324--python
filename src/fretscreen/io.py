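"""Readers and writers for the package's small tabular file dialects.

Spectra, titrations and decay curves travel as two-column CSV/TSV with a
header (``wavelength_nm,intensity``; ``conc_M,intensity``;
``time_ns,counts``); docking scores as ``model_id,score`` CSV. Delimiters
are sniffed from the extension (.tsv → tab, otherwise comma).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .photophysics import DecayCurve, EmissionSpectrum, QuenchTitration

__all__ = [
    "read_spectrum_csv",
    "read_titration_csv",
    "read_decay_csv",
    "read_scores_csv",
    "write_titration_csv",
    "write_decay_csv",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def _require_columns(df: pd.DataFrame, columns: tuple, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_spectrum_csv(path: str | Path, excitation_wavelength: float = 295.0,
                      label: str = "") -> EmissionSpectrum:
    df = _read_table(path)
    _require_columns(df, ("wavelength_nm", "intensity"), path)
    return EmissionSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
        excitation_wavelength=excitation_wavelength,
        label=label or Path(path).stem,
    )


def read_titration_csv(path: str | Path,
                       analysis_wavelength: float = 346.0) -> QuenchTitration:
    df = _read_table(path)
    _require_columns(df, ("conc_M", "intensity"), path)
    return QuenchTitration(
        quencher_concentrations=df["conc_M"].to_numpy(float),
        peak_intensities=df["intensity"].to_numpy(float),
        analysis_wavelength=analysis_wavelength,
    )


def read_decay_csv(path: str | Path, peak_target_counts: int = 10000) -> DecayCurve:
    df = _read_table(path)
    _require_columns(df, ("time_ns", "counts"), path)
    return DecayCurve(
        times=df["time_ns"].to_numpy(float),
        counts=df["counts"].to_numpy(float),
        peak_target_counts=peak_target_counts,
    )


def read_scores_csv(path: str | Path) -> dict[str, float]:
    """Docking scores keyed by model id (lower = better)."""
    df = _read_table(path)
    _require_columns(df, ("model_id", "score"), path)
    if df["model_id"].duplicated().any():
        dupes = df["model_id"][df["model_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate model id(s) {dupes}")
    return dict(zip(df["model_id"].astype(str), df["score"].astype(float)))


def write_titration_csv(titration: QuenchTitration, path: str | Path) -> None:
    pd.DataFrame({
        "conc_M": titration.quencher_concentrations,
        "intensity": titration.peak_intensities,
    }).to_csv(path, index=False)


def write_decay_csv(decay: DecayCurve, path: str | Path) -> None:
    pd.DataFrame({"time_ns": decay.times, "counts": decay.counts}).to_csv(
        path, index=False)
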