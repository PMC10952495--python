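"""CSV readers and writers for the measurement formats the pipeline consumes.

All files are plain UTF-8 CSV with '.' decimal separators and a header row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinetics import RateTable, TempRateSeries
from .melt import MeltCurve
from .spectra import EmissionSpectrum

__all__ = [
    "spectra_to_frame",
    "spectra_from_frame",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_melt_csv",
    "read_rate_table_csv",
    "read_temp_series_csv",
]


def spectra_to_frame(spectra: list[EmissionSpectrum]) -> pd.DataFrame:
    """Long format: excitation_nm, emission_nm, intensity, replicate."""
    rows = []
    for s in spectra:
        rows.append(pd.DataFrame({
            "excitation_nm": s.excitation_wavelength,
            "emission_nm": s.emission_wavelengths,
            "intensity": s.intensities,
            "replicate": s.replicate_id if s.replicate_id is not None else "0",
        }))
    return pd.concat(rows, ignore_index=True)


def spectra_from_frame(df: pd.DataFrame) -> list[EmissionSpectrum]:
    required = {"excitation_nm", "emission_nm", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    if "replicate" not in df.columns:
        df = df.assign(replicate="0")
    spectra = []
    for (ex, rep), grp in df.groupby(["excitation_nm", "replicate"], sort=True):
        grp = grp.sort_values("emission_nm")
        spectra.append(EmissionSpectrum(
            excitation_wavelength=float(ex),
            emission_wavelengths=grp["emission_nm"].to_numpy(float),
            intensities=grp["intensity"].to_numpy(float),
            replicate_id=str(rep),
        ))
    return spectra


def read_spectra_csv(path) -> list[EmissionSpectrum]:
    return spectra_from_frame(pd.read_csv(path))


def write_spectra_csv(spectra: list[EmissionSpectrum], path) -> None:
    spectra_to_frame(spectra).to_csv(path, index=False)


def read_melt_csv(path) -> MeltCurve:
    """Columns: temperature, signal, optional units ('K' or 'C'; Celsius is
    converted to Kelvin)."""
    df = pd.read_csv(path)
    if not {"temperature", "signal"} <= set(df.columns):
        raise ValueError("melt CSV needs 'temperature' and 'signal' columns")
    t = df["temperature"].to_numpy(float)
    if "units" in df.columns and str(df["units"].iloc[0]).upper().startswith("C"):
        t = t + 273.15
    return MeltCurve(t, df["signal"].to_numpy(float))


def read_rate_table_csv(path, enzyme_M: float | None = None) -> RateTable:
    """Columns: substrate_mM plus either rate_s or dA450_per_min (the latter
    requires ``enzyme_M`` for conversion)."""
    from .kinetics import rate_from_absorbance

    df = pd.read_csv(path)
    if "substrate_mM" not in df.columns:
        raise ValueError("rate CSV needs a 'substrate_mM' column")
    if "rate_s" in df.columns:
        rates = df["rate_s"].to_numpy(float)
    elif "dA450_per_min" in df.columns:
        if enzyme_M is None:
            raise ValueError("absorbance slopes need an enzyme concentration")
        rates = np.array([
            rate_from_absorbance(s, enzyme_M) for s in df["dA450_per_min"]
        ])
    else:
        raise ValueError("rate CSV needs 'rate_s' or 'dA450_per_min'")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return RateTable(df["substrate_mM"].to_numpy(float), rates, rep)


def read_temp_series_csv(path) -> TempRateSeries:
    df = pd.read_csv(path)
    if not {"temperature_K", "kcat_s"} <= set(df.columns):
        raise ValueError("series CSV needs 'temperature_K' and 'kcat_s' columns")
    return TempRateSeries(df["temperature_K"].to_numpy(float),
                          df["kcat_s"].to_numpy(float))
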