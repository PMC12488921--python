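"""CSV readers/writers for the pipeline's tabular artifacts.

CSV is the interchange format for everything tabular (instrument exports
are CSV-like); JSON is used for fit reports and run configuration, and
FASTA only for sequences.  Headers are matched case-insensitively and
schema violations are reported with the offending column names.  Time
columns may be declared in hours (``time_h``) and are converted to
seconds on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin, kelvin_to_celsius
from .errors import SchemaError
from .hydrodynamics import FusedDistribution, SedimentationDistribution
from .kinetics import SizeTimeSeries
from .mass_photometry import MassHistogram
from .synthetic import MPEventSet, RefractometrySeries


def read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    """Read a CSV with case-insensitive header validation.

    Raises SchemaError naming any required column that is missing.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c.lower() not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    bad_rows = df[df[[c.lower() for c in required]].isna().any(axis=1)]
    if len(bad_rows):
        raise SchemaError(
            f"{path.name}: malformed rows at lines {list(bad_rows.index + 2)}"
        )
    return df


# --- events ---

def write_events(events: MPEventSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "event_id": np.arange(len(events.measured_mass)),
            "mass_kda": events.measured_mass,
        }
    )
    if events.true_N is not None:
        df["true_n"] = events.true_N
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> MPEventSet:
    df = read_table(path, ["event_id", "mass_kda"])
    true_n = df["true_n"].to_numpy() if "true_n" in df.columns else None
    return MPEventSet(measured_mass=df["mass_kda"].to_numpy(), true_N=true_n)


# --- histograms ---

def write_histogram(hist: MassHistogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_center_kda": hist.bin_centers,
            "count": hist.counts,
            "weighting": hist.weighting,
            "monomer_mass_kda": hist.monomer_mass,
        }
    ).to_csv(path, index=False)


def read_histogram(path: str | Path) -> MassHistogram:
    df = read_table(path, ["bin_center_kda", "count", "weighting"])
    centers = df["bin_center_kda"].to_numpy(dtype=float)
    widths = np.diff(centers)
    if centers.size > 1 and not np.allclose(widths, widths[0]):
        raise SchemaError(f"{Path(path).name}: bins are not uniform")
    width = widths[0] if centers.size > 1 else centers[0] or 1.0
    edges = np.concatenate([centers - width / 2.0, [centers[-1] + width / 2.0]])
    weighting = str(df["weighting"].iloc[0])
    monomer = (
        float(df["monomer_mass_kda"].iloc[0])
        if "monomer_mass_kda" in df.columns
        else width
    )
    return MassHistogram(
        bin_edges=edges,
        counts=df["count"].to_numpy(dtype=float),
        weighting=weighting,
        monomer_mass=monomer,
    )


# --- sedimentation distributions ---

def write_sedimentation(dist: SedimentationDistribution, path: str | Path) -> None:
    pd.DataFrame(
        {
            "s_svedberg": dist.s_values,
            "amplitude": dist.amplitudes,
            "temperature_c": kelvin_to_celsius(dist.temperature),
            "corrected": dist.corrected_to_20C,
        }
    ).to_csv(path, index=False)


def read_sedimentation(path: str | Path) -> SedimentationDistribution:
    df = read_table(path, ["s_svedberg", "amplitude", "temperature_c"])
    corrected = bool(df["corrected"].iloc[0]) if "corrected" in df.columns else False
    return SedimentationDistribution(
        s_values=df["s_svedberg"].to_numpy(dtype=float),
        amplitudes=df["amplitude"].to_numpy(dtype=float),
        temperature=celsius_to_kelvin(float(df["temperature_c"].iloc[0])),
        corrected_to_20C=corrected,
    )


# --- time series ---

def write_series(series_list: list[SizeTimeSeries], path: str | Path) -> None:
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.times,
                    "value": s.values,
                    "sd": s.sd if s.sd is not None else np.nan,
                    "temperature_c": kelvin_to_celsius(s.temperature),
                    "replicate": s.replicate_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_series(path: str | Path) -> list[SizeTimeSeries]:
    """Read dissociation series; a ``time_h`` column is converted to seconds."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "time_h" in df.columns and "time_s" not in df.columns:
        df["time_s"] = df["time_h"] * 3600.0
    missing = [c for c in ("time_s", "value", "temperature_c", "replicate") if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing required columns {missing}")
    out = []
    for (t_c, rep), grp in df.groupby(["temperature_c", "replicate"], sort=True):
        grp = grp.sort_values("time_s")
        sd = grp["sd"].to_numpy(dtype=float) if "sd" in grp.columns else None
        if sd is not None and np.all(np.isnan(sd)):
            sd = None
        out.append(
            SizeTimeSeries(
                times=grp["time_s"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
                sd=sd,
                temperature=celsius_to_kelvin(float(t_c)),
                replicate_id=int(rep),
            )
        )
    return out


# --- refractometry ---

def write_refractometry(series: RefractometrySeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "conc_mg_ml": series.concentrations,
            "refractive_index": series.n_values,
            "wavelength_nm": series.wavelength_nm,
        }
    ).to_csv(path, index=False)


def read_refractometry(path: str | Path) -> RefractometrySeries:
    df = read_table(path, ["conc_mg_ml", "refractive_index"])
    wavelength = (
        float(df["wavelength_nm"].iloc[0]) if "wavelength_nm" in df.columns else 546.0
    )
    return RefractometrySeries(
        concentrations=df["conc_mg_ml"].to_numpy(dtype=float),
        n_values=df["refractive_index"].to_numpy(dtype=float),
        wavelength_nm=wavelength,
    )


# --- fused output ---

def write_fused(fused: FusedDistribution, path: str | Path) -> None:
    fused.to_frame().to_csv(path, index=False)
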