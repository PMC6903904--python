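"""Plain-text file formats for FIDs, spectra, timecourses and results.

FIDs are stored as two-column text (real, imaginary) with a JSON
metadata sidecar; spectra as (ppm, intensity) columns; labeling data as
a tidy CSV with one row per (sample, time, metabolite, fragment,
mass shift); results as one-row-per-animal CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .isotopomer_model import IsotopomerTimecourse
from .nmr_processing import FidRecord, Spectrum
from .saturation_transfer import InversionRecoverySeries, SaturationTransferResult
from .synthetic_data import STDataset

__all__ = [
    "write_fid",
    "read_fid",
    "write_spectrum",
    "read_spectrum",
    "write_st_dataset",
    "read_st_dataset",
    "labeling_to_frame",
    "write_labeling_csv",
    "read_labeling_csv",
    "peak_fits_to_frame",
    "st_results_to_frame",
]

LABELING_COLUMNS = [
    "sample_id", "group", "time_s", "metabolite", "fragment",
    "mass_shift", "fraction", "sd",
]


def write_fid(fid: FidRecord, path) -> None:
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([fid.samples.real, fid.samples.imag]),
        header="real imaginary",
    )
    sidecar = {
        "dwell_time": fid.dwell_time,
        "spectrometer_freq": fid.spectrometer_freq,
        "metadata": fid.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_fid(path) -> FidRecord:
    path = Path(path)
    data = np.loadtxt(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FidRecord(
        samples=data[:, 0] + 1j * data[:, 1],
        dwell_time=meta["dwell_time"],
        spectrometer_freq=meta["spectrometer_freq"],
        metadata=meta.get("metadata", {}),
    )


def write_spectrum(spec: Spectrum, path) -> None:
    np.savetxt(
        path,
        np.column_stack([spec.axis, spec.intensity]),
        header=f"ppm intensity reference_freq={spec.reference_freq}",
    )


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    ref = float(header.rsplit("reference_freq=", 1)[1])
    data = np.loadtxt(path)
    return Spectrum(axis=data[:, 0], intensity=data[:, 1], reference_freq=ref)


def write_st_dataset(ds: STDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fid(ds.control_fid, out / "control.fid")
    write_fid(ds.saturated_fid, out / "saturated.fid")
    write_fid(ds.mirror_fid, out / "mirror.fid")
    rows = []
    for label, series in ds.ir.items():
        for t, m in zip(series.inv_times, series.magnetization):
            rows.append((label, float(t), float(m)))
    pd.DataFrame(rows, columns=["resonance", "inv_time_s", "magnetization"]).to_csv(
        out / "inversion_recovery.csv", index=False
    )
    (out / "meta.json").write_text(json.dumps({"atp_conc": ds.atp_conc}, indent=1))


def read_st_dataset(in_dir) -> STDataset:
    src = Path(in_dir)
    ir_df = pd.read_csv(src / "inversion_recovery.csv")
    ir = {
        label: InversionRecoverySeries(
            inv_times=g["inv_time_s"].to_numpy(),
            magnetization=g["magnetization"].to_numpy(),
            resonance_label=label,
        )
        for label, g in ir_df.groupby("resonance")
    }
    meta = json.loads((src / "meta.json").read_text())
    return STDataset(
        control_fid=read_fid(src / "control.fid"),
        saturated_fid=read_fid(src / "saturated.fid"),
        mirror_fid=read_fid(src / "mirror.fid"),
        ir=ir,
        atp_conc=meta["atp_conc"],
    )


def labeling_to_frame(
    tc: IsotopomerTimecourse,
    sample_id: str = "S01",
    group: str = "C",
    sd: float = 0.0,
) -> pd.DataFrame:
    df = tc.to_frame()
    df.insert(0, "sample_id", sample_id)
    df.insert(1, "group", group)
    df["sd"] = sd
    return df[LABELING_COLUMNS]


def write_labeling_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_labeling_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LABELING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"labeling CSV missing columns: {sorted(missing)}")
    return df


def peak_fits_to_frame(fits) -> pd.DataFrame:
    """One row per fitted peak (centre, height, FWHM, shape, area)."""
    return pd.DataFrame(
        [
            {
                "label": f.label,
                "center_ppm": f.center,
                "amplitude": f.amplitude,
                "fwhm_hz": f.fwhm,
                "gauss_fraction": f.gauss_fraction,
                "area": f.area,
                "converged": f.converged,
            }
            for f in fits
        ]
    )


def st_results_to_frame(
    results: dict[str, SaturationTransferResult]
) -> pd.DataFrame:
    rows = [
        {
            "animal_id": animal,
            "dM_frac": r.dM_frac,
            "T1app": r.T1app,
            "T1_intrinsic": r.T1_intrinsic,
            "kf": r.kf,
            "Pi_conc": r.Pi_conc,
            "atp_flux": r.atp_flux,
            "qc_flags": "; ".join(r.qc_flags),
        }
        for animal, r in results.items()
    ]
    return pd.DataFrame(rows)
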