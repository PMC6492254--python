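"""Serialization helpers: signal CSV schema, estimate JSON, NIfTI maps, configs.

The signal CSV schema (version 1) is shared by the simulator output and the
fitting input:

    seq_type, flip_deg, tr_s, phase_inc_rad, b1rms_uT, re, im

Angles are degrees and B1rms is µT at this boundary; everything is SI inside
the library.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .relaxometry import MeasurementSet, RelaxometryResults

__all__ = [
    "CSV_SCHEMA_VERSION",
    "write_signals_csv",
    "read_signals_csv",
    "write_estimate_json",
    "write_nifti",
    "read_nifti",
]

CSV_SCHEMA_VERSION = 1


def write_signals_csv(ms: MeasurementSet, path: str | Path) -> None:
    """Write a measurement set in the versioned signal CSV schema."""
    f = ms.frame
    sig = f["signal"].to_numpy(dtype=complex)
    b1 = (
        f["b1rms_T"].to_numpy(dtype=float) * 1e6
        if "b1rms_T" in f.columns
        else np.full(len(f), np.nan)
    )
    out = pd.DataFrame(
        {
            "seq_type": f["seq_type"],
            "flip_deg": np.degrees(f["flip_rad"].to_numpy(dtype=float)),
            "tr_s": f["tr_s"],
            "phase_inc_rad": f["phase_inc_rad"],
            "b1rms_uT": b1,
            "re": sig.real,
            "im": sig.imag,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# csmt-signals schema v{CSV_SCHEMA_VERSION}\n")
        out.to_csv(fh, index=False, lineterminator="\n")


def read_signals_csv(path: str | Path) -> MeasurementSet:
    """Read a signal CSV back into a :class:`MeasurementSet`."""
    frame = pd.read_csv(path, comment="#")
    needed = {"seq_type", "flip_deg", "tr_s", "phase_inc_rad", "re", "im"}
    missing = needed - set(frame.columns)
    if missing:
        raise ValueError(f"signal CSV missing columns: {sorted(missing)}")
    ms_frame = pd.DataFrame(
        {
            "seq_type": frame["seq_type"],
            "flip_rad": np.radians(frame["flip_deg"].to_numpy(dtype=float)),
            "tr_s": frame["tr_s"],
            "phase_inc_rad": frame["phase_inc_rad"],
            "signal": frame["re"].to_numpy(dtype=float)
            + 1j * frame["im"].to_numpy(dtype=float),
        }
    )
    ms = MeasurementSet(ms_frame)
    if "b1rms_uT" in frame.columns:
        ms.frame["b1rms_T"] = frame["b1rms_uT"].to_numpy(dtype=float) * 1e-6
    return ms


def write_estimate_json(result: RelaxometryResults, path: str | Path) -> None:
    """Write a fit result as JSON (times in seconds, angles in radians)."""
    d = result.to_dict()
    for k, v in list(d.items()):
        if isinstance(v, float) and math.isnan(v):
            d[k] = None
    Path(path).write_text(json.dumps(d, indent=2, default=float) + "\n")


def write_nifti(
    data: np.ndarray, path: str | Path, description: str = ""
) -> None:
    """Write an array as NIfTI with unit metadata in the header description."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4))
    img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> np.ndarray:
    """Load a NIfTI volume as a float array."""
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata())
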