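"""HDF5/CSV persistence for volumes, ground truth, curves and maps.

Volume container layout::

    /frames/<k>/re, /frames/<k>/im     float arrays (z, x, y)
    /frames/<k>  attrs: timestamp [s], dropout flag
    root attrs: delta, pitch_x, pitch_y [m], wavelength [m]
    /ground_truth/U, /ground_truth/eps, /ground_truth/anterior_px, ...

A JSON sidecar (``<file>.json``) records the phantom config and scenario
for provenance.  Complex data are stored as paired real arrays for the
broadest reader compatibility.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .phantom import DeformationScenario, GroundTruth, PhantomConfig
from .timeseries import DepthTimeMap, StrainCurve
from .volume import ComplexVolume

__all__ = [
    "save_volumes",
    "load_volumes",
    "curve_to_frame",
    "save_curves",
    "load_curves",
    "save_depth_time_map",
    "export_tiff",
]


def export_tiff(path: str | Path, array: np.ndarray) -> None:
    """Write a structural-amplitude or strain map as a float32 TIFF.

    Inspection convenience; requires the optional ``tifffile`` dependency.
    """
    import tifffile

    tifffile.imwrite(str(path), np.asarray(array, dtype=np.float32))


def save_volumes(
    path: str | Path,
    frames: Sequence[ComplexVolume],
    ground_truth: GroundTruth | None = None,
    config: PhantomConfig | None = None,
    scenario: DeformationScenario | None = None,
    wavelength: float = 877.8e-9,
) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        v0 = frames[0]
        f.attrs["delta"] = v0.delta
        f.attrs["pitch_x"] = v0.pitch_x
        f.attrs["pitch_y"] = v0.pitch_y
        f.attrs["wavelength"] = wavelength
        grp = f.create_group("frames")
        for k, vol in enumerate(frames):
            g = grp.create_group(str(k))
            g.create_dataset("re", data=vol.data.real.astype(np.float32))
            g.create_dataset("im", data=vol.data.imag.astype(np.float32))
            g.attrs["timestamp"] = vol.timestamp
            g.attrs["dropout"] = bool(vol.meta.get("dropout", False))
        if ground_truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("U", data=ground_truth.U.astype(np.float32))
            g.create_dataset("eps", data=ground_truth.eps.astype(np.float32))
            g.create_dataset("anterior_px", data=ground_truth.anterior_px)
            g.create_dataset("posterior_px", data=ground_truth.posterior_px)
            g.create_dataset("dropout_frames", data=np.asarray(ground_truth.dropout_frames, dtype=int))
            if ground_truth.times_min is not None:
                g.create_dataset("times_min", data=ground_truth.times_min)
    sidecar = {}
    if config is not None:
        sidecar["config"] = {
            k: (None if isinstance(v, float) and math.isinf(v) else v)
            for k, v in dataclasses.asdict(config).items()
        }
    if scenario is not None:
        sidecar["scenario"] = {
            "name": scenario.name,
            "duration": scenario.duration,
            "frame_interval": scenario.frame_interval,
            "onset_time": scenario.onset_time,
            "affected_depth": scenario.affected_depth,
            "dropout_period": scenario.dropout_period,
            "dropout_duration": scenario.dropout_duration,
        }
    if sidecar:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_volumes(path: str | Path) -> tuple[list[ComplexVolume], GroundTruth | None]:
    path = Path(path)
    frames: list[ComplexVolume] = []
    gt = None
    with h5py.File(path, "r") as f:
        delta = float(f.attrs["delta"])
        px = float(f.attrs["pitch_x"])
        py = float(f.attrs["pitch_y"])
        keys = sorted(f["frames"].keys(), key=int)
        for k in keys:
            g = f["frames"][k]
            data = g["re"][()].astype(np.float64) + 1j * g["im"][()].astype(np.float64)
            meta = {"frame": int(k)}
            if g.attrs.get("dropout", False):
                meta["dropout"] = True
            frames.append(
                ComplexVolume(
                    data=data,
                    delta=delta,
                    pitch_x=px,
                    pitch_y=py,
                    timestamp=float(g.attrs["timestamp"]),
                    meta=meta,
                )
            )
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = GroundTruth(
                U=g["U"][()].astype(np.float64),
                eps=g["eps"][()].astype(np.float64),
                anterior_px=g["anterior_px"][()],
                posterior_px=g["posterior_px"][()],
                dropout_frames=list(map(int, g["dropout_frames"][()])),
                times_min=g["times_min"][()] if "times_min" in g else None,
            )
    return frames, gt


def curve_to_frame(curve: StrainCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_min": curve.t,
            "cum_strain_pct": curve.cum_strain,
            "increment": curve.increments,
            "valid": curve.valid.astype(int),
            "label": curve.label,
        }
    )


def save_curves(path: str | Path, curves: Sequence[StrainCurve]) -> None:
    pd.concat([curve_to_frame(c) for c in curves], ignore_index=True).to_csv(
        path, index=False, float_format="%.8g"
    )


def load_curves(path: str | Path) -> list[StrainCurve]:
    df = pd.read_csv(path)
    out = []
    for label, grp in df.groupby("label", sort=False):
        out.append(
            StrainCurve(
                t=grp["t_min"].to_numpy(),
                cum_strain=grp["cum_strain_pct"].to_numpy(),
                increments=grp["increment"].to_numpy(),
                valid=grp["valid"].to_numpy().astype(bool),
                label=str(label),
            )
        )
    return out


def save_depth_time_map(path: str | Path, dtm: DepthTimeMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("M", data=dtm.M.filled(np.nan))
        f.create_dataset("mask", data=np.ma.getmaskarray(dtm.M))
        f.create_dataset("t_min", data=dtm.t)
        f.create_dataset("z_px", data=dtm.z_px)
        f.attrs["label"] = dtm.label
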