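"""Cumulative regional strain curves and depth–time strain maps.

Axial deformation is computed incrementally between consecutive C-scans;
per pair, the strain map is averaged over a regional mask (spatial first),
and the regional increments are then accumulated over time (plain running
sum — per-pair strains are a few per-mille at most, so compounding error is
second order).  Pairs involving a quality-flagged frame contribute zero and
are flagged, mirroring the gaps visible when fluid application destroys the
phase correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import RegionSpec, SurfaceModel, UndefinedRegionError, region_mean
from .strain import strain_from_pair
from .volume import ComplexVolume, ProcessingParams, StrainMap

__all__ = [
    "StrainCurve",
    "DepthTimeMap",
    "incremental_strain_series",
    "accumulate",
    "depth_time_map",
    "difference_curve",
    "regional_curve",
]


@dataclass
class StrainCurve:
    """Cumulative regional axial strain (%) vs time (minutes).

    ``increments`` are the per-pair regional mean strains (dimensionless);
    ``cum_strain[k] = 100 · Σ_{i≤k, valid} increments[i]``.  Invalid pairs
    contribute zero and are flagged in ``valid``.
    """

    t: np.ndarray
    cum_strain: np.ndarray
    increments: np.ndarray
    valid: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        n = len(self.t)
        if not (len(self.cum_strain) == len(self.increments) == len(self.valid) == n):
            raise ValueError("curve fields must be aligned")


@dataclass
class DepthTimeMap:
    """Laterally averaged strain indexed (z, frame pair); masked where invalid."""

    M: np.ma.MaskedArray
    t: np.ndarray
    z_px: np.ndarray
    label: str = ""


def incremental_strain_series(
    frames: Sequence[ComplexVolume],
    params: ProcessingParams,
    tissue: np.ndarray | None = None,
    min_valid_fraction: float = 0.5,
) -> list[StrainMap]:
    """One StrainMap per consecutive frame pair, quality-flagged.

    ``tissue`` (boolean, volume grid) scopes the quality statistics; when
    None it is taken from the first frame's metadata if the phantom put it
    there, else the whole frame is used.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    ts = np.array([f.timestamp for f in frames], dtype=float)
    if np.any(np.diff(ts) <= 0):
        raise ValueError("frame timestamps must be strictly increasing")
    if tissue is None:
        tissue = frames[0].meta.get("tissue_mask")
    return [
        strain_from_pair(frames[k], frames[k + 1], params, tissue, min_valid_fraction)
        for k in range(len(frames) - 1)
    ]


def accumulate(
    increments: Sequence[float],
    valid: Sequence[bool],
    times_min: Sequence[float],
    label: str = "",
) -> StrainCurve:
    """Running sum of valid regional strain increments, in percent."""
    inc = np.asarray(increments, dtype=float)
    val = np.asarray(valid, dtype=bool)
    t = np.asarray(times_min, dtype=float)
    if not (len(inc) == len(val) == len(t)):
        raise ValueError("increments, valid flags and times must be aligned")
    cum = 100.0 * np.cumsum(np.where(val, inc, 0.0))
    return StrainCurve(t=t, cum_strain=cum, increments=inc, valid=val, label=label)


def regional_curve(
    strains: Sequence[StrainMap],
    surf: SurfaceModel,
    spec: RegionSpec,
    pitch_x_um: float,
    pitch_y_um: float,
    label: str = "",
) -> StrainCurve:
    """Regional mean per pair, then temporal accumulation (%)."""
    incs, flags, times = [], [], []
    for smap in strains:
        ok = smap.frame_valid
        value = 0.0
        if ok:
            try:
                value, _ = region_mean(smap, surf, spec, pitch_x_um, pitch_y_um)
            except UndefinedRegionError:
                ok = False
        incs.append(value)
        flags.append(ok)
        times.append(smap.t_mid / 60.0)
    return accumulate(incs, flags, times, label=label)


def depth_time_map(
    strains: Sequence[StrainMap],
    surf: SurfaceModel,
    lateral_window_um: float = 448.0,
    pitch_x_um: float = 12.0,
    label: str = "",
) -> DepthTimeMap:
    """Strain vs (depth, time) over the central A-scans of the central B-scan.

    Invalid pairs appear as fully masked columns (the vertical stripes seen
    when fluid application interrupts the phase correlation).
    """
    if len(strains) == 0:
        raise ValueError("empty strain series")
    n_z, n_x, n_y = strains[0].eps_zz.shape
    iy = n_y // 2
    centers = (np.arange(n_x) - (n_x - 1) / 2.0) * pitch_x_um
    xw = np.abs(centers) <= lateral_window_um / 2.0 + 1e-9
    if not xw.any():
        xw[n_x // 2] = True
    cols, times = [], []
    for smap in strains:
        eps = smap.eps_zz[:, xw, iy]
        msk = smap.mask[:, xw, iy]
        if not smap.frame_valid:
            col = np.ma.masked_all(n_z)
        else:
            cnt = msk.sum(axis=1)
            s = np.where(msk, eps, 0.0).sum(axis=1)
            col = np.ma.masked_array(
                np.divide(s, cnt, out=np.zeros(n_z), where=cnt > 0), mask=cnt == 0
            )
        cols.append(col)
        times.append(smap.t_mid / 60.0)
    M = np.ma.stack(cols, axis=1)
    return DepthTimeMap(M=M, t=np.asarray(times), z_px=np.arange(n_z), label=label)


def difference_curve(a: StrainCurve, b: StrainCurve) -> StrainCurve:
    """Pointwise a − b after linear resampling onto a common time grid.

    Used to isolate a treatment effect by subtracting a control group's
    cumulative strain from the treated group's.  The common grid is the
    union of both curves' times restricted to their overlap; a point is
    valid when the nearest source point of each curve is valid.
    """
    lo = max(a.t.min(), b.t.min())
    hi = min(a.t.max(), b.t.max())
    if lo >= hi:
        raise ValueError("curves have disjoint time ranges")
    t = np.union1d(a.t, b.t)
    t = t[(t >= lo) & (t <= hi)]
    ca = np.interp(t, a.t, a.cum_strain)
    cb = np.interp(t, b.t, b.cum_strain)

    def nearest_valid(curve: StrainCurve) -> np.ndarray:
        idx = np.clip(np.searchsorted(curve.t, t), 0, len(curve.t) - 1)
        idx_lo = np.clip(idx - 1, 0, len(curve.t) - 1)
        nearer = np.where(
            np.abs(curve.t[idx] - t) <= np.abs(t - curve.t[idx_lo]), idx, idx_lo
        )
        return curve.valid[nearer]

    valid = nearest_valid(a) & nearest_valid(b)
    diff = ca - cb
    inc = np.empty_like(diff)
    inc[0] = diff[0] / 100.0
    inc[1:] = np.diff(diff) / 100.0
    return StrainCurve(
        t=t,
        cum_strain=diff,
        increments=inc,
        valid=valid,
        label=f"{a.label}-{b.label}" if a.label or b.label else "difference",
    )
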