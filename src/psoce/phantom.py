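"""Synthetic complex OCT C-scans of a curved two-surface cornea phantom.

The phantom emulates what the strain estimator sees in the osmotic-swelling
and cross-linking experiments: a corneal band between an anterior and a
posterior surface filled with fully developed speckle (randomly placed point
scatterers convolved with a Gaussian PSF, giving circular-Gaussian complex
statistics), imaged repeatedly while a prescribed depth- and time-dependent
axial strain field deforms it.  Deformation is imposed in phase space — each
voxel is multiplied by exp(i·4πn·U/λ_mean), the exact signal the
phase-sensitive estimator inverts — optionally with physical resampling of
the speckle pattern to emulate decorrelation.

Every simulation returns a :class:`GroundTruth` with the exact displacement
and incremental strain fields so downstream estimates can be validated
without real data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .volume import ComplexVolume, ProcessingParams

__all__ = [
    "PhantomConfig",
    "DeformationScenario",
    "GroundTruth",
    "make_cornea_phantom",
    "apply_axial_displacement",
    "simulate_timeseries",
]

_UM = 1e-6

SCENARIO_NAMES = (
    "isotonic",
    "hypotonic_swelling",
    "hypertonic_deswelling",
    "control_swelling",
    "cxl",
)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, sampling and noise of the simulated C-scans.

    Lengths are in micrometres.  Defaults mirror the imaging conditions of
    the corneal experiments (δ = 4.48 µm axial sampling in tissue, 12 µm
    A-scan pitch, ~1 mm thick curved cornea); reduced sizes are routinely
    used in tests and simulations for speed.

    ``scatterer_density`` is the mean number of point scatterers per voxel;
    a value of 0 requests a deterministic uniform-amplitude band instead of
    speckle (useful for exact closed-form checks).  ``snr_db`` is the
    amplitude SNR of additive circular-Gaussian noise relative to the
    in-tissue RMS amplitude (``inf`` ⇒ noise-free).  ``decorrelation`` is
    the std (rad) of fresh per-voxel phase noise added to every frame.
    """

    n_z: int = 300
    n_x: int = 256
    n_y: int = 3
    delta: float = 4.48
    pitch_x: float = 12.0
    pitch_y: float = 120.0
    anterior_apex_depth: float = 150.0
    corneal_thickness: float = 1000.0
    curvature_radius: float = math.inf
    scatterer_density: float = 2.0
    snr_db: float = 30.0
    decorrelation: float = 0.02
    seed: int = 0
    psf_sigma_z: float = 0.7
    psf_sigma_x: float = 0.7

    def __post_init__(self) -> None:
        if min(self.n_z, self.n_x, self.n_y) < 1:
            raise ValueError("volume dimensions must be positive")
        if not (self.delta > 0 and self.pitch_x > 0 and self.pitch_y > 0):
            raise ValueError("pixel pitches must be positive")
        if self.n_z * self.delta < self.anterior_apex_depth + self.corneal_thickness:
            raise ValueError(
                "cornea does not fit in the frame: "
                f"n_z*delta = {self.n_z * self.delta:.0f} µm < apex depth + thickness "
                f"= {self.anterior_apex_depth + self.corneal_thickness:.0f} µm"
            )
        if math.isnan(self.snr_db):
            raise ValueError("snr_db must be finite or +inf")
        if self.decorrelation < 0:
            raise ValueError("decorrelation must be >= 0")
        if self.scatterer_density < 0:
            raise ValueError("scatterer_density must be >= 0")

    # -- geometry -----------------------------------------------------------
    def surfaces_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Anterior/posterior surface depth (µm) per lateral position (x, y)."""
        x = (np.arange(self.n_x) - (self.n_x - 1) / 2.0) * self.pitch_x
        y = (np.arange(self.n_y) - (self.n_y - 1) / 2.0) * self.pitch_y
        r2 = x[:, None] ** 2 + y[None, :] ** 2
        if math.isinf(self.curvature_radius):
            sag = np.zeros_like(r2)
        else:
            R = self.curvature_radius
            if r2.max() >= R**2:
                raise ValueError("lateral extent exceeds the curvature radius")
            sag = R - np.sqrt(R**2 - r2)
        ant = self.anterior_apex_depth + sag
        return ant, ant + self.corneal_thickness

    def surfaces_px(self) -> tuple[np.ndarray, np.ndarray]:
        ant, post = self.surfaces_um()
        return ant / self.delta, post / self.delta

    def tissue_mask(self) -> np.ndarray:
        """Boolean (z, x, y) mask of voxels whose center lies inside the cornea."""
        ant_px, post_px = self.surfaces_px()
        z = np.arange(self.n_z)[:, None, None]
        return (z >= ant_px[None]) & (z < post_px[None])


@dataclass
class DeformationScenario:
    """Prescribed spatio-temporal axial strain-rate field.

    ``rate_profile(d, t)`` returns the axial strain rate (fraction per
    minute) at normalized stromal depth ``d`` ∈ [0, 1] (0 = anterior
    surface) and time ``t`` minutes; it must accept numpy arrays of ``d``.
    ``dropout_period`` > 0 schedules ``dropout_duration`` phase-randomized
    frames every period, emulating the periodic loss of phase data caused by
    fluid application during treatment.
    """

    name: str
    duration: float  # minutes
    frame_interval: float  # seconds
    rate_profile: Callable[[np.ndarray, float], np.ndarray]
    onset_time: float = 0.0  # minutes (cxl only)
    affected_depth: float = 0.0  # µm (cxl only)
    dropout_period: float = 0.0  # minutes; 0 = no dropout
    dropout_duration: int = 1  # frames
    dropout_start: float = 0.0  # minutes; fluid applications begin here
    dropout_end: float | None = None  # minutes; None = end of experiment

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if self.onset_time >= self.duration and self.onset_time > 0:
            raise ValueError("onset_time must precede the end of the experiment")
        probe = np.asarray(self.rate_profile(np.linspace(0, 1, 5), 0.0), dtype=float)
        if not np.all(np.isfinite(probe)):
            raise ValueError("rate_profile must return finite values")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration * 60.0 / self.frame_interval)) + 1

    def frame_times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval / 60.0

    def dropout_frames(self) -> list[int]:
        if self.dropout_period <= 0:
            return []
        times = self.frame_times_min()
        end = self.duration if self.dropout_end is None else self.dropout_end
        out: list[int] = []
        m = 1
        while True:
            t_m = self.dropout_start + m * self.dropout_period
            if t_m > end:
                break
            k0 = int(np.argmin(np.abs(times - t_m)))
            out.extend(range(k0, min(k0 + self.dropout_duration, len(times))))
            m += 1
        return sorted(set(out))


@dataclass
class GroundTruth:
    """Exact displacement/strain fields of a simulated time series.

    ``U`` [n_frames, n_z, n_x, n_y] is the cumulative axial displacement in
    metres (positive toward greater depth, posterior surface anchored);
    ``eps`` [n_frames-1, n_z-1, n_x, n_y] the incremental strain of each
    consecutive pair on the strain grid (row i = between axial samples i and
    i+1), so that ``diff(U, axis=z)/δ`` equals ``eps`` exactly.
    """

    U: np.ndarray
    eps: np.ndarray
    anterior_px: np.ndarray  # [n_frames, n_x, n_y]
    posterior_px: np.ndarray
    dropout_frames: list[int] = field(default_factory=list)
    times_min: np.ndarray | None = None

    def cumulative_strain(self, frame: int) -> np.ndarray:
        """Cumulative true strain field up to ``frame`` on the strain grid."""
        return self.eps[:frame].sum(axis=0)


# ---------------------------------------------------------------------------


def _speckle_field(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Complex scatterer field inside the corneal band (no additive noise)."""
    tissue = config.tissue_mask()
    if config.scatterer_density == 0:
        return tissue.astype(np.complex128)
    n_scat = int(round(config.scatterer_density * tissue.size))
    pos = rng.random((3, n_scat)) * np.array(
        [[config.n_z], [config.n_x], [config.n_y]], dtype=float
    )
    idx = tuple(pos.astype(np.intp))
    phases = rng.uniform(-np.pi, np.pi, n_scat)
    fld = np.zeros(tissue.shape, dtype=np.complex128)
    np.add.at(fld, idx, np.exp(1j * phases))
    fld[~tissue] = 0.0
    if config.psf_sigma_z > 0 or config.psf_sigma_x > 0:
        sig = (config.psf_sigma_z, config.psf_sigma_x, 0.0)
        fld = ndimage.gaussian_filter(fld.real, sig) + 1j * ndimage.gaussian_filter(
            fld.imag, sig
        )
        fld[~tissue] = 0.0  # PSF tails must not leak outside the band
    return fld


def _additive_noise(
    config: PhantomConfig, signal_rms: float, rng: np.random.Generator
) -> np.ndarray:
    if math.isinf(config.snr_db):
        return np.zeros((config.n_z, config.n_x, config.n_y), dtype=np.complex128)
    noise_rms = signal_rms * 10.0 ** (-config.snr_db / 20.0)
    s = noise_rms / math.sqrt(2.0)
    shape = (config.n_z, config.n_x, config.n_y)
    return s * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))


def make_cornea_phantom(config: PhantomConfig, rng: np.random.Generator | None = None) -> ComplexVolume:
    """One static C-scan of the two-surface cornea phantom.

    Deterministic for a fixed ``config.seed``.  The returned volume's
    ``meta`` holds the exact anterior/posterior surface indices (pixels) and
    the tissue mask used to build it.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fld = _speckle_field(config, rng)
    tissue = config.tissue_mask()
    amp = np.abs(fld[tissue])
    signal_rms = float(np.sqrt(np.mean(amp**2))) if amp.size else 0.0
    fld = fld + _additive_noise(config, signal_rms, rng)
    ant_px, post_px = config.surfaces_px()
    return ComplexVolume(
        data=fld,
        delta=config.delta * _UM,
        pitch_x=config.pitch_x * _UM,
        pitch_y=config.pitch_y * _UM,
        timestamp=0.0,
        meta={
            "anterior_px": ant_px,
            "posterior_px": post_px,
            "tissue_mask": tissue,
            "signal_rms": signal_rms,
        },
    )


def apply_axial_displacement(
    vol: ComplexVolume,
    U: np.ndarray,
    params: ProcessingParams,
    mode: str = "phase_only",
) -> ComplexVolume:
    """Impose an axial displacement field ``U`` (metres) on a volume.

    ``phase_only`` multiplies each voxel by exp(i·4πn·U/λ_mean) — exactly
    the signal the phase estimator inverts — preserving amplitude.
    ``resample`` additionally shifts the speckle pattern axially by U/δ
    pixels (linear interpolation), introducing genuine decorrelation.

    A displacement magnitude beyond the wrap-free bound λ/(4n) is legal but
    recorded as ``meta['wrap_warning']``.
    """
    if mode not in ("phase_only", "resample"):
        raise ValueError("mode must be 'phase_only' or 'resample'")
    U = np.broadcast_to(np.asarray(U, dtype=float), vol.shape)
    if not np.all(np.isfinite(U)):
        raise ValueError("displacement field must be finite")
    phase = 4.0 * np.pi * params.n_refr * U / params.lambda_mean
    if mode == "resample":
        z, x, y = np.meshgrid(
            np.arange(vol.shape[0], dtype=float),
            np.arange(vol.shape[1], dtype=float),
            np.arange(vol.shape[2], dtype=float),
            indexing="ij",
        )
        coords = np.stack([z - U / vol.delta, x, y])
        data = ndimage.map_coordinates(
            vol.data.real, coords, order=1, mode="constant", cval=0.0
        ) + 1j * ndimage.map_coordinates(
            vol.data.imag, coords, order=1, mode="constant", cval=0.0
        )
        data = data * np.exp(1j * phase)
    else:
        data = vol.data * np.exp(1j * phase)
    meta = dict(vol.meta)
    if np.abs(U).max() > params.displacement_bound:
        meta["wrap_warning"] = True
    return ComplexVolume(
        data=data,
        delta=vol.delta,
        pitch_x=vol.pitch_x,
        pitch_y=vol.pitch_y,
        timestamp=vol.timestamp,
        meta=meta,
    )


def _rate_increment(
    scenario: DeformationScenario,
    d: np.ndarray,
    t0: float,
    t1: float,
    n_sub: int = 4,
) -> np.ndarray:
    """∫_{t0}^{t1} rate(d, τ) dτ by midpoint sub-sampling (fraction units)."""
    dt = (t1 - t0) / n_sub
    acc = np.zeros_like(d, dtype=float)
    for i in range(n_sub):
        tm = t0 + (i + 0.5) * dt
        acc += np.asarray(scenario.rate_profile(d, tm), dtype=float) * dt
    return acc


def simulate_timeseries(
    config: PhantomConfig,
    scenario: DeformationScenario,
    params: ProcessingParams | None = None,
    mode: str = "phase_only",
) -> tuple[list[ComplexVolume], GroundTruth]:
    """Full time series of C-scans under a deformation scenario.

    Frame ``k`` is acquired at ``t_k = k·frame_interval``; its displacement
    field integrates the scenario's strain-rate profile over [0, t_k] at
    each voxel's normalized stromal depth, anchored at the posterior
    surface (swelling pushes the anterior surface toward the probe).
    Dropout frames keep their amplitude but have their phase randomized.
    """
    if params is None:
        params = ProcessingParams(delta=config.delta * _UM)
    rng = np.random.default_rng(config.seed)
    base = make_cornea_phantom(config, rng)
    tissue = base.meta["tissue_mask"]
    ant_px, post_px = config.surfaces_px()
    delta_m = config.delta * _UM

    # normalized stromal depth per voxel (clipped; only in-tissue used)
    z = np.arange(config.n_z, dtype=float)[:, None, None]
    d = np.clip((z - ant_px[None]) / (post_px - ant_px)[None], 0.0, 1.0)

    times = scenario.frame_times_min()
    n_frames = len(times)
    dropouts = set(scenario.dropout_frames())

    shape = (config.n_z, config.n_x, config.n_y)
    U = np.zeros((n_frames,) + shape)
    eps_pairs = np.zeros((n_frames - 1, config.n_z - 1, config.n_x, config.n_y))
    ant_frames = np.zeros((n_frames, config.n_x, config.n_y))
    post_frames = np.zeros_like(ant_frames)

    eps_cum = np.zeros(shape)
    signal_rms = base.meta["signal_rms"]
    frames: list[ComplexVolume] = []
    wrap_frames: list[int] = []

    for k in range(n_frames):
        if k > 0:
            inc = _rate_increment(scenario, d, times[k - 1], times[k])
            inc[~tissue] = 0.0
            eps_cum = eps_cum + inc
            eps_pairs[k - 1] = inc[:-1]
        # posterior-anchored displacement: U(z) = -δ·Σ_{z'>=z} ε(z')
        U_k = -delta_m * np.cumsum(eps_cum[::-1], axis=0)[::-1]
        U[k] = U_k
        if k > 0 and np.abs(U[k] - U[k - 1]).max() > params.displacement_bound:
            wrap_frames.append(k)
        ant_frames[k] = ant_px + U_k[np.clip(ant_px.astype(int), 0, config.n_z - 1),
                                     np.arange(config.n_x)[:, None],
                                     np.arange(config.n_y)[None, :]] / delta_m
        post_frames[k] = post_px

        vol = ComplexVolume(
            data=base.data.copy(),
            delta=base.delta,
            pitch_x=base.pitch_x,
            pitch_y=base.pitch_y,
            timestamp=times[k] * 60.0,
            meta={"frame": k, "anterior_px": ant_px, "posterior_px": post_px,
                  "tissue_mask": tissue},
        )
        vol = apply_axial_displacement(vol, U_k, params, mode=mode)
        vol.timestamp = times[k] * 60.0
        if scenario.name:
            vol.meta["scenario"] = scenario.name
        if config.decorrelation > 0:
            vol.data = vol.data * np.exp(
                1j * rng.normal(0.0, config.decorrelation, shape)
            )
        vol.data = vol.data + _additive_noise(config, signal_rms, rng)
        if k in dropouts:
            vol.data = np.abs(vol.data) * np.exp(
                1j * rng.uniform(-np.pi, np.pi, shape)
            )
            vol.meta["dropout"] = True
        frames.append(vol)

    if wrap_frames:
        shown = wrap_frames[:5]
        suffix = "..." if len(wrap_frames) > 5 else ""
        warnings.warn(
            f"per-pair displacement exceeds the wrap-free bound λ/(4n) at "
            f"{len(wrap_frames)} frames (e.g. {shown}{suffix}); the displacement map "
            "wraps there but strain stays unambiguous while |ε| < λ/(4nδ)",
            RuntimeWarning,
            stacklevel=2,
        )
        for k in wrap_frames:
            frames[k].meta["wrap_warning"] = True

    gt = GroundTruth(
        U=U,
        eps=eps_pairs,
        anterior_px=ant_frames,
        posterior_px=post_frames,
        dropout_frames=sorted(dropouts),
        times_min=times,
    )
    return frames, gt
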