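"""Core data containers for phase-sensitive OCE processing.

A C-scan is stored as a 3-D complex field indexed ``(z, x, y)``: ``z`` is the
axial (depth) index with 0 at the shallowest optical depth, ``x`` the A-scan
index within a B-scan, and ``y`` the B-scan index.  Physical pitches are kept
in metres on the containers; phantom configuration uses micrometres (the
field's customary unit) and converts on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ProcessingParams",
    "ComplexVolume",
    "ComplexMap",
    "DisplacementMap",
    "StrainMap",
]


@dataclass(frozen=True)
class ProcessingParams:
    """Physical and window constants of the phase-sensitive strain estimator.

    Parameters
    ----------
    lambda_mean : float
        Central wavelength of the OCT source in metres.
    n_refr : float
        Group refractive index of the tissue (dimensionless).
    delta : float
        Axial sampling unit *in tissue*, metres per pixel.
    w_z, w_x : int
        Half-widths (pixels) of the phase-processing window applied in the
        axial and lateral (within-B-scan) directions; the full window spans
        ``2*w + 1`` pixels.
    amp_threshold : float
        Relative amplitude floor used by the validity mask: positions whose
        structural amplitude falls below ``amp_threshold`` times the median
        in-tissue amplitude are masked.
    coherence_threshold : float
        Minimum windowed complex-correlation magnitude for a position to be
        considered phase-stable between two frames.
    """

    lambda_mean: float = 877.8e-9
    n_refr: float = 1.375
    delta: float = 4.48e-6
    w_z: int = 3
    w_x: int = 3
    amp_threshold: float = 0.1
    coherence_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not self.lambda_mean > 0:
            raise ValueError("lambda_mean must be positive")
        if not self.n_refr >= 1:
            raise ValueError("n_refr must be >= 1")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.w_z < 0 or self.w_x < 0 or int(self.w_z) != self.w_z or int(self.w_x) != self.w_x:
            raise ValueError("w_z and w_x must be non-negative integers")
        if not 0 <= self.amp_threshold < 1:
            raise ValueError("amp_threshold must lie in [0, 1)")

    @property
    def displacement_bound(self) -> float:
        """Largest unambiguous per-pair axial displacement, λ/(4n), metres."""
        return self.lambda_mean / (4.0 * self.n_refr)

    @property
    def strain_bound(self) -> float:
        """Largest unambiguous per-pair axial strain, λ/(4nδ), dimensionless."""
        return self.lambda_mean / (4.0 * self.n_refr * self.delta)

    def phase_per_strain(self) -> float:
        """Phase-ramp slope (rad/pixel) produced by unit axial strain."""
        return 4.0 * np.pi * self.n_refr * self.delta / self.lambda_mean


@dataclass
class ComplexVolume:
    """One complex OCT C-scan with its physical grid and timestamp.

    ``data`` is complex, indexed ``(z, x, y)``; ``delta`` (axial) and
    ``pitch_x``/``pitch_y`` (lateral) are in metres; ``timestamp`` in seconds
    since the start of the experiment.  ``meta`` carries non-essential
    annotations (e.g. phase-wrap warnings recorded by the phantom).
    """

    data: np.ndarray
    delta: float
    pitch_x: float
    pitch_y: float
    timestamp: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ComplexVolume.data must be 3-D (z, x, y)")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if not (self.delta > 0 and self.pitch_x > 0 and self.pitch_y > 0):
            raise ValueError("pixel pitches must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    def same_grid(self, other: "ComplexVolume") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.delta, other.delta)
            and np.isclose(self.pitch_x, other.pitch_x)
            and np.isclose(self.pitch_y, other.pitch_y)
        )


@dataclass
class ComplexMap:
    """A complex field derived from one or two volumes.

    ``kind`` is ``"W"`` for the self-normalized inter-frame cross-correlation
    (unit modulus wherever valid) or ``"R"`` for the axial-gradient
    correlation.  ``valid`` marks positions where the windowed sum had
    non-negligible modulus.
    """

    data: np.ndarray
    kind: Literal["W", "R"]
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("W", "R"):
            raise ValueError("kind must be 'W' or 'R'")
        if self.data.shape != self.valid.shape:
            raise ValueError("data and valid must share a shape")


@dataclass
class DisplacementMap:
    """Per-voxel axial displacement (metres) between two frames, with mask."""

    U: np.ndarray
    mask: np.ndarray


@dataclass
class StrainMap:
    """Per-voxel incremental axial strain (dimensionless), with mask.

    The strain grid has one axial row fewer than its source volumes: row ``i``
    is the strain between axial samples ``i`` and ``i+1``.  ``frame_valid``
    records whether the whole frame pair passed quality control; invalid
    pairs are excluded from temporal accumulation.
    """

    eps_zz: np.ndarray
    mask: np.ndarray
    frame_valid: bool = True
    t_mid: float = 0.0
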