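"""Phase-sensitive displacement and axial-strain estimation.

The estimator compares two consecutive complex OCT C-scans.  An
amplitude-weighted complex cross-correlation over a small (2·w_z+1) ×
(2·w_x+1) window,

    W(z, x, y) = Σ_j Σ_k  C2(z+j, x+k, y) · C1*(z+j, x+k, y) ,

normalized by its own modulus, carries the inter-frame phase shift; the axial
displacement follows as U = λ_mean·∠W / (4πn).  A second windowed
correlation between axially adjacent rows of W,

    R(z, x, y) = Σ_j Σ_k  W(z+1+j, x+k, y) · W*(z+j, x+k, y) ,

carries the axial phase gradient, and the axial strain is
ε_zz = dU/dz = λ_mean·∠R / (4πnδ).

Sign convention: the conjugation order above is fixed so that a voxel whose
phase advances by φ between frames reads back ∠W = +φ, and axial expansion
(dU/dz > 0, tissue swelling) yields positive ε_zz.

Windows are truncated at array borders (sums run over in-bounds indices
only); where the windowed sum has negligible modulus the output is set to 0
and flagged invalid rather than normalized.  No phase unwrapping is
performed: per-pair displacements are unambiguous only within ±λ/(4n) and
strains within ±λ/(4nδ); values beyond alias to their wrapped counterparts.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import ComplexMap, ComplexVolume, DisplacementMap, ProcessingParams, StrainMap

__all__ = [
    "complex_cross_correlation",
    "displacement_map",
    "strain_correlation",
    "axial_strain_map",
    "quality_mask",
    "strain_from_pair",
    "interior_tissue_mask",
]

# Modulus floor (relative to the largest windowed sum) below which a
# normalized correlation is considered undefined.
_REL_FLOOR = 1e-15


def _windowed_sum(field: np.ndarray, w_z: int, w_x: int) -> np.ndarray:
    """Truncated-border windowed sum over (z, x) per B-scan."""
    kernel = np.ones((2 * w_z + 1, 2 * w_x + 1, 1))
    if np.iscomplexobj(field):
        re = ndimage.correlate(field.real, kernel, mode="constant", cval=0.0)
        im = ndimage.correlate(field.imag, kernel, mode="constant", cval=0.0)
        return re + 1j * im
    return ndimage.correlate(field, kernel, mode="constant", cval=0.0)


def _normalize(s: np.ndarray, kind: str) -> ComplexMap:
    mag = np.abs(s)
    floor = _REL_FLOOR * mag.max() if mag.size and mag.max() > 0 else np.inf
    valid = mag > floor
    out = np.zeros_like(s)
    np.divide(s, mag, out=out, where=valid)
    return ComplexMap(data=out, kind=kind, valid=valid)


def complex_cross_correlation(
    C1: ComplexVolume, C2: ComplexVolume, params: ProcessingParams
) -> ComplexMap:
    """Self-normalized windowed cross-correlation W between two C-scans.

    ∠W is the amplitude-weighted inter-frame phase shift; |W| = 1 wherever
    the windowed sum is non-negligible, 0 (flagged invalid) elsewhere.
    """
    if C1.shape != C2.shape:
        raise ValueError(f"shape mismatch: {C1.shape} vs {C2.shape}")
    prod = C2.data * np.conj(C1.data)
    s = _windowed_sum(prod, params.w_z, params.w_x)
    m = _normalize(s, "W")
    return m


def displacement_map(W: ComplexMap, params: ProcessingParams) -> DisplacementMap:
    """Axial displacement U = λ_mean·∠W/(4πn), metres; mask from W validity."""
    if W.kind != "W":
        raise ValueError("displacement_map expects a kind-'W' map")
    U = params.lambda_mean * np.angle(W.data) / (4.0 * np.pi * params.n_refr)
    return DisplacementMap(U=U, mask=W.valid.copy())


def strain_correlation(W: ComplexMap, params: ProcessingParams) -> ComplexMap:
    """Second correlation R between axially adjacent rows of W.

    The output grid has one axial row fewer than W: row ``i`` correlates
    rows ``i`` and ``i+1``.  Invalid W positions are zero and so contribute
    nothing to the windowed sums.
    """
    if W.kind != "W":
        raise ValueError("strain_correlation expects a kind-'W' map")
    n_z = W.data.shape[0]
    if n_z < 2 * params.w_z + 2:
        raise ValueError(
            f"need at least {2 * params.w_z + 2} axial samples for the strain window, got {n_z}"
        )
    pair = W.data[1:] * np.conj(W.data[:-1])
    s = _windowed_sum(pair, params.w_z, params.w_x)
    return _normalize(s, "R")


def axial_strain_map(R: ComplexMap, params: ProcessingParams) -> StrainMap:
    """Axial strain ε_zz = λ_mean·∠R/(4πnδ); positive = axial expansion."""
    if R.kind != "R":
        raise ValueError("axial_strain_map expects a kind-'R' map")
    eps = params.lambda_mean * np.angle(R.data) / (4.0 * np.pi * params.n_refr * params.delta)
    return StrainMap(eps_zz=eps, mask=R.valid.copy())


def interior_tissue_mask(tissue: np.ndarray, params: ProcessingParams) -> np.ndarray:
    """Strain-grid rows whose full processing support lies inside tissue.

    The two stacked windows (W then R) reach 2·w_z+1 axial and 2·w_x lateral
    pixels beyond a strain pixel; positions closer than that to the tissue
    boundary see truncated, asymmetric windows whose amplitude weighting
    biases the local phase.  Quantitative per-pixel checks should restrict
    to this eroded interior.
    """
    interior = tissue[:-1] & tissue[1:]
    struct = np.ones((4 * params.w_z + 3, 4 * params.w_x + 1, 1), dtype=bool)
    return ndimage.binary_erosion(interior, struct)


def quality_mask(
    C1: ComplexVolume,
    C2: ComplexVolume,
    params: ProcessingParams,
    tissue: np.ndarray | None = None,
    min_valid_fraction: float = 0.5,
) -> tuple[np.ndarray, bool]:
    """Per-position validity mask and per-pair validity flag.

    A position is valid when (a) the structural amplitude in both frames
    exceeds ``amp_threshold`` times the median in-tissue amplitude of that
    frame, and (b) the windowed complex correlation coefficient

        γ = |Σ C2·C1*| / sqrt(Σ|C1|² · Σ|C2|²)

    exceeds ``coherence_threshold`` — a phase-decorrelated pair (e.g. a
    dropout frame with randomized phase) keeps its amplitude but loses γ.
    The pair is flagged invalid when the valid fraction inside ``tissue``
    (whole frame if None) falls below ``min_valid_fraction``.
    """
    if C1.shape != C2.shape:
        raise ValueError("shape mismatch")
    a1, a2 = C1.amplitude, C2.amplitude
    if tissue is None:
        tissue = np.ones(a1.shape, dtype=bool)
    amp_ok = np.ones(a1.shape, dtype=bool)
    for amp in (a1, a2):
        ref = np.median(amp[tissue]) if tissue.any() else 0.0
        amp_ok &= amp >= params.amp_threshold * ref

    num = np.abs(_windowed_sum(C2.data * np.conj(C1.data), params.w_z, params.w_x))
    p1 = _windowed_sum(a1**2, params.w_z, params.w_x)
    p2 = _windowed_sum(a2**2, params.w_z, params.w_x)
    denom = np.sqrt(p1 * p2)
    coh = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    mask = amp_ok & (coh >= params.coherence_threshold)

    n_tissue = int(tissue.sum())
    frame_valid = bool(n_tissue > 0 and mask[tissue].mean() >= min_valid_fraction)
    return mask, frame_valid


def strain_from_pair(
    C1: ComplexVolume,
    C2: ComplexVolume,
    params: ProcessingParams,
    tissue: np.ndarray | None = None,
    min_valid_fraction: float = 0.5,
) -> StrainMap:
    """Full per-pair pipeline: W → R → ε_zz with quality masking.

    The quality mask (computed on the volume grid) is intersected with the
    strain grid by requiring both bounding axial rows to be valid.
    """
    W = complex_cross_correlation(C1, C2, params)
    R = strain_correlation(W, params)
    smap = axial_strain_map(R, params)
    qmask, frame_valid = quality_mask(C1, C2, params, tissue, min_valid_fraction)
    smap.mask &= qmask[:-1] & qmask[1:]
    smap.frame_valid = frame_valid
    smap.t_mid = 0.5 * (C1.timestamp + C2.timestamp)
    return smap
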