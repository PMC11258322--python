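"""Naive reference implementations of the windowed correlations.

Literal nested-loop transcriptions of the two windowed sums, independent of
the vectorized path in :mod:`psoce.strain`; used by the validation suite to
certify the production implementation on small volumes.  O(N·window) per
position — only for tiny inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["naive_w", "naive_r"]


def naive_w(c1: np.ndarray, c2: np.ndarray, w_z: int, w_x: int) -> np.ndarray:
    """Brute-force self-normalized cross-correlation W (zeros where undefined)."""
    n_z, n_x, n_y = c1.shape
    out = np.zeros_like(c1, dtype=np.complex128)
    for y in range(n_y):
        for z in range(n_z):
            for x in range(n_x):
                s = 0.0 + 0.0j
                for j in range(-w_z, w_z + 1):
                    for k in range(-w_x, w_x + 1):
                        zz, xx = z + j, x + k
                        if 0 <= zz < n_z and 0 <= xx < n_x:
                            s += c2[zz, xx, y] * np.conj(c1[zz, xx, y])
                if abs(s) > 0:
                    out[z, x, y] = s / abs(s)
    return out


def naive_r(w: np.ndarray, w_z: int, w_x: int) -> np.ndarray:
    """Brute-force axial-gradient correlation R on the (n_z − 1) strain grid."""
    n_z, n_x, n_y = w.shape
    out = np.zeros((n_z - 1, n_x, n_y), dtype=np.complex128)
    for y in range(n_y):
        for z in range(n_z - 1):
            for x in range(n_x):
                s = 0.0 + 0.0j
                for j in range(-w_z, w_z + 1):
                    for k in range(-w_x, w_x + 1):
                        zz, xx = z + j, x + k
                        if 0 <= zz < n_z - 1 and 0 <= xx < n_x:
                            s += w[zz + 1, xx, y] * np.conj(w[zz, xx, y])
                if abs(s) > 0:
                    out[z, x, y] = s / abs(s)
    return out
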