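"""Named deformation scenarios emulating the corneal experiments.

Rate magnitudes default to the cumulative strains the experiments reached
divided by the time they took — descriptive defaults that reproduce the
qualitative dynamics (osmotic swelling/deswelling, cross-linking shrinkage),
not quantitative claims about tissue:

* ``isotonic`` — storage medium in osmotic balance with the stroma; no
  deformation (null scenario).
* ``hypotonic_swelling`` — low-osmolarity bath (saline-like): fast uniform
  swelling that levels off once osmotic equilibrium is reached (~3.7 %
  anterior strain in the first 20 min, then nearly flat).
* ``hypertonic_deswelling`` — high-osmolarity bath (dextran-enriched
  medium): anterior shrinkage with posterior swelling, strain rate linear
  in depth and crossing zero at 55 % of stromal thickness.
* ``control_swelling`` — the cross-linking control arms: steady uniform
  swelling (~0.14 %/min in the first 20 min, ~0.09 %/min thereafter) over
  an 80-min session.
* ``cxl`` — identical background until UV onset; from ``onset_time`` the
  anterior ``affected_depth`` µm flip to a negative rate (photochemical
  stiffening and shrinkage), while the deeper stroma keeps swelling.
  Periodic riboflavin instillation is emulated as phase-randomized dropout
  frames every 5 min.

``rate_scale`` multiplies the whole rate field and is the hook for
eye-to-eye biological variability when simulating groups.
"""

from __future__ import annotations

import numpy as np

from .phantom import DeformationScenario

__all__ = ["make_scenario", "SCENARIO_DEFAULTS"]

# per-minute strain fractions
_PBS_EARLY = 0.037 / 20.0  # 3.7 % over the first 20 min
_PBS_LATE = 0.002 / 25.0  # +0.2 % over the remaining 25 min
_HYPER_ANT = -0.056 / 20.0  # −5.6 % anterior over 20 min
_CTRL_EARLY = 0.0014  # 0.14 %/min, pre-treatment segment
_CTRL_LATE = 0.0009  # 0.09 %/min, during/after segments
_CXL_SHRINK = -0.0007  # −0.07 %/min in the affected anterior layer

SCENARIO_DEFAULTS: dict[str, dict] = {
    "isotonic": {"duration": 45.0, "frame_interval": 60.0},
    "hypotonic_swelling": {"duration": 45.0, "frame_interval": 60.0},
    "hypertonic_deswelling": {"duration": 45.0, "frame_interval": 60.0},
    "control_swelling": {"duration": 80.0, "frame_interval": 20.0},
    "cxl": {
        "duration": 80.0,
        "frame_interval": 20.0,
        "onset_time": 30.0,
        "affected_depth": 200.0,
        "dropout_period": 5.0,
        "dropout_start": 20.0,  # riboflavin instillation during irradiation only
        "dropout_end": 50.0,
    },
}


def make_scenario(
    name: str,
    duration: float | None = None,
    frame_interval: float | None = None,
    rate_scale: float = 1.0,
    corneal_thickness: float = 1000.0,
    zero_crossing: float = 0.55,
    onset_time: float | None = None,
    affected_depth: float | None = None,
    dropout_period: float | None = None,
    dropout_duration: int = 1,
) -> DeformationScenario:
    """Build one of the named scenarios, optionally overriding its schedule.

    ``corneal_thickness`` (µm) converts the cxl scenario's affected depth
    into normalized-depth units; keep it equal to the phantom's thickness.
    """
    if name not in SCENARIO_DEFAULTS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIO_DEFAULTS)}")
    defaults = SCENARIO_DEFAULTS[name]
    duration = defaults["duration"] if duration is None else duration
    frame_interval = defaults["frame_interval"] if frame_interval is None else frame_interval
    onset = defaults.get("onset_time", 0.0) if onset_time is None else onset_time
    depth = defaults.get("affected_depth", 0.0) if affected_depth is None else affected_depth
    drop = defaults.get("dropout_period", 0.0) if dropout_period is None else dropout_period
    drop_start = defaults.get("dropout_start", 0.0)
    drop_end = defaults.get("dropout_end", None)
    s = rate_scale

    if name == "isotonic":

        def rate(d, t):
            return np.zeros_like(np.asarray(d, dtype=float))

    elif name == "hypotonic_swelling":

        def rate(d, t):
            r = _PBS_EARLY if t <= 20.0 else _PBS_LATE
            return np.full_like(np.asarray(d, dtype=float), s * r)

    elif name == "hypertonic_deswelling":

        def rate(d, t):
            d = np.asarray(d, dtype=float)
            return s * _HYPER_ANT * (zero_crossing - d) / zero_crossing

    elif name == "control_swelling":

        def rate(d, t):
            r = _CTRL_EARLY if t <= 20.0 else _CTRL_LATE
            return np.full_like(np.asarray(d, dtype=float), s * r)

    else:  # cxl
        d_affected = depth / corneal_thickness

        def rate(d, t):
            d = np.asarray(d, dtype=float)
            base = _CTRL_EARLY if t <= 20.0 else _CTRL_LATE
            out = np.full_like(d, s * base)
            if t >= onset:
                out[d <= d_affected] = s * _CXL_SHRINK
            return out

    return DeformationScenario(
        name=name,
        duration=duration,
        frame_interval=frame_interval,
        rate_profile=rate,
        onset_time=onset,
        affected_depth=depth,
        dropout_period=drop,
        dropout_duration=dropout_duration,
        dropout_start=drop_start,
        dropout_end=drop_end,
    )
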