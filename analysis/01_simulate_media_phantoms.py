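#!/usr/bin/env python
"""Simulate the preservation-media experiments on the digital cornea phantom.

One eye per bathing medium — saline-like (hypotonic, swelling), moderate
dextran (isotonic, stable) and high dextran (hypertonic, anterior
deswelling) — imaged every minute for 45 min at the instrument's native
axial sampling.  Volumes (with ground truth) go to scratch/ as HDF5; the
scenario definitions echo the known osmotic dynamics so every downstream
estimate can be checked against truth.
"""

from pathlib import Path

import numpy as np

from psoce import PhantomConfig, ProcessingParams, make_scenario, simulate_timeseries
from psoce.io import save_volumes

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "scratch" / "media"

MEDIA = {
    "pbs": "hypotonic_swelling",
    "dextran5": "isotonic",
    "dextran7": "hypertonic_deswelling",
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = ProcessingParams()
    for i, (medium, scenario) in enumerate(MEDIA.items()):
        cfg = PhantomConfig(
            n_z=280, n_x=24, n_y=3, delta=4.48, pitch_x=24.0, pitch_y=120.0,
            anterior_apex_depth=90.0, corneal_thickness=1000.0,
            scatterer_density=2.0, snr_db=25.0, decorrelation=0.02, seed=SEED + i,
        )
        scen = make_scenario(scenario, duration=45.0, frame_interval=60.0,
                             corneal_thickness=cfg.corneal_thickness)
        frames, gt = simulate_timeseries(cfg, scen, params)
        path = OUT / f"{medium}.h5"
        save_volumes(path, frames, gt, cfg, scen)
        print(f"{medium:9s} ({scenario}): {len(frames)} frames -> {path}")
    print("done; run 02_media_strain_curves.py next")


if __name__ == "__main__":
    main()
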