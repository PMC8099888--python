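#!/usr/bin/env python
"""Render a synthetic urethane dose series and save it as TIFF recordings.

Writes recordings + ground-truth component tables under scratch/simulated/
(regenerable bulk data), plus an index CSV. These files are the input of
02_detect_response.py and 03_unmix_components.py, mirroring how acquired data
would enter the pipeline. The full 174x130 acquisition grid is kept (the
response must occupy ~5% of the field for the 95th-percentile contour
threshold to be meaningful); trial count and doses are reduced to demo scale.
"""

from pathlib import Path

import pandas as pd

from oiskit import synth
from oiskit.io import IlluminationSchedule, StimulusProtocol, save_recording

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "scratch" / "simulated"

scene = synth.SceneConfig()
dose_cfg = synth.DoseConfig(anesthetic="urethane",
                            concentrations=(0.0, 0.5, 1.0, 1.5), tau_ls=1.4)
protocol = StimulusProtocol(n_trials=4, inter_train_s=30.0)
schedule = IlluminationSchedule()
GRID = synth.DEFAULT_GRID

OUT.mkdir(parents=True, exist_ok=True)
rows = []
for c, recording, truth in synth.iter_dose_series(
        scene, dose_cfg, protocol=protocol, schedule=schedule, grid=GRID,
        seed=SEED):
    tag = f"urethane_c{c:g}".replace(".", "p")
    save_recording(recording, OUT / f"{tag}.tif", OUT / f"{tag}.json")
    pd.DataFrame({"time_s": truth.time_axis_s, "LS_frac": truth.ls_t,
                  "HbO": truth.hbo_t, "HbR": truth.hbr_t}).to_csv(
        OUT / f"{tag}_truth.csv", index=False)
    rows.append({"concentration": c, "unit": dose_cfg.unit,
                 "stack": f"{tag}.tif", "sidecar": f"{tag}.json",
                 "true_area_mm2": truth.footprint_area_mm2,
                 "true_ls_peak_frac": truth.config.ls_peak_frac})
    print(f"c={c:g} {dose_cfg.unit}: LS peak {truth.config.ls_peak_frac:+.2e} "
          f"(x{dose_cfg.scale(c):.3f} of control), area {truth.footprint_area_mm2:.2f} mm^2")

pd.DataFrame(rows).to_csv(OUT / "index.csv", index=False)
print(f"\nwrote {len(rows)} recordings to {OUT}")
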