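"""Simulate a hand area and map its finger clusters with the traveling wave.

Builds one synthetic participant, runs the lag cross-correlation analysis
on the forward and backward localizer runs, applies per-finger FDR, and
compares the resulting clusters to the generator's ground truth.
"""

import numpy as np

from handmap.config import CLUSTERS, StudyConfig
from handmap import localizer, synth

cfg = StudyConfig(n_voxels=200, noise_sd=0.2, seed=1)
tm = synth.generate_tuning_map(cfg)
runs = [
    synth.generate_wave_run(tm, cfg, "forward", run=0),
    synth.generate_wave_run(tm, cfg, "backward", run=1),
]

refs = localizer.build_reference_models(tr=cfg.tr_seconds)
print(f"reference models: {refs.n_lags} (one per 2-s lag of the 40-s cycle)")

fcmap = localizer.correlate_voxels(runs, refs)
cmap = localizer.define_clusters(fcmap, np.ones(cfg.n_voxels, bool), q=0.01)

print("cluster sizes:", cmap.sizes())
assigned = cmap.labels != localizer.UNASSIGNED
agree = (cmap.labels[assigned] == tm.labels[assigned]).mean()
print(f"assigned voxels: {assigned.sum()}/{cfg.n_voxels}; "
      f"agreement with ground truth: {agree:.1%}")
print("Each cluster is the set of voxels whose winning finger survived the "
      "q<0.01 FDR threshold; agreement shows the traveling-wave analysis "
      "recovers the simulated topography.")
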