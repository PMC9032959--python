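"""Fit the 5-unit recurrent model and recover the homeostatic gains.

Fits feedforward weights to baseline cluster activity, shows that the
static model (no parameter change) collapses the blocked finger's
representation, and recovers the generating gain configuration (0.75
shared, 1.25 blocked unit) from block-session activity.
"""

import numpy as np

from handmap.config import FINGERS, StudyConfig
from handmap import cortical, localizer, peripheral, remapping, synth

cfg = StudyConfig(n_voxels=200, seed=4)
spread = peripheral.build_spread(cfg.spread_scale)
drives = peripheral.baseline_drives(spread)
blocked = peripheral.blocked_drives(drives, "D2", cfg.block_fraction)

tm = synth.generate_tuning_map(cfg)
clusters = localizer.ClusterMap.from_truth(tm.labels)
activity = remapping.cluster_activity(
    synth.noiseless_means(tm, "baseline", cfg, drives), clusters
)
model = cortical.fit_baseline(activity.to_numpy(), drives, b=0.0)

for f in FINGERS:
    r = cortical.settle(model, drives[f], tol=1e-3)
    print(f"{f}: settled in {r.iterations} steps, activity of its unit = "
          f"{r.c[FINGERS.index(f)]:.3f}")

base_rdm = cortical.model_rdm(cortical.settle_all(model, drives, tol=1e-9))
_, static_rdm = cortical.predict_static_block(model, blocked)
print(f"\nD2 distance-from-rest, baseline:      {base_rdm.get('D2', 'rest'):.3f}")
print(f"D2 distance-from-rest, static block:  {static_rdm.get('D2', 'rest'):.3f}")
print("Holding every parameter fixed, the block collapses D2's "
      "representation far more than is seen empirically.")

generating = model.with_gains(0.75, 1.25)
target = np.column_stack(
    [cortical.fixed_point(generating, blocked[f]) for f in FINGERS]
).T
g, gb = cortical.fit_gains(model, blocked, target)
print(f"\nrecovered gains: shared = {g:.4f}, blocked unit = {gb:.4f}")
print("The two-parameter homeostatic fit recovers the generating "
      "configuration: a global down-regulation plus an up-regulated "
      "blocked cluster.")
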