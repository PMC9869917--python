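"""Generate a synthetic MP-MRI case and score it with the RX detector.

The phantom draws a 7-channel Gaussian "normal prostate" background and
inserts one lesion whose channel means are shifted by a tumor signature.
RX is each voxel's squared Mahalanobis distance from the background, so
background voxels score near C = 7 (the chi-square mean) while lesion
voxels score far higher.
"""

import numpy as np

import mpmri_anomaly as mp

spec = mp.default_spec(seed=42)
slices, truth = mp.generate_phantom(spec)
cube, masks = mp.stitch_cubes(
    slices,
    masks={"prostate": list(truth.prostate_mask), "tumor": list(truth.tumor_mask)},
    channel_names=spec.channel_names,
)
print(f"hypercube {cube.data.shape}: 3 slices of 64x64 stitched to 64x192, "
      f"{int(masks['prostate'].sum())} prostate voxels")

normal = masks["prostate"] & ~masks["tumor"]
stats = mp.compute_stats(cube, normal)
cs = mp.condition_unprocessed(stats)
rx = mp.rx_map(cube, cs, masks["prostate"])

bg_scores = rx.scores[normal]
tum_scores = rx.scores[masks["tumor"]]
print(f"mean RX: background {bg_scores.mean():.2f} (chi-square_7 mean is 7), "
      f"tumor {tum_scores.mean():.2f}")

roc = mp.roc_curve(rx, masks["tumor"], masks["prostate"])
print(f"RX vs ground truth: AUC={roc.auc:.3f}, Youden index={roc.yi:.3f} "
      f"at RX threshold {roc.yi_threshold:.1f}")
print("AUC near 1 means the anomaly score almost perfectly ranks lesion "
      "voxels above normal tissue.")
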