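"""Compare the five covariance-conditioning routes for RX.

The sample covariance of normal tissue is noisiest in its smallest
eigenvalues, exactly where the inverse amplifies.  This script adds two
pure-noise channels to the phantom and shows that deleting the two
low-eigenvalue principal components recovers the detection performance the
plain inverse loses; it also shows shrinkage selection and the robust EVM
estimator on contaminated data.
"""

import numpy as np

import mpmri_anomaly as mp
from mpmri_anomaly import background as bg

# --- delete-PC on a cube with two known-noise channels -------------------
cov7 = mp.phantom.default_background_cov()
c9 = 9
cov9 = np.zeros((c9, c9))
cov9[:7, :7] = cov7
cov9[7, 7] = cov9[8, 8] = 1e-6
spec = mp.PhantomSpec(
    grid_shape=(64, 64), n_slices=3,
    channel_names=mp.CHANNELS + ("noise_a", "noise_b"),
    background_mean=np.r_[mp.phantom.default_background_mean(), 0.0, 0.0],
    background_cov=cov9,
    tumor_regions=[mp.TumorRegion(
        1, (24.0, 36.0), 6.0,
        np.r_[mp.phantom.default_tumor_signature(cov7, 3.0), 0.0, 0.0])],
    seed=11,
)
slices, truth = mp.generate_phantom(spec)
cube, masks = mp.stitch_cubes(
    slices,
    masks={"prostate": list(truth.prostate_mask), "tumor": list(truth.tumor_mask)},
    channel_names=spec.channel_names,
)
normal = masks["prostate"] & ~masks["tumor"]
stats = mp.compute_stats(cube, normal)
for name, cs in [
    ("unprocessed", bg.condition_unprocessed(stats)),
    ("delete 2 PC", bg.filter_pcs(stats, 2)),
]:
    rx = mp.rx_map(cube, cs, masks["prostate"])
    auc = mp.roc_curve(rx, masks["tumor"], masks["prostate"]).auc
    print(f"{name:12s} RX AUC vs truth: {auc:.3f}")
print("the two tiny-eigenvalue noise components dilute the plain inverse; "
      "filtering them restores separation.\n")

# --- shrinkage selection by cross-validated likelihood -------------------
g_big, _ = bg.select_gamma(cube, normal, "regularized")
few = np.zeros_like(normal)
few[np.argwhere(normal)[:40, 0], np.argwhere(normal)[:40, 1]] = True
g_small, _ = bg.select_gamma(cube, few, "regularized")
print(f"shrinkage weight gamma*: {g_big:.2f} with {int(normal.sum())} voxels, "
      f"{g_small:.2f} with 40 voxels")
print("well-sampled covariances need no shrinkage; scarce data pulls the "
      "estimate toward its diagonal.\n")

# --- EVM on contaminated background --------------------------------------
spec_c = mp.default_spec(seed=12, outlier_fraction=0.05)
slices, truth = mp.generate_phantom(spec_c)
cube, masks = mp.stitch_cubes(
    slices, masks={"prostate": list(truth.prostate_mask)},
    channel_names=spec_c.channel_names)
cs_evm = bg.evm(cube, masks["prostate"], trials=200, seed=12)
cs_raw = bg.condition_unprocessed(bg.compute_stats(cube, masks["prostate"]))
d_evm = np.linalg.slogdet(cs_evm.cov)[1]
d_raw = np.linalg.slogdet(cs_raw.cov)[1]
print(f"EVM log-det {d_evm:.3f} vs unprocessed {d_raw:.3f} "
      f"(reduction {d_raw - d_evm:.3f}) with 5% outliers at 10 sigma")
print("the minimum-volume subset sheds gross outliers, tightening the "
      "background ellipsoid so artifacts score as anomalies.")
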