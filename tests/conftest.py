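import numpy as np
import pytest

import mpmri_anomaly as mp


@pytest.fixture(scope="session")
def default_case():
    """One stitched phantom case with a clearly separable lesion."""
    spec = mp.default_spec(seed=7)
    slices, truth = mp.generate_phantom(spec)
    cube, masks = mp.stitch_cubes(
        slices,
        masks={
            "prostate": list(truth.prostate_mask),
            "tumor": list(truth.tumor_mask),
        },
        channel_names=spec.channel_names,
    )
    return spec, truth, cube, masks


@pytest.fixture(scope="session")
def big_background():
    """~20k pure-background voxels as an (n, 7) matrix plus the true stats."""
    spec = mp.PhantomSpec(grid_shape=(200, 200), n_slices=1, seed=11)
    slices, truth = mp.generate_phantom(spec)
    x = slices[0][truth.prostate_mask[0]]
    return x, spec.background_mean, spec.background_cov


def random_spd(rng: np.random.Generator, c: int, scale: float = 1.0) -> np.ndarray:
    """Well-conditioned random SPD matrix for oracle tests."""
    a = rng.standard_normal((c, c))
    return scale * (a @ a.T + c * np.eye(c))
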