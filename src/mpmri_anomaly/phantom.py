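"""Synthetic multi-parametric MRI phantoms.

The phantom emulates the statistical structure the detection pipeline
assumes: a multivariate-Gaussian "normal prostate" background with a
user-specified 7x7 covariance, focal tumor regions whose channel means are
shifted by a spectral signature, optional gross outlier voxels standing in
for acquisition/registration artifacts, and a per-voxel dynamic
contrast-enhancement (DCE) time curve that rises to a peak and then decays
exponentially at the voxel's washout rate k_ep.

Everything is driven by a single integer seed so that identical
:class:`PhantomSpec` objects produce bit-identical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

#: Canonical channel order of the 7-component hypercube.
CHANNELS = ("t1_pre", "t1_max", "t2", "adc", "dwi_high_b", "kep", "prob")

# Default background statistics, in arbitrary intensity units.  The
# correlation structure couples the diffusion pair (ADC vs high-B DWI,
# strongly anti-correlated), the DCE pair (kep vs prob), and the two
# T1-weighted channels, which is the qualitative structure multi-parametric
# prostate MRI exhibits.
_DEFAULT_MEAN = np.array([400.0, 900.0, 600.0, 1200.0, 250.0, 0.010, 0.60])
_DEFAULT_SD = np.array([60.0, 140.0, 110.0, 220.0, 55.0, 0.004, 0.15])
_DEFAULT_CORR = np.array(
    [
        [1.00, 0.55, 0.10, 0.05, 0.00, 0.05, 0.05],
        [0.55, 1.00, 0.10, 0.00, 0.05, 0.30, 0.25],
        [0.10, 0.10, 1.00, 0.35, -0.25, 0.00, 0.00],
        [0.05, 0.00, 0.35, 1.00, -0.60, -0.20, -0.15],
        [0.00, 0.05, -0.25, -0.60, 1.00, 0.25, 0.20],
        [0.05, 0.30, 0.00, -0.20, 0.25, 1.00, 0.50],
        [0.05, 0.25, 0.00, -0.15, 0.20, 0.50, 1.00],
    ]
)


def default_background_mean() -> np.ndarray:
    return _DEFAULT_MEAN.copy()


def default_background_cov() -> np.ndarray:
    """Default SPD 7x7 covariance with realistic cross-modality structure."""
    return _DEFAULT_CORR * np.outer(_DEFAULT_SD, _DEFAULT_SD)


def signature_with_mahalanobis(
    cov: np.ndarray, direction: np.ndarray, length: float
) -> np.ndarray:
    """Scale ``direction`` so the returned mean shift has the requested
    Mahalanobis length ``sqrt(delta^T cov^-1 delta) == length``."""
    direction = np.asarray(direction, dtype=float)
    d2 = float(direction @ np.linalg.solve(cov, direction))
    if d2 <= 0:
        raise ValueError("signature direction has zero Mahalanobis length")
    return direction * (length / np.sqrt(d2))


def default_tumor_signature(cov: np.ndarray, length: float = 4.5) -> np.ndarray:
    """Archetypal lesion contrast: enhancing (T1max up), restricted diffusion
    (ADC down, high-B DWI up), fast washout (kep and prob up), scaled to the
    given Mahalanobis length."""
    sd = np.sqrt(np.diag(cov))
    direction = sd * np.array([0.0, 1.5, -1.0, -1.5, 1.0, 2.5, 2.0])
    return signature_with_mahalanobis(cov, direction, length)


@dataclass
class TumorRegion:
    """A filled disc of tumor tissue in one slice."""

    slice_index: int
    center: tuple[float, float]  # (row, col) voxel coordinates
    radius: float  # voxels
    signature: np.ndarray  # 7-vector additive mean shift

    def to_jsonable(self) -> dict:
        return {
            "slice_index": self.slice_index,
            "center": list(self.center),
            "radius": self.radius,
            "signature": np.asarray(self.signature).tolist(),
        }


@dataclass
class PhantomSpec:
    """Full description of a synthetic MP-MRI case.

    Defaults describe a 3-slice, 64x64 phantom with one clearly separable
    lesion per interior slice and no gross outliers.
    """

    grid_shape: tuple[int, int] = (64, 64)
    n_slices: int = 3
    channel_names: tuple[str, ...] = CHANNELS
    background_mean: np.ndarray = field(default_factory=default_background_mean)
    background_cov: np.ndarray = field(default_factory=default_background_cov)
    tumor_regions: list[TumorRegion] = field(default_factory=list)
    outlier_fraction: float = 0.0
    outlier_scale: float = 10.0
    dce_times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 310.0, 10.0)
    )
    dce_kep_range: tuple[float, float] = (0.005, 0.02)
    dce_t_peak: float = 60.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.background_mean = np.asarray(self.background_mean, dtype=float)
        self.background_cov = np.asarray(self.background_cov, dtype=float)
        self.dce_times = np.asarray(self.dce_times, dtype=float)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def validate(self) -> None:
        c = self.n_channels
        if self.background_mean.shape != (c,):
            raise ValueError("background_mean length must match channel count")
        if self.background_cov.shape != (c, c):
            raise ValueError("background_cov must be CxC")
        if not np.allclose(self.background_cov, self.background_cov.T):
            raise ValueError("background_cov must be symmetric")
        eigvals = np.linalg.eigvalsh(self.background_cov)
        if eigvals.min() <= 0:
            raise ValueError(
                "background_cov is not positive definite: smallest eigenvalue "
                f"{eigvals.min():.3e} <= 0"
            )
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must lie in [0, 0.5)")
        if np.any(np.diff(self.dce_times) <= 0):
            raise ValueError("dce_times must be strictly increasing")
        lo, hi = self.dce_kep_range
        if not 0 <= lo <= hi:
            raise ValueError("dce_kep_range must satisfy 0 <= min <= max")
        rows, cols = self.grid_shape
        a, b = _ellipse_semi_axes(rows, cols)
        cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
        for t in self.tumor_regions:
            if not 0 <= t.slice_index < self.n_slices:
                raise ValueError(f"tumor slice index {t.slice_index} out of range")
            # tumor disc (inflated by its radius) must fit in the prostate ellipse
            dr, dc = t.center[0] - cr, t.center[1] - cc
            if (dr / max(a - t.radius, 1e-9)) ** 2 + (
                dc / max(b - t.radius, 1e-9)
            ) ** 2 > 1.0:
                raise ValueError(
                    f"tumor at {t.center} (r={t.radius}) extends beyond the "
                    "prostate ellipse"
                )

    def to_json(self) -> str:
        d = asdict(self)
        d["background_mean"] = self.background_mean.tolist()
        d["background_cov"] = self.background_cov.tolist()
        d["dce_times"] = self.dce_times.tolist()
        d["tumor_regions"] = [t.to_jsonable() for t in self.tumor_regions]
        d["channel_names"] = list(self.channel_names)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["channel_names"] = tuple(d["channel_names"])
        d["dce_kep_range"] = tuple(d["dce_kep_range"])
        d["tumor_regions"] = [
            TumorRegion(
                slice_index=t["slice_index"],
                center=tuple(t["center"]),
                radius=t["radius"],
                signature=np.asarray(t["signature"], dtype=float),
            )
            for t in d["tumor_regions"]
        ]
        return cls(**d)


@dataclass
class PhantomTruth:
    """Voxel-level ground truth accompanying a generated phantom.

    All masks are (n_slices, rows, cols) boolean arrays on the phantom grid;
    ``kep_true`` holds the washout rate (1/s) used for the DCE curves, zero
    outside the prostate.
    """

    prostate_mask: np.ndarray
    tumor_mask: np.ndarray
    outlier_mask: np.ndarray
    kep_true: np.ndarray


def _ellipse_semi_axes(rows: int, cols: int) -> tuple[float, float]:
    # pi*a*b = 0.5*rows*cols  ->  ellipse covers ~50% of the slice
    f = np.sqrt(0.5 / np.pi)
    return f * rows, f * cols


def prostate_ellipse_mask(grid_shape: tuple[int, int]) -> np.ndarray:
    """Filled ellipse covering ~50% of the grid; the per-slice organ outline."""
    rows, cols = grid_shape
    a, b = _ellipse_semi_axes(rows, cols)
    r = np.arange(rows)[:, None] - (rows - 1) / 2.0
    c = np.arange(cols)[None, :] - (cols - 1) / 2.0
    return (r / a) ** 2 + (c / b) ** 2 <= 1.0


def default_spec(
    seed: int = 0,
    grid_shape: tuple[int, int] = (64, 64),
    n_slices: int = 3,
    tumor_mahalanobis: float = 4.5,
    tumor_radius: float | None = None,
    outlier_fraction: float = 0.0,
    noise_sd: float = 0.0,
) -> PhantomSpec:
    """A ready-to-use phantom: one lesion in the middle slice, offset from
    the gland center.  The lesion radius scales with the grid (~9% of the
    short side) unless given explicitly."""
    cov = default_background_cov()
    sig = default_tumor_signature(cov, tumor_mahalanobis)
    rows, cols = grid_shape
    if tumor_radius is None:
        tumor_radius = max(2.0, round(0.094 * min(rows, cols)))
    center = ((rows - 1) / 2.0 - rows * 0.12, (cols - 1) / 2.0 + cols * 0.15)
    spec = PhantomSpec(
        grid_shape=grid_shape,
        n_slices=n_slices,
        tumor_regions=[TumorRegion(n_slices // 2, center, tumor_radius, sig)],
        outlier_fraction=outlier_fraction,
        noise_sd=noise_sd,
        seed=seed,
    )
    spec.validate()
    return spec


def _disc_mask(grid_shape, center, radius) -> np.ndarray:
    r = np.arange(grid_shape[0])[:, None] - center[0]
    c = np.arange(grid_shape[1])[None, :] - center[1]
    return r * r + c * c <= radius * radius


def generate_phantom(spec: PhantomSpec) -> tuple[list[np.ndarray], PhantomTruth]:
    """Draw one phantom case.

    Returns per-slice ``(rows, cols, C)`` channel arrays and the aligned
    :class:`PhantomTruth`.  Voxels outside the prostate ellipse are zero.
    Background voxels are i.i.d. multivariate normal; tumor voxels get their
    region's signature added to the mean; outlier voxels (chosen among
    non-tumor prostate voxels) are displaced by ``outlier_scale`` channel
    standard deviations along a random unit direction.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    rows, cols = spec.grid_shape
    c = spec.n_channels
    ell = prostate_ellipse_mask(spec.grid_shape)

    prostate = np.repeat(ell[None], spec.n_slices, axis=0)
    tumor = np.zeros_like(prostate)
    for t in spec.tumor_regions:
        tumor[t.slice_index] |= _disc_mask(spec.grid_shape, t.center, t.radius) & ell

    chol = np.linalg.cholesky(spec.background_cov)
    sd = np.sqrt(np.diag(spec.background_cov))

    slices: list[np.ndarray] = []
    outlier = np.zeros_like(prostate)
    for s in range(spec.n_slices):
        data = np.zeros((rows, cols, c))
        n_in = int(ell.sum())
        z = rng.standard_normal((n_in, c))
        vox = spec.background_mean + z @ chol.T
        data[ell] = vox
        for t in spec.tumor_regions:
            if t.slice_index == s:
                m = _disc_mask(spec.grid_shape, t.center, t.radius) & ell
                data[m] += np.asarray(t.signature, dtype=float)
        if spec.outlier_fraction > 0:
            cand = np.flatnonzero((ell & ~tumor[s]).ravel())
            n_out = int(round(spec.outlier_fraction * cand.size))
            picked = rng.choice(cand, size=n_out, replace=False)
            u = rng.standard_normal((n_out, c))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            flat = data.reshape(-1, c)
            flat[picked] += spec.outlier_scale * u * sd
            om = np.zeros(rows * cols, dtype=bool)
            om[picked] = True
            outlier[s] = om.reshape(rows, cols)
        slices.append(data)

    # Washout ground truth: reuse the generated kep channel where it falls in
    # range, so the DCE series and the spectral kep channel agree.
    kep_idx = spec.channel_names.index("kep") if "kep" in spec.channel_names else None
    kep_true = np.zeros((spec.n_slices, rows, cols))
    lo, hi = spec.dce_kep_range
    for s in range(spec.n_slices):
        if kep_idx is not None:
            kep_true[s][prostate[s]] = np.clip(
                slices[s][..., kep_idx][prostate[s]], lo, hi
            )
        else:
            kep_true[s][prostate[s]] = rng.uniform(lo, hi, int(prostate[s].sum()))

    truth = PhantomTruth(
        prostate_mask=prostate,
        tumor_mask=tumor,
        outlier_mask=outlier,
        kep_true=kep_true,
    )
    return slices, truth


def generate_dce_series(spec: PhantomSpec, truth: PhantomTruth) -> np.ndarray:
    """Per-voxel DCE time curves consistent with ``truth.kep_true``.

    Each prostate voxel's curve rises linearly from 0 to a random amplitude
    A ~ U(1, 2) at ``spec.dce_t_peak`` and then decays as
    ``A * exp(-kep * (t - t_peak))``, plus N(0, noise_sd) noise.  Returns a
    ``(T, n_slices, rows, cols)`` array; voxels outside the prostate are zero.
    """
    spec.validate()
    times = spec.dce_times
    t_peak = spec.dce_t_peak
    if times.max() <= max(t_peak, 50.0):
        raise ValueError("dce_times must extend beyond the peak and 50 s")
    n_post = int(np.sum(times > max(t_peak, 50.0)))
    if n_post < 4:
        raise ValueError(
            f"washout fit underdetermined: only {n_post} samples after the "
            "peak (need >= 4)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xDCE]))
    rows, cols = spec.grid_shape
    out = np.zeros((times.size, spec.n_slices, rows, cols))
    rise = np.clip(times / t_peak, 0.0, 1.0)
    for s in range(spec.n_slices):
        m = truth.prostate_mask[s]
        n = int(m.sum())
        amp = rng.uniform(1.0, 2.0, n)
        kep = truth.kep_true[s][m]
        decay = np.exp(-np.outer(np.maximum(times - t_peak, 0.0), kep))
        curves = amp * rise[:, None] * decay  # (T, n)
        if spec.noise_sd > 0:
            curves = curves + rng.normal(0.0, spec.noise_sd, curves.shape)
        out[:, s][:, m] = curves
    return out
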