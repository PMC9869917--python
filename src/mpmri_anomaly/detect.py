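"""Per-voxel detectors.

RX (Reed-Xiaoli) is the unsupervised anomaly score: the squared Mahalanobis
distance of a voxel's 7-channel value from the background mean,
``RX(x) = (x - mu)^T Sigma^-1 (x - mu)`` — i.e. squared Euclidean distance
in whitened space, so its decision surface is a hypersphere around the
background.  Under an exactly Gaussian background with known full-rank
statistics RX follows a chi-square distribution with C degrees of freedom.

ACE (adaptive cosine estimator) is the supervised counterpart: the squared
cosine of the whitened angle between the voxel and a tumor signature s,

    ACE(x) = [(x-mu)^T S (s-mu)]^2 /
             ([(x-mu)^T S (x-mu)] [(s-mu)^T S (s-mu)]),   S = Sigma^-1,

bounded in [0, 1] by Cauchy-Schwarz.  With a rank-deficient (delete-PC)
operator both vectors are implicitly projected onto the retained subspace,
which keeps the bound; that pairing is an extension beyond the usual
full-rank usage and is flagged in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .background import ConditionedStats

#: Value carried by voxels outside the scored domain (impossible for both
#: detectors: RX >= 0 and ACE in [0, 1]).
NO_DATA = -1.0


@dataclass
class Signature:
    """Tumor spectral signature: one value per MRI channel."""

    s: np.ndarray
    n_voxels: int = 0  # seed-region size it was averaged over

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if not np.all(np.isfinite(self.s)):
            raise ValueError("signature must be finite")


@dataclass
class DetectionMap:
    scores: np.ndarray  # 2D, NO_DATA outside domain_mask
    method: str  # "rx" | "ace"
    domain_mask: np.ndarray
    stats_method: str
    flags: list[str] = field(default_factory=list)

    def masked_scores(self) -> np.ndarray:
        return self.scores[self.domain_mask]


def _cube_data(cube) -> np.ndarray:
    if isinstance(cube, np.ndarray):
        return np.asarray(cube, dtype=float)
    return cube.data


def rx_scores(x: np.ndarray, cs: ConditionedStats) -> np.ndarray:
    """RX of each row of an (n, C) voxel matrix."""
    d = x - cs.mu
    return np.einsum("ij,jk,ik->i", d, cs.inv_op, d)


def rx_map(cube, cs: ConditionedStats, domain_mask: np.ndarray | None = None) -> DetectionMap:
    """Squared Mahalanobis distance of every domain voxel from the background."""
    data = _cube_data(cube)
    if data.shape[-1] != cs.n_channels:
        raise ValueError(
            f"cube has {data.shape[-1]} channels but stats expect {cs.n_channels}"
        )
    if domain_mask is None:
        domain_mask = np.ones(data.shape[:-1], dtype=bool)
    domain_mask = np.asarray(domain_mask, dtype=bool)
    scores = np.full(data.shape[:-1], NO_DATA)
    scores[domain_mask] = rx_scores(data[domain_mask], cs)
    return DetectionMap(scores, "rx", domain_mask, cs.method)


def ace_scores(x: np.ndarray, cs: ConditionedStats, sig: Signature) -> np.ndarray:
    """ACE of each row of an (n, C) voxel matrix; zero-norm voxels score 0."""
    t = sig.s - cs.mu
    st = cs.inv_op @ t
    tt = float(t @ st)
    if tt <= 0:
        raise ValueError(
            "degenerate signature: zero whitened length (signature equals the "
            "background mean, or lies in the deleted subspace)"
        )
    d = x - cs.mu
    num = (d @ st) ** 2
    den = np.einsum("ij,jk,ik->i", d, cs.inv_op, d) * tt
    out = np.zeros(x.shape[0])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, 0.0, 1.0)


def ace_map(
    cube,
    cs: ConditionedStats,
    sig: Signature,
    domain_mask: np.ndarray | None = None,
) -> DetectionMap:
    """Squared whitened cosine between each voxel and the tumor signature."""
    data = _cube_data(cube)
    if data.shape[-1] != cs.n_channels or sig.s.size != cs.n_channels:
        raise ValueError("cube, stats and signature dimensions must agree")
    if domain_mask is None:
        domain_mask = np.ones(data.shape[:-1], dtype=bool)
    domain_mask = np.asarray(domain_mask, dtype=bool)
    scores = np.full(data.shape[:-1], NO_DATA)
    scores[domain_mask] = ace_scores(data[domain_mask], cs, sig)
    flags = ["projected_subspace_ace"] if cs.method == "delete_pc" else []
    return DetectionMap(scores, "ace", domain_mask, cs.method, flags)


def extract_signature(cube, seed_region_mask: np.ndarray) -> Signature:
    """In-scene signature: the per-channel mean over a seed region."""
    data = _cube_data(cube)
    m = np.asarray(seed_region_mask, dtype=bool)
    n = int(m.sum())
    if n == 0:
        raise ValueError("seed region is empty")
    return Signature(s=data[m].mean(axis=0), n_voxels=n)
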