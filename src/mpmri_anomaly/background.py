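"""Normal-prostate background statistics and covariance conditioning.

The RX detector needs the inverse covariance of normal tissue.  The raw
sample covariance of a few thousand voxels in 7 channels is noisy exactly
where inversion is most sensitive — in its smallest eigenvalues — so five
conditioning strategies are provided:

``unprocessed``
    plain inverse of the sample covariance;
``delete_pc``
    drop the k smallest-eigenvalue principal components and invert on the
    retained subspace (rank C-k pseudo-inverse);
``regularized`` / ``modified_regularized``
    shrink toward a diagonal target, ``CM(g) = (1-g)*S + g*D`` with
    ``D = diag(S)`` (regularized) or ``D = (trace(S)/C) * I`` (modified);
    the mixing weight g is chosen by cross-validated Gaussian likelihood;
``evm``
    elliptical volume minimization: repeatedly drop a random 10% of the
    voxels and keep the subset whose covariance ellipsoid (volume
    proportional to sqrt(det)) is smallest — a randomized robust estimator
    in the spirit of minimum-covariance-determinant methods.

All conditioned operators are symmetric positive semi-definite, so RX
scores are guaranteed non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

#: Eigenvalues below EIG_TOL * lambda_max are treated as exactly zero.
EIG_TOL = 1e-12

ShrinkMode = Literal["regularized", "modified_regularized"]

#: Fixed mixing-parameter grid for cross-validated shrinkage selection.
GAMMA_GRID = np.round(np.linspace(0.0, 1.0, 21), 2)


@dataclass
class BackgroundStats:
    """First- and second-order statistics of the normal-prostate voxels."""

    mu: np.ndarray  # (C,)
    cov: np.ndarray  # (C, C), divisor n-1
    n: int  # voxels used

    @property
    def n_channels(self) -> int:
        return self.mu.size

    def is_singular(self) -> bool:
        w = np.linalg.eigvalsh(self.cov)
        return bool(w.min() <= EIG_TOL * max(w.max(), 0.0))


@dataclass
class ConditionedStats:
    """A background model ready for scoring: mean plus the operator applied
    as the inverse covariance."""

    mu: np.ndarray
    inv_op: np.ndarray  # symmetric PSD; applied as Sigma^-1
    method: str
    params: dict = field(default_factory=dict)
    eigenvalues: np.ndarray | None = None
    retained: np.ndarray | None = None  # bool flags per eigenvector
    cov: np.ndarray | None = None  # the covariance the operator inverts

    @property
    def n_channels(self) -> int:
        return self.mu.size

    def to_jsonable(self) -> dict:
        return {
            "method": self.method,
            "params": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.params.items()
            },
            "mu": self.mu.tolist(),
            "inv_op": self.inv_op.tolist(),
            "cov": None if self.cov is None else self.cov.tolist(),
            "eigenvalues": None
            if self.eigenvalues is None
            else self.eigenvalues.tolist(),
            "retained": None if self.retained is None else self.retained.tolist(),
        }


def _masked_voxels(cube, mask: np.ndarray) -> np.ndarray:
    """Extract an (n, C) voxel matrix from a Hypercube or (rows, cols, C)."""
    data = np.asarray(cube, dtype=float) if isinstance(cube, np.ndarray) else cube.data
    return data[np.asarray(mask, dtype=bool)]


def compute_stats(cube, normal_mask: np.ndarray) -> BackgroundStats:
    """Sample mean and covariance (divisor n-1) over the masked voxels."""
    x = _masked_voxels(cube, normal_mask)
    n, c = x.shape
    if n <= c:
        raise ValueError(
            f"covariance rank-deficient by construction: {n} voxels for "
            f"{c} channels"
        )
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    return BackgroundStats(mu=mu, cov=np.atleast_2d(cov), n=n)


def _eigh_sorted(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, v = np.linalg.eigh(cov)  # ascending
    return w[::-1], v[:, ::-1]  # descending


def condition_unprocessed(stats: BackgroundStats) -> ConditionedStats:
    """Plain inverse of the sample covariance (via its eigensystem)."""
    w, v = _eigh_sorted(stats.cov)
    if w.min() <= EIG_TOL * w.max():
        raise np.linalg.LinAlgError(
            "sample covariance is singular; condition it (delete_pc, shrink, "
            "evm) before inverting"
        )
    inv_op = (v / w) @ v.T
    return ConditionedStats(
        mu=stats.mu.copy(),
        inv_op=_symmetrize(inv_op),
        method="unprocessed",
        eigenvalues=w,
        retained=np.ones_like(w, dtype=bool),
        cov=stats.cov.copy(),
    )


def filter_pcs(stats: BackgroundStats, k: int) -> ConditionedStats:
    """Delete the k smallest-eigenvalue principal components.

    The scoring operator becomes the rank ``C - k`` pseudo-inverse
    ``sum_retained v_i v_i^T / lambda_i``: variation along the deleted
    (noisy) directions no longer contributes to RX.
    """
    c = stats.n_channels
    if not 0 <= k < c:
        raise ValueError(f"k must satisfy 0 <= k < {c}, got {k}")
    w, v = _eigh_sorted(stats.cov)
    retained = np.zeros(c, dtype=bool)
    retained[: c - k] = True
    wr = w[retained]
    if wr.min() <= EIG_TOL * w.max():
        raise np.linalg.LinAlgError(
            "retained eigenvalues are numerically zero; increase k"
        )
    vr = v[:, retained]
    inv_op = (vr / wr) @ vr.T
    return ConditionedStats(
        mu=stats.mu.copy(),
        inv_op=_symmetrize(inv_op),
        method="delete_pc",
        params={"k": k},
        eigenvalues=w,
        retained=retained,
        cov=stats.cov.copy(),
    )


def shrink_target(cov: np.ndarray, mode: ShrinkMode) -> np.ndarray:
    if mode == "regularized":
        return np.diag(np.diag(cov))
    if mode == "modified_regularized":
        c = cov.shape[0]
        return (np.trace(cov) / c) * np.eye(c)
    raise ValueError(f"unknown shrinkage mode: {mode!r}")


def shrunk_cov(cov: np.ndarray, gamma: float, mode: ShrinkMode) -> np.ndarray:
    """``CM(gamma) = (1-gamma) * cov + gamma * D`` for the mode's target D."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return (1.0 - gamma) * cov + gamma * shrink_target(cov, mode)


def shrink(stats: BackgroundStats, gamma: float, mode: ShrinkMode) -> ConditionedStats:
    """Mix a diagonal target into the covariance and invert the result."""
    cm = shrunk_cov(stats.cov, gamma, mode)
    w, v = _eigh_sorted(cm)
    if w.min() <= EIG_TOL * w.max():
        raise np.linalg.LinAlgError(
            f"CM(gamma={gamma}) is singular; raise gamma above 0"
        )
    inv_op = (v / w) @ v.T
    return ConditionedStats(
        mu=stats.mu.copy(),
        inv_op=_symmetrize(inv_op),
        method=mode,
        params={"gamma": float(gamma)},
        eigenvalues=w,
        retained=np.ones_like(w, dtype=bool),
        cov=cm,
    )


def _gaussian_loglik(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """Mean Gaussian log-density of rows of x; -inf if cov is not PD."""
    c = mu.size
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return -np.inf
    try:
        sol = np.linalg.solve(cov, (x - mu).T)
    except np.linalg.LinAlgError:
        return -np.inf
    quad = np.einsum("ij,ij->j", (x - mu).T, sol)
    return float(np.mean(-0.5 * (quad + logdet + c * np.log(2.0 * np.pi))))


def select_gamma(
    cube,
    normal_mask: np.ndarray,
    mode: ShrinkMode,
    n_folds: int = 5,
    grid: np.ndarray = GAMMA_GRID,
) -> tuple[float, np.ndarray]:
    """Choose the shrinkage weight by K-fold cross-validated likelihood.

    For each gamma on the fixed grid, held-out background voxels are scored
    under the Gaussian fitted (mean, shrunk covariance) on the training
    folds; the gamma maximizing the mean held-out log-likelihood wins, ties
    going to the smaller gamma.  Returns ``(gamma_star, curve)`` with the
    full likelihood curve over the grid.
    """
    x = _masked_voxels(cube, normal_mask)
    n = x.shape[0]
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} voxels for {n_folds}-fold CV")
    # deterministic interleaved folds: voxel order is already arbitrary
    fold_of = np.arange(n) % n_folds
    curve = np.zeros(grid.size)
    for gi, g in enumerate(grid):
        ll = 0.0
        for f in range(n_folds):
            train, test = x[fold_of != f], x[fold_of == f]
            mu = train.mean(axis=0)
            cov = np.cov(train, rowvar=False, ddof=1)
            ll += _gaussian_loglik(test, mu, shrunk_cov(cov, g, mode))
        curve[gi] = ll / n_folds
    best = int(np.argmax(curve))  # argmax takes the first = smallest gamma
    return float(grid[best]), curve


def shrink_cv(cube, normal_mask: np.ndarray, mode: ShrinkMode) -> ConditionedStats:
    """Full shrinkage pipeline: select gamma by CV, then condition."""
    gamma, curve = select_gamma(cube, normal_mask, mode)
    stats = compute_stats(cube, normal_mask)
    cs = shrink(stats, gamma, mode)
    cs.params["likelihood_curve"] = curve
    cs.params["gamma_grid"] = np.asarray(GAMMA_GRID)
    return cs


def evm(
    cube,
    normal_mask: np.ndarray,
    trials: int = 100,
    seed: int = 0,
    drop_fraction: float = 0.1,
) -> ConditionedStats:
    """Elliptical volume minimization.

    Each trial drops ``drop_fraction`` of the masked voxels at random and
    records the covariance of the remaining voxels together with its
    ellipsoid volume (proportional to sqrt(det)).  The minimum-volume
    subset wins; aberrant voxels inflate the ellipsoid, so subsets that
    exclude them are preferred.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    x = _masked_voxels(cube, normal_mask)
    n, c = x.shape
    keep = n - int(round(drop_fraction * n))
    if keep <= c:
        raise ValueError(f"subset of {keep} voxels cannot support {c} channels")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    n_skipped = 0
    for _ in range(trials):
        idx = rng.choice(n, size=keep, replace=False)
        sub = x[idx]
        cov = np.cov(sub, rowvar=False, ddof=1)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            n_skipped += 1
            continue
        log_volume = 0.5 * logdet  # log of sqrt(det); monotone in the volume
        if best is None or log_volume < best[0]:
            best = (log_volume, sub.mean(axis=0), cov)
    if best is None:
        raise np.linalg.LinAlgError(
            f"all {trials} EVM trials produced rank-deficient covariances"
        )
    log_volume, mu, cov = best
    w, v = _eigh_sorted(cov)
    if w.min() <= EIG_TOL * w.max():
        raise np.linalg.LinAlgError("minimum-volume covariance is singular")
    inv_op = (v / w) @ v.T
    return ConditionedStats(
        mu=mu,
        inv_op=_symmetrize(inv_op),
        method="evm",
        params={
            "trials": trials,
            "seed": seed,
            "drop_fraction": drop_fraction,
            "min_log_volume": float(log_volume),
            "n_skipped": n_skipped,
        },
        eigenvalues=w,
        retained=np.ones_like(w, dtype=bool),
        cov=cov,
    )


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + a.T)


def condition(
    cube,
    normal_mask: np.ndarray,
    method: str,
    seed: int = 0,
) -> ConditionedStats:
    """Dispatch a conditioning method by name.

    Recognised names: ``unprocessed``, ``delete_pc_<k>``, ``regularized``,
    ``modified_regularized``, ``evm``.
    """
    if method == "unprocessed":
        return condition_unprocessed(compute_stats(cube, normal_mask))
    if method.startswith("delete_pc"):
        k = int(method.rsplit("_", 1)[1]) if method != "delete_pc" else 3
        return filter_pcs(compute_stats(cube, normal_mask), k)
    if method in ("regularized", "modified_regularized"):
        return shrink_cv(cube, normal_mask, method)  # type: ignore[arg-type]
    if method == "evm":
        return evm(cube, normal_mask, seed=seed)
    raise ValueError(f"unknown conditioning method: {method!r}")
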