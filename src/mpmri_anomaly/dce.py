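"""Voxel-wise DCE washout kinetics.

After contrast injection a voxel's signal rises to a peak (past ~50 s in
tumors) and then decays.  The post-peak tail is modelled as a single
exponential ``A * exp(-kep * (t - t_peak))``; ``kep`` (1/s) is the washout
rate, a surrogate for vascular efflux.  The decay is fitted in two
deterministic steps: a weighted log-linear regression (weights ``y^2``, the
exact linearization for additive noise) provides the starting point, and a
nonlinear least-squares refinement of ``(A, kep)`` in the intensity domain
brings the estimator close to the Cramér-Rao bound; both steps are exact on
noiseless curves.  The fit quality, the R^2 of the fitted exponential
clamped to [0, 1], is reported as the ``prob`` image: a bounded, monotone
goodness-of-washout score used as the seventh hypercube channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Washout fitting only uses samples strictly after this time (s) or after
#: the observed peak, whichever is later.
WASHOUT_START_S = 50.0


@dataclass
class WashoutFit:
    kep: float  # decay rate, 1/s (clamped >= 0)
    amplitude: float  # fitted signal at t_peak
    t_peak: float  # s, one of the sample times
    prob: float  # R^2 of the log-linear fit, in [0, 1]
    flags: list[str] = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        return bool(self.flags)


def find_peak_time(curve: np.ndarray, times: np.ndarray) -> tuple[float, str | None]:
    """Time of maximum intensity; ties break toward the earliest sample.

    Returns ``(t_peak, flag)`` where ``flag`` is None for a clean interior
    peak, ``"constant"`` for an all-constant curve (first time returned) and
    ``"no_washout"`` when the maximum sits at the final sample.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    if curve.size < 6:
        raise ValueError("need at least 6 samples to locate a peak")
    if np.ptp(curve) == 0:
        return float(times[0]), "constant"
    idx = int(np.argmax(curve))  # argmax returns the first maximum
    if idx == curve.size - 1:
        return float(times[idx]), "no_washout"
    return float(times[idx]), None


def _wls_loglinear(dt: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Weighted (w = y^2) linear fit of log(y) vs dt; returns (slope, intercept)."""
    ly = np.log(y)
    w = y * y
    w = w / w.sum()
    xm = float(w @ dt)
    ym = float(w @ ly)
    sxx = float(w @ ((dt - xm) ** 2))
    slope = float(w @ ((dt - xm) * (ly - ym))) / sxx
    return slope, ym - slope * xm


def fit_washout(
    curve: np.ndarray,
    times: np.ndarray,
    min_post_peak: int = 4,
    washout_start: float = WASHOUT_START_S,
) -> WashoutFit:
    """Exponential-decay fit of the post-peak samples.

    Samples strictly after ``max(t_peak, washout_start)`` enter the fit.
    A weighted log-linear regression (weights ``y^2``) seeds a nonlinear
    least-squares refinement of ``y = A * exp(-kep * (t - t_peak))``;
    ``kep`` is clamped at 0 and ``prob`` is the R^2 of the fitted
    exponential in the intensity domain, clamped to [0, 1].  Non-positive
    intensities are floored at half the smallest positive value of the
    curve before taking logs.  Under-determined or zero-variance cases
    return a flagged degenerate fit with ``kep = 0`` and ``prob = 0``.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    t_peak, peak_flag = find_peak_time(curve, times)
    flags = [peak_flag] if peak_flag else []

    start = max(t_peak, washout_start)
    post = times > start
    if int(post.sum()) < min_post_peak:
        return WashoutFit(0.0, 0.0, t_peak, 0.0, flags + ["insufficient_post_peak"])

    y = curve[post].copy()
    pos = y[y > 0]
    if pos.size == 0:
        return WashoutFit(0.0, 0.0, t_peak, 0.0, flags + ["nonpositive"])
    floor = 0.5 * pos.min()
    y[y <= 0] = floor
    dt = times[post] - t_peak

    if np.ptp(np.log(y)) == 0:  # flat tail: rate 0, R^2 degenerate by convention
        return WashoutFit(0.0, float(y[0]), t_peak, 0.0, flags)

    slope, intercept = _wls_loglinear(dt, y)
    a0, k0 = float(np.exp(intercept)), max(-slope, 0.0)
    a_hat, k_hat = a0, k0
    try:
        from scipy.optimize import curve_fit

        p, _ = curve_fit(
            lambda t, a, k: a * np.exp(-k * t),
            dt,
            y,
            p0=[max(a0, floor), k0],
            maxfev=200,
        )
        if np.all(np.isfinite(p)) and p[0] > 0:
            a_hat, k_hat = float(p[0]), float(p[1])
    except RuntimeError:
        flags = flags + ["refinement_failed"]

    kep = max(k_hat, 0.0)
    resid = y - a_hat * np.exp(-kep * dt)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return WashoutFit(
        kep=kep,
        amplitude=a_hat,
        t_peak=t_peak,
        prob=float(np.clip(r2, 0.0, 1.0)),
        flags=flags,
    )


def washout_maps(
    dce: np.ndarray,
    times: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Apply :func:`fit_washout` per voxel of a ``(T, ...)`` DCE stack.

    Returns ``(kep, prob, n_degenerate)`` where the maps share the spatial
    shape of the stack and voxels outside ``mask`` are zero.
    """
    dce = np.asarray(dce, dtype=float)
    times = np.asarray(times, dtype=float)
    if dce.shape[0] != times.size:
        raise ValueError("time axis length does not match times")
    spatial = dce.shape[1:]
    kep = np.zeros(spatial)
    prob = np.zeros(spatial)
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    n_degenerate = 0
    flat = dce.reshape(times.size, -1)
    midx = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
    kf, pf = kep.ravel(), prob.ravel()
    for j in midx:
        fit = fit_washout(flat[:, j], times)
        kf[j] = fit.kep
        pf[j] = fit.prob
        n_degenerate += fit.degenerate
    return kep, prob, n_degenerate
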