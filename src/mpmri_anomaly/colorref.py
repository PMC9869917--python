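"""Color-derived tumor reference masks.

An RGB display is composed from selected hypercube channels (by default the
DCE washout rate on red, the high-B diffusion image on green and ADC on
blue, so the archetypal lesion — fast washout, restricted diffusion —
renders yellow), converted to the device-independent CIELAB space, and thresholded on
yellowness.  In CIELAB the b* axis carries the blue-yellow opponent pair —
positive b* means yellow — and a voxel rendered bright red+green (fast
washout, good washout fit) lands at high b*.  Yellowness is normalized by
the b* of pure sRGB yellow so the dimensionless 0.35 cutoff is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

#: b* of pure sRGB yellow (1,1,0) under D65 — the yellowness normalizer.
B_STAR_YELLOW = float(skcolor.rgb2lab(np.array([[[1.0, 1.0, 0.0]]]))[0, 0, 2])

#: Default CIELAB reference-mask threshold on normalized yellowness.
CIELAB_THRESHOLD = 0.35
#: Default ACE reference-mask threshold.
ACE_THRESHOLD = 0.65


@dataclass
class LabImage:
    L: np.ndarray  # lightness, 0-100 for in-gamut input
    a: np.ndarray  # green(-) to red(+)
    b: np.ndarray  # blue(-) to yellow(+)


@dataclass
class ChannelColorMap:
    """Which channels feed the three color planes, with the percentile
    window used to robust-stretch each channel over the prostate."""

    red_source: str = "kep"
    green_source: str = "dwi_high_b"
    blue_source: str = "adc"
    percentiles: tuple[float, float] = (2.0, 98.0)

    def sources(self) -> tuple[str, str, str]:
        return self.red_source, self.green_source, self.blue_source


def _stretch(channel: np.ndarray, mask: np.ndarray, pcts) -> tuple[np.ndarray, bool]:
    lo, hi = np.percentile(channel[mask], pcts)
    if hi <= lo:  # constant channel: flagged, plane all zeros
        return np.zeros_like(channel, dtype=float), True
    return np.clip((channel - lo) / (hi - lo), 0.0, 1.0), False


def compose_rgb(
    cube,
    cmap: ChannelColorMap,
    prostate_mask: np.ndarray,
) -> tuple[np.ndarray, list[str]]:
    """Robust-stretched (rows, cols, 3) RGB in [0,1] plus degeneracy flags."""
    lo, hi = cmap.percentiles
    if not lo < hi:
        raise ValueError("percentile window must satisfy low < high")
    mask = np.asarray(prostate_mask, dtype=bool)
    planes, flags = [], []
    for name in cmap.sources():
        plane, const = _stretch(cube.channel(name), mask, cmap.percentiles)
        planes.append(plane)
        if const:
            flags.append(f"constant_channel:{name}")
    return np.stack(planes, axis=-1), flags


def rgb_to_lab(rgb: np.ndarray) -> LabImage:
    """sRGB -> linear RGB -> XYZ (D65) -> CIELAB, clamping out-of-range input."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.min() < 0 or rgb.max() > 1:
        import warnings

        warnings.warn("RGB values outside [0,1] clamped before Lab conversion")
        rgb = np.clip(rgb, 0.0, 1.0)
    lab = skcolor.rgb2lab(rgb)
    return LabImage(L=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


def yellowness(lab: LabImage) -> np.ndarray:
    """b* normalized by pure-yellow b*, clamped to [0, 1]."""
    return np.clip(lab.b / B_STAR_YELLOW, 0.0, 1.0)


def yellow_mask(
    lab: LabImage,
    prostate_mask: np.ndarray,
    threshold: float = CIELAB_THRESHOLD,
) -> np.ndarray:
    """CIELAB tumor reference: yellowness >= threshold, inside the prostate."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (yellowness(lab) >= threshold) & np.asarray(prostate_mask, dtype=bool)


def ace_reference(
    ace_scores: np.ndarray,
    prostate_mask: np.ndarray,
    threshold: float = ACE_THRESHOLD,
):
    """ACE tumor reference: score >= threshold (inclusive), inside the prostate."""
    scores = getattr(ace_scores, "scores", ace_scores)
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(scores) >= threshold) & np.asarray(prostate_mask, dtype=bool)


def cielab_reference(
    cube,
    prostate_mask: np.ndarray,
    cmap: ChannelColorMap | None = None,
    threshold: float = CIELAB_THRESHOLD,
) -> np.ndarray:
    """Convenience: compose RGB, convert to Lab, threshold yellowness."""
    rgb, _ = compose_rgb(cube, cmap or ChannelColorMap(), prostate_mask)
    return yellow_mask(rgb_to_lab(rgb), prostate_mask, threshold)
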