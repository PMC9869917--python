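"""Spatially registered hypercube assembly.

Individual MRI channels arrive as per-slice grids at possibly different
in-plane resolutions.  They are resampled to a common grid (bilinear for
intensities, nearest-neighbour for masks), rigidly translated by small
in-plane offsets, and finally the per-slice 7-channel cubes are stitched
side-by-side into one wide mosaic — a layout trick borrowed from remote
sensing that lets every purely spectral computation (background statistics,
RX, ACE) run once over a single 2D grid instead of slice by slice.

Conventions: 0-based row/column indices, row-major arrays; masks are boolean
grids on the identical lattice; slice spacing is carried as metadata only
(no through-slice processing ever happens).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class ChannelStack:
    """One modality: ``data`` is ``(n_slices, rows, cols)`` intensities."""

    data: np.ndarray
    in_plane_resolution: float  # mm per voxel, isotropic in-plane
    channel_name: str
    slice_spacing: float = 6.0  # mm, metadata only

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ChannelStack data must be (n_slices, rows, cols)")


def resample_to_grid(stack: ChannelStack, target_mm: float) -> ChannelStack:
    """Bilinearly resample every slice to ``target_mm`` in-plane resolution."""
    if target_mm <= 0:
        raise ValueError("target resolution must be positive")
    if stack.in_plane_resolution <= 0:
        raise ValueError("stack resolution must be positive")
    factor = stack.in_plane_resolution / target_mm
    if factor == 1.0:
        return replace(stack, data=stack.data.copy())
    out = np.stack(
        [
            ndimage.zoom(sl, factor, order=1, mode="nearest", grid_mode=True)
            for sl in stack.data
        ]
    )
    return replace(stack, data=out, in_plane_resolution=target_mm)


def translate_rigid(
    stack: ChannelStack,
    offset_mm: tuple[float, float],
    fill: float | None = None,
) -> ChannelStack:
    """Shift every slice by ``offset_mm`` (row, col); linear interpolation.

    Out-of-field voxels take ``fill``; by default the slice median, which
    avoids manufacturing border anomalies downstream.
    """
    dv = np.asarray(offset_mm, dtype=float) / stack.in_plane_resolution
    out = np.empty_like(stack.data)
    for i, sl in enumerate(stack.data):
        cval = float(np.median(sl)) if fill is None else float(fill)
        out[i] = ndimage.shift(sl, dv, order=1, mode="constant", cval=cval)
    return replace(stack, data=out)


def stacks_to_slices(stacks: list[ChannelStack]) -> list[np.ndarray]:
    """Merge registered channel stacks into per-slice (rows, cols, C) cubes."""
    shapes = {s.data.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError(f"channel stacks disagree in shape: {shapes}")
    return list(np.stack([s.data for s in stacks], axis=-1))


@dataclass
class Hypercube:
    """The stitched mosaic: ``data`` is ``(rows, cols, C)``.

    ``provenance`` records ``(slice_id, column_offset)`` for every stitched
    slice so the mosaic can be taken apart again exactly.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    provenance: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Hypercube data must be (rows, cols, C)")
        if self.data.shape[-1] != len(self.channel_names):
            raise ValueError("channel_names length must match last axis")

    @property
    def n_channels(self) -> int:
        return self.data.shape[-1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[..., self.channel_names.index(name)]

    def validate_finite(self, mask: np.ndarray) -> None:
        if not np.all(np.isfinite(self.data[mask])):
            raise ValueError("non-finite values inside the prostate mask")


def stitch_cubes(
    slices: list[np.ndarray],
    masks: dict[str, list[np.ndarray]] | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> tuple[Hypercube, dict[str, np.ndarray]]:
    """Concatenate per-slice cubes side-by-side along the column axis.

    ``masks`` maps a mask name to one boolean grid per slice; each is
    stitched with the identical layout.  Stitching is a pure re-layout:
    voxel sets, and hence any pooled statistic, are preserved.
    """
    if not slices:
        raise ValueError("no slices to stitch")
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"slices disagree in shape: {shapes}")
    if channel_names is None:
        from .phantom import CHANNELS

        channel_names = CHANNELS
    if slices[0].shape[-1] != len(channel_names):
        raise ValueError("slice channel count does not match channel_names")
    width = slices[0].shape[1]
    provenance = [(i, i * width) for i in range(len(slices))]
    cube = Hypercube(
        data=np.concatenate(slices, axis=1),
        channel_names=tuple(channel_names),
        provenance=provenance,
    )
    stitched_masks: dict[str, np.ndarray] = {}
    if masks:
        for name, per_slice in masks.items():
            if len(per_slice) != len(slices):
                raise ValueError(f"mask '{name}' slice count mismatch")
            if any(m.shape != slices[0].shape[:2] for m in per_slice):
                raise ValueError(f"mask '{name}' shape mismatch")
            stitched_masks[name] = np.concatenate(
                [np.asarray(m, dtype=bool) for m in per_slice], axis=1
            )
    return cube, stitched_masks


def unstitch(cube: Hypercube) -> list[np.ndarray]:
    """Invert :func:`stitch_cubes` exactly, using the recorded provenance."""
    if not cube.provenance:
        return [cube.data.copy()]
    offsets = [off for _, off in cube.provenance] + [cube.data.shape[1]]
    return [
        cube.data[:, offsets[i] : offsets[i + 1]].copy()
        for i in range(len(cube.provenance))
    ]


def unstitch_mask(mask: np.ndarray, cube: Hypercube) -> list[np.ndarray]:
    offsets = [off for _, off in cube.provenance] + [mask.shape[1]]
    return [
        mask[:, offsets[i] : offsets[i + 1]].copy()
        for i in range(len(cube.provenance))
    ]


# ---------------------------------------------------------------------------
# NIfTI I/O.  Channels live on the 4th axis of a 4D volume; masks are {0,1}
# uint8 volumes.  The affine encodes the in-plane resolution.


def save_cube_nifti(path, cube: Hypercube, resolution_mm: float = 1.0) -> None:
    affine = np.diag([resolution_mm, resolution_mm, 1.0, 1.0])
    data = cube.data[:, :, None, :].astype(np.float32)  # rows, cols, 1, C
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = ",".join(cube.channel_names)[:79].encode()
    nib.save(img, str(path))


def load_cube_nifti(path, channel_names: tuple[str, ...] | None = None) -> Hypercube:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        data = data[:, :, 0, :]
    if channel_names is None:
        desc = img.header["descrip"].tobytes().split(b"\x00")[0].decode()
        channel_names = tuple(desc.split(",")) if desc else tuple(
            f"ch{i}" for i in range(data.shape[-1])
        )
    return Hypercube(data=data, channel_names=channel_names)


def save_image_nifti(path, image: np.ndarray, resolution_mm: float = 1.0) -> None:
    affine = np.diag([resolution_mm, resolution_mm, 1.0, 1.0])
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(np.float32)
    nib.save(nib.Nifti1Image(arr[:, :, None], affine), str(path))


def load_image_nifti(path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj)
    return np.squeeze(data, axis=2) if data.ndim == 3 else data


def load_mask_nifti(path) -> np.ndarray:
    return load_image_nifti(path) > 0.5
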