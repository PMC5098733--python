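"""In-memory carriers for image series and parameter maps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import FormatError
from .protocol import VoxelGrid

__all__ = ["ContrastAxis", "ImageStack", "ParameterMap"]

_AXIS_KINDS = ("echo", "flip", "bvalue-direction", "time")


@dataclass(frozen=True)
class ContrastAxis:
    """Semantic label and coordinate values of the 4th (contrast) dimension.

    ``kind`` is one of ``echo`` (TE in ms), ``flip`` (nominal flip angle in
    degrees), ``bvalue-direction`` (pairs of (direction index, b-value)),
    or ``time`` (frame time in s).
    """

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in _AXIS_KINDS:
            raise FormatError(f"unknown contrast axis kind {self.kind!r}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return int(self.values.shape[0])


@dataclass
class ImageStack:
    """A voxel grid with one extra contrast dimension.

    ``frames`` has shape ``(nx, ny, nz, n_contrast)`` and carries signal in
    arbitrary units; the contrast axis says what varies across the 4th
    dimension (echo time, flip angle, b-value/direction, or frame time).
    """

    grid: VoxelGrid
    frames: np.ndarray
    contrast_axis: ContrastAxis

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 3:
            self.frames = self.frames[..., np.newaxis]
        if self.frames.shape[:3] != self.grid.shape:
            raise FormatError(
                f"frame grid {self.frames.shape[:3]} does not match "
                f"declared grid {self.grid.shape}"
            )
        if self.frames.shape[3] != len(self.contrast_axis):
            raise FormatError(
                f"stack has {self.frames.shape[3]} frames but the contrast "
                f"axis lists {len(self.contrast_axis)} coordinates"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[3]


@dataclass
class ParameterMap:
    """Per-voxel scalar map with a unit tag and a validity mask.

    Voxels where the fit failed or diverged are marked invalid in
    ``valid_mask`` and carry NaN in ``values`` — never a silent zero.
    """

    grid: VoxelGrid
    values: np.ndarray
    unit: str
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise FormatError(
                f"map shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise FormatError("valid_mask shape does not match values")
            # invariant: non-finite values are never marked valid
            self.valid_mask &= np.isfinite(self.values)
        self.values = np.where(self.valid_mask, self.values, np.nan)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def reciprocal(self, unit: str, scale: float = 1000.0) -> "ParameterMap":
        """Convert a relaxation time map (ms) to a rate map (s^-1) or back.

        R [s^-1] = scale / T [ms] with scale = 1000; the same call inverts.
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            values = scale / self.values
        return ParameterMap(self.grid, values, unit, self.valid_mask & (self.values != 0))

    def plot(self, slice_index: int | None = None, ax=None, **imshow_kwargs):
        """Show one axial slice with invalid voxels masked out."""
        import matplotlib.pyplot as plt

        if slice_index is None:
            slice_index = self.grid.nz // 2
        if ax is None:
            _, ax = plt.subplots()
        data = np.ma.masked_invalid(self.values[:, :, slice_index].T)
        im = ax.imshow(data, origin="lower", **imshow_kwargs)
        ax.set_title(f"{self.unit}, slice {slice_index}")
        plt.colorbar(im, ax=ax)
        return ax
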