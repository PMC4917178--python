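"""3D image stacks with anisotropic physical voxel spacing.

The whole pipeline operates on :class:`ImageStack`: a ``(z, y, x)``-indexed
grid of non-negative intensities together with a :class:`VoxelSpacing` giving
the physical size of one voxel in micrometres.  Confocal stacks are strongly
anisotropic — the reference spacing of 0.691 x 0.691 x 1.75 um reflects a
point-spread function that extends much further axially than laterally — so
the spacing is carried explicitly and never inferred silently from file
metadata.

Physical coordinates are reported as ``(x, y, z)`` in um with voxel centers
at ``(i + 0.5) * spacing`` along each axis.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelSpacing",
    "REFERENCE_SPACING",
    "ImageStack",
    "read_stack",
    "write_stack",
    "write_centroids",
    "read_centroids",
]


@dataclasses.dataclass(frozen=True)
class VoxelSpacing:
    """Physical size of one voxel, in micrometres per voxel."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"voxel spacing must be strictly positive, got {self}")

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    def as_zyx(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)


#: Reference confocal acquisition spacing (um), 40x/1.0 NA water objective.
REFERENCE_SPACING = VoxelSpacing(0.691, 0.691, 1.75)


@dataclasses.dataclass
class ImageStack:
    """A 3D grayscale stack indexed ``(z, y, x)`` with physical spacing.

    Parameters
    ----------
    voxels
        3D array of finite, non-negative intensities.
    spacing
        Physical voxel size in um.
    bit_depth
        Informational; 8 or 16.  Processing is done in float64 regardless.
    """

    voxels: np.ndarray
    spacing: VoxelSpacing
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.voxels.ndim}")
        if self.voxels.size == 0:
            raise ValueError("stack must contain at least one voxel")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("stack intensities must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def physical_size_um(self) -> tuple[float, float, float]:
        """Extent of the stack as (X, Y, Z) in um."""
        nz, ny, nx = self.voxels.shape
        return (nx * self.spacing.dx, ny * self.spacing.dy, nz * self.spacing.dz)

    def astype_float(self) -> "ImageStack":
        return ImageStack(self.voxels.astype(np.float64), self.spacing, self.bit_depth)

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return ImageStack(voxels, self.spacing, self.bit_depth)


def read_stack(path: str | Path, spacing: VoxelSpacing) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    The voxel spacing is an explicit argument: TIFF resolution tags are noisy
    in practice and are never trusted silently.  RGB and float TIFFs are
    rejected — converting them implicitly would corrupt intensity statistics
    (and channel mixing would invalidate two-channel evaluation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TIFF stack: {path}")
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        if "S" in series.axes or series.axes.endswith("C"):
            raise ValueError(
                f"{path}: RGB/multichannel TIFF (axes {series.axes!r}); "
                "split channels before segmentation."
            )
        data = series.asarray()
    if data.ndim == 2:
        data = data[np.newaxis, :, :]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale stack (pages x H x W); got shape {data.shape}. "
            "RGB/multichannel TIFFs are not supported — split channels first."
        )
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(
            f"{path}: float TIFF without a conversion rule; convert to 8/16-bit first."
        )
    bit_depth = 16 if data.dtype.itemsize > 1 else 8
    return ImageStack(data, spacing, bit_depth)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack (or integer label mask) as a multi-page TIFF.

    Integer data round-trips voxel-exactly through :func:`read_stack`.
    """
    path = Path(path)
    data = stack.voxels
    if np.issubdtype(data.dtype, np.integer):
        out = data.astype(np.uint8 if data.max(initial=0) < 256 and stack.bit_depth == 8 else np.uint16)
    else:
        out = data.astype(np.uint16) if stack.bit_depth == 16 else data.astype(np.uint8)
    tifffile.imwrite(path, out, photometric="minisblack")


def write_centroids(table: pd.DataFrame, path: str | Path) -> None:
    """Write a centroid table as CSV with a fixed header and row order.

    Columns: ``object_id, x_um, y_um, z_um, volume_voxels``; rows sorted by
    ``object_id`` so outputs are diffable across runs.
    """
    cols = ["object_id", "x_um", "y_um", "z_um", "volume_voxels"]
    if list(table.columns) != cols:
        table = table[cols]
    if table["object_id"].duplicated().any():
        raise ValueError("object_id values must be unique")
    table = table.sort_values("object_id", kind="stable")
    table.to_csv(path, index=False)


def read_centroids(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def centroid_table(objects) -> pd.DataFrame:
    """Build a centroid table from a list of segmented objects."""
    rows = [
        {
            "object_id": o.object_id,
            "x_um": o.centroid_um[0],
            "y_um": o.centroid_um[1],
            "z_um": o.centroid_um[2],
            "volume_voxels": o.volume,
        }
        for o in objects
    ]
    return pd.DataFrame(rows, columns=["object_id", "x_um", "y_um", "z_um", "volume_voxels"])
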