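"""Conversion of 3D confocal-style image stacks into nuclei tables.

This is the in-package stand-in for interactive spot detection: a global
threshold on the nuclei channel, 26-connected component labelling, and
intensity-weighted centroids, followed by per-nucleus marker-channel
classification.  It is deliberately simple — adequate for well-separated
nuclei; touching nuclei are not split (no watershed), which is a
documented limitation.

Stacks are stored as (z, y, x) arrays per channel with a physical voxel
size in μm; centroids are reported in physical μm as (x_um, y_um, z_um)
with the origin at the stack corner and voxel centers at half-integer
multiples of the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage import measure

__all__ = ["ImageStack", "segment_nuclei", "classify_marker", "read_stack", "write_stack"]


@dataclass
class ImageStack:
    """Multi-channel 3D intensity stack.

    ``channels`` maps channel name (nuclei, ki67, caspase, dead, ...) to
    a (z, y, x) float array; all channels share one shape.
    ``voxel_size`` is (dx, dy, dz) in μm.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def require(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"stack has no channel {name!r}")
        return self.channels[name]


def segment_nuclei(
    stack: ImageStack,
    threshold: float,
    min_voxels: int = 5,
    *,
    condition: str = "unknown",
    cell_type: str = "cancer",
    t_h: float = 0.0,
) -> pd.DataFrame:
    """Detect nuclei in the ``nuclei`` channel and return a centroid table.

    Voxels above ``threshold`` are grouped into 26-connected components;
    components of at least ``min_voxels`` voxels become one nucleus each,
    with an intensity-weighted centroid mapped to physical μm.
    """
    img = stack.require("nuclei")
    mask = img > threshold
    labels = measure.label(mask, connectivity=3)
    props = measure.regionprops(labels, intensity_image=img)
    dx, dy, dz = stack.voxel_size
    rows = []
    nucleus_id = 0
    for p in props:
        if p.area < min_voxels:
            continue
        cz, cy, cx = p.centroid_weighted
        rows.append(
            {
                "id": nucleus_id,
                "t_h": t_h,
                "x_um": (cx + 0.5) * dx,
                "y_um": (cy + 0.5) * dy,
                "z_um": (cz + 0.5) * dz,
                "condition": condition,
                "cell_type": cell_type,
            }
        )
        nucleus_id += 1
    columns = ["id", "t_h", "x_um", "y_um", "z_um", "condition", "cell_type"]
    return pd.DataFrame(rows, columns=columns)


def classify_marker(
    stack: ImageStack,
    table: pd.DataFrame,
    marker: str,
    radius: float,
    threshold: float,
) -> pd.DataFrame:
    """Flag each nucleus whose mean marker intensity near its centroid
    exceeds ``threshold``.

    The marker signal is averaged over voxels within ``radius`` μm of
    the centroid; the returned copy of the table gains a 0/1 column
    named after the marker channel.
    """
    img = stack.require(marker)
    dx, dy, dz = stack.voxel_size
    nz, ny, nx = img.shape
    zz, yy, xx = np.meshgrid(
        (np.arange(nz) + 0.5) * dz,
        (np.arange(ny) + 0.5) * dy,
        (np.arange(nx) + 0.5) * dx,
        indexing="ij",
    )
    out = table.copy()
    flags = np.zeros(len(table), dtype=int)
    for i, row in enumerate(table.itertuples(index=False)):
        dist2 = (xx - row.x_um) ** 2 + (yy - row.y_um) ** 2 + (zz - row.z_um) ** 2
        ball = dist2 <= radius**2
        if ball.any():
            flags[i] = int(img[ball].mean() > threshold)
    out[marker] = flags
    return out


def read_stack(path: str | Path, channel_names: list[str], voxel_size: tuple[float, float, float]) -> ImageStack:
    """Load a (channel, z, y, x) multi-page TIFF into an ImageStack."""
    data = tifffile.imread(str(path))
    if data.ndim == 3:
        data = data[None]
    if data.shape[0] != len(channel_names):
        raise ValueError(
            f"TIFF has {data.shape[0]} channels but {len(channel_names)} names given"
        )
    channels = {name: data[i].astype(float) for i, name in enumerate(channel_names)}
    return ImageStack(channels=channels, voxel_size=voxel_size)


def write_stack(stack: ImageStack, path: str | Path, channel_order: list[str] | None = None) -> None:
    """Write channels as a (channel, z, y, x) TIFF."""
    names = channel_order or sorted(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(str(path), data, metadata={"channels": names})
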