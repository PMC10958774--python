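"""Deterministic known-answer inputs for the metrics and pipeline rules.

Every generator ships with an analytically known answer (pixel area, sector
count, occupancy, slope), so the whole metrics suite is testable without
any real microscopy data.  Rasterization follows the same pixel/voxel
center-inside convention as the morphometrics reference circle, making the
known answers exact rather than approximate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .morphometrics import ProjectionImage, SurfaceMask, VoxelGeometry

__all__ = [
    "make_rasterized_disk",
    "make_sphere_shell",
    "paint_sectors",
    "make_two_channel_pair",
    "make_sector_series",
]


def make_rasterized_disk(radius_px: float,
                         pixel_size: float = 1.0) -> ProjectionImage:
    """Disk of pixels whose centers lie within ``radius_px`` of a pixel center."""
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    half = int(np.ceil(radius_px)) + 1
    ax = np.arange(-half, half + 1)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    return ProjectionImage(d2 <= radius_px**2, pixel_size=(pixel_size, pixel_size))


def _shell_distances(radius_vox: float):
    half = int(np.ceil(radius_vox)) + 2
    ax = np.arange(-half, half + 1, dtype=float)
    d = np.sqrt(
        ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    )
    return d


def make_sphere_shell(radius_vox: float, thickness: float = 1.0,
                      color: int = 1) -> np.ndarray:
    """Hollow voxel sphere: centers at distance in [radius - thickness, radius].

    Connected under 6-connectivity for radius >= 3; the center stays empty.
    """
    if radius_vox < 2:
        raise ValueError("radius must be >= 2")
    d = _shell_distances(radius_vox)
    shell = (d >= radius_vox - thickness) & (d <= radius_vox)
    return np.where(shell, np.int32(color), np.int32(0))


def paint_sectors(
    shell: np.ndarray,
    layout: str = "wedges",
    k: int = 4,
    seed: int | None = None,
    geometry: VoxelGeometry | None = None,
) -> SurfaceMask:
    """Color a shell volume into sectors with known ground truth.

    layout='wedges'
        k meridian wedges (about the z axis), each its own color 1..k —
        exactly k connected sectors.
    layout='hemispheres'
        color 1 for z >= center, color 2 below — occupancy 1/2 per color up
        to the equatorial voxel ring.
    layout='random'
        i.i.d. color 1 or 2 per voxel (seeded).
    """
    coords = np.argwhere(shell != 0)
    if coords.shape[0] == 0:
        raise ValueError("shell volume is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > coords.shape[0]:
        raise ValueError("more wedges than shell voxels")
    center = (np.array(shell.shape) - 1) / 2.0
    rel = coords - center
    if layout == "wedges":
        theta = np.arctan2(rel[:, 1], rel[:, 0])  # (-pi, pi]
        frac = (theta + np.pi) / (2 * np.pi)
        colors = np.minimum((frac * k).astype(np.int64), k - 1) + 1
    elif layout == "hemispheres":
        colors = np.where(rel[:, 2] >= 0, 1, 2)
    elif layout == "random":
        rng = np.random.default_rng(seed)
        colors = rng.integers(1, 3, size=coords.shape[0])
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return SurfaceMask(
        coords=coords,
        colors=colors.astype(np.int32),
        shape=shell.shape,
        geometry=geometry or VoxelGeometry(),
    )


def make_two_channel_pair(
    radius_vox: float = 8.0,
    overlap_rings: int = 1,
    geometry: VoxelGeometry | None = None,
):
    """Two binary channel volumes from a hemisphere-painted shell.

    The green channel claims the upper hemisphere, red the lower; a band of
    ``overlap_rings`` voxel layers around the equator is claimed by both,
    exercising the double-label resolution rule.
    """
    shell = make_sphere_shell(radius_vox)
    coords = np.argwhere(shell != 0)
    cz = (shell.shape[2] - 1) / 2.0
    z = coords[:, 2] - cz
    green = np.zeros(shell.shape, dtype=bool)
    red = np.zeros(shell.shape, dtype=bool)
    green[tuple(coords[z >= 0].T)] = True
    red[tuple(coords[z <= 0].T)] = True
    if overlap_rings > 0:
        band = np.abs(z) <= overlap_rings
        green[tuple(coords[band].T)] = True
        red[tuple(coords[band].T)] = True
    from .mask_pipeline import ChannelVolumePair

    return ChannelVolumePair(green=green, red=red,
                             geometry=geometry or VoxelGeometry())


def make_sector_series(
    sigma0: float = 120.0,
    merge_rate: float = 10.0,
    split_rate: float = 1.0,
    floor: float = 5.0,
    noise: float = 0.0,
    t_max: float = 40.0,
    dt: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic ensemble-mean sector count with known structure.

    sigma(t) = max(floor, sigma0 - merge_rate * t) + split_rate * t plus
    i.i.d. Gaussian noise: a merging decay crossing over to a linear
    splitting branch of known slope, the ground truth for the fit-window
    logic.
    """
    if merge_rate < 0 or split_rate < 0:
        raise ValueError("rates must be nonnegative")
    t = np.arange(0.0, t_max + dt / 2, dt)
    sigma = np.maximum(floor, sigma0 - merge_rate * t) + split_rate * t
    if noise > 0:
        rng = np.random.default_rng(seed)
        sigma = sigma + rng.normal(0.0, noise, size=t.size)
    return pd.DataFrame({"t": t, "sigma_mean": sigma})
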