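"""Shared in-memory containers for image and point-pattern data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = ["VoxelVolume", "SynapseImage", "PointPattern"]


@dataclass
class VoxelVolume:
    """3D grid (z, y, x axis order) with anisotropic voxel spacing.

    ``voxel_size_nm`` is given as (x, y, z) edge lengths in nm.  Physical
    coordinates follow the voxel-center convention:
    ``coord = (index + 0.5) * voxel_size``.
    """

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float] = (43.0, 43.0, 120.0)
    volume_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VoxelVolume expects a 3D array (z, y, x)")
        if any(s <= 0 for s in self.voxel_size_nm):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_nm3(self) -> float:
        sx, sy, sz = self.voxel_size_nm
        return sx * sy * sz


@dataclass
class SynapseImage:
    """Two-channel en-face 2D image of a single synapse with its ROI mask."""

    ch1: np.ndarray
    ch2: np.ndarray
    roi_mask: np.ndarray
    pixel_size_nm: float = 25.0
    synapse_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.ch1.shape != self.ch2.shape or self.ch1.shape != self.roi_mask.shape:
            raise ValueError("channels and ROI mask must share one shape")
        if not self.roi_mask.any():
            raise ValueError("ROI mask is empty")


@dataclass
class PointPattern:
    """2D particle coordinates (nm) with marks inside an observation window.

    ``coords`` is (n, 2) as (x, y) in nm; ``marks`` may carry per-particle
    area (nm^2) and intensity columns; ``window`` is the ROI polygon in nm.
    """

    coords: np.ndarray
    window: Polygon
    marks: pd.DataFrame = field(default_factory=pd.DataFrame)
    channel: int = 1
    synapse_id: str = ""

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 2)
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")

    @property
    def n(self) -> int:
        return self.coords.shape[0]
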