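"""Shared array containers: 3D tomographic volumes, 2D elemental maps, label maps.

Axis convention is 0-based ``(z, y, x)`` for volumes and ``(y, x)`` for maps.
Units are tracked explicitly on every container so that downstream arithmetic
can refuse physically meaningless operations (e.g. dividing counts by mmol/cm2).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: unit tags for Volume data
VOLUME_UNITS = ("raw", "HU", "mg/cc")
#: unit tags for ElementMap data
MAP_UNITS = ("counts", "mmol/cm2", "mmol/cm3")


@dataclass
class Volume:
    """A 3D scalar voxel grid with voxel-size metadata.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``.
    voxel_size_um
        Isotropic voxel edge length in micrometres.
    units
        One of ``"raw"`` (detector intensity), ``"HU"`` (air = 0, water = 1000)
        or ``"mg/cc"`` (hydroxyapatite-equivalent mineral density).
    """

    data: np.ndarray
    voxel_size_um: float = 3.84
    units: str = "raw"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.units not in VOLUME_UNITS:
            raise ValueError(f"units must be one of {VOLUME_UNITS}, got {self.units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3


@dataclass
class ElementMap:
    """A 2D per-element raster (XRF map) with unit bookkeeping.

    ``units`` moves ``counts -> mmol/cm2 -> mmol/cm3`` through the
    quantification chain; any arithmetic between maps of differing units or
    geometry is rejected by the consumers in :mod:`mineralmap.ratios`.
    """

    element: str
    data: np.ndarray
    units: str = "counts"
    pixel_size_um: float = 1.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"ElementMap data must be 2D, got shape {self.data.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.units not in MAP_UNITS:
            raise ValueError(f"units must be one of {MAP_UNITS}, got {self.units!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelMap:
    """Integer segment labels over a volume (0 = outside the analysis mask)."""

    labels: np.ndarray
    mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.mask is None:
            self.mask = self.labels > 0
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.labels.shape:
            raise ValueError("mask shape must match labels shape")

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels[self.mask])
        return ids[ids > 0]
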