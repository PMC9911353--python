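"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .geometry import Frame3D

__all__ = ["VolumeStack", "ProjectedImage", "MODALITIES"]

#: Recognised 2D image modalities.
MODALITIES = ("LM_via_FIB", "FIB", "SEM", "TEM", "LM_topdown")


@dataclass
class VolumeStack:
    """A 3D multichannel intensity grid with physical calibration.

    ``data`` has shape (C, Z, Y, X); ``frame`` holds origin and per-axis
    voxel pitch; ``channels`` are the channel labels ("BF" is the
    reflected-light bright-field channel by convention).
    """

    data: np.ndarray
    frame: Frame3D
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) data, got shape {self.data.shape}")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} channels"
            )
        self.channels = tuple(self.channels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(label)]
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channels}") from None

    def extent_um(self) -> np.ndarray:
        """Physical extent (x, y, z) spanned by voxel centers, µm."""
        nz, ny, nx = self.shape_zyx
        sx, sy, sz = self.frame.voxel_size_um
        return np.array([(nx - 1) * sx, (ny - 1) * sy, (nz - 1) * sz])


@dataclass
class ProjectedImage:
    """A calibrated 2D image (per-channel) with projection provenance.

    ``data`` has shape (C, H, W); rows run along the second projection
    axis (b / u2) and columns along the first (a / u1).  ``origin_um``
    gives the plane coordinates (a, b) of pixel (row 0, col 0) so pixel
    and physical coordinates are interconvertible.
    """

    data: np.ndarray
    pixel_size_um: float
    modality: str
    channels: tuple[str, ...] = ("0",)
    origin_um: tuple[float, float] = (0.0, 0.0)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"expected (C, H, W) data, got shape {self.data.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if len(self.channels) != self.data.shape[0]:
            self.channels = tuple(str(i) for i in range(self.data.shape[0]))
        self.channels = tuple(self.channels)

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(label)]
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channels}") from None

    def px_to_um(self, xy_px: np.ndarray) -> np.ndarray:
        """Pixel (col, row) -> plane coordinates (a, b) in µm."""
        q = np.asarray(xy_px, dtype=float)
        a0, b0 = self.origin_um
        return np.stack(
            [a0 + q[..., 0] * self.pixel_size_um, b0 + q[..., 1] * self.pixel_size_um],
            axis=-1,
        )

    def um_to_px(self, ab_um: np.ndarray) -> np.ndarray:
        """Plane coordinates (a, b) µm -> fractional pixel (col, row)."""
        q = np.asarray(ab_um, dtype=float)
        a0, b0 = self.origin_um
        return np.stack(
            [(q[..., 0] - a0) / self.pixel_size_um, (q[..., 1] - b0) / self.pixel_size_um],
            axis=-1,
        )
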