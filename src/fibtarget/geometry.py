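"""Coordinate conventions and the milling-direction projection map.

Package-wide coordinate convention
----------------------------------
Right-handed Cartesian frame in micrometres:

* ``x`` — the stage tilt axis,
* ``y`` — in-plane, perpendicular to the tilt axis,
* ``z`` — the sample-plane normal, pointing toward the light objective.

Image and volume arrays are indexed ``[z, y, x]`` (``[row, col]`` = ``[y, x]``
for 2D images); pixel/voxel *centers* sit at integer indices, index (0,0,0)
at the frame origin.  All angles are in degrees at the API surface.

The ion beam descends onto the sample plane at the milling angle ``beta``
(the angle between the beam and the plane).  For beam azimuth 0 the beam
lies in the y–z plane and its unit direction is ``v = (0, cos β, −sin β)``.
The projection plane is spanned by the orthonormal pair

* ``u1 = (1, 0, 0)`` (the tilt axis), and
* ``u2 = (0, sin β, cos β)``,

so a point ``p`` projects to image-plane coordinates ``(p·u1, p·u2)``.
In-plane distances along ``u2`` are foreshortened by exactly ``sin β``;
depth differences map onto ``u2`` with factor ``cos β``.  A nonzero beam
azimuth rotates all three vectors about ``z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MillingGeometry", "Frame3D", "projection_basis", "project_point"]


@dataclass(frozen=True)
class MillingGeometry:
    """Ion-beam/stage geometry during milling.

    Parameters
    ----------
    milling_angle_deg:
        Angle β between the ion beam and the sample plane, degrees;
        must satisfy 0 < β ≤ 90 (β = 90 is the top-down limit).  All
        projection math uses β.
    stage_tilt_deg:
        Stage tilt α during milling, degrees.  Carried as metadata only;
        the α→β offset is instrument specific and never derived here.
    beam_azimuth_deg:
        In-plane direction of the beam's horizontal component, degrees;
        0 means the beam lies in the y–z plane.
    fov_um, image_px:
        Side length (µm) and pixel count of the square ion-beam image.
    """

    milling_angle_deg: float = 18.0
    stage_tilt_deg: float | None = 17.0
    beam_azimuth_deg: float = 0.0
    fov_um: float = 84.0
    image_px: int = 1536

    def __post_init__(self) -> None:
        if not 0.0 < self.milling_angle_deg <= 90.0:
            raise ValueError(
                f"milling_angle_deg must lie in (0, 90], got {self.milling_angle_deg}"
            )
        if self.fov_um <= 0 or self.image_px <= 0:
            raise ValueError("fov_um and image_px must be positive")

    @property
    def pixel_size_um(self) -> float:
        return self.fov_um / self.image_px

    @property
    def beta_rad(self) -> float:
        return float(np.deg2rad(self.milling_angle_deg))

    @property
    def foreshortening(self) -> float:
        """sin β — apparent compression of in-plane distances along u2."""
        return float(np.sin(self.beta_rad))


@dataclass(frozen=True)
class Frame3D:
    """Sampling frame of a 3D stack: origin and per-axis voxel pitch (µm).

    Axis order of the attached arrays is ``[z, y, x]``; ``voxel_size_um``
    is given as ``(sx, sy, sz)``.  Anisotropic stacks (sz != sx) are the
    normal confocal case.
    """

    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.3)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size_um):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size_um}")

    @property
    def is_isotropic(self) -> bool:
        sx, sy, sz = self.voxel_size_um
        return sx == sy == sz

    def index_to_um(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Voxel index (z, y, x) -> physical position (x, y, z) in µm."""
        idx = np.asarray(idx_zyx, dtype=float)
        sx, sy, sz = self.voxel_size_um
        ox, oy, oz = self.origin_um
        return np.stack(
            [ox + idx[..., 2] * sx, oy + idx[..., 1] * sy, oz + idx[..., 0] * sz],
            axis=-1,
        )

    def um_to_index(self, pos_xyz: np.ndarray) -> np.ndarray:
        """Physical position (x, y, z) µm -> fractional voxel index (z, y, x)."""
        p = np.asarray(pos_xyz, dtype=float)
        sx, sy, sz = self.voxel_size_um
        ox, oy, oz = self.origin_um
        return np.stack(
            [(p[..., 2] - oz) / sz, (p[..., 1] - oy) / sy, (p[..., 0] - ox) / sx],
            axis=-1,
        )


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def projection_basis(geom: MillingGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal projection basis (u1, u2) and the beam direction v.

    For azimuth 0: ``v = (0, cos β, −sin β)``, ``u1 = (1, 0, 0)``,
    ``u2 = (0, sin β, cos β)``.  {u1, u2, v} is an orthonormal triple for
    every azimuth (the azimuth rotates all three about z).
    """
    b = geom.beta_rad
    v = np.array([0.0, np.cos(b), -np.sin(b)])
    u1 = np.array([1.0, 0.0, 0.0])
    u2 = np.array([0.0, np.sin(b), np.cos(b)])
    if geom.beam_azimuth_deg != 0.0:
        R = _rot_z(geom.beam_azimuth_deg)
        v, u1, u2 = R @ v, R @ u1, R @ u2
    return u1, u2, v


def project_point(p: np.ndarray, geom: MillingGeometry) -> np.ndarray:
    """Project 3D point(s) ``p`` (µm, last axis (x,y,z)) along the beam.

    Returns the 2D coordinates ``(p·u1, p·u2)`` in the projection plane, µm.
    The map is linear; points on the sample plane are foreshortened by
    sin β along u2, and depth differences contribute cos β along u2.
    """
    u1, u2, _ = projection_basis(geom)
    p = np.asarray(p, dtype=float)
    return np.stack([p @ u1, p @ u2], axis=-1)
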