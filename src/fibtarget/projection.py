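"""Oblique projection of confocal stacks and virtual-lamella previews.

The central operation renders the "LM via FIB" image: the 3D confocal
stack projected along the ion-beam direction, so that it shares the view
(and the sin β surface foreshortening) of the ion-beam image and the two
can be registered by a simple 2D offset.  Virtual lamellae are slab
projections of the same volume — a preview of what a lamella milled at a
candidate position would contain.

All projections sample the volume on an absolute cubic grid (pitch = the
cubic voxel size, grid lines at integer multiples of the pitch), traverse
it along the projection axis, and reduce with ``max`` / ``sum`` / ``mean``.
Samples falling outside the volume contribute zero, so projections near
the edges dim rather than hallucinate signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import ProjectedImage, VolumeStack
from .geometry import Frame3D, MillingGeometry, projection_basis

__all__ = [
    "VirtualLamellaSpec",
    "resample_isotropic",
    "lm_via_fib",
    "virtual_lamella",
]

_MODES = ("max", "sum", "mean")


@dataclass(frozen=True)
class VirtualLamellaSpec:
    """A candidate lamella: mid-plane offset d along u2, thickness t (µm).

    ``render_mode`` chooses the viewing direction of the preview:
    ``"face_on"`` looks along u2 (straight at the lamella face) and
    ``"top_down"`` along −z (comparable with a top-down LM image of the
    milled lamella; at β = 18° the two differ only by a cos β scale).
    """

    plane_offset_um: float
    thickness_um: float
    render_mode: str = "face_on"

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("thickness_um must be > 0")
        if self.render_mode not in ("face_on", "top_down"):
            raise ValueError("render_mode must be 'face_on' or 'top_down'")


def resample_isotropic(
    stack: VolumeStack, target_voxel_um: float | None = None, order: int = 3
) -> VolumeStack:
    """Resample a stack onto a cubic-voxel grid of pitch ``target_voxel_um``.

    Confocal stacks are anisotropic (axial step >> lateral pixel); oblique
    reslicing needs cubic voxels.  Interpolation is cubic B-spline by
    default (``order=1`` gives trilinear).  The physical extent is
    preserved to within one voxel.  An input already isotropic at the
    target pitch is returned unchanged, bit-exactly.
    """
    sx, sy, sz = stack.frame.voxel_size_um
    if target_voxel_um is None:
        target_voxel_um = min(sx, sy, sz)
    if target_voxel_um <= 0:
        raise ValueError("target_voxel_um must be > 0")
    ext = stack.extent_um()
    if np.any(target_voxel_um > ext):
        raise ValueError(
            f"target voxel {target_voxel_um} µm exceeds stack extent {tuple(ext)} µm"
        )
    if stack.frame.is_isotropic and sx == target_voxel_um:
        return stack

    h = float(target_voxel_um)
    nz, ny, nx = stack.shape_zyx
    out_shape = (
        int(np.floor((nz - 1) * sz / h)) + 1,
        int(np.floor((ny - 1) * sy / h)) + 1,
        int(np.floor((nx - 1) * sx / h)) + 1,
    )
    # output index k -> input index k * h / s  (both grids share the origin)
    matrix = np.diag([h / sz, h / sy, h / sx])
    dtype = np.float64 if stack.data.dtype == np.float64 else np.float32
    out = np.empty((stack.n_channels, *out_shape), dtype=dtype)
    for c in range(stack.n_channels):
        out[c] = ndimage.affine_transform(
            stack.data[c].astype(np.float64),
            matrix,
            output_shape=out_shape,
            order=order,
            mode="nearest",
        )
    frame = Frame3D(voxel_size_um=(h, h, h), origin_um=stack.frame.origin_um)
    return VolumeStack(data=out, frame=frame, channels=stack.channels)


def _abs_axis(lo: float, hi: float, h: float) -> np.ndarray:
    """Sample positions k*h covering [lo, hi] (absolute grid, call-invariant)."""
    k0 = int(np.floor(lo / h))
    k1 = int(np.ceil(hi / h))
    return h * np.arange(k0, k1 + 1)


def _oblique_reduce(
    stack: VolumeStack,
    e1: np.ndarray,
    e2: np.ndarray,
    e3: np.ndarray,
    mode: str,
    order: int,
    slab: tuple[np.ndarray, float, float] | None = None,
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Project ``stack`` along e3 onto the (e1, e2) plane.

    {e1, e2, e3} must be orthonormal.  If ``slab = (u2, lo, hi)`` is given,
    only sample points with p·u2 in the half-open interval (lo, hi]
    contribute (half-open so that contiguous slabs partition the volume
    exactly).  Returns (per-channel image, pitch, (a0, b0) plane origin).
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if not stack.frame.is_isotropic:
        stack = resample_isotropic(stack, order=order)
    h = stack.frame.voxel_size_um[0]
    origin = np.asarray(stack.frame.origin_um)
    ext = stack.extent_um()
    corners = origin + ext * np.array(
        [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    )
    a = _abs_axis((corners @ e1).min(), (corners @ e1).max(), h)
    b = _abs_axis((corners @ e2).min(), (corners @ e2).max(), h)
    s = _abs_axis((corners @ e3).min(), (corners @ e3).max(), h)

    filtered = [
        ndimage.spline_filter(stack.data[c].astype(np.float64), order=order)
        if order > 1
        else stack.data[c].astype(np.float64)
        for c in range(stack.n_channels)
    ]
    nh, nw = len(b), len(a)
    acc = np.zeros((stack.n_channels, nh, nw))
    if mode == "max":
        acc[:] = -np.inf
    count = np.zeros((nh, nw))
    A = a[None, :, None]  # (1, nw) broadcast over rows -> axes (b, a)
    B = b[:, None, None]
    base = A * e1[None, None, :] + B * e2[None, None, :]  # (nh, nw, 3)

    chunk = 16
    for k0 in range(0, len(s), chunk):
        sc = s[k0 : k0 + chunk]
        # points p = a e1 + b e2 + s e3, shape (nc, nh, nw, 3)
        p = base[None] + sc[:, None, None, None] * e3[None, None, None, :]
        if slab is not None:
            u2, lo, hi = slab
            m = (p @ u2 > lo) & (p @ u2 <= hi)
            if not m.any():
                continue
        else:
            m = None
        idx = np.moveaxis((p - origin) / h, -1, 0)[::-1]  # (z, y, x) fractional indices
        for c in range(stack.n_channels):
            vals = ndimage.map_coordinates(
                filtered[c], idx, order=order, prefilter=False, mode="constant", cval=0.0
            )
            if m is not None:
                vals = np.where(m, vals, -np.inf if mode == "max" else 0.0)
            if mode == "max":
                acc[c] = np.maximum(acc[c], vals.max(axis=0))
            else:
                acc[c] += vals.sum(axis=0)
        if m is not None:
            count += m.sum(axis=0)
        else:
            count += len(sc)

    if mode == "max":
        acc[acc == -np.inf] = 0.0
    elif mode == "mean":
        with np.errstate(invalid="ignore"):
            acc = np.where(count > 0, acc / count, 0.0)
    return acc, h, (float(a[0]), float(b[0]))


def lm_via_fib(
    stack: VolumeStack,
    geom: MillingGeometry,
    mode: str = "max",
    order: int = 3,
) -> ProjectedImage:
    """Project the confocal stack along the ion-beam direction.

    The output shares the ion-beam view: a point emitter at p lands at
    plane coordinates (p·u1, p·u2); surface distances along u2 are
    foreshortened by sin β.  Pixel pitch equals the cubic voxel size.
    ``mode="max"`` (default) suits point targets; ``"sum"`` conserves
    integrated intensity up to interpolation error.
    """
    u1, u2, v = projection_basis(geom)
    img, h, origin = _oblique_reduce(stack, u1, u2, v, mode, order)
    return ProjectedImage(
        data=img.astype(np.float32),
        pixel_size_um=h,
        modality="LM_via_FIB",
        channels=stack.channels,
        origin_um=origin,
        provenance={
            "milling_angle_deg": geom.milling_angle_deg,
            "beam_azimuth_deg": geom.beam_azimuth_deg,
            "foreshortening": geom.foreshortening,
            "mode": mode,
            "interpolation": f"cubic-bspline-{order}" if order > 1 else "trilinear",
            "renderer": "lm_via_fib",
        },
    )


def virtual_lamella(
    stack: VolumeStack,
    geom: MillingGeometry,
    spec: VirtualLamellaSpec,
    mode: str = "max",
    order: int = 3,
) -> ProjectedImage:
    """Render the slab |p·u2 − d| ≤ t/2 of the volume — a virtual lamella.

    ``face_on`` mode projects the slab along u2 (the lamella seen face on,
    image axes u1 and the in-lamella beam direction); ``top_down`` projects
    along z for comparison with a top-down LM image of the milled lamella.
    Raises if the slab contains no voxels, reporting the valid d range.
    """
    u1, u2, v = projection_basis(geom)
    d, t = spec.plane_offset_um, spec.thickness_um
    origin = np.asarray(stack.frame.origin_um)
    ext = stack.extent_um()
    corners = origin + ext * np.array(
        [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    )
    u2_lo, u2_hi = (corners @ u2).min(), (corners @ u2).max()
    if d + t / 2 <= u2_lo or d - t / 2 >= u2_hi:
        raise ValueError(
            f"empty slab: mid-plane offset {d} µm (thickness {t} µm) misses the "
            f"volume; valid offsets lie in [{u2_lo:.3f}, {u2_hi:.3f}] µm along u2"
        )
    if spec.render_mode == "face_on":
        e1, e2, e3 = u1, -v, u2
    else:
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 1.0, 0.0])
        e3 = np.array([0.0, 0.0, 1.0])
    img, h, img_origin = _oblique_reduce(
        stack, e1, e2, e3, mode, order, slab=(u2, d - t / 2, d + t / 2)
    )
    return ProjectedImage(
        data=img.astype(np.float32),
        pixel_size_um=h,
        modality="LM_via_FIB" if spec.render_mode == "face_on" else "LM_topdown",
        channels=stack.channels,
        origin_um=img_origin,
        provenance={
            "milling_angle_deg": geom.milling_angle_deg,
            "plane_offset_um": d,
            "thickness_um": t,
            "render_mode": spec.render_mode,
            "mode": mode,
            "interpolation": f"cubic-bspline-{order}" if order > 1 else "trilinear",
            "renderer": "virtual_lamella",
        },
    )
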