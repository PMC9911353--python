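"""LM ↔ TEM correlation of the finished lamella.

The lamella's LM image and a TEM image of the same lamella are brought to
a common pixel size and aligned by a pure rigid transform (rotation +
translation — no shear, no scale beyond the declared pixel-size rescale,
no nonrigid deformation).  The cue shared by both modalities is the
lamella outline, so the automated estimator correlates edge maps: a
coarse rotation sweep scored by phase correlation, parabolic refinement
of the angle, then a sub-pixel translation estimate.  A manual mode
accepts an operator-supplied transform and only scores it.

The aligned fluorescence channel then yields ranked acquisition boxes in
TEM coordinates for tomography navigation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import sobel
from skimage.registration import phase_cross_correlation
from skimage.transform import rescale, rotate

from .containers import ProjectedImage

__all__ = [
    "RigidTransform2D",
    "rescale_to_common",
    "register_rigid",
    "overlay_and_navigate",
]


@dataclass(frozen=True)
class RigidTransform2D:
    """Rigid map from moving (LM) to fixed (TEM) pixel coordinates.

    A point p = (x, y) maps to ``R(θ)·(p − c) + c + t`` where c is the
    rotation center (the moving image center), θ the rotation and t the
    translation.  The linear part is orthogonal with unit determinant by
    construction — rigidity is structural, not fitted.
    """

    rotation_deg: float
    translation_px: tuple[float, float]
    center_px: tuple[float, float] = (0.0, 0.0)
    score: float = float("nan")

    @property
    def matrix(self) -> np.ndarray:
        """2x2 linear part (image axes: x right, y down; θ CCW on screen)."""
        th = np.deg2rad(self.rotation_deg)
        return np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])

    def apply_points(self, pts_px: np.ndarray) -> np.ndarray:
        p = np.asarray(pts_px, dtype=float)
        c = np.asarray(self.center_px)
        t = np.asarray(self.translation_px)
        return (p - c) @ self.matrix.T + c + t

    def apply_image(self, img: np.ndarray) -> np.ndarray:
        out = rotate(np.asarray(img, dtype=float), self.rotation_deg, preserve_range=True)
        tx, ty = self.translation_px
        return ndimage.shift(out, (ty, tx), order=1, mode="constant", cval=0.0)

    def inverse(self) -> "RigidTransform2D":
        Rinv = self.matrix.T
        t = np.asarray(self.translation_px)
        return RigidTransform2D(
            rotation_deg=-self.rotation_deg,
            translation_px=tuple(-(Rinv @ t)),
            center_px=self.center_px,
            score=self.score,
        )


def _image_center(shape_hw: tuple[int, int]) -> tuple[float, float]:
    # matches skimage.transform.rotate's default center
    h, w = shape_hw
    return (w / 2 - 0.5, h / 2 - 0.5)


def rescale_to_common(
    lm: ProjectedImage, tem: ProjectedImage, prefer: str = "down"
) -> tuple[ProjectedImage, ProjectedImage]:
    """Bring both images to one pixel size.

    ``prefer="down"`` downsamples the finer image to the coarser pixel
    (anti-aliased); ``"up"`` upsamples the coarser one.  Physical extents
    are preserved to within one pixel.  Equal pixel sizes return the
    inputs unchanged.
    """
    if prefer not in ("down", "up"):
        raise ValueError("prefer must be 'down' or 'up'")
    p_lm, p_tem = lm.pixel_size_um, tem.pixel_size_um
    if np.isclose(p_lm, p_tem, rtol=1e-9):
        return lm, tem
    target = max(p_lm, p_tem) if prefer == "down" else min(p_lm, p_tem)

    def _to(img: ProjectedImage) -> ProjectedImage:
        if np.isclose(img.pixel_size_um, target, rtol=1e-9):
            return img
        factor = img.pixel_size_um / target
        out = np.stack(
            [
                rescale(
                    img.data[c].astype(np.float64),
                    factor,
                    anti_aliasing=factor < 1,
                    preserve_range=True,
                )
                for c in range(img.data.shape[0])
            ]
        )
        return ProjectedImage(
            data=out.astype(np.float32),
            pixel_size_um=target,
            modality=img.modality,
            channels=img.channels,
            origin_um=img.origin_um,
            provenance={**img.provenance, "rescaled_from_um": img.pixel_size_um},
        )

    return _to(lm), _to(tem)


def _edge_map(img: np.ndarray, smooth: float = 1.5) -> np.ndarray:
    e = sobel(ndimage.gaussian_filter(np.asarray(img, dtype=np.float64), smooth))
    rng = e.max() - e.min()
    return (e - e.min()) / rng if rng > 0 else e * 0.0


def _pad_to(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=img.dtype)
    h = min(img.shape[0], shape[0])
    w = min(img.shape[1], shape[1])
    out[:h, :w] = img[:h, :w]
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def register_rigid(
    lm: ProjectedImage,
    tem: ProjectedImage,
    init: RigidTransform2D | None = None,
    manual: RigidTransform2D | None = None,
    angle_range_deg: float = 15.0,
    coarse_step_deg: float = 0.5,
    lm_channel: str | None = None,
    score_threshold: float = 0.1,
) -> RigidTransform2D:
    """Estimate (or, in manual mode, validate) the LM→TEM rigid transform.

    Both images must already share one pixel size (see
    :func:`rescale_to_common`).  ``manual`` replicates the operator-driven
    procedure: the supplied transform is returned with its edge-correlation
    score attached.  Otherwise the rotation is swept (optionally around
    ``init``), refined parabolically, and the translation estimated by
    upsampled phase correlation of the edge maps.  A score below
    ``score_threshold`` warns but still returns the transform.
    """
    import warnings

    if not np.isclose(lm.pixel_size_um, tem.pixel_size_um, rtol=1e-6):
        raise ValueError(
            f"pixel sizes differ ({lm.pixel_size_um} vs {tem.pixel_size_um} µm); "
            "run rescale_to_common first"
        )
    if lm_channel is None:
        lm_channel = "BF" if "BF" in lm.channels else lm.channels[0]
    mov = np.asarray(lm.channel(lm_channel), dtype=np.float64)
    fix = np.asarray(tem.channel(tem.channels[0]), dtype=np.float64)
    shape = (max(mov.shape[0], fix.shape[0]), max(mov.shape[1], fix.shape[1]))
    mov_e = _edge_map(_pad_to(mov, shape))
    fix_e = _edge_map(_pad_to(fix, shape))
    center = _image_center(shape)

    def _score_at(tf: RigidTransform2D) -> float:
        return _ncc(tf.apply_image(mov_e), fix_e)

    if manual is not None:
        tf = RigidTransform2D(
            manual.rotation_deg, manual.translation_px, center_px=center
        )
        score = _score_at(tf)
        if score < score_threshold:
            warnings.warn(f"manual registration scores low ({score:.3f})", stacklevel=2)
        return RigidTransform2D(tf.rotation_deg, tf.translation_px, center, score)

    theta0 = init.rotation_deg if init is not None else 0.0
    angles = theta0 + np.arange(-angle_range_deg, angle_range_deg + 1e-9, coarse_step_deg)
    errs = np.empty_like(angles)
    for i, ang in enumerate(angles):
        rot = rotate(mov_e, ang, preserve_range=True)
        _, errs[i], _ = phase_cross_correlation(fix_e, rot, upsample_factor=4)
    k = int(np.argmin(errs))
    theta = angles[k]
    if 0 < k < len(angles) - 1:  # parabolic refinement of the angle
        denom = errs[k - 1] - 2 * errs[k] + errs[k + 1]
        if denom > 0:
            theta = angles[k] + 0.5 * (errs[k - 1] - errs[k + 1]) / denom * coarse_step_deg

    rot = rotate(mov_e, theta, preserve_range=True)
    shift, _, _ = phase_cross_correlation(fix_e, rot, upsample_factor=100)
    tf = RigidTransform2D(
        rotation_deg=float(theta),
        translation_px=(float(shift[1]), float(shift[0])),
        center_px=center,
    )
    score = _score_at(tf)
    if score < score_threshold:
        warnings.warn(
            f"rigid registration low confidence (score {score:.3f} < {score_threshold})",
            stacklevel=2,
        )
    return RigidTransform2D(tf.rotation_deg, tf.translation_px, center, score)


def overlay_and_navigate(
    lm: ProjectedImage,
    tem: ProjectedImage,
    transform: RigidTransform2D,
    channel: str = "green",
    box_size_px: int = 48,
    max_boxes: int = 5,
    threshold_rel: float = 0.2,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Overlay fluorescence on the TEM image and rank acquisition boxes.

    The fluorescence channel is mapped into the TEM frame with the rigid
    transform; candidate boxes are centered on fluorescence maxima and
    ranked by integrated intensity.  Returns (RGB overlay, box table with
    columns x_px, y_px, box_size, rank, integrated_intensity).
    """
    fluo = np.asarray(lm.channel(channel), dtype=np.float64)
    fix = np.asarray(tem.channel(tem.channels[0]), dtype=np.float64)
    mapped = transform.apply_image(_pad_to(fluo, fix.shape))[: fix.shape[0], : fix.shape[1]]

    peaks: list[tuple[int, int]] = []
    if mapped.max() > 0:
        peaks = [
            (int(r), int(c))
            for r, c in peak_local_max(
                mapped,
                min_distance=max(box_size_px // 2, 1),
                threshold_rel=threshold_rel,
                num_peaks=max_boxes,
            )
        ]
    rows = []
    half = box_size_px // 2
    for r, c in peaks:
        sl = (
            slice(max(r - half, 0), min(r + half + 1, mapped.shape[0])),
            slice(max(c - half, 0), min(c + half + 1, mapped.shape[1])),
        )
        rows.append(
            dict(x_px=float(c), y_px=float(r), box_size=box_size_px,
                 integrated_intensity=float(mapped[sl].sum()))
        )
    boxes = pd.DataFrame(rows, columns=["x_px", "y_px", "box_size", "integrated_intensity"])
    boxes = boxes.sort_values("integrated_intensity", ascending=False, ignore_index=True)
    boxes["rank"] = np.arange(1, len(boxes) + 1)

    def _norm(a: np.ndarray) -> np.ndarray:
        rng = a.max() - a.min()
        return (a - a.min()) / rng if rng > 0 else a * 0.0

    overlay = np.stack([_norm(fix)] * 3, axis=-1)
    overlay[..., 1] = np.clip(overlay[..., 1] + _norm(mapped), 0, 1)
    return overlay, boxes
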