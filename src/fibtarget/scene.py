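"""Synthetic matched-modality scenes with known ground truth.

A scene is a flat vitrified sample: point emitters (quantum dots,
centrosome-like spots) and diffuse organelle-like blobs below a flat
surface at ``surface_z_um``, a protective coat on top, and a cross-shaped
reference pattern (RP) etched into the surface.  From one :class:`SceneSpec`
the module renders

* a 3D confocal stack (:func:`render_confocal`) — fluorescence channels
  plus a reflected-light bright-field ("BF") channel in which the RP
  appears as an intensity deficit at the surface, and
* the ion-beam view of the same scene (:func:`render_fib_view`) — an
  orthographic rendering along the beam in which the surface is
  foreshortened by sin β and only surface-level features are visible.

Both renders share the ground truth exported by :func:`truth_table`, so
every downstream stage (projection, registration, planning) can be tested
against known positions without an instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import ProjectedImage, VolumeStack
from .geometry import Frame3D, MillingGeometry, projection_basis, project_point

__all__ = [
    "ReferencePatternSpec",
    "Emitter",
    "Blob",
    "SceneSpec",
    "default_scene",
    "random_scene",
    "truth_table",
    "render_confocal",
    "render_fib_view",
    "apply_drift",
]


@dataclass(frozen=True)
class ReferencePatternSpec:
    """Cross-shaped reference pattern etched into the sample surface."""

    center_um: tuple[float, float] = (6.0, 6.0)
    arm_length_um: float = 6.0
    arm_width_um: float = 0.8
    depth_contrast: float = 0.6  # fractional intensity deficit of the etched region

    def __post_init__(self) -> None:
        if not self.arm_length_um > self.arm_width_um > 0:
            raise ValueError(
                "require arm_length_um > arm_width_um > 0, got "
                f"{self.arm_length_um}, {self.arm_width_um}"
            )
        if not 0 < self.depth_contrast <= 1:
            raise ValueError("depth_contrast must lie in (0, 1]")

    def mask(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Boolean cross footprint evaluated at surface coordinates (µm)."""
        cx, cy = self.center_um
        dx, dy = np.abs(x_um - cx), np.abs(y_um - cy)
        half_l, half_w = self.arm_length_um / 2, self.arm_width_um / 2
        horiz = (dx <= half_l) & (dy <= half_w)
        vert = (dy <= half_l) & (dx <= half_w)
        return horiz | vert

    def coverage(self, x_um: np.ndarray, y_um: np.ndarray, soft_um: float) -> np.ndarray:
        """Fractional cross coverage with a linear edge ramp of ``soft_um``.

        Sampling the sharp footprint on a pixel grid aliases the edges and
        biases subpixel center estimates; a ramp one sample wide stands in
        for the area integral over each pixel.
        """
        if soft_um <= 0:
            return self.mask(x_um, y_um).astype(float)
        cx, cy = self.center_um
        dx, dy = x_um - cx, y_um - cy
        half_l, half_w = self.arm_length_um / 2, self.arm_width_um / 2

        def slab(d, half):
            return np.clip((half - np.abs(d)) / soft_um + 0.5, 0.0, 1.0)

        horiz = slab(dx, half_l) * slab(dy, half_w)
        vert = slab(dy, half_l) * slab(dx, half_w)
        return np.maximum(horiz, vert)


@dataclass(frozen=True)
class Emitter:
    """Point emitter (QD-like): position (x, y, z) µm, amplitude, channel."""

    position_um: tuple[float, float, float]
    amplitude: float = 1.0
    channel: str = "green"


@dataclass(frozen=True)
class Blob:
    """Diffuse organelle-like Gaussian blob with per-axis widths (µm)."""

    center_um: tuple[float, float, float]
    sigma_um: tuple[float, float, float] = (0.8, 0.8, 0.8)
    amplitude: float = 0.5
    channel: str = "red"


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene; the seed fixes every render."""

    bounds_um: tuple[float, float, float] = (24.0, 24.0, 8.0)
    emitters: tuple[Emitter, ...] = ()
    blobs: tuple[Blob, ...] = ()
    surface_z_um: float = 6.0
    coat_thickness_um: float = 2.5  # protective Pt layer on top of the surface
    rp: ReferencePatternSpec = field(default_factory=ReferencePatternSpec)
    psf_sigma_um: tuple[float, float] = (0.15, 0.45)  # lateral, axial
    noise_sigma: float = 0.0
    poisson: bool = False
    drift_rate_nm_per_min: float = 100.0
    channels: tuple[str, ...] = ("BF", "green", "red")
    seed: int = 0

    def __post_init__(self) -> None:
        lx, ly, lz = self.bounds_um
        for e in self.emitters:
            if not _inside(e.position_um, self.bounds_um):
                raise ValueError(f"emitter at {e.position_um} outside bounds {self.bounds_um}")
            if e.channel not in self.channels:
                raise ValueError(f"emitter channel {e.channel!r} not in {self.channels}")
        for b in self.blobs:
            if not _inside(b.center_um, self.bounds_um):
                raise ValueError(f"blob at {b.center_um} outside bounds {self.bounds_um}")
        if any(s <= 0 for s in self.psf_sigma_um):
            raise ValueError("psf sigmas must be > 0")
        if self.drift_rate_nm_per_min < 0:
            raise ValueError("drift rate must be >= 0")
        if not 0 <= self.surface_z_um <= lz:
            raise ValueError("surface_z_um must lie inside the z bounds")


def _inside(p: tuple[float, float, float], bounds: tuple[float, float, float]) -> bool:
    return all(0.0 <= c <= b for c, b in zip(p, bounds))


def default_scene(seed: int = 0) -> SceneSpec:
    """A representative scene: one QD-like target near the RP, two blobs."""
    return SceneSpec(
        bounds_um=(24.0, 24.0, 8.0),
        emitters=(Emitter((15.0, 14.0, 6.0), amplitude=1.0, channel="green"),),
        blobs=(
            Blob((10.0, 16.0, 4.0), (1.2, 0.9, 0.7), 0.5, "red"),
            Blob((17.0, 9.0, 3.5), (0.8, 1.1, 0.8), 0.4, "red"),
        ),
        surface_z_um=6.0,
        rp=ReferencePatternSpec(center_um=(7.0, 7.0)),
        noise_sigma=0.01,
        seed=seed,
    )


def random_scene(
    seed: int,
    bounds_um: tuple[float, float, float] = (16.0, 16.0, 5.0),
    n_emitters: int = 1,
    surface_level: bool = True,
    noise_sigma: float = 0.005,
) -> SceneSpec:
    """A randomized validation scene: RP plus emitters at safe margins.

    The RP and the emitters are placed uniformly at random, at least
    2.5 µm apart and clear of the scene edges, so every feature is fully
    inside both the confocal grid and the rendered ion-beam field of
    view.  ``surface_level=True`` puts emitters on the sample surface
    (visible in the ion-beam view, like sputter-exposed QDs); otherwise
    their depth is drawn uniformly within the sample.
    """
    rng = substream(seed, "scene-layout")
    lx, ly, lz = bounds_um
    z0 = round(0.7 * lz, 3)
    # generous arms and margins: at grazing milling angles the oblique
    # projection smears the cross by ~sigma_axial*cot(beta) along y, so a
    # small benchmark would wash out and one near the field edge would
    # overlap the projected volume boundary
    arm_um = 5.0
    margin = arm_um / 2 + 2.8

    def draw() -> np.ndarray:
        return rng.uniform([margin, margin], [lx - margin, ly - margin])

    rp_xy = draw()
    positions: list[tuple[float, float, float]] = []
    while len(positions) < n_emitters:
        xy = draw()
        others = [rp_xy] + [np.array(p[:2]) for p in positions]
        if min(float(np.linalg.norm(xy - o)) for o in others) < 2.5:
            continue
        z = z0 if surface_level else float(rng.uniform(0.2 * lz, z0))
        positions.append((float(xy[0]), float(xy[1]), z))
    return SceneSpec(
        bounds_um=bounds_um,
        emitters=tuple(Emitter(p, 1.0, "green") for p in positions),
        surface_z_um=z0,
        rp=ReferencePatternSpec(
            center_um=(float(rp_xy[0]), float(rp_xy[1])),
            arm_length_um=arm_um,
            arm_width_um=0.6,
        ),
        noise_sigma=noise_sigma,
        channels=("BF", "green"),
        seed=seed,
    )


def truth_table(spec: SceneSpec) -> pd.DataFrame:
    """Machine-readable ground truth for every feature in the scene."""
    rows: list[dict] = []
    for e in spec.emitters:
        x, y, z = e.position_um
        rows.append(
            dict(kind="emitter", x_um=x, y_um=y, z_um=z, amplitude=e.amplitude, channel=e.channel)
        )
    for b in spec.blobs:
        x, y, z = b.center_um
        rows.append(
            dict(kind="blob", x_um=x, y_um=y, z_um=z, amplitude=b.amplitude, channel=b.channel)
        )
    cx, cy = spec.rp.center_um
    rows.append(
        dict(kind="rp", x_um=cx, y_um=cy, z_um=spec.surface_z_um, amplitude=np.nan, channel="BF")
    )
    rows.append(
        dict(kind="surface", x_um=np.nan, y_um=np.nan, z_um=spec.surface_z_um,
             amplitude=np.nan, channel="BF")
    )
    return pd.DataFrame(rows)


def _axis_coords(n: int, step: float, origin: float) -> np.ndarray:
    return origin + step * np.arange(n)


def render_confocal(spec: SceneSpec, frame: Frame3D | None = None) -> VolumeStack:
    """Render the 3D confocal stack of a scene on the grid of ``frame``.

    Each emitter contributes a separable anisotropic Gaussian of the PSF
    widths; blobs contribute Gaussians of their own widths; the RP appears
    as an intensity deficit in the BF channel at the surface.  Noise
    (optional Poisson, then additive Gaussian) is applied last; a fixed
    seed makes the output bit-reproducible.
    """
    import logging

    if frame is None:
        frame = Frame3D(voxel_size_um=(0.15, 0.15, 0.45))
    lx, ly, lz = spec.bounds_um
    sx, sy, sz = frame.voxel_size_um
    ox, oy, oz = frame.origin_um
    nx = int(np.floor((lx - ox) / sx)) + 1
    ny = int(np.floor((ly - oy) / sy)) + 1
    nz = int(np.floor((lz - oz) / sz)) + 1
    if nx < 2 or ny < 2 or nz < 2:
        raise ValueError("frame grid does not cover the scene bounds")
    sig_lat, sig_ax = spec.psf_sigma_um
    if sig_lat < min(sx, sy) or sig_ax < sz:
        logging.getLogger(__name__).warning(
            "grid too coarse to resolve the PSF (sigma < 1 voxel); spots will alias"
        )

    xs = _axis_coords(nx, sx, ox)
    ys = _axis_coords(ny, sy, oy)
    zs = _axis_coords(nz, sz, oz)
    data = np.zeros((len(spec.channels), nz, ny, nx), dtype=np.float64)

    def _add_gaussian(ch: int, center, sigmas, amp) -> None:
        cx, cy, cz = center
        gx = np.exp(-0.5 * ((xs - cx) / sigmas[0]) ** 2)
        gy = np.exp(-0.5 * ((ys - cy) / sigmas[1]) ** 2)
        gz = np.exp(-0.5 * ((zs - cz) / sigmas[2]) ** 2)
        data[ch] += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]

    for e in spec.emitters:
        _add_gaussian(spec.channels.index(e.channel), e.position_um, (sig_lat, sig_lat, sig_ax), e.amplitude)
    for b in spec.blobs:
        _add_gaussian(spec.channels.index(b.channel), b.center_um, b.sigma_um, b.amplitude)

    if "BF" in spec.channels:
        bf = spec.channels.index("BF")
        cross = spec.rp.coverage(xs[None, :], ys[:, None], min(sx, sy))  # (ny, nx)
        gz = np.exp(-0.5 * ((zs - spec.surface_z_um) / sig_ax) ** 2)
        surface = 1.0 - spec.rp.depth_contrast * cross
        data[bf] += gz[:, None, None] * surface[None, :, :]

    rng = substream(spec.seed, "confocal")
    if spec.poisson:
        scale = 100.0  # photons per unit intensity
        data = rng.poisson(np.clip(data, 0, None) * scale) / scale
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    return VolumeStack(data=data.astype(np.float32), frame=frame, channels=spec.channels)


def render_fib_view(spec: SceneSpec, geom: MillingGeometry) -> ProjectedImage:
    """Orthographic ion-beam view of the scene surface.

    Only the surface is visible: the flat sample plane (foreshortened by
    sin β along the second image axis), the etched RP cross as an intensity
    deficit, the protective-coat cross-section as a bright band past the far
    surface edge, and surface-level emitters as small bright spots.
    Sub-surface fluorophores do not appear — ion images carry no depth
    information, which is the whole reason the confocal stack is needed.
    """
    u1, u2, v = projection_basis(geom)
    n = geom.image_px
    h = geom.pixel_size_um
    lx, ly, lz = spec.bounds_um
    z0 = spec.surface_z_um
    b_rad = geom.beta_rad
    sin_b, cos_b = np.sin(b_rad), np.cos(b_rad)

    center3 = np.array([lx / 2, ly / 2, z0])
    a_c, b_c = project_point(center3, geom)
    a0 = a_c - (n - 1) / 2 * h
    b0 = b_c - (n - 1) / 2 * h
    a = a0 + h * np.arange(n)[None, :]  # columns
    b = b0 + h * np.arange(n)[:, None]  # rows

    # invert the surface map: a = x', b = y' sinβ + z0 cosβ (rotated in-plane frame)
    xp = np.broadcast_to(a, (n, n))
    yp = (b - z0 * cos_b) / sin_b
    rho = np.deg2rad(geom.beam_azimuth_deg)
    x = np.cos(rho) * xp - np.sin(rho) * yp
    y = np.sin(rho) * xp + np.cos(rho) * yp

    rp_center3 = np.array([*spec.rp.center_um, z0])
    rp_ab = project_point(rp_center3, geom)
    if not (a0 <= rp_ab[0] <= a0 + (n - 1) * h and b0 <= rp_ab[1] <= b0 + (n - 1) * h):
        raise ValueError(
            f"reference pattern projects to {tuple(rp_ab)} µm, outside the "
            f"field of view [{a0:.2f}, {a0 + (n - 1) * h:.2f}] x "
            f"[{b0:.2f}, {b0 + (n - 1) * h:.2f}] µm"
        )

    on_surface = (x >= 0) & (x <= lx) & (y >= 0) & (y <= ly)
    base = 0.6
    img = np.where(on_surface, base, 0.05)
    cov = spec.rp.coverage(x, y, h)
    img = np.where(on_surface, img - base * spec.rp.depth_contrast * cov, img)

    # protective coat: cross-section past the far surface edge, apparent height t*cosβ
    b_far = ly * sin_b + z0 * cos_b
    coat = (~on_surface) & (b >= b_far) & (b <= b_far + spec.coat_thickness_um * cos_b)
    img = np.where(np.broadcast_to(coat, img.shape), 0.85, img)

    # surface-level emitters are sputter-exposed bright spots
    spot_sigma = 0.08  # µm, ion-image spot width
    for e in spec.emitters:
        ex, ey, ez = e.position_um
        if abs(ez - z0) <= spec.psf_sigma_um[1]:
            img = img + 0.5 * e.amplitude * np.exp(
                -((x - ex) ** 2 + (y - ey) ** 2) / (2 * spot_sigma**2)
            ) * on_surface

    rng = substream(spec.seed, "fib")
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    return ProjectedImage(
        data=img.astype(np.float32),
        pixel_size_um=h,
        modality="FIB",
        channels=("ion",),
        origin_um=(a0, b0),
        provenance={
            "milling_angle_deg": geom.milling_angle_deg,
            "beam_azimuth_deg": geom.beam_azimuth_deg,
            "foreshortening": sin_b,
            "surface_z_um": z0,
            "renderer": "render_fib_view",
            "seed": spec.seed,
        },
    )


def apply_drift(
    coords_um: np.ndarray,
    rate_nm_per_min: float,
    duration_min: float,
    direction: np.ndarray,
) -> np.ndarray:
    """Translate coordinates by stage drift: rate x duration along ``direction``.

    ``direction`` is normalised internally; displacement is linear in
    duration (constant-rate translational drift, no rotation or creep).
    Coordinates and the returned array are in µm.
    """
    if rate_nm_per_min < 0 or duration_min < 0:
        raise ValueError("drift rate and duration must be >= 0")
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    disp_um = rate_nm_per_min * duration_min / 1000.0
    return np.asarray(coords_um, dtype=float) + disp_um * d / norm
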