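"""Shared fixtures: small matched scenes renderable in well under a second."""

from __future__ import annotations

import numpy as np
import pytest

from fibtarget import (
    Emitter,
    MillingGeometry,
    ReferencePatternSpec,
    SceneSpec,
    render_confocal,
)
from fibtarget.geometry import Frame3D


@pytest.fixture
def small_scene() -> SceneSpec:
    """One QD-like emitter near the RP on a 16 x 16 x 6 µm sample."""
    return SceneSpec(
        bounds_um=(16.0, 16.0, 6.0),
        emitters=(Emitter((11.0, 10.0, 4.0), 1.0, "green"),),
        surface_z_um=4.0,
        rp=ReferencePatternSpec(center_um=(5.0, 6.0), arm_length_um=4.0, arm_width_um=0.6),
        noise_sigma=0.005,
        channels=("BF", "green"),
        seed=3,
    )


@pytest.fixture
def small_frame() -> Frame3D:
    return Frame3D(voxel_size_um=(0.15, 0.15, 0.45))


@pytest.fixture
def small_geom() -> MillingGeometry:
    return MillingGeometry(milling_angle_deg=18.0, fov_um=16.0, image_px=320)


@pytest.fixture
def small_stack(small_scene, small_frame):
    return render_confocal(small_scene, small_frame)


def gaussian_spot_image(
    rng: np.random.Generator,
    shape: tuple[int, int],
    center_xy: tuple[float, float],
    sigma_px: float = 1.8,
    amplitude: float = 1.0,
    noise_sigma: float = 0.0,
) -> np.ndarray:
    """Analytic 2D Gaussian spot plus optional Gaussian noise (oracle image)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = amplitude * np.exp(
        -((xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2) / (2 * sigma_px**2)
    )
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, shape)
    return img
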