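"""Oblique projection and virtual lamellae against analytic oracles."""

import numpy as np
import pytest

from fibtarget import (
    Emitter,
    MillingGeometry,
    SceneSpec,
    VirtualLamellaSpec,
    lm_via_fib,
    project_point,
    projection_basis,
    render_confocal,
    resample_isotropic,
    virtual_lamella,
)
from fibtarget.containers import VolumeStack
from fibtarget.geometry import Frame3D


def _u2_range(stack, geom):
    _, u2, _ = projection_basis(geom)
    origin = np.asarray(stack.frame.origin_um)
    ext = stack.extent_um()
    corners = origin + ext * np.array(
        [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    )
    return (corners @ u2).min(), (corners @ u2).max(), u2


class TestResampleIsotropic:
    def test_isotropic_input_returned_bit_exact(self):
        data = np.random.default_rng(0).random((1, 8, 9, 10)).astype(np.float32)
        stack = VolumeStack(data, Frame3D((0.2, 0.2, 0.2)), ("0",))
        out = resample_isotropic(stack, 0.2)
        assert out.data is stack.data

    def test_linear_ramp_interpolated_exactly(self):
        """A linear intensity ramp along z survives resampling to half spacing.

        Trilinear interpolation reproduces the ramp exactly everywhere; the
        cubic B-spline does so away from the volume faces (its boundary
        handling rings near the ends, decaying geometrically inward)."""
        nz, ny, nx = 26, 6, 6
        z = np.arange(nz, dtype=np.float64) * 0.4  # physical z, voxel 0.4 um
        data = np.broadcast_to(z[:, None, None], (nz, ny, nx)).copy()
        stack = VolumeStack(data[None], Frame3D((0.2, 0.2, 0.4)), ("0",))
        lin = resample_isotropic(stack, 0.2, order=1)
        zz = np.arange(lin.shape_zyx[0]) * 0.2
        np.testing.assert_allclose(lin.data[0][1:, 3, 3], zz[1:], rtol=1e-6)
        cub = resample_isotropic(stack, 0.2, order=3)
        interior = slice(18, -18)
        np.testing.assert_allclose(cub.data[0][interior, 3, 3], zz[interior], rtol=1e-6)

    def test_gaussian_blob_intensity_conserved(self):
        spec = SceneSpec(
            bounds_um=(4, 4, 4),
            emitters=(Emitter((2.0, 2.0, 2.0), 1.0, "green"),),
            surface_z_um=3.5,
            psf_sigma_um=(0.3, 0.6),
            noise_sigma=0.0,
        )
        stack = render_confocal(spec, Frame3D((0.1, 0.1, 0.4)))
        out = resample_isotropic(stack, 0.1)
        a = stack.channel("green").sum() * 0.1 * 0.1 * 0.4
        b = out.channel("green").sum() * 0.1**3
        assert abs(a - b) / a < 0.01

    def test_target_voxel_exceeding_extent_rejected(self):
        stack = VolumeStack(np.zeros((1, 4, 4, 4)), Frame3D((0.1, 0.1, 0.1)), ("0",))
        with pytest.raises(ValueError, match="extent"):
            resample_isotropic(stack, 5.0)


@pytest.fixture(scope="module")
def emitter_stack():
    """Three well-separated emitters on an isotropic grid (oracle scene)."""
    spec = SceneSpec(
        bounds_um=(10, 10, 5),
        emitters=(
            Emitter((2.5, 3.0, 1.5), 1.0, "green"),
            Emitter((7.0, 4.5, 3.2), 0.9, "green"),
            Emitter((4.8, 7.5, 2.1), 1.1, "green"),
        ),
        surface_z_um=4.5,
        noise_sigma=0.0,
        channels=("BF", "green"),
    )
    return spec, render_confocal(spec, Frame3D((0.15, 0.15, 0.45)))


class TestLmViaFib:
    def test_vertical_limit_equals_axial_mip(self, emitter_stack):
        _, stack = emitter_stack
        iso = resample_isotropic(stack)
        geom = MillingGeometry(milling_angle_deg=90.0, fov_um=10.0, image_px=100)
        proj = lm_via_fib(iso, geom, mode="max")
        mip = iso.channel("green").max(axis=0)
        got = proj.channel("green")
        assert got.shape == mip.shape
        np.testing.assert_allclose(got, mip, atol=1e-6)

    @pytest.mark.parametrize("beta", [18.0, 60.0])
    def test_emitters_land_at_analytic_positions(self, emitter_stack, beta):
        """Spot maxima sit at (x, y sin b + z cos b) within one cubic voxel."""
        spec, stack = emitter_stack
        geom = MillingGeometry(milling_angle_deg=beta, fov_um=10.0, image_px=100)
        proj = lm_via_fib(stack, geom, mode="max")
        g = proj.channel("green")
        for e in spec.emitters:
            truth = proj.um_to_px(project_point(np.array(e.position_um), geom))
            r0, c0 = int(round(truth[1])), int(round(truth[0]))
            win = g[max(r0 - 3, 0) : r0 + 4, max(c0 - 3, 0) : c0 + 4]
            dr, dc = np.unravel_index(np.argmax(win), win.shape)
            peak = (max(c0 - 3, 0) + dc, max(r0 - 3, 0) + dr)
            assert abs(peak[0] - truth[0]) <= 1.0 and abs(peak[1] - truth[1]) <= 1.0

    def test_degenerate_depths_merge_to_single_spot(self):
        """Two emitters on one projection ray produce one merged spot."""
        beta = 18.0
        sb, cb = np.sin(np.deg2rad(beta)), np.cos(np.deg2rad(beta))
        z1, z2 = 3.0, 1.0
        y1 = 5.0
        y2 = y1 + (z1 - z2) * cb / sb  # same y sin b + z cos b
        spec = SceneSpec(
            bounds_um=(10, 16, 5),
            emitters=(Emitter((5.0, y1, z1), 1.0, "green"), Emitter((5.0, y2, z2), 1.0, "green")),
            surface_z_um=4.5,
            noise_sigma=0.0,
        )
        stack = render_confocal(spec, Frame3D((0.15, 0.15, 0.45)))
        proj = lm_via_fib(stack, MillingGeometry(milling_angle_deg=beta, fov_um=16, image_px=160))
        g = proj.channel("green")
        blob = g > 0.5 * g.max()
        from scipy import ndimage

        _, n = ndimage.label(blob)
        assert n == 1

    def test_sum_mode_conserves_intensity(self, emitter_stack):
        _, stack = emitter_stack
        iso = resample_isotropic(stack)
        geom = MillingGeometry(milling_angle_deg=18.0, fov_um=10.0, image_px=100)
        proj = lm_via_fib(iso, geom, mode="sum")
        a = float(iso.channel("green").sum())
        b = float(proj.channel("green").sum())
        assert abs(a - b) / a < 0.01

    def test_invalid_mode_rejected(self, emitter_stack):
        _, stack = emitter_stack
        with pytest.raises(ValueError, match="mode"):
            lm_via_fib(stack, MillingGeometry(), mode="median")


class TestVirtualLamella:
    def test_whole_volume_slab_equals_full_sum_projection(self, emitter_stack):
        _, stack = emitter_stack
        iso = resample_isotropic(stack)
        geom = MillingGeometry(milling_angle_deg=18.0, fov_um=10.0, image_px=100)
        lo, hi, _ = _u2_range(iso, geom)
        full = virtual_lamella(
            iso, geom, VirtualLamellaSpec((lo + hi) / 2, (hi - lo) * 1.001), mode="sum"
        )
        # every voxel is in the slab, so total intensity is fully accounted for
        a = float(iso.channel("green").sum())
        b = float(full.channel("green").sum())
        assert abs(a - b) / a < 0.01

    def test_slab_partition_reconstructs_full_projection(self, emitter_stack):
        """Sum projections of contiguous slabs tiling the volume add up exactly."""
        _, stack = emitter_stack
        iso = resample_isotropic(stack)
        geom = MillingGeometry(milling_angle_deg=18.0, fov_um=10.0, image_px=100)
        lo, hi, _ = _u2_range(iso, geom)
        edges = np.linspace(lo - 1e-3, hi + 1e-3, 6)
        parts = [
            virtual_lamella(
                iso,
                geom,
                VirtualLamellaSpec((edges[i] + edges[i + 1]) / 2, edges[i + 1] - edges[i]),
                mode="sum",
            )
            for i in range(5)
        ]
        full = virtual_lamella(
            iso, geom, VirtualLamellaSpec((edges[0] + edges[-1]) / 2, edges[-1] - edges[0]),
            mode="sum",
        )
        total = sum(p.data for p in parts)
        denom = float(np.abs(full.data).max())
        assert float(np.abs(total - full.data).max()) / denom < 1e-6

    def test_slab_membership_selects_emitters(self):
        geom = MillingGeometry(milling_angle_deg=18.0, fov_um=10.0, image_px=100)
        _, u2, _ = projection_basis(geom)
        e = Emitter((5.0, 5.0, 2.0), 1.0, "green")
        spec = SceneSpec(bounds_um=(10, 10, 5), emitters=(e,), surface_z_um=4.5, noise_sigma=0.0)
        stack = render_confocal(spec, Frame3D((0.15, 0.15, 0.45)))
        iso = resample_isotropic(stack)
        d = float(np.array(e.position_um) @ u2)
        t = 2.0
        inside = virtual_lamella(iso, geom, VirtualLamellaSpec(d, t), mode="max")
        outside = virtual_lamella(iso, geom, VirtualLamellaSpec(d + t, t), mode="max")
        assert inside.channel("green").max() > 0.8
        assert outside.channel("green").max() < 0.1 * inside.channel("green").max()

    def test_top_down_mode_views_along_z(self, emitter_stack):
        spec, stack = emitter_stack
        iso = resample_isotropic(stack)
        geom = MillingGeometry(milling_angle_deg=18.0, fov_um=10.0, image_px=100)
        lo, hi, _ = _u2_range(iso, geom)
        img = virtual_lamella(
            iso, geom, VirtualLamellaSpec((lo + hi) / 2, hi - lo + 1), mode="max",
        )
        top = virtual_lamella(
            iso, geom,
            VirtualLamellaSpec((lo + hi) / 2, hi - lo + 1, render_mode="top_down"),
            mode="max",
        )
        # whole-volume top-down slab = plain axial MIP; face-on differs
        np.testing.assert_allclose(
            top.channel("green"), iso.channel("green").max(axis=0), atol=1e-6
        )
        assert top.modality == "LM_topdown" and img.modality == "LM_via_FIB"

    def test_empty_slab_reports_valid_range(self, emitter_stack):
        _, stack = emitter_stack
        geom = MillingGeometry(milling_angle_deg=18.0, fov_um=10.0, image_px=100)
        with pytest.raises(ValueError, match="valid offsets"):
            virtual_lamella(stack, geom, VirtualLamellaSpec(50.0, 0.5))

    def test_invalid_thickness_rejected(self):
        with pytest.raises(ValueError):
            VirtualLamellaSpec(0.0, -1.0)
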