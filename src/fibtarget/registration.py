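"""Reference-pattern detection, calibration, target mapping and spot fitting.

The registration principle: the LM-via-FIB projection and the ion-beam
image share one view, so a target is transferred between them by a pure
2D offset measured from a common benchmark — the FIB-etched cross-shaped
reference pattern (RP).  No fiducial beads, no coordinate transformation:
``fib_pos = rp_center_fib + (dx, dy) / fib_pixel`` with (dx, dy) the
target→RP offset measured on the LM-via-FIB image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import match_template

from .containers import ProjectedImage
from .scene import ReferencePatternSpec

__all__ = [
    "TargetRecord",
    "CalibrationResult",
    "RPDetection",
    "RPDetectionError",
    "SpotNotFoundError",
    "SpotFit",
    "nominal_pixel_nm",
    "detect_rp",
    "calibrate",
    "measure_offset",
    "map_to_fib",
    "localization_precision",
    "locate_spot",
]


class RPDetectionError(RuntimeError):
    """Raised when the reference pattern cannot be found confidently."""


class SpotNotFoundError(RuntimeError):
    """Raised when no local maximum stands above the background."""


@dataclass
class TargetRecord:
    """A target's bookkeeping across modalities.

    ``rp_offset_px = proj_pos_px − rp_center_px`` by construction;
    ``sigma_loc_nm`` is the localization-precision estimate attached to
    the measurement.
    """

    proj_pos_px: tuple[float, float]
    rp_offset_px: tuple[float, float]
    stack_pos_um: tuple[float, float, float] | None = None
    fib_pos_px: tuple[float, float] | None = None
    sigma_loc_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_loc_nm < 0:
            raise ValueError("sigma_loc_nm must be >= 0")


@dataclass(frozen=True)
class CalibrationResult:
    """Pixel sizes of the two modalities and the detected RP centers."""

    lm_pixel_nm: float
    fib_pixel_nm: float
    rp_center_lm_px: tuple[float, float]
    rp_center_fib_px: tuple[float, float]

    def __post_init__(self) -> None:
        if self.lm_pixel_nm <= 0 or self.fib_pixel_nm <= 0:
            raise ValueError("pixel sizes must be > 0")

    @property
    def scale_ratio(self) -> float:
        return self.lm_pixel_nm / self.fib_pixel_nm


def nominal_pixel_nm(fov_um: float, image_px: int) -> int:
    """Nominal integer pixel size in nm for a square FOV (truncated).

    An 84 µm field imaged at 1536 x 1536 gives 84000/1536 = 54.6875, i.e.
    a nominal 54 nm pixel — the figure quoted for both imaging modalities.
    """
    if fov_um <= 0 or image_px <= 0:
        raise ValueError("fov_um and image_px must be positive")
    return int(fov_um * 1000.0 // image_px)


@dataclass(frozen=True)
class RPDetection:
    center_px: tuple[float, float]  # (x, y) = (col, row)
    score: float


def _render_template(
    spec: ReferencePatternSpec,
    pixel_size_um: float,
    foreshortening: float,
    axial_sigma_um: float = 0.0,
) -> np.ndarray:
    """Cross template as an intensity deficit, foreshortened along rows.

    The template is rendered the way each modality actually sees the RP.
    In a surface view (ion-beam image) the cross is a sharp deficit,
    compressed by sin β along rows.  In an LM-via-FIB projection the
    bright-field surface is an axial-PSF-thick sheet max-projected along
    the oblique beam: each ray samples the surface over a y-range of
    ~σ_axial·cot β, so the deficit survives only where the cross covers
    that whole range.  With ``axial_sigma_um > 0`` the template models
    this by maximizing ``exp(−δ²/2σ²)·(1 − c·cross)`` over depth offsets
    δ along the ray, exactly mirroring the projection of the rendered
    surface sheet.
    """
    sin_b = foreshortening
    cos_b = float(np.sqrt(max(1.0 - sin_b**2, 0.0)))
    # keep the template compact along rows: a tall constant border would
    # overlap unrelated structure (e.g. the projected surface-band edge)
    # and bias the correlation peak
    half_a = spec.arm_length_um / 2 * 1.25
    half_b = half_a * sin_b + axial_sigma_um * cos_b
    n_a = max(int(np.ceil(2 * half_a / pixel_size_um)) | 1, 5)
    n_b = max(int(np.ceil(2 * half_b / pixel_size_um)) | 1, 5)
    a = (np.arange(n_a) - (n_a - 1) / 2) * pixel_size_um
    b = (np.arange(n_b) - (n_b - 1) / 2) * pixel_size_um
    centered = ReferencePatternSpec(
        center_um=(0.0, 0.0),
        arm_length_um=spec.arm_length_um,
        arm_width_um=spec.arm_width_um,
        depth_contrast=spec.depth_contrast,
    )
    if axial_sigma_um <= 0 or cos_b == 0.0:
        xp = np.broadcast_to(a[None, :], (n_b, n_a))
        yp = np.broadcast_to(b[:, None] / sin_b, (n_b, n_a))
        tmpl = -centered.coverage(xp, yp, pixel_size_um)
    else:
        deltas = np.linspace(-3 * axial_sigma_um, 3 * axial_sigma_um, 25)
        w = np.exp(-0.5 * (deltas / axial_sigma_um) ** 2)
        xp = np.broadcast_to(a[None, None, :], (len(deltas), n_b, n_a))
        yp = (b[None, :, None] - deltas[:, None, None] * cos_b) / sin_b
        yp = np.broadcast_to(yp, (len(deltas), n_b, n_a))
        sheet = w[:, None, None] * (
            1.0 - spec.depth_contrast * centered.coverage(xp, yp, pixel_size_um)
        )
        tmpl = sheet.max(axis=0)
    return ndimage.gaussian_filter(tmpl, 0.5)


def _quadratic_peak(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Subpixel refinement of a correlation maximum by 1D parabola fits."""
    r, c = peak
    out = [float(c), float(r)]
    for axis, (i, n) in enumerate(((c, corr.shape[1]), (r, corr.shape[0]))):
        if 0 < i < n - 1:
            if axis == 0:
                cm1, c0, cp1 = corr[r, i - 1], corr[r, i], corr[r, i + 1]
            else:
                cm1, c0, cp1 = corr[i - 1, c], corr[i, c], corr[i + 1, c]
            denom = cm1 - 2 * c0 + cp1
            if denom < 0:
                out[axis] = i + 0.5 * (cm1 - cp1) / denom
    return out[0], out[1]


#: Default axial PSF width assumed when matching the RP in an LM-via-FIB
#: projection (matches the synthetic-scene default for an NA-0.9 objective).
DEFAULT_AXIAL_SIGMA_UM = 0.45


def detect_rp(
    image: ProjectedImage,
    spec: ReferencePatternSpec,
    channel: str | None = None,
    foreshortening: float | None = None,
    axial_sigma_um: float | None = None,
    threshold: float = 0.5,
) -> RPDetection:
    """Locate the RP center by normalized cross-correlation.

    A cross template (foreshortened like the image; axially smeared for
    LM-via-FIB projections, see :func:`_render_template`) is matched
    against the chosen channel; the correlation peak is refined to
    subpixel precision by a quadratic fit.  Raises
    :class:`RPDetectionError` when the match score stays below
    ``threshold``, reporting the best candidate.
    """
    if channel is None:
        channel = "BF" if "BF" in image.channels else image.channels[0]
    img = np.asarray(image.channel(channel), dtype=np.float64)
    if foreshortening is None:
        foreshortening = float(image.provenance.get("foreshortening", 1.0))
    if axial_sigma_um is None:
        axial_sigma_um = DEFAULT_AXIAL_SIGMA_UM if image.modality == "LM_via_FIB" else 0.0
    tmpl = _render_template(spec, image.pixel_size_um, foreshortening, axial_sigma_um)
    if tmpl.shape[0] > img.shape[0] or tmpl.shape[1] > img.shape[1]:
        raise ValueError("RP template larger than the image; check the field of view")
    corr = match_template(img, tmpl, pad_input=True)
    r, c = np.unravel_index(int(np.argmax(corr)), corr.shape)
    x, y = _quadratic_peak(corr, (r, c))
    score = float(max(corr[r, c], 0.0))
    if score < threshold:
        raise RPDetectionError(
            f"reference pattern not found: best match score {score:.3f} < "
            f"{threshold} at pixel ({x:.1f}, {y:.1f})"
        )
    return RPDetection(center_px=(x, y), score=min(score, 1.0))


def _arm_length_px(img: np.ndarray, center: tuple[float, float], contrast: float) -> float:
    """Apparent horizontal arm length (px) from half-depth profile crossings."""
    x, y = center
    r = int(round(y))
    rows = img[max(r - 1, 0) : r + 2]
    profile = rows.mean(axis=0)
    baseline = np.median(profile)
    thresh = baseline - contrast * baseline / 2
    below = np.nonzero(profile < thresh)[0]
    if below.size < 2:
        raise RPDetectionError("cannot measure RP arm: no clear deficit profile")
    i0, i1 = below[0], below[-1]

    def _cross(i_out: int, i_in: int) -> float:
        p0, p1 = profile[i_out], profile[i_in]
        if p0 == p1:
            return float(i_in)
        return i_out + (p0 - thresh) / (p0 - p1) * (i_in - i_out)

    left = _cross(i0 - 1, i0) if i0 > 0 else float(i0)
    right = _cross(i1 + 1, i1) if i1 < profile.size - 1 else float(i1)
    return right - left


def calibrate(
    lm_img: ProjectedImage,
    fib_img: ProjectedImage,
    spec: ReferencePatternSpec,
    tolerance: float = 0.02,
) -> CalibrationResult:
    """Calibrate pixel sizes and locate the RP in both modalities.

    Pixel sizes come from image metadata (FOV / pixel count); the ratio is
    cross-validated against the RP as imaged — the only structure
    guaranteed present in both modalities.  Between two surface views the
    apparent arm lengths are measured directly and a discrepancy beyond
    ``tolerance`` (default 2%) warns; an LM-via-FIB projection smears the
    cross axially and carries no sharp scale information, so there the
    metadata is trusted (the projection pixel size is derived from the
    stack voxel size by construction).
    """
    det_lm = detect_rp(lm_img, spec)
    det_fib = detect_rp(fib_img, spec)
    lm_nm = lm_img.pixel_size_um * 1000.0
    fib_nm = fib_img.pixel_size_um * 1000.0
    meta_ratio = lm_nm / fib_nm
    try:
        if lm_img.modality != "LM_via_FIB" and fib_img.modality != "LM_via_FIB":
            # both are surface views with a sharp cross: measure the
            # (unforeshortened) horizontal arm in pixels in each image
            lm_ch = "BF" if "BF" in lm_img.channels else lm_img.channels[0]
            arm_lm = _arm_length_px(
                np.asarray(lm_img.channel(lm_ch)), det_lm.center_px, spec.depth_contrast
            )
            arm_fib = _arm_length_px(
                np.asarray(fib_img.channel(fib_img.channels[0])),
                det_fib.center_px,
                spec.depth_contrast,
            )
            measured_ratio = arm_fib / arm_lm  # same physical arm -> pixel ratio
        else:
            # the projected bright-field cross has no sharp arm profile (the
            # oblique max-projection smears it by ~sigma_axial*cot(beta)), so
            # it carries no usable scale information; the LM-via-FIB pixel
            # size is derived from the stack voxel size by construction and
            # the metadata is trusted
            logging.getLogger(__name__).info(
                "pixel-size cross-check skipped: projected cross carries no "
                "sharp scale information; trusting metadata pixel sizes"
            )
            measured_ratio = None
        if measured_ratio is not None and abs(measured_ratio / meta_ratio - 1.0) > tolerance:
            warnings.warn(
                f"pixel-size cross-check: RP-derived ratio {measured_ratio:.4f} deviates "
                f"from metadata ratio {meta_ratio:.4f} by more than {tolerance:.0%}",
                stacklevel=2,
            )
    except RPDetectionError:
        warnings.warn("RP arm length not measurable; trusting metadata pixel sizes", stacklevel=2)
    return CalibrationResult(
        lm_pixel_nm=lm_nm,
        fib_pixel_nm=fib_nm,
        rp_center_lm_px=det_lm.center_px,
        rp_center_fib_px=det_fib.center_px,
    )


def measure_offset(
    proj: ProjectedImage,
    target_px: tuple[float, float],
    rp_center_px: tuple[float, float],
    calib: CalibrationResult | None = None,
) -> tuple[float, float, float]:
    """Target→RP offset (dx, dy) in µm on the LM-via-FIB image, plus distance.

    Physical offsets are pixel offsets times the calibrated pixel size.
    """
    pixel_um = (calib.lm_pixel_nm / 1000.0) if calib is not None else proj.pixel_size_um
    dx = (target_px[0] - rp_center_px[0]) * pixel_um
    dy = (target_px[1] - rp_center_px[1]) * pixel_um
    return dx, dy, float(np.hypot(dx, dy))


def map_to_fib(
    offset_um: tuple[float, float],
    calib: CalibrationResult,
    fib_shape_hw: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Map a (dx, dy) µm offset onto the ion-beam image via the RP there.

    ``fib_pos = rp_center_fib + (dx, dy) / fib_pixel`` — no image
    superposition involved.  With ``fib_shape_hw`` given, a position
    outside the image raises with the offending coordinates.
    """
    fx = calib.rp_center_fib_px[0] + offset_um[0] * 1000.0 / calib.fib_pixel_nm
    fy = calib.rp_center_fib_px[1] + offset_um[1] * 1000.0 / calib.fib_pixel_nm
    if fib_shape_hw is not None:
        h, w = fib_shape_hw
        if not (0 <= fx <= w - 1 and 0 <= fy <= h - 1):
            raise ValueError(
                f"mapped position ({fx:.1f}, {fy:.1f}) px falls outside the "
                f"{w} x {h} ion-beam image"
            )
    return fx, fy


def localization_precision(
    pixel_nm: float,
    sel_err_px: float | tuple[float, ...] | list[float],
    mode: str = "worst_case",
) -> float:
    """Localization precision (nm) from manual pick errors.

    ``worst_case`` (default): max pick error times the pixel size — a 4 px
    pick at a 54 nm pixel gives 216 nm, the "approximately 200 nm" budget.
    ``quadrature``: pixel size times the root-sum-square of the independent
    pick errors (TOI and RP in each modality).  Monotone non-decreasing in
    every input.
    """
    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be > 0")
    errs = np.atleast_1d(np.asarray(sel_err_px, dtype=float))
    if np.any(errs < 0):
        raise ValueError("selection errors must be >= 0")
    if mode == "worst_case":
        return float(pixel_nm * errs.max())
    if mode == "quadrature":
        return float(pixel_nm * np.sqrt(np.sum(errs**2)))
    raise ValueError("mode must be 'worst_case' or 'quadrature'")


@dataclass(frozen=True)
class SpotFit:
    """Refined spot position; coordinates are (x, y[, z]) fractional pixels."""

    position_px: tuple[float, ...]
    sigma_px: tuple[float, ...]
    amplitude: float
    method: str  # "gaussian" or "centroid"


def _gauss2d(coords, amp, x0, y0, sx, sy, off):
    x, y = coords
    return (
        amp * np.exp(-((x - x0) ** 2) / (2 * sx**2) - ((y - y0) ** 2) / (2 * sy**2)) + off
    ).ravel()


def locate_spot(
    data: np.ndarray,
    approx_px: tuple[float, ...] | None = None,
    search_radius_px: int = 6,
    window_px: int = 5,
    min_snr: float = 4.0,
) -> SpotFit:
    """Refine a point-target position to subpixel/subvoxel precision.

    Finds the brightest pixel (within ``search_radius_px`` of ``approx_px``
    if given), then fits a Gaussian around it — a 2D elliptical Gaussian
    for images, per-axis 1D Gaussians of the marginal profiles for stacks —
    falling back to an intensity-weighted centroid if the fit fails.
    Raises :class:`SpotNotFoundError` when no maximum stands ``min_snr``
    robust sigmas above the background.
    """
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim not in (2, 3):
        raise ValueError("expected a 2D image or 3D stack")
    bg = float(np.median(arr))
    sigma = 1.4826 * float(np.median(np.abs(arr - bg)))

    if approx_px is not None:
        idx = tuple(int(round(c)) for c in reversed(approx_px))  # (z,)y,x -> index order
        sl = tuple(
            slice(max(i - search_radius_px, 0), min(i + search_radius_px + 1, n))
            for i, n in zip(idx, arr.shape)
        )
        sub = arr[sl]
        loc = np.unravel_index(int(np.argmax(sub)), sub.shape)
        peak_idx = tuple(s.start + l for s, l in zip(sl, loc))
    else:
        peak_idx = np.unravel_index(int(np.argmax(arr)), arr.shape)
    peak = arr[peak_idx]
    if peak - bg <= max(min_snr * sigma, 1e-12):
        raise SpotNotFoundError(
            f"no spot: peak {peak:.4g} within {min_snr} robust sigmas of background {bg:.4g}"
        )

    w = window_px
    sl = tuple(
        slice(max(i - w, 0), min(i + w + 1, n)) for i, n in zip(peak_idx, arr.shape)
    )
    sub = arr[sl] - bg
    offs = np.array([s.start for s in sl], dtype=float)

    if arr.ndim == 2:
        yy, xx = np.mgrid[sl]
        p0 = (float(sub.max()), float(peak_idx[1]), float(peak_idx[0]), 1.5, 1.5, 0.0)
        try:
            popt, _ = optimize.curve_fit(
                _gauss2d,
                (xx.astype(float), yy.astype(float)),
                (arr[sl] - bg).ravel(),
                p0=p0,
                bounds=(
                    [0, sl[1].start, sl[0].start, 0.2, 0.2, -np.inf],
                    [np.inf, sl[1].stop - 1, sl[0].stop - 1, 4 * w, 4 * w, np.inf],
                ),
                maxfev=2000,
            )
            return SpotFit(
                position_px=(float(popt[1]), float(popt[2])),
                sigma_px=(float(popt[3]), float(popt[4])),
                amplitude=float(popt[0]),
                method="gaussian",
            )
        except (RuntimeError, ValueError):
            pass
        wgt = np.clip(sub, 0, None)
        cy = float((wgt.sum(axis=1) * (offs[0] + np.arange(sub.shape[0]))).sum() / wgt.sum())
        cx = float((wgt.sum(axis=0) * (offs[1] + np.arange(sub.shape[1]))).sum() / wgt.sum())
        return SpotFit(
            position_px=(cx, cy), sigma_px=(np.nan, np.nan), amplitude=float(peak - bg), method="centroid"
        )

    # 3D: 1D Gaussian fit of each marginal profile through the window
    centers, widths = [], []
    for ax in range(3):
        other = tuple(i for i in range(3) if i != ax)
        prof = np.clip(sub, 0, None).sum(axis=other)
        coords = offs[ax] + np.arange(prof.size)

        def _g1(x, amp, x0, s, off):
            return amp * np.exp(-((x - x0) ** 2) / (2 * s**2)) + off

        try:
            popt, _ = optimize.curve_fit(
                _g1,
                coords,
                prof,
                p0=(float(prof.max()), float(peak_idx[ax]), 1.5, 0.0),
                maxfev=2000,
            )
            centers.append(float(popt[1]))
            widths.append(abs(float(popt[2])))
        except (RuntimeError, ValueError):
            centers.append(float((prof * coords).sum() / prof.sum()))
            widths.append(np.nan)
    # index order (z, y, x) -> coordinate order (x, y, z)
    return SpotFit(
        position_px=(centers[2], centers[1], centers[0]),
        sigma_px=(widths[2], widths[1], widths[0]),
        amplitude=float(peak - bg),
        method="gaussian",
    )
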