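"""Contour-perpendicular FWHM profiling of membrane images.

Reimplements the bulk line-profile workflow used to estimate effective
optical resolution from images of thin membranes: resample a user-traced
contour at regular arc-length intervals (default every 3 px), draw a
perpendicular line at each point (default 40 px long), sample the image
along it, fit a Gaussian, and report FWHM = 2*sqrt(2 ln 2) * sigma.
Because a lipid bilayer (~8 nm) is far thinner than any optical
resolution, the mean measured FWHM estimates the effective PSF FWHM, and
the confocal/STED ratio of means quantifies the resolution gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.ndimage import map_coordinates, spline_filter
from scipy.optimize import curve_fit

from .core_io import ContourPolyline, ImageStack

GAUSS_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class ProfileSamplingParams:
    """How profiles are placed and sampled along the contour.

    ``spacing_px``: arc-length gap between consecutive anchors (default 3).
    ``profile_length_px``: total perpendicular line length (default 40,
    even); samples run over [-L/2, +L/2].
    ``samples_per_px``: sampling density along the line; the default 1
    mirrors a 40-sample line.
    ``interp_order``: spline order for sub-pixel sampling.  The default 3
    (cubic) keeps interpolation broadening negligible; bilinear (1) is
    available but measurably widens profiles narrower than ~2 px SD.
    """

    spacing_px: float = 3.0
    profile_length_px: int = 40
    samples_per_px: int = 1
    interp_order: int = 3

    def __post_init__(self) -> None:
        if not self.spacing_px > 0:
            raise ValueError("spacing_px must be positive")
        if self.profile_length_px < 8 or self.profile_length_px % 2:
            raise ValueError("profile_length_px must be an even integer >= 8")
        if self.samples_per_px < 1:
            raise ValueError("samples_per_px must be >= 1")


@dataclass
class LineProfile:
    """One perpendicular intensity profile."""

    anchor: tuple[float, float]
    direction: tuple[float, float]  # unit normal to the local tangent
    positions: np.ndarray  # signed offsets, px, symmetric about 0
    intensities: np.ndarray
    rejected: bool = False  # endpoints left the image


@dataclass
class GaussianFitResult:
    """Least-squares Gaussian fit of one profile and its derived FWHM."""

    offset: float = float("nan")
    amplitude: float = float("nan")
    center_px: float = float("nan")
    sigma_px: float = float("nan")
    fwhm_px: float = float("nan")
    fwhm_nm: float = float("nan")
    converged: bool = False
    rss: float = float("nan")
    reason: str = ""  # why the fit was rejected, empty when converged


@dataclass
class FWHMSummary:
    """Aggregate FWHM over the converged fits of one or more images."""

    n_profiles_used: int
    n_rejected: int
    mean_fwhm_nm: float
    sd_fwhm_nm: float
    per_image_means_nm: list[float] = field(default_factory=list)


class ResolutionRatio(NamedTuple):
    ratio: float
    sd: float


# ---------------------------------------------------------------------------
# Contour resampling
# ---------------------------------------------------------------------------

def resample_contour(
    contour: ContourPolyline, spacing_px: float = 3.0
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Anchors at arc-length multiples of ``spacing_px`` with unit tangents.

    Anchors are placed along the polyline starting at vertex 0; a final
    partial interval is dropped.  The tangent at each anchor is the central
    difference across its neighbouring anchors (wrapping for closed
    contours, one-sided at the open ends).
    """
    if not spacing_px > 0:
        raise ValueError("spacing_px must be positive")
    verts = contour.vertices
    if contour.closed:
        verts = np.vstack([verts, verts[:1]])
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    if total <= 0:
        raise ValueError("zero-length contour")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_anchor = int(math.floor(total / spacing_px)) + 1
    arcs = np.arange(n_anchor) * spacing_px
    if contour.closed and n_anchor > 1 and abs(arcs[-1] - total) < 1e-9:
        arcs = arcs[:-1]  # avoid duplicating the start point
    xs = np.interp(arcs, cum, verts[:, 0])
    ys = np.interp(arcs, cum, verts[:, 1])
    pts = np.column_stack([xs, ys])

    n = len(pts)
    tangents = np.zeros_like(pts)
    if n == 1:
        tangents[0] = seg[0] / seg_len[0]
    elif contour.closed:
        tangents = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    else:
        tangents[1:-1] = pts[2:] - pts[:-2]
        tangents[0] = pts[1] - pts[0]
        tangents[-1] = pts[-1] - pts[-2]
    norm = np.hypot(tangents[:, 0], tangents[:, 1])
    norm[norm == 0] = 1.0
    tangents /= norm[:, None]
    return [
        ((float(px), float(py)), (float(tx), float(ty)))
        for (px, py), (tx, ty) in zip(pts, tangents)
    ]


# ---------------------------------------------------------------------------
# Profile extraction
# ---------------------------------------------------------------------------

def extract_profile(
    image: np.ndarray,
    anchor: tuple[float, float],
    normal: tuple[float, float],
    params: ProfileSamplingParams | None = None,
    image_is_prefiltered: bool = False,
) -> LineProfile:
    """Sample the image along a perpendicular line centred on ``anchor``.

    Intensities are spline-interpolated (cubic by default) at equidistant
    signed offsets in ``[-L/2, +L/2]``.  A profile whose endpoints leave
    the image is marked ``rejected`` rather than raising.  Callers
    sampling many profiles from one image can pass the output of
    :func:`scipy.ndimage.spline_filter` with ``image_is_prefiltered=True``
    to avoid re-filtering per profile.
    """
    params = params or ProfileSamplingParams()
    half = params.profile_length_px / 2.0
    n = params.profile_length_px * params.samples_per_px + 1
    positions = np.linspace(-half, half, n)
    nx, ny = normal
    nrm = math.hypot(nx, ny)
    nx, ny = nx / nrm, ny / nrm
    x = anchor[0] + positions * nx
    y = anchor[1] + positions * ny
    h, w = image.shape
    rejected = bool(
        x.min() < 0 or y.min() < 0 or x.max() > w - 1 or y.max() > h - 1
    )
    if rejected:
        vals = np.full(n, np.nan)
    else:
        vals = map_coordinates(
            np.asarray(image, dtype=np.float64),
            np.vstack([y, x]),
            order=params.interp_order,
            mode="mirror",
            prefilter=not image_is_prefiltered,
        )
    return LineProfile(
        anchor=(float(anchor[0]), float(anchor[1])),
        direction=(nx, ny),
        positions=positions,
        intensities=vals,
        rejected=rejected,
    )


# ---------------------------------------------------------------------------
# Gaussian fitting
# ---------------------------------------------------------------------------

def _gauss(x: np.ndarray, offset: float, amp: float, center: float, sigma: float):
    return offset + amp * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def fit_gaussian_profile(
    profile: LineProfile,
    pixel_size_nm: float = 20.0,
    min_sigma_px: float = 0.5,
    contrast_snr: float = 2.0,
) -> GaussianFitResult:
    """Fit ``offset + amp * exp(-(x-c)^2 / 2 sigma^2)`` to one profile.

    Initialisation: offset = min, amplitude = max - min, centre at the
    argmax, sigma from the profile's second moment about the argmax.  The
    fit is marked non-converged when the optimiser fails or when any
    rejection rule fires: sigma outside (``min_sigma_px``, L/4), centre
    farther than L/4 from the anchor (e.g. a second membrane dominating
    the window), or amplitude below ``contrast_snr`` times the residual
    noise SD.  These rules are deliberately conservative so border and
    bimodal profiles drop out instead of biasing the mean.
    """
    res = GaussianFitResult()
    if profile.rejected:
        res.reason = "profile left the image"
        return res
    x = profile.positions
    y = profile.intensities
    if len(y) < 8 or not np.all(np.isfinite(y)):
        res.reason = "too few finite samples"
        return res
    ymin, ymax = float(y.min()), float(y.max())
    if ymax == ymin:
        res.reason = "flat profile"
        return res
    L = float(x.max() - x.min())
    i_max = int(np.argmax(y))
    wgt = np.clip(y - ymin, 0.0, None)
    sigma0 = math.sqrt(float(np.sum(wgt * (x - x[i_max]) ** 2) / np.sum(wgt)))
    sigma0 = min(max(sigma0, min_sigma_px), L / 4.0)
    p0 = [ymin, ymax - ymin, float(x[i_max]), sigma0]
    try:
        popt, _ = curve_fit(_gauss, x, y, p0=p0, maxfev=2000)
    except (RuntimeError, ValueError):
        res.reason = "optimizer failed"
        return res
    offset, amp, center, sigma = map(float, popt)
    sigma = abs(sigma)
    resid = y - _gauss(x, *popt)
    rss = float(np.sum(resid**2))
    noise_sd = float(np.std(resid))
    res = GaussianFitResult(
        offset=offset,
        amplitude=amp,
        center_px=center,
        sigma_px=sigma,
        fwhm_px=GAUSS_FWHM_FACTOR * sigma,
        fwhm_nm=GAUSS_FWHM_FACTOR * sigma * pixel_size_nm,
        converged=True,
        rss=rss,
    )
    if amp <= 0:
        res.converged, res.reason = False, "non-positive amplitude"
    elif not (min_sigma_px < sigma < L / 4.0):
        res.converged, res.reason = False, "sigma out of bounds"
    elif abs(center) > L / 4.0:
        res.converged, res.reason = False, "centre outside window"
    elif noise_sd > 0 and amp < contrast_snr * noise_sd:
        res.converged, res.reason = False, "insufficient contrast"
    return res


def summarize_fwhm(
    fits: Sequence[GaussianFitResult], pixel_size_nm: float = 20.0
) -> FWHMSummary:
    """Mean and SD of FWHM (nm) over converged fits only."""
    used = [f for f in fits if f.converged]
    n_rej = len(fits) - len(used)
    if not used:
        raise ValueError("no valid profiles: every fit was rejected")
    vals = np.array([
        f.fwhm_nm if np.isfinite(f.fwhm_nm) else f.fwhm_px * pixel_size_nm
        for f in used
    ])
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return FWHMSummary(
        n_profiles_used=len(used),
        n_rejected=n_rej,
        mean_fwhm_nm=float(vals.mean()),
        sd_fwhm_nm=sd,
    )


def profile_image_fwhm(
    image: np.ndarray,
    contour: ContourPolyline,
    pixel_size_nm: float = 20.0,
    params: ProfileSamplingParams | None = None,
) -> list[GaussianFitResult]:
    """Full per-image pipeline: resample, extract perpendiculars, fit.

    The perpendicular at each anchor is the local tangent rotated by 90°.
    Returns every fit (converged or not) in anchor order.
    """
    params = params or ProfileSamplingParams()
    image = np.asarray(image, dtype=np.float64)
    prefiltered = params.interp_order > 1
    if prefiltered:
        image = spline_filter(image, order=params.interp_order, mode="mirror")
    fits = []
    for anchor, (tx, ty) in resample_contour(contour, params.spacing_px):
        normal = (-ty, tx)
        prof = extract_profile(
            image, anchor, normal, params, image_is_prefiltered=prefiltered
        )
        fits.append(fit_gaussian_profile(prof, pixel_size_nm=pixel_size_nm))
    return fits


def aggregate_images(
    per_image_fits: Sequence[Sequence[GaussianFitResult]],
    pixel_size_nm: float = 20.0,
) -> FWHMSummary:
    """Pool fits over several images and also report per-image means.

    The headline mean/SD pools every converged profile; the per-image
    means support the alternative order of averaging (mean of image
    means), which for balanced designs agrees closely.
    """
    flat = [f for fits in per_image_fits for f in fits]
    summary = summarize_fwhm(flat, pixel_size_nm)
    for fits in per_image_fits:
        used = [f.fwhm_nm for f in fits if f.converged]
        if used:
            summary.per_image_means_nm.append(float(np.mean(used)))
    return summary


def resolution_ratio(confocal: FWHMSummary, sted: FWHMSummary) -> ResolutionRatio:
    """Confocal mean FWHM over STED mean FWHM; > 1 means finer STED detail.

    The SD is propagated to first order from the two summary SDs.
    """
    if sted.mean_fwhm_nm == 0:
        raise ZeroDivisionError("STED mean FWHM is zero")
    r = confocal.mean_fwhm_nm / sted.mean_fwhm_nm
    rel = 0.0
    if confocal.mean_fwhm_nm != 0:
        rel = math.sqrt(
            (confocal.sd_fwhm_nm / confocal.mean_fwhm_nm) ** 2
            + (sted.sd_fwhm_nm / sted.mean_fwhm_nm) ** 2
        )
    return ResolutionRatio(ratio=r, sd=abs(r) * rel)


def measure_stack_fwhm(
    stack: ImageStack,
    contour: ContourPolyline,
    params: ProfileSamplingParams | None = None,
) -> FWHMSummary:
    """Convenience: run the profile pipeline on every page of a stack."""
    fits = [
        profile_image_fwhm(pg, contour, stack.pixel_size_nm, params)
        for pg in stack.pages
    ]
    return aggregate_images(fits, stack.pixel_size_nm)
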