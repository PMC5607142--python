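"""Synthetic membrane phantoms with complete ground truth.

The generator emulates the specimens the analysis modules are built for:
equatorial planes of giant plasma-membrane vesicles (GPMVs) appearing as
thin rings, phase-separated vesicles with ordered/disordered arcs,
sub-resolution discs standing in for endocytic vesicles or virions, and a
GFP-filled lumen for spectral-separation scenarios.

Physical picture
----------------
The membrane is a ring of radius ``radius_nm`` with a rectangular (top-hat)
radial cross-section of width ``membrane_width_nm`` (default 8 nm — the
thickness of a lipid bilayer, far below any optical resolution, so the
cross-section shape is immaterial but is stated).  Each painted arc or disc
emits ``brightness`` expected photons per nm of contour (per frame); those
photons are split across detection bands or 9-nm spectral windows either by
a fixed channel fraction or by integrating a Gaussian emission spectrum.
The optics are an isotropic 2-D Gaussian PSF parameterised by its FWHM
(presets: confocal 240 nm, STED 80 nm).  Rendering happens on a 4x
supersampled grid and is box-binned to the target pixel size so that line
integrals through the thin membrane are accurate; Poisson noise is applied
independently per pixel and page when requested.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .core_io import AxisKind, CircleRoi, ContourPolyline, ImageStack, RoiSet

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: effective PSF FWHM presets in nm for the two imaging modes
PSF_PRESETS_NM = {"confocal": 240.0, "sted": 80.0}


class NoiseModel(str, enum.Enum):
    NONE = "none"
    POISSON = "poisson"


@dataclass
class EmissionModel:
    """Gaussian emission spectrum of a probe in one membrane environment."""

    peak_nm: float
    width_nm: float  # spectral SD, nm
    brightness: float = 1.0  # expected photons per nm of membrane per frame

    def __post_init__(self) -> None:
        if not self.width_nm > 0:
            raise ValueError("width_nm must be positive")
        if not self.brightness > 0:
            raise ValueError("brightness must be positive")


@dataclass
class PhasePaint:
    """How a membrane phase (or object) distributes photons across bands.

    Exactly one of ``spectrum`` and ``channel_fraction_1`` must be set.
    ``channel_fraction_1`` is the fraction of detected photons landing in
    the first (ordered, lower-wavelength) detection band; the remainder
    lands in the second.  For a two-band acquisition this fixes the true
    generalized polarization: ``GP_true = 2 * channel_fraction_1 - 1``.
    """

    brightness: float = 50.0
    spectrum: EmissionModel | None = None
    channel_fraction_1: float | None = None

    def __post_init__(self) -> None:
        if (self.spectrum is None) == (self.channel_fraction_1 is None):
            raise ValueError(
                "set exactly one of spectrum / channel_fraction_1"
            )
        if self.channel_fraction_1 is not None and not (
            0.0 <= self.channel_fraction_1 <= 1.0
        ):
            raise ValueError("channel_fraction_1 must be in [0, 1]")
        if not self.brightness > 0:
            raise ValueError("brightness must be positive")


@dataclass
class ArcPhase:
    """An angular arc of the vesicle membrane bound to one paint."""

    label: str
    start_deg: float
    end_deg: float
    paint: PhasePaint
    purpose: str = "membrane"

    @property
    def span_deg(self) -> float:
        return (self.end_deg - self.start_deg) % 360.0 or 360.0


@dataclass
class DiscObject:
    """Sub-resolution disc (endocytic vesicle, virion, or filled lumen).

    ``total_photons`` is the expected photon budget of the whole disc per
    frame; the paint's per-length brightness does not apply to discs.
    """

    label: str
    center_px: tuple[float, float]
    diameter_nm: float
    paint: PhasePaint
    total_photons: float = 10000.0
    purpose: str = "vesicle"

    def __post_init__(self) -> None:
        if not self.diameter_nm > 0:
            raise ValueError("diameter_nm must be positive")
        if not self.total_photons > 0:
            raise ValueError("total_photons must be positive")


@dataclass
class PhantomSpec:
    """Full generative description of one synthetic acquisition."""

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 20.0
    vesicle_center_px: tuple[float, float] | None = None  # default: image centre
    vesicle_radius_nm: float = 2000.0
    membrane_width_nm: float = 8.0
    phases: list[ArcPhase] = field(default_factory=list)
    extra_objects: list[DiscObject] = field(default_factory=list)
    psf_fwhm_nm: float = PSF_PRESETS_NM["sted"]
    detection_bands_nm: list[tuple[float, float]] | None = None
    lambda_windows_nm: tuple[float, float, float] | None = None  # (start, stop, step=9)
    bleach_survival_per_frame: float = 1.0
    n_frames: int = 1
    noise: NoiseModel = NoiseModel.NONE
    seed: int = 0
    supersample: int = 4
    background_offset: float = 0.0  # additive expected counts per pixel
    band_transmission: list[float] | None = None  # optional per-band gain
    roi_radius_nm: float = 150.0

    def __post_init__(self) -> None:
        self.noise = NoiseModel(self.noise)
        if self.vesicle_center_px is None:
            h, w = self.image_size_px
            self.vesicle_center_px = ((w - 1) / 2.0, (h - 1) / 2.0)
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        if not 0.0 < self.bleach_survival_per_frame <= 1.0:
            raise ValueError("bleach_survival_per_frame must be in (0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if self.phases and self.membrane_width_nm >= self.psf_fwhm_nm:
            raise ValueError(
                "membrane_width_nm must be below psf_fwhm_nm (sub-resolution membrane)"
            )
        if self.lambda_windows_nm is not None:
            start, stop, step = self.lambda_windows_nm
            if step != 9:
                raise ValueError("lambda window step must be 9 nm")
            if stop <= start:
                raise ValueError("lambda window range is empty")
        if self.phases:
            _check_arc_cover(self.phases)
        if self.detection_bands_nm is not None:
            edges = sorted(self.detection_bands_nm)
            for (lo0, hi0), (lo1, hi1) in zip(edges, edges[1:]):
                if lo1 < hi0:
                    raise ValueError("detection bands overlap")

    # -- derived ---------------------------------------------------------
    def band_edges(self) -> list[tuple[float, float]] | None:
        """Band edges of the rendered pages (windows, bands, or None)."""
        if self.lambda_windows_nm is not None:
            start, stop, step = self.lambda_windows_nm
            edges = []
            lo = start
            while lo + step <= stop + 1e-9:
                edges.append((lo, lo + step))
                lo += step
            return edges
        if self.detection_bands_nm is not None:
            return [tuple(b) for b in self.detection_bands_nm]
        return None

    def axis_kind(self) -> AxisKind:
        if self.n_frames > 1:
            return AxisKind.TIME
        if self.lambda_windows_nm is not None:
            return AxisKind.WAVELENGTH
        if self.detection_bands_nm is not None:
            return AxisKind.CHANNEL
        return AxisKind.SINGLE


@dataclass
class GroundTruth:
    """Generative truth attached to a rendered phantom."""

    gp_true: dict[str, float]  # per label; only for two-band acquisitions
    band_fractions: dict[str, np.ndarray]  # per label, one value per page
    psf_fwhm_nm: float
    bleach_survival_per_frame: float
    contour: ContourPolyline | None
    seed: int


def _check_arc_cover(phases: Sequence[ArcPhase]) -> None:
    """Arcs must tile [0, 360) exactly, without overlap."""
    if len(phases) == 1 and phases[0].span_deg == 360.0:
        return
    arcs = sorted(
        ((p.start_deg % 360.0, p.span_deg, p.label) for p in phases),
        key=lambda t: t[0],
    )
    total = sum(a[1] for a in arcs)
    if abs(total - 360.0) > 1e-6:
        raise ValueError(f"arcs cover {total:.4f} degrees, need exactly 360")
    for (s0, span0, lb0), (s1, _, lb1) in zip(arcs, arcs[1:] + arcs[:1]):
        end0 = (s0 + span0) % 360.0
        if abs((end0 - s1) % 360.0) > 1e-6 and abs((end0 - s1) % 360.0 - 360.0) > 1e-6:
            raise ValueError(f"arcs {lb0!r} and {lb1!r} overlap or leave a gap")


# ---------------------------------------------------------------------------
# Spectral band integration
# ---------------------------------------------------------------------------

def band_fractions(
    model: EmissionModel, bands: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Fraction of a unit-normalised Gaussian spectrum inside each band.

    The spectrum is a Gaussian centred at ``peak_nm`` with SD ``width_nm``,
    normalised over the whole wavelength axis; returned values therefore
    lie in [0, 1] and sum to at most 1 for non-overlapping bands.
    """
    edges = [(float(lo), float(hi)) for lo, hi in bands]
    for lo, hi in edges:
        if lo >= hi:
            raise ValueError(f"degenerate band ({lo}, {hi})")
    for (lo0, hi0), (lo1, hi1) in zip(sorted(edges), sorted(edges)[1:]):
        if lo1 < hi0:
            raise ValueError("bands overlap")
    s = model.width_nm * math.sqrt(2.0)
    out = [
        0.5 * (erf((hi - model.peak_nm) / s) - erf((lo - model.peak_nm) / s))
        for lo, hi in edges
    ]
    return np.asarray(out, dtype=float)


def _paint_page_fractions(
    paint: PhasePaint, edges: list[tuple[float, float]] | None
) -> np.ndarray:
    """Per-page photon fractions for one paint under the acquisition bands."""
    if edges is None:
        return np.array([1.0])
    if paint.spectrum is not None:
        return band_fractions(paint.spectrum, edges)
    f = paint.channel_fraction_1
    if len(edges) == 1:
        return np.array([1.0])
    if len(edges) == 2:
        return np.array([f, 1.0 - f])
    raise ValueError(
        "channel_fraction paints need one or two detection bands; "
        "use a spectrum paint for lambda stacks"
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_label_fields(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Noise-free PSF-blurred image (target grid) of each painted label.

    The label field holds expected photons per pixel for a photon budget of
    one *full* emission (all bands summed); per-page images scale these by
    the paint's band fractions.  Convolution commutes with the band split,
    so each label is convolved once.
    """
    s = spec.supersample
    h, w = spec.image_size_px
    sub_nm = spec.pixel_size_nm / s
    # subpixel centres in pixel coordinates
    xs = (np.arange(w * s, dtype=np.float64) + 0.5) / s - 0.5
    ys = (np.arange(h * s, dtype=np.float64) + 0.5) / s - 0.5
    cx, cy = spec.vesicle_center_px
    dx = (xs[None, :] - cx) * spec.pixel_size_nm
    dy = (ys[:, None] - cy) * spec.pixel_size_nm
    sigma_sub = spec.psf_fwhm_nm * FWHM_TO_SIGMA / sub_nm

    fields: dict[str, np.ndarray] = {}

    def _blur_bin(sub_img: np.ndarray) -> np.ndarray:
        blurred = gaussian_filter(sub_img, sigma_sub, mode="constant", truncate=6.0)
        return blurred.reshape(h, s, w, s).sum(axis=(1, 3))

    if spec.phases:
        r = np.sqrt(dx * dx + dy * dy)
        annulus = np.abs(r - spec.vesicle_radius_nm) <= spec.membrane_width_nm / 2.0
        theta = np.degrees(np.arctan2(dy, dx)) % 360.0
        for ph in spec.phases:
            if ph.span_deg == 360.0:
                mask = annulus
            else:
                s0 = ph.start_deg % 360.0
                e0 = ph.end_deg % 360.0
                if s0 < e0:
                    mask = annulus & (theta >= s0) & (theta < e0)
                else:  # wraps through 0 degrees
                    mask = annulus & ((theta >= s0) | (theta < e0))
            # photons per nm of contour -> areal density over the top-hat
            density = ph.paint.brightness / spec.membrane_width_nm * sub_nm**2
            sub_img = np.zeros((h * s, w * s), dtype=np.float64)
            sub_img[mask] = density
            fields[ph.label] = _blur_bin(sub_img)

    for obj in spec.extra_objects:
        ox, oy = obj.center_px
        rad_nm = obj.diameter_nm / 2.0
        odx = (xs[None, :] - ox) * spec.pixel_size_nm
        ody = (ys[:, None] - oy) * spec.pixel_size_nm
        mask = odx * odx + ody * ody <= rad_nm * rad_nm
        n_sub = int(mask.sum())
        if n_sub == 0:
            raise ValueError(f"disc {obj.label!r} covers no subpixels")
        sub_img = np.zeros((h * s, w * s), dtype=np.float64)
        sub_img[mask] = obj.total_photons / n_sub
        if obj.label in fields:
            fields[obj.label] = fields[obj.label] + _blur_bin(sub_img)
        else:
            fields[obj.label] = _blur_bin(sub_img)

    if not fields:
        raise ValueError("phantom paints nothing: no phases and no extra objects")
    return fields


def _all_paints(spec: PhantomSpec) -> dict[str, PhasePaint]:
    paints: dict[str, PhasePaint] = {}
    for ph in spec.phases:
        paints[ph.label] = ph.paint
    for obj in spec.extra_objects:
        paints[obj.label] = obj.paint
    return paints


def _membrane_contour(spec: PhantomSpec, n_vertices: int = 360) -> ContourPolyline | None:
    if not spec.phases:
        return None
    cx, cy = spec.vesicle_center_px
    r_px = spec.vesicle_radius_nm / spec.pixel_size_nm
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    verts = np.column_stack([cx + r_px * np.cos(ang), cy + r_px * np.sin(ang)])
    return ContourPolyline(vertices=verts, closed=True)


def phantom_rois(spec: PhantomSpec) -> RoiSet:
    """ROIs the ground truth implies: the membrane contour (labelled
    ``contour``), one circle per painted arc (at the arc's mid-angle,
    radius ``roi_radius_nm``) and one circle per disc object."""
    rois = RoiSet()
    contour = _membrane_contour(spec)
    if contour is not None:
        rois.add("contour", contour, purpose="membrane")
    cx, cy = spec.vesicle_center_px
    r_px = spec.vesicle_radius_nm / spec.pixel_size_nm
    roi_r_px = spec.roi_radius_nm / spec.pixel_size_nm
    for ph in spec.phases:
        mid = math.radians((ph.start_deg + ph.span_deg / 2.0) % 360.0)
        center = (cx + r_px * math.cos(mid), cy + r_px * math.sin(mid))
        rois.add(ph.label, CircleRoi(center=center, radius=roi_r_px), ph.purpose)
    for obj in spec.extra_objects:
        rois.add(
            obj.label,
            CircleRoi(center=obj.center_px, radius=roi_r_px),
            obj.purpose,
        )
    return rois


def _ground_truth(spec: PhantomSpec) -> GroundTruth:
    edges = spec.band_edges()
    paints = _all_paints(spec)
    fracs = {lb: _paint_page_fractions(p, edges) for lb, p in paints.items()}
    gp_true: dict[str, float] = {}
    if edges is not None and len(edges) == 2:
        for lb, f in fracs.items():
            tot = f.sum()
            gp_true[lb] = float((f[0] - f[1]) / tot) if tot > 0 else float("nan")
    return GroundTruth(
        gp_true=gp_true,
        band_fractions=fracs,
        psf_fwhm_nm=spec.psf_fwhm_nm,
        bleach_survival_per_frame=spec.bleach_survival_per_frame,
        contour=_membrane_contour(spec),
        seed=spec.seed,
    )


def render_phantom(spec: PhantomSpec) -> tuple[ImageStack, GroundTruth, RoiSet]:
    """Render one acquisition: one page per detection band or λ window.

    The expected (noise-free) intensity of a pixel is the line integral of
    membrane brightness across the pixel, convolved with the Gaussian PSF
    and split across pages by each label's paint.  With
    ``noise='poisson'`` each pixel of each page is an independent Poisson
    draw around that expectation, reproducible from ``spec.seed``.
    """
    edges = spec.band_edges()
    fields = _render_label_fields(spec)
    paints = _all_paints(spec)
    n_pages = 1 if edges is None else len(edges)
    transmission = spec.band_transmission or [1.0] * n_pages
    if len(transmission) != n_pages:
        raise ValueError("band_transmission length must match the page count")

    h, w = spec.image_size_px
    pages = []
    for p in range(n_pages):
        page = np.full((h, w), float(spec.background_offset), dtype=np.float64)
        for lb, fld in fields.items():
            frac = _paint_page_fractions(paints[lb], edges)[p]
            page += fld * frac
        pages.append(page * transmission[p])

    rng = np.random.default_rng(spec.seed)
    if spec.noise is NoiseModel.POISSON:
        pages = [rng.poisson(pg).astype(np.float32) for pg in pages]
    else:
        pages = [pg.astype(np.float32) for pg in pages]

    if spec.lambda_windows_nm is not None:
        kind = AxisKind.WAVELENGTH
    elif spec.detection_bands_nm is not None:
        kind = AxisKind.CHANNEL
    else:
        kind = AxisKind.SINGLE
    stack = ImageStack(
        pages=pages,
        axis_kind=kind,
        pixel_size_nm=spec.pixel_size_nm,
        band_edges_nm=edges,
    )
    return stack, _ground_truth(spec), phantom_rois(spec)


def render_bleach_series(spec: PhantomSpec) -> ImageStack:
    """Render a sequential-frame series with exponential photobleaching.

    Frame ``k`` (0-based) has expected brightness scaled by
    ``bleach_survival_per_frame ** k``; Poisson noise (if requested) is
    applied after scaling, independently per frame.  All photons are
    collected into a single page per frame.
    """
    if spec.n_frames < 2:
        raise ValueError("a bleach series needs n_frames >= 2")
    fields = _render_label_fields(spec)
    expected = np.full(spec.image_size_px, float(spec.background_offset), dtype=np.float64)
    for fld in fields.values():
        expected += fld
    rng = np.random.default_rng(spec.seed)
    s = spec.bleach_survival_per_frame
    frames = []
    for k in range(spec.n_frames):
        lam = expected * (s**k)
        if spec.noise is NoiseModel.POISSON:
            frames.append(rng.poisson(lam).astype(np.float32))
        else:
            frames.append(lam.astype(np.float32))
    return ImageStack(
        pages=frames, axis_kind=AxisKind.TIME, pixel_size_nm=spec.pixel_size_nm
    )


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

#: detection bands of the two-channel GP acquisition, nm
GP_BANDS_NM = [(520.0, 570.0), (620.0, 700.0)]


def preset(name: str, mode: str = "sted", seed: int = 0, **overrides) -> PhantomSpec:
    """Named generative setups mirroring the study conditions.

    ``mode`` selects the PSF preset (``confocal`` 240 nm / ``sted`` 80 nm).
    Any :class:`PhantomSpec` field can be overridden by keyword.

    Presets
    -------
    ``fig3-gpmv``
        Uniform 5-µm-radius vesicle, single detection band; the resolution
        phantom for FWHM profiling.
    ``fig5-nanodomain``
        2-µm vesicle with a 500-nm disordered arc (channel-1 fraction
        0.405, i.e. GP −0.19) in an ordered surround (0.540, GP +0.08).
    ``fig5-endosome``
        2-µm cell membrane (fraction 0.660, GP +0.32) with a 150-nm
        internal disc (0.555, GP +0.11) 500 nm inside the membrane.
    ``bleach-20``
        20-frame series with per-frame survival 0.9875.
    ``spectra-shift``
        Phase-separated vesicle with ordered/disordered emission peaks at
        570/610 nm (SD 25 nm), twenty 9-nm λ windows from 513 nm.
    ``gfp-gpmv``
        Non-phase-separated vesicle (peak 600 nm) filled with a GFP-like
        lumen emitter (peak 510 nm), λ windows from 495 nm.
    """
    psf = PSF_PRESETS_NM[mode]
    if name == "fig3-gpmv":
        spec = PhantomSpec(
            image_size_px=(600, 600),
            vesicle_radius_nm=5000.0,
            phases=[
                ArcPhase("membrane", 0.0, 360.0, PhasePaint(channel_fraction_1=1.0))
            ],
            psf_fwhm_nm=psf,
            noise=NoiseModel.POISSON,
            seed=seed,
        )
    elif name == "fig5-nanodomain":
        # a 500 nm arc on a 2 um vesicle subtends 500/2000 rad = 14.324 deg
        half = math.degrees(0.25) / 2.0
        spec = PhantomSpec(
            image_size_px=(256, 256),
            vesicle_radius_nm=2000.0,
            phases=[
                ArcPhase(
                    "domain",
                    (-half) % 360.0,
                    half,
                    PhasePaint(channel_fraction_1=0.405),
                    purpose="domain",
                ),
                ArcPhase(
                    "surround",
                    half,
                    (-half) % 360.0,
                    PhasePaint(channel_fraction_1=0.540),
                    purpose="surround",
                ),
            ],
            detection_bands_nm=GP_BANDS_NM,
            psf_fwhm_nm=psf,
            noise=NoiseModel.POISSON,
            seed=seed,
        )
    elif name == "fig5-endosome":
        h = w = 256
        cx = cy = (w - 1) / 2.0
        r_px = 2000.0 / 20.0
        spec = PhantomSpec(
            image_size_px=(h, w),
            vesicle_radius_nm=2000.0,
            phases=[
                ArcPhase(
                    "plasma_membrane",
                    0.0,
                    360.0,
                    PhasePaint(channel_fraction_1=0.660),
                    purpose="membrane",
                )
            ],
            extra_objects=[
                DiscObject(
                    "vesicle",
                    # 500 nm inside the membrane, on the +x axis
                    center_px=(cx + r_px - 500.0 / 20.0, cy),
                    diameter_nm=150.0,
                    paint=PhasePaint(channel_fraction_1=0.555),
                    total_photons=12000.0,
                    purpose="vesicle",
                )
            ],
            detection_bands_nm=GP_BANDS_NM,
            psf_fwhm_nm=psf,
            noise=NoiseModel.POISSON,
            seed=seed,
        )
    elif name == "bleach-20":
        spec = PhantomSpec(
            image_size_px=(160, 160),
            vesicle_radius_nm=1000.0,
            phases=[
                ArcPhase("membrane", 0.0, 360.0, PhasePaint(channel_fraction_1=1.0))
            ],
            psf_fwhm_nm=psf,
            bleach_survival_per_frame=0.9875,
            n_frames=20,
            noise=NoiseModel.POISSON,
            seed=seed,
        )
    elif name == "spectra-shift":
        spec = PhantomSpec(
            image_size_px=(256, 256),
            vesicle_radius_nm=2000.0,
            phases=[
                ArcPhase(
                    "disordered",
                    0.0,
                    180.0,
                    PhasePaint(spectrum=EmissionModel(610.0, 25.0)),
                    purpose="domain",
                ),
                ArcPhase(
                    "ordered",
                    180.0,
                    360.0,
                    PhasePaint(spectrum=EmissionModel(570.0, 25.0)),
                    purpose="surround",
                ),
            ],
            lambda_windows_nm=(513.0, 693.0, 9.0),
            psf_fwhm_nm=psf,
            noise=NoiseModel.POISSON,
            seed=seed,
            roi_radius_nm=300.0,
        )
    elif name == "gfp-gpmv":
        h = w = 256
        cx = cy = (w - 1) / 2.0
        spec = PhantomSpec(
            image_size_px=(h, w),
            vesicle_radius_nm=2000.0,
            phases=[
                ArcPhase(
                    "membrane",
                    0.0,
                    360.0,
                    PhasePaint(spectrum=EmissionModel(600.0, 25.0)),
                )
            ],
            extra_objects=[
                DiscObject(
                    "lumen",
                    center_px=(cx, cy),
                    diameter_nm=3800.0,
                    paint=PhasePaint(spectrum=EmissionModel(510.0, 15.0)),
                    total_photons=8.5e5,
                    purpose="background",
                )
            ],
            lambda_windows_nm=(495.0, 693.0, 9.0),
            psf_fwhm_nm=psf,
            noise=NoiseModel.POISSON,
            seed=seed,
            roi_radius_nm=300.0,
        )
    else:
        raise KeyError(f"unknown preset {name!r}")
    if overrides:
        if "image_size_px" in overrides and "vesicle_center_px" not in overrides:
            overrides = {**overrides, "vesicle_center_px": None}
        spec = replace(spec, **overrides)
    return spec
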