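"""λ-stack spectral analysis: ROI emission spectra, peak shifts, ratios.

A λ-stack holds one page per narrow (9 nm) spectral detection window.
From it this module extracts per-ROI emission spectra, estimates emission
peak positions (optionally with sub-window parabolic refinement), computes
the ordered/disordered peak shift that polarity-sensitive probes show
between lipid phases, forms per-window intensity ratios between two ROIs,
and recombines windows into a two-band channel pair (e.g. to separate a
GFP-filled lumen from a red-shifted membrane probe).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import AxisKind, ImageStack, RoiGeometry, rasterize_roi
from .gp_mapping import ChannelPair


class PeakMethod(str, enum.Enum):
    ARGMAX_BIN = "argmax_bin"
    PARABOLIC = "parabolic"


@dataclass
class SpectrumTrace:
    """Mean ROI intensity per spectral window."""

    wavelengths_nm: np.ndarray  # window centres
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.shape != self.intensities.shape:
            raise ValueError("wavelength and intensity lengths differ")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.normalized and self.intensities.size:
            peak = self.intensities.max()
            if peak > 0 and not np.isclose(peak, 1.0):
                raise ValueError("a normalized trace must have max 1")

    def normalize(self) -> "SpectrumTrace":
        """Divide by the maximum; idempotent."""
        peak = float(self.intensities.max()) if self.intensities.size else 0.0
        if peak == 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return SpectrumTrace(
            self.wavelengths_nm, self.intensities / peak, normalized=True
        )


@dataclass
class PeakEstimate:
    peak_nm: float
    method: PeakMethod


def _wavelength_stack(stack: ImageStack) -> np.ndarray:
    if stack.axis_kind is not AxisKind.WAVELENGTH or stack.band_edges_nm is None:
        raise ValueError("spectral analysis needs a wavelength stack with band edges")
    return stack.band_centers_nm


def extract_spectrum(
    stack: ImageStack,
    roi: RoiGeometry,
    normalize: bool = False,
    background: float = 0.0,
) -> SpectrumTrace:
    """Mean intensity over the ROI pixels, per spectral window.

    ``background`` subtracts a constant per-window offset before
    normalisation (default 0: spectra are reported as recorded).
    """
    centers = _wavelength_stack(stack)
    mask = rasterize_roi(roi, stack.shape)
    if not mask.any():
        raise ValueError("ROI covers no pixels of the image")
    vals = np.array([float(pg[mask].mean()) for pg in stack.pages])
    vals = np.clip(vals - background, 0.0, None)
    trace = SpectrumTrace(centers, vals, normalized=False)
    return trace.normalize() if normalize else trace


def peak_wavelength(
    trace: SpectrumTrace, method: PeakMethod | str = PeakMethod.PARABOLIC
) -> PeakEstimate:
    """Emission-peak position of a sampled spectrum.

    ``argmax_bin`` returns the centre of the brightest window;
    ``parabolic`` refines it with a quadratic through the brightest window
    and its two neighbours (exact for a parabola, and accurate to well
    under a window for smooth band shapes), falling back to the bin centre
    at the axis edge.
    """
    method = PeakMethod(method)
    lam = trace.wavelengths_nm
    y = trace.intensities
    if lam.size < 3:
        raise ValueError("need at least 3 spectral windows")
    if np.all(y == 0):
        raise ValueError("all-zero spectrum has no peak")
    i = int(np.argmax(y))
    peak = float(lam[i])
    if method is PeakMethod.PARABOLIC and 0 < i < lam.size - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # proper local maximum
            step = (lam[i + 1] - lam[i - 1]) / 2.0
            peak = float(lam[i] + 0.5 * step * (y0 - y2) / denom)
    return PeakEstimate(peak_nm=peak, method=method)


def peak_shift(
    ordered: SpectrumTrace,
    disordered: SpectrumTrace,
    method: PeakMethod | str = PeakMethod.PARABOLIC,
) -> float:
    """Disordered-minus-ordered peak position in nm; positive = red shift."""
    if ordered.wavelengths_nm.shape != disordered.wavelengths_nm.shape or not np.allclose(
        ordered.wavelengths_nm, disordered.wavelengths_nm
    ):
        raise ValueError("traces are on different wavelength axes")
    return (
        peak_wavelength(disordered, method).peak_nm
        - peak_wavelength(ordered, method).peak_nm
    )


def channel_intensity_ratio(
    stack: ImageStack, roi_ordered: RoiGeometry, roi_disordered: RoiGeometry
) -> list[tuple[float, float]]:
    """Per-window ordered/disordered mean-intensity ratio.

    Windows whose disordered mean is zero are excluded (with a warning)
    rather than propagating infinities.
    """
    centers = _wavelength_stack(stack)
    m_o = rasterize_roi(roi_ordered, stack.shape)
    m_d = rasterize_roi(roi_disordered, stack.shape)
    if not m_o.any() or not m_d.any():
        raise ValueError("empty ROI")
    out: list[tuple[float, float]] = []
    dropped = []
    for lam, pg in zip(centers, stack.pages):
        denom = float(pg[m_d].mean())
        if denom == 0:
            dropped.append(float(lam))
            continue
        out.append((float(lam), float(pg[m_o].mean()) / denom))
    if dropped:
        warnings.warn(
            f"excluded {len(dropped)} window(s) with zero disordered-ROI mean",
            stacklevel=2,
        )
    return out


def recombine_bands(
    stack: ImageStack,
    band_a: tuple[float, float],
    band_b: tuple[float, float],
) -> ChannelPair:
    """Sum spectral windows into two bands, as a two-channel image.

    A window belongs to a band when its centre lies inside the band's
    ``[low, high]`` range (windows straddling an edge are assigned by
    centre).  Either band empty of windows is an error.
    """
    centers = _wavelength_stack(stack)
    arr = stack.as_array()

    def _band_sum(band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        sel = (centers >= lo) & (centers <= hi)
        if not sel.any():
            raise ValueError(f"band {band} contains no spectral windows")
        return arr[sel].sum(axis=0)

    return ChannelPair(
        I1=_band_sum(band_a), I2=_band_sum(band_b), pixel_size_nm=stack.pixel_size_nm
    )
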