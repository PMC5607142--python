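"""Photobleaching quantification over sequential image series.

Sequential frames of the same field progressively bleach the probe; the
membrane-ROI mean intensity per frame, normalised to the first frame,
summarises photostability.  A single per-frame survival factor ``s``
(expected intensity of frame k proportional to ``s**k``) condenses a
curve to one number; the fractional loss after N frames is what imaging
practice cares about.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core_io import AxisKind, ImageStack, RoiGeometry, rasterize_roi


@dataclass
class BleachCurve:
    """Per-frame ROI mean intensity, normalised so frame 0 equals 1."""

    frame_index: np.ndarray
    normalized_intensity: np.ndarray
    roi_label: str = ""

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.normalized_intensity = np.asarray(self.normalized_intensity, dtype=float)
        if self.frame_index.shape != self.normalized_intensity.shape:
            raise ValueError("index and intensity lengths differ")
        if self.normalized_intensity.size and not np.isclose(
            self.normalized_intensity[0], 1.0
        ):
            raise ValueError("frame 0 must be normalised to 1")
        if np.any(self.normalized_intensity < 0):
            raise ValueError("normalised intensities must be >= 0")

    def __len__(self) -> int:
        return int(self.frame_index.size)


def bleach_curve(
    stack: ImageStack,
    roi: RoiGeometry,
    roi_label: str = "",
    background_roi: RoiGeometry | None = None,
) -> BleachCurve:
    """Frame-wise ROI mean divided by the frame-0 mean.

    The same fixed ROI is applied to every frame (no re-segmentation or
    drift correction).  ``background_roi``, when given, subtracts a
    per-frame background-ROI mean before normalisation (default: none).
    """
    if stack.axis_kind is not AxisKind.TIME:
        raise ValueError("bleach analysis needs a time-series stack")
    if stack.n_pages < 2:
        raise ValueError("need at least 2 frames")
    mask = rasterize_roi(roi, stack.shape)
    if not mask.any():
        raise ValueError("ROI covers no pixels")
    means = np.array([float(pg[mask].mean()) for pg in stack.pages])
    if background_roi is not None:
        bg_mask = rasterize_roi(background_roi, stack.shape)
        if not bg_mask.any():
            raise ValueError("background ROI covers no pixels")
        means = means - np.array([float(pg[bg_mask].mean()) for pg in stack.pages])
    if means[0] == 0:
        raise ValueError("frame-0 ROI mean is zero; cannot normalise")
    norm = means / means[0]
    if np.any(norm < 0):
        norm = np.clip(norm, 0.0, None)
    return BleachCurve(
        frame_index=np.arange(stack.n_pages),
        normalized_intensity=norm,
        roi_label=roi_label,
    )


def fractional_loss(curve: BleachCurve, n_frames: int) -> float:
    """Signal fraction lost after ``n_frames`` frames: 1 - I[n_frames - 1].

    A brightening series yields a negative loss, returned as-is with a
    warning (the sign convention is 'loss is positive').
    """
    if not 1 <= n_frames <= len(curve):
        raise ValueError(f"n_frames must be in [1, {len(curve)}]")
    loss = 1.0 - float(curve.normalized_intensity[n_frames - 1])
    if loss < 0:
        warnings.warn("intensity increased over the series: negative loss", stacklevel=2)
    return loss


def fit_decay(curve: BleachCurve) -> tuple[float, float]:
    """Least-squares fit of ``s**k`` to the curve; returns ``(s, rss)``.

    ``s`` is constrained to (0, 1.1]; values slightly above 1 accommodate
    noisy non-bleaching series.
    """
    if len(curve) < 3:
        raise ValueError("need at least 3 frames to fit a decay")
    y = curve.normalized_intensity
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    k = curve.frame_index.astype(float)
    popt, _ = curve_fit(
        lambda kk, s: s**kk,
        k,
        y,
        p0=[max(min(float(y[-1]) ** (1.0 / max(k[-1], 1.0)), 1.05), 0.1)],
        bounds=([1e-9], [1.1]),
        maxfev=2000,
    )
    s = float(popt[0])
    rss = float(np.sum((s**k - y) ** 2))
    return s, rss
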