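"""Shared data model and lossless image/ROI/table input-output.

Conventions used throughout the package:

* Pixel coordinates are 0-based with ``(x, y) = (column, row)`` and the
  origin at the centre of the top-left pixel.  Continuous coordinates are
  valid anywhere; pixel ``(i, j)`` covers ``[i - 0.5, i + 0.5]`` in each
  axis.
* Images travel as multi-page grayscale TIFF (16-bit integer or 32-bit
  float); a JSON sidecar (``<image>.meta.json``) carries the axis
  semantics, pixel size and spectral band edges.
* Regions of interest are stored in a documented JSON schema rather than
  any binary ROI format, so fixtures diff cleanly and round-trip exactly.
* Intensities are treated as linear, photon-proportional counts.
"""

from __future__ import annotations

import enum
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import line as _draw_line
from skimage.draw import polygon as _draw_polygon


class AxisKind(str, enum.Enum):
    """Meaning of the page axis of an :class:`ImageStack`."""

    CHANNEL = "channel"
    WAVELENGTH = "wavelength"
    TIME = "time"
    SINGLE = "single"


class FormatError(ValueError):
    """Raised when an on-disk image or ROI file violates the expected format."""


@dataclass
class ImageStack:
    """An ordered stack of equally shaped 2-D intensity pages.

    Parameters
    ----------
    pages:
        Sequence of 2-D arrays of non-negative intensities (photon counts
        or expected counts).  Stored as float32 unless already float.
    axis_kind:
        What the page axis means: detection ``channel``, spectral
        ``wavelength`` window, ``time`` frame, or ``single`` page.
    pixel_size_nm:
        Lateral pixel pitch in nanometres (default 20, the STED-optimised
        sampling the analyses assume).
    band_edges_nm:
        For ``wavelength`` (and optionally ``channel``) stacks, one
        ``(low, high)`` nm pair per page, ascending and non-overlapping.
    """

    pages: list[np.ndarray]
    axis_kind: AxisKind = AxisKind.SINGLE
    pixel_size_nm: float = 20.0
    band_edges_nm: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.axis_kind = AxisKind(self.axis_kind)
        if len(self.pages) == 0:
            raise ValueError("ImageStack needs at least one page")
        pages = []
        for k, p in enumerate(self.pages):
            a = np.asarray(p)
            if a.ndim != 2:
                raise FormatError(f"page {k} is not 2-D (shape {a.shape})")
            if not np.issubdtype(a.dtype, np.floating):
                a = a.astype(np.float32)
            pages.append(a)
        shape0 = pages[0].shape
        for k, p in enumerate(pages):
            if p.shape != shape0:
                raise FormatError(
                    f"page {k} shape {p.shape} differs from page 0 shape {shape0}"
                )
        self.pages = pages
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.band_edges_nm is not None:
            edges = [(float(lo), float(hi)) for lo, hi in self.band_edges_nm]
            if len(edges) != len(pages):
                raise ValueError(
                    f"{len(edges)} band edges for {len(pages)} pages"
                )
            for lo, hi in edges:
                if not lo < hi:
                    raise ValueError(f"degenerate band ({lo}, {hi})")
            for (lo0, hi0), (lo1, hi1) in zip(edges, edges[1:]):
                if lo1 < hi0:
                    raise ValueError("band edges must be ascending and non-overlapping")
            self.band_edges_nm = edges
        elif self.axis_kind is AxisKind.WAVELENGTH:
            raise ValueError("wavelength stacks require band_edges_nm")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pages[0].shape

    @property
    def n_pages(self) -> int:
        return len(self.pages)

    @property
    def band_centers_nm(self) -> np.ndarray:
        if self.band_edges_nm is None:
            raise ValueError("stack has no band edges")
        return np.array([(lo + hi) / 2.0 for lo, hi in self.band_edges_nm])

    def as_array(self) -> np.ndarray:
        """Pages stacked into one (n_pages, H, W) array."""
        return np.stack(self.pages, axis=0)


@dataclass
class ContourPolyline:
    """Ordered vertex list tracing a membrane, in pixel coordinates."""

    vertices: np.ndarray  # (N, 2) array of (x, y)
    closed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("contour needs an (N>=2, 2) vertex array")
        if np.any(np.all(v[1:] == v[:-1], axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        self.vertices = v

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def segment_lengths(self) -> np.ndarray:
        v = self.vertices
        if self.closed:
            v = np.vstack([v, v[:1]])
        return np.hypot(*(np.diff(v, axis=0).T))

    def perimeter(self) -> float:
        return float(self.segment_lengths().sum())

    def check_inside(self, shape: tuple[int, int]) -> None:
        h, w = shape
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        if x.min() < 0 or y.min() < 0 or x.max() > w - 1 or y.max() > h - 1:
            raise ValueError("contour vertices fall outside the image bounds")


@dataclass
class CircleRoi:
    """Circular ROI: centre (x, y) and radius, all in pixels."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("circle radius must be positive")
        self.center = (float(self.center[0]), float(self.center[1]))


RoiGeometry = Union[ContourPolyline, CircleRoi]

#: tags describing what an ROI delineates
ROI_PURPOSES = ("membrane", "domain", "surround", "vesicle", "background")


@dataclass
class RoiSet:
    """Labelled collection of ROIs with a purpose tag per ROI."""

    rois: dict[str, RoiGeometry] = field(default_factory=dict)
    purposes: dict[str, str] = field(default_factory=dict)

    def add(self, label: str, roi: RoiGeometry, purpose: str = "membrane") -> None:
        if label in self.rois:
            raise ValueError(f"duplicate ROI label {label!r}")
        self.rois[label] = roi
        self.purposes[label] = purpose

    def __getitem__(self, label: str) -> RoiGeometry:
        return self.rois[label]

    def __contains__(self, label: str) -> bool:
        return label in self.rois

    def __len__(self) -> int:
        return len(self.rois)

    def labels(self) -> list[str]:
        return list(self.rois)

    def by_purpose(self, purpose: str) -> list[str]:
        return [lb for lb, p in self.purposes.items() if p == purpose]


def rasterize_roi(roi: RoiGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Boolean pixel mask of an ROI on an image of the given ``(H, W)`` shape.

    Circles select pixels whose centres lie within the radius.  Closed
    polylines select the polygon interior; open polylines select the
    1-pixel-wide trace of their segments.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    if isinstance(roi, CircleRoi):
        cx, cy = roi.center
        yy, xx = np.ogrid[:h, :w]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= roi.radius**2
    elif isinstance(roi, ContourPolyline):
        v = roi.vertices
        if roi.closed:
            rr, cc = _draw_polygon(v[:, 1], v[:, 0], shape=(h, w))
            mask[rr, cc] = True
        else:
            for (x0, y0), (x1, y1) in zip(v[:-1], v[1:]):
                rr, cc = _draw_line(
                    int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
                )
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                mask[rr[keep], cc[keep]] = True
    else:  # pragma: no cover - guarded by type checks upstream
        raise TypeError(f"unsupported ROI type {type(roi)!r}")
    return mask


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: str | os.PathLike) -> str:
    return f"{os.fspath(path)}.meta.json"


def write_image_stack(stack: ImageStack, path: str | os.PathLike) -> str:
    """Write a stack as a multi-page grayscale TIFF plus a JSON sidecar.

    Float pages are written as float32 (NaN preserved); integer-valued
    pages are still written as float32 so the round trip is bit-exact for
    every value the analyses produce.
    """
    path = os.fspath(path)
    data = np.stack([p.astype(np.float32, copy=False) for p in stack.pages])
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "axis_kind": stack.axis_kind.value,
        "pixel_size_nm": stack.pixel_size_nm,
        "band_edges_nm": stack.band_edges_nm,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_image_stack(
    path: str | os.PathLike,
    axis_kind: AxisKind | str | None = None,
    band_edges_nm: Sequence[tuple[float, float]] | None = None,
    pixel_size_nm: float | None = None,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF as an :class:`ImageStack`.

    Metadata can be passed explicitly; anything left ``None`` falls back to
    the JSON sidecar written by :func:`write_image_stack`, then to the
    defaults (``single`` axis, 20 nm pixels).
    """
    path = os.fspath(path)
    try:
        with tifffile.TiffFile(path) as tf:
            pages = [pg.asarray() for pg in tf.pages]
    except Exception as exc:  # noqa: BLE001 - normalise into FormatError
        raise FormatError(f"cannot read TIFF {path!r}: {exc}") from exc
    if not pages:
        raise FormatError(f"{path!r} contains no pages")
    for k, p in enumerate(pages):
        if p.ndim == 3 and p.shape[0] == 1:
            pages[k] = p[0]
        elif p.ndim != 2:
            raise FormatError(f"page {k} of {path!r} is not grayscale 2-D")
    if len(pages) == 1 and pages[0].ndim == 3:
        pages = list(pages[0])

    meta: dict = {}
    if os.path.exists(_sidecar_path(path)):
        with open(_sidecar_path(path)) as fh:
            meta = json.load(fh)
    if axis_kind is None:
        axis_kind = meta.get("axis_kind", AxisKind.SINGLE)
    if band_edges_nm is None and meta.get("band_edges_nm") is not None:
        band_edges_nm = [tuple(e) for e in meta["band_edges_nm"]]
    if pixel_size_nm is None:
        pixel_size_nm = float(meta.get("pixel_size_nm", 20.0))
    try:
        return ImageStack(
            pages=[np.asarray(p, dtype=np.float32) for p in pages],
            axis_kind=AxisKind(axis_kind),
            pixel_size_nm=pixel_size_nm,
            band_edges_nm=list(band_edges_nm) if band_edges_nm is not None else None,
        )
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


# ---------------------------------------------------------------------------
# ROI JSON I/O
# ---------------------------------------------------------------------------

def save_rois(rois: RoiSet, path: str | os.PathLike) -> str:
    """Persist an :class:`RoiSet` to the documented JSON schema."""
    payload: dict[str, dict] = {}
    for label, roi in rois.rois.items():
        purpose = rois.purposes.get(label, "membrane")
        if isinstance(roi, CircleRoi):
            payload[label] = {
                "type": "circle",
                "center": list(roi.center),
                "radius": roi.radius,
                "purpose": purpose,
            }
        else:
            payload[label] = {
                "type": "polyline",
                "vertices": roi.vertices.tolist(),
                "closed": roi.closed,
                "purpose": purpose,
            }
    with open(os.fspath(path), "w") as fh:
        json.dump({"rois": payload}, fh, indent=1)
    return os.fspath(path)


def load_rois(path: str | os.PathLike) -> RoiSet:
    """Load an ROI JSON sidecar; rejects duplicate labels and bad geometry."""
    with open(os.fspath(path)) as fh:
        raw = json.load(fh, object_pairs_hook=_no_duplicate_keys)
    if "rois" not in raw:
        raise FormatError("ROI file lacks a top-level 'rois' object")
    out = RoiSet()
    for label, entry in raw["rois"].items():
        kind = entry.get("type")
        purpose = entry.get("purpose", "membrane")
        try:
            if kind == "circle":
                roi: RoiGeometry = CircleRoi(
                    center=tuple(entry["center"]), radius=float(entry["radius"])
                )
            elif kind == "polyline":
                roi = ContourPolyline(
                    vertices=np.asarray(entry["vertices"], dtype=float),
                    closed=bool(entry.get("closed", False)),
                )
            else:
                raise ValueError(f"unknown ROI type {kind!r}")
        except (KeyError, ValueError, TypeError) as exc:
            raise FormatError(f"malformed ROI {label!r}: {exc}") from exc
        out.add(label, roi, purpose)
    return out


def _no_duplicate_keys(pairs: Iterable[tuple[str, object]]) -> dict:
    d: dict = {}
    for k, v in pairs:
        if k in d:
            raise FormatError(f"duplicate ROI label {k!r}")
        d[k] = v
    return d


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

@dataclass
class ResultsTable:
    """A tidy table of named numeric fields plus provenance.

    Thin wrapper over a :class:`pandas.DataFrame` that records where the
    numbers came from (source file, producing module, parameter hash) and
    writes deterministic CSV.
    """

    df: pd.DataFrame
    source: str = ""
    module: str = ""
    parameters: Mapping[str, object] = field(default_factory=dict)

    @property
    def parameters_hash(self) -> str:
        blob = json.dumps(dict(self.parameters), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_csv(self, path: str | os.PathLike) -> str:
        path = os.fspath(path)
        self.df.to_csv(path, index=False, float_format="%.10g")
        return path

    def save_parameters(self, path: str | os.PathLike) -> str:
        record = {
            "source": self.source,
            "module": self.module,
            "parameters": dict(self.parameters),
            "parameters_hash": self.parameters_hash,
        }
        with open(os.fspath(path), "w") as fh:
            json.dump(record, fh, indent=1, sort_keys=True, default=str)
        return os.fspath(path)
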