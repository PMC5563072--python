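"""Membrane intensity profile extraction from midsection images.

The central abstraction is the :class:`MembraneProfile`: fluorescence
intensity along the cell perimeter, sampled at normalized arclength
``x in [0, 1)``, together with locally estimated cytoplasmic and
background levels that allow condition-independent normalization.

Profiles are obtained by extracting a wide stripe of pixels straddling
the membrane (default 60 px deep, sampled along the local contour
normal), straightening it, and collapsing each arclength column to a
single membrane value (mean of the brightest few central pixels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter1d


class GeometryError(ValueError):
    """Contour or ROI geometry incompatible with the requested sampling."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class MembraneStripe:
    """Straightened band of pixels around the cell contour.

    ``pixels`` has shape (n_arclength, depth) with depth running from the
    *outside* of the cell (background) to the *inside* (cytoplasm).  The
    arclength axis is circular: the first and last rows are adjacent on
    the cell.
    """

    pixels: np.ndarray              # (n_arclength, depth), outside -> inside
    arclength_px: float             # pixels of perimeter per row
    source_contour: np.ndarray      # (n, 2) resampled contour, (x, y)
    depth_order: str = "outside_to_inside"

    @property
    def n_samples(self) -> int:
        return self.pixels.shape[0]

    @property
    def depth(self) -> int:
        return self.pixels.shape[1]

    @property
    def perimeter_px(self) -> float:
        return self.n_samples * self.arclength_px


@dataclass
class MembraneProfile:
    """Per-arclength membrane signal with local context levels.

    ``normalized`` is filled by :func:`normalize_profile`; until then it
    is ``None``.  ``mask`` marks positions where normalization was
    undefined (non-positive cytoplasm-minus-background denominator).
    """

    x: np.ndarray                   # normalized arclength in [0, 1)
    membrane: np.ndarray            # AU
    cytoplasm_local: np.ndarray     # AU
    background_local: np.ndarray    # AU
    normalized: np.ndarray | None = None
    mask: np.ndarray | None = None
    flagged: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.x)
        for name in ("membrane", "cytoplasm_local", "background_local"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != x length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")

    def values(self) -> np.ndarray:
        """Normalized signal if available, raw membrane signal otherwise."""
        return self.normalized if self.normalized is not None else self.membrane


# --------------------------------------------------------------------------
# contour helpers
# --------------------------------------------------------------------------

def resample_contour(contour: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a closed polygon to uniform arclength spacing (px)."""
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise GeometryError("contour must be an (n>=3, 2) point array")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = s[-1]
    if perimeter <= 0:
        raise GeometryError("degenerate contour with zero perimeter")
    n_out = max(int(round(perimeter / spacing)), 8)
    s_new = np.arange(n_out) * (perimeter / n_out)
    x = np.interp(s_new, s, closed[:, 0])
    y = np.interp(s_new, s, closed[:, 1])
    return np.column_stack([x, y])


def _outward_normals(contour: np.ndarray) -> np.ndarray:
    """Unit outward normals of a closed uniformly sampled contour."""
    nxt = np.roll(contour, -1, axis=0)
    prv = np.roll(contour, 1, axis=0)
    tang = nxt - prv
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    # signed area > 0 <=> counterclockwise in (x, y)
    x, y = contour[:, 0], contour[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area > 0:
        normals = np.column_stack([tang[:, 1], -tang[:, 0]])
    else:
        normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    return normals


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def extract_stripe(image: np.ndarray, contour: np.ndarray,
                   width: int = 60) -> MembraneStripe:
    """Straighten a ``width``-deep stripe of pixels centred on the contour.

    For each arclength sample the image is sampled by bilinear
    interpolation along the local outward normal, from ``width/2`` px
    outside the contour to ``width/2`` px inside it.  Rows run along the
    perimeter (circular); columns run outside -> inside.

    Raises
    ------
    GeometryError
        If any sample would fall outside the image, naming the first
        offending contour point.
    """
    image = np.asarray(image, dtype=float)
    pts = resample_contour(contour, spacing=1.0)
    normals = _outward_normals(pts)
    # depth offsets: +half (outside) down to -half (inside)
    offsets = (width - 1) / 2.0 - np.arange(width)
    # sample coordinates, shape (n, width, 2)
    coords = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    xs, ys = coords[..., 0], coords[..., 1]
    h, w = image.shape
    bad = (xs < 0) | (xs > w - 1) | (ys < 0) | (ys > h - 1)
    if np.any(bad):
        i = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise GeometryError(
            f"stripe of width {width} exits image bounds near contour point "
            f"{tuple(np.round(pts[i], 2))} (index {i})")
    stripe = map_coordinates(image, [ys.ravel(), xs.ravel()], order=1,
                             mode="nearest").reshape(len(pts), width)
    return MembraneStripe(pixels=stripe, arclength_px=1.0, source_contour=pts)


def membrane_from_stripe(stripe: MembraneStripe, top_k: int = 4,
                         central_band: float = 1 / 3,
                         edge_band: float = 1 / 6) -> MembraneProfile:
    """Collapse a stripe to a membrane profile with local context levels.

    The membrane signal at each arclength position is the mean of the
    ``top_k`` brightest pixels within the central ``central_band``
    fraction of the stripe depth.  Background and cytoplasm are taken as
    the mean of the outermost and innermost ``edge_band`` fractions.
    """
    px = stripe.pixels
    n, depth = px.shape
    if top_k > depth:
        raise ValueError("top_k exceeds stripe depth")
    b = max(int(round(depth * central_band)), top_k)
    lo = (depth - b) // 2
    band = px[:, lo:lo + b]
    membrane = np.sort(band, axis=1)[:, -top_k:].mean(axis=1)
    e = max(int(round(depth * edge_band)), 1)
    background = px[:, :e].mean(axis=1)       # outside edge
    cytoplasm = px[:, -e:].mean(axis=1)       # inside edge
    flagged = bool(np.ptp(px) == 0)
    x = np.arange(n) / n
    return MembraneProfile(x=x, membrane=membrane, cytoplasm_local=cytoplasm,
                           background_local=background, flagged=flagged,
                           meta={"perimeter_px": stripe.perimeter_px})


def normalize_profile(profile: MembraneProfile,
                      smooth_frac: float = 0.05) -> MembraneProfile:
    """Background-subtract and cytoplasm-normalize a membrane profile.

    ``normalized = (membrane - background) / (cytoplasm - background)``
    so that pure cytoplasm maps to 1 and pure background to 0.  The
    local cytoplasm and background estimates are smoothed with a
    circular moving average (window = ``smooth_frac`` of the perimeter)
    before division to avoid amplifying noise in the denominator.

    Positions with a non-positive denominator are masked with a warning;
    a fully masked profile raises ``ValueError``.
    """
    n = len(profile.x)
    win = max(int(round(smooth_frac * n)), 1)
    cy = uniform_filter1d(profile.cytoplasm_local, size=win, mode="wrap")
    bg = uniform_filter1d(profile.background_local, size=win, mode="wrap")
    denom = cy - bg
    bad = denom <= 0
    if bad.all():
        raise ValueError("cytoplasm - background non-positive everywhere; "
                         "cannot normalize")
    if bad.any():
        warnings.warn(f"normalize_profile: {int(bad.sum())}/{n} positions "
                      "have non-positive denominator and were masked")
    normalized = np.where(bad, np.nan,
                          (profile.membrane - bg) / np.where(bad, 1.0, denom))
    return replace(profile, normalized=normalized, mask=bad)


def anterior_cortical_intensity(image: np.ndarray, domain_line: np.ndarray,
                                cytoplasm_roi: np.ndarray,
                                line_width: int = 2) -> float:
    """Membrane-to-cytoplasm intensity ratio for fixed-cell images.

    Mean intensity of a ``line_width``-px wide polyline over the cortical
    domain divided by the mean of a nearby cytoplasmic ROI.  Values
    greater than 1 indicate enrichment at the membrane.

    ``cytoplasm_roi`` may be a boolean mask (image shape) or an
    ``(y0, y1, x0, x1)`` rectangle.
    """
    image = np.asarray(image, dtype=float)
    line = np.asarray(domain_line, dtype=float)
    if line.ndim != 2 or line.shape[1] != 2 or len(line) < 2:
        raise GeometryError("domain_line must be an (n>=2, 2) polyline")
    # densify the polyline at ~0.5 px spacing, sample +/- offsets normal to it
    seg = np.diff(line, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(lens)])
    if s[-1] <= 0:
        raise GeometryError("degenerate domain line")
    s_new = np.linspace(0, s[-1], max(int(s[-1] * 2), 2))
    px = np.interp(s_new, s, line[:, 0])
    py = np.interp(s_new, s, line[:, 1])
    tx = np.gradient(px)
    ty = np.gradient(py)
    norm = np.hypot(tx, ty)
    nx, ny = ty / norm, -tx / norm
    offs = np.linspace(-(line_width - 1) / 2, (line_width - 1) / 2, line_width)
    sx = px[None, :] + offs[:, None] * nx[None, :]
    sy = py[None, :] + offs[:, None] * ny[None, :]
    h, w = image.shape
    if sx.min() < 0 or sx.max() > w - 1 or sy.min() < 0 or sy.max() > h - 1:
        raise GeometryError("domain line (with width) exits image bounds")
    line_vals = map_coordinates(image, [sy.ravel(), sx.ravel()], order=1)
    roi = np.asarray(cytoplasm_roi)
    if roi.dtype == bool:
        roi_vals = image[roi]
    else:
        y0, y1, x0, x1 = (int(v) for v in roi)
        roi_vals = image[y0:y1, x0:x1].ravel()
    if roi_vals.size == 0:
        raise ValueError("empty cytoplasm ROI")
    roi_mean = roi_vals.mean()
    if roi_mean == 0:
        raise ValueError("cytoplasm ROI has zero mean")
    return float(line_vals.mean() / roi_mean)


def temporal_mean_projection(stack: np.ndarray, window_s: float = 180.0,
                             frame_interval: float = 1.0,
                             start_frame: int = 0) -> np.ndarray:
    """Per-pixel mean over the frames spanning ``window_s`` seconds.

    Time-averaging turns directed particle motion into streaks along the
    motion axis, revealing e.g. anterior-directed cortical tracks.
    """
    stack = np.asarray(stack, dtype=float)
    n_frames = int(round(window_s / frame_interval))
    if n_frames < 1:
        raise ValueError("window shorter than one frame")
    if start_frame + n_frames > stack.shape[0]:
        raise ValueError("stack duration shorter than requested window")
    return stack[start_frame:start_frame + n_frames].mean(axis=0)
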