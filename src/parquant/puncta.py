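"""Punctum (focus) detection and density-based asymmetry.

Foci on cortical-plane images are detected with a Crocker-Grier-style
pipeline: band-pass filtering (Gaussian noise smoothing minus a boxcar
background estimate at the feature scale), local-maximum candidate
selection above a threshold, sub-pixel centroid refinement by
intensity-weighted mean, and merging of duplicates closer than half the
feature diameter (the brighter focus wins).

For asymmetry scoring the cell mask is partitioned into anterior,
middle and posterior thirds along the pole-to-pole axis; the ASI uses
the per-area punctum densities of the anterior and posterior thirds
(the middle third is excluded since the index compares anterior with
posterior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter
from skimage.feature import peak_local_max

from .asymmetry import AsymmetryInputs, asi_raw


@dataclass
class FociSet:
    """Detected puncta: sub-pixel centroids (x, y) and integrated
    intensities, with the detection parameters that produced them."""

    centroids: np.ndarray                    # (n, 2), (x, y)
    intensities: np.ndarray                  # (n,)
    detection_params: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.centroids)


@dataclass
class EmbryoPartition:
    """Anterior / middle / posterior pixel regions of an embryo mask."""

    masks: dict                              # name -> boolean array
    areas: dict                              # name -> px^2

    def region_of(self, x: float, y: float) -> str | None:
        yi, xi = int(round(y)), int(round(x))
        for name, m in self.masks.items():
            if 0 <= yi < m.shape[0] and 0 <= xi < m.shape[1] and m[yi, xi]:
                return name
        return None


def bandpass(image: np.ndarray, diameter: int, noise_sigma: float = 1.0,
             clip: bool = True) -> np.ndarray:
    """Gaussian smooth minus boxcar background at the feature scale,
    clipped at zero unless ``clip=False``."""
    image = np.asarray(image, float)
    bp = gaussian_filter(image, noise_sigma) - uniform_filter(image, diameter)
    return np.clip(bp, 0, None) if clip else bp


def auto_threshold(bp_image: np.ndarray, n_sd: float = 5.0) -> float:
    """mean + n_sd * sd of the (unclipped) band-passed image.

    5 sd by default: over a large field the maxima of smoothed Gaussian
    noise routinely exceed 3-4 sd, so a lower cut admits spurious peaks
    on spot-sparse images.  Pass the unclipped band-pass so the noise
    spread is not underestimated.
    """
    return float(bp_image.mean() + n_sd * bp_image.std())


def detect_foci(image: np.ndarray, diameter: int = 7,
                threshold: float | str = "auto",
                noise_sigma: float = 1.0,
                min_separation: float | None = None) -> FociSet:
    """Detect bright puncta of characteristic ``diameter`` pixels.

    ``threshold`` is an absolute intensity on the band-passed image, or
    ``"auto"`` for mean + 3 sd.  ``min_separation`` defaults to
    diameter / 2; of two candidates closer than that, only the brighter
    is kept.  An empty result is valid (blank images yield no foci).
    """
    if diameter < 3 or diameter % 2 == 0:
        raise ValueError("diameter must be odd and >= 3")
    image = np.asarray(image, float)
    raw_bp = bandpass(image, diameter, noise_sigma, clip=False)
    bp = np.clip(raw_bp, 0, None)
    thr = auto_threshold(raw_bp) if threshold == "auto" else float(threshold)
    if min_separation is None:
        min_separation = diameter / 2.0
    peaks = peak_local_max(bp, min_distance=max(diameter // 2, 1),
                           threshold_abs=thr, exclude_border=False)
    r = diameter // 2
    cents, intens = [], []
    h, w = bp.shape
    for py, px in peaks:
        y0, y1 = max(py - r, 0), min(py + r + 1, h)
        x0, x1 = max(px - r, 0), min(px + r + 1, w)
        win = bp[y0:y1, x0:x1]
        tot = win.sum()
        if tot <= 0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        cents.append(((xx * win).sum() / tot, (yy * win).sum() / tot))
        intens.append(tot)
    params = {"diameter": diameter, "threshold": thr,
              "noise_sigma": noise_sigma, "min_separation": min_separation}
    if not cents:
        return FociSet(centroids=np.empty((0, 2)),
                       intensities=np.empty(0), detection_params=params)
    cents = np.asarray(cents)
    intens = np.asarray(intens)
    # merge duplicates: brightest first, greedy exclusion radius
    order = np.argsort(intens)[::-1]
    kept: list[int] = []
    for i in order:
        if all(np.hypot(*(cents[i] - cents[j])) >= min_separation
               for j in kept):
            kept.append(i)
    kept = sorted(kept)
    return FociSet(centroids=cents[kept], intensities=intens[kept],
                   detection_params=params)


def partition_thirds(embryo_mask: np.ndarray, axis) -> EmbryoPartition:
    """Cut a mask into thirds along the pole-to-pole axis projection.

    ``axis = (anterior_pole, posterior_pole)`` in (x, y) pixels.  A
    masked pixel with normalized projection t onto the axis falls in the
    anterior third for t < 1/3, posterior for t >= 2/3, middle
    otherwise; every mask pixel is assigned exactly once.
    """
    mask = np.asarray(embryo_mask, bool)
    if mask.sum() == 0:
        raise ValueError("empty embryo mask")
    pa = np.asarray(axis[0], float)
    pp = np.asarray(axis[1], float)
    u = pp - pa
    L2 = float(u @ u)
    if L2 == 0:
        raise ValueError("degenerate pole axis")
    ys, xs = np.nonzero(mask)
    t = ((xs - pa[0]) * u[0] + (ys - pa[1]) * u[1]) / L2
    names = ("anterior", "middle", "posterior")
    sel = {"anterior": t < 1 / 3,
           "middle": (t >= 1 / 3) & (t < 2 / 3),
           "posterior": t >= 2 / 3}
    masks, areas = {}, {}
    for name in names:
        m = np.zeros_like(mask)
        m[ys[sel[name]], xs[sel[name]]] = True
        masks[name] = m
        areas[name] = int(sel[name].sum())
    return EmbryoPartition(masks=masks, areas=areas)


def foci_density_asi(foci: FociSet,
                     partition: EmbryoPartition) -> AsymmetryInputs:
    """Per-area punctum densities of the anterior vs posterior third.

    A = anterior count / anterior area, P = posterior count / posterior
    area; the middle third is excluded.  With no foci at all the inputs
    are (0, 0), flagged by a warning — the ASI is 0 by convention (see
    :func:`foci_asi`).
    """
    for name in ("anterior", "posterior"):
        if partition.areas[name] <= 0:
            raise ValueError(f"zero {name} area")
    counts = {"anterior": 0, "middle": 0, "posterior": 0}
    for (x, y) in foci.centroids:
        region = partition.region_of(x, y)
        if region is not None:
            counts[region] += 1
    if len(foci) == 0:
        warnings.warn("foci_density_asi: no foci detected; ASI is 0 by "
                      "convention")
    return AsymmetryInputs(A=counts["anterior"] / partition.areas["anterior"],
                           P=counts["posterior"] / partition.areas["posterior"],
                           feature_kind="foci_density")


def foci_asi(foci: FociSet, partition: EmbryoPartition) -> float:
    """Density ASI with the zero-foci convention (returns 0.0)."""
    inputs = foci_density_asi(foci, partition)
    if inputs.A + inputs.P == 0:
        return 0.0
    return asi_raw(inputs)
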