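"""Membrane-signal estimation, cortical flow speeds and FRAP recovery.

Covers three measurement families:

* **Total membrane signal** by reference cross-section subtraction: the
  straightened membrane stripe is projected along arclength to a depth
  profile spanning background -> membrane -> cytoplasm, normalized to
  background = 0 / cytoplasm = 1, and compared with a mean reference
  cross-section from cells with no membrane signal.  The summed
  difference is the membrane signal; ratios of it before/after a
  treatment give retention measures.
* **Cortical flow speed** from kymograph traces: velocity is total
  displacement over time of the straight line joining a granule's start
  and end positions on the kymograph, in um/min.
* **FRAP**: mean intensity of a monitoring box per frame, normalized to
  the pre-bleach mean, with an optional single-exponential recovery fit
  returning the half-time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .profiles import MembraneProfile, MembraneStripe


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class CrossSection:
    """Depth profile of the membrane stripe, outside -> inside.

    When ``normalized`` the outer (background) edge band averages 0 and
    the inner (cytoplasm) edge band averages 1; any membrane produces a
    bump above the monotone background-to-cytoplasm step.
    """

    depth_profile: np.ndarray
    normalized: bool = False
    sd: np.ndarray | None = None    # per-depth dispersion for mean sections

    @property
    def depth(self) -> int:
        return len(self.depth_profile)


@dataclass
class KymographTrace:
    """Straight-line granule trace on a kymograph (space px, time frames)."""

    start: tuple[float, float]      # (position px, time frame)
    end: tuple[float, float]
    pixel_size: float               # um / px
    frame_interval: float           # s / frame
    truncated: bool = False

    def __post_init__(self):
        if self.end[1] <= self.start[1]:
            raise ValueError("trace must span positive time")


@dataclass
class FrapCurve:
    time: np.ndarray                # s, per frame
    intensity: np.ndarray           # AU, mean of monitoring box
    bleach_frame: int
    normalized: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.bleach_frame < 1:
            raise ValueError("need at least one pre-bleach frame")
        pre = self.intensity[: self.bleach_frame].mean()
        if pre <= 0:
            raise ValueError("non-positive pre-bleach intensity")
        self.normalized = self.intensity / pre


# --------------------------------------------------------------------------
# total membrane signal
# --------------------------------------------------------------------------

def cross_section(stripe: MembraneStripe, edge_band: float = 1 / 6,
                  normalize: bool = True) -> CrossSection:
    """Project a stripe along arclength to a normalized depth profile.

    The projection is the mean over all arclength rows at each depth.
    Normalization is affine: the outer edge band is mapped to 0 and the
    inner edge band to 1, and is therefore idempotent.
    """
    prof = stripe.pixels.mean(axis=0)
    if not normalize:
        return CrossSection(depth_profile=prof, normalized=False)
    e = max(int(round(len(prof) * edge_band)), 1)
    bg = prof[:e].mean()
    cy = prof[-e:].mean()
    if cy == bg:
        raise ValueError("outer and inner edge bands have equal means; "
                         "normalization undefined")
    return CrossSection(depth_profile=(prof - bg) / (cy - bg), normalized=True)


def normalize_cross_section(section: CrossSection,
                            edge_band: float = 1 / 6) -> CrossSection:
    """Affine-rescale so the outer edge band = 0 and inner edge band = 1."""
    prof = section.depth_profile
    e = max(int(round(len(prof) * edge_band)), 1)
    bg = prof[:e].mean()
    cy = prof[-e:].mean()
    if cy == bg:
        raise ValueError("edge bands have equal means; normalization undefined")
    return CrossSection(depth_profile=(prof - bg) / (cy - bg), normalized=True)


def reference_cross_section(sections: list[CrossSection]) -> CrossSection:
    """Mean cross-section of membrane-free cells.

    Averaging the outside-to-inside fluorescence step over cells that
    lack detectable membrane signal defines the reference step shape to
    subtract from membrane-bearing cells.  The per-depth standard
    deviation is attached as a consistency report.
    """
    if len(sections) < 2:
        raise ValueError("need at least 2 sections for a reference")
    depths = {s.depth for s in sections}
    if len(depths) > 1:
        raise ValueError(f"depth length mismatch among sections: {depths}")
    mat = np.stack([s.depth_profile for s in sections])
    return CrossSection(depth_profile=mat.mean(axis=0),
                        normalized=all(s.normalized for s in sections),
                        sd=mat.std(axis=0))


def total_membrane_signal(section: CrossSection,
                          reference: CrossSection) -> float:
    """Sum over depth of (section - reference); both must be normalized.

    The signed sum is used (not the sum of positive deviations) so noise
    cancels in expectation.
    """
    if not (section.normalized and reference.normalized):
        raise ValueError("both cross-sections must be normalized "
                         "(background = 0, cytoplasm = 1)")
    if section.depth != reference.depth:
        raise ValueError("depth length mismatch")
    return float(np.sum(section.depth_profile - reference.depth_profile))


def profile_membrane_signal(profile: MembraneProfile) -> float:
    """Total excess-over-cytoplasm signal of a cytoplasm-normalized profile."""
    if profile.normalized is None:
        raise ValueError("profile must be cytoplasm-normalized first")
    return float(np.nansum(profile.normalized - 1.0))


def par2_retention(before: MembraneProfile, after: MembraneProfile) -> float:
    """Ratio of total membrane signal after vs before a treatment.

    Both profiles come from cytoplasm-normalized thin (typically 4 px)
    membrane stripes of the same cell.  A ratio of 1 means full
    retention at the membrane; 0 means complete clearance.  A
    non-positive before-signal makes the ratio undefined (NaN, with a
    warning).
    """
    sig_before = profile_membrane_signal(before)
    sig_after = profile_membrane_signal(after)
    if sig_before <= 0:
        warnings.warn("par2_retention: non-positive before-signal; "
                      "ratio undefined")
        return float("nan")
    return sig_after / sig_before


# --------------------------------------------------------------------------
# flow speeds
# --------------------------------------------------------------------------

def flow_speed_from_trace(trace: KymographTrace) -> float:
    """Straight-line granule speed in um/min.

    Total distance over time from the line connecting the start and end
    positions on the kymograph; intermediate wiggle is ignored by
    construction.  Invariant under time reversal (absolute displacement).
    """
    dpos = abs(trace.end[0] - trace.start[0]) * trace.pixel_size     # um
    dt = (trace.end[1] - trace.start[1]) * trace.frame_interval      # s
    if dt <= 0:
        raise ValueError("zero or negative time span")
    return dpos / dt * 60.0


def embryo_flow_speed(traces: list[KymographTrace],
                      min_traces: int = 10) -> float:
    """Mean per-trace flow speed for one embryo (um/min).

    Fewer than ``min_traces`` traces triggers a warning, matching the
    convention of requiring at least 10 granule trajectories per embryo.
    """
    if len(traces) == 0:
        raise ValueError("no traces")
    if len(traces) < min_traces:
        warnings.warn(f"embryo_flow_speed: only {len(traces)} traces "
                      f"(recommended >= {min_traces})")
    return float(np.mean([flow_speed_from_trace(t) for t in traces]))


# --------------------------------------------------------------------------
# FRAP
# --------------------------------------------------------------------------

def frap_curve(stack: np.ndarray, box: tuple[int, int, int, int],
               bleach_frame: int, frame_interval: float = 2.0) -> FrapCurve:
    """Monitoring-box mean intensity per frame, normalized to pre-bleach.

    ``box`` is (row0, row1, col0, col1) in pixels (half-open), typically
    a central 20 x 100 px region.
    """
    stack = np.asarray(stack, dtype=float)
    r0, r1, c0, c1 = box
    nf, h, w = stack.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError("monitoring box outside image bounds")
    intensity = stack[:, r0:r1, c0:c1].mean(axis=(1, 2))
    time = np.arange(nf) * frame_interval
    return FrapCurve(time=time, intensity=intensity, bleach_frame=bleach_frame)


def fit_frap_halftime(curve: FrapCurve) -> float:
    """Half-time (s) of a single-exponential recovery fit.

    Fits ``N(t) = plateau - (plateau - floor) * exp(-k (t - t_bleach))``
    to the normalized post-bleach curve; half-time = ln(2)/k.
    """
    t = curve.time[curve.bleach_frame:]
    y = curve.normalized[curve.bleach_frame:]
    if len(t) < 4:
        raise ValueError("too few post-bleach frames for a recovery fit")
    t0 = t[0]

    def model(tt, floor, plateau, k):
        return plateau - (plateau - floor) * np.exp(-k * (tt - t0))

    span = max(t[-1] - t0, 1e-9)
    p0 = (float(y[0]), float(y[-1]), 1.0 / span)
    popt, _ = curve_fit(model, t, y, p0=p0,
                        bounds=([-np.inf, -np.inf, 1e-12],
                                [np.inf, np.inf, np.inf]),
                        maxfev=10000)
    return float(np.log(2) / popt[2])
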