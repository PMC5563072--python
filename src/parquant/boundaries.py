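"""Error-function boundary models for cortical domain quantification.

A PAR domain boundary in a membrane intensity profile is a smooth
sigmoidal transition well described by an error function.  Two models
are fitted by nonlinear least squares:

* single boundary, for half-profiles of fixed cells::

      I(x) = a + (b/2) * erf(m * (x - c))

* double boundary, for full circular profiles with one domain::

      I(x) = a + (b/2) * [erf(m * (x - c1)) - erf(m * (x - c2))]

where ``c`` (resp. ``c1 < c2``) is the boundary position in the same
units as ``x`` (normalized arclength), ``m`` the boundary steepness, and
``a``, ``b`` scale/offset the profile.  ``b`` is signed: positive means
the marker is enriched inside ``[c1, c2]`` (posterior marker), negative
means depleted (anterior marker).  Domain sizes follow directly from the
boundary positions: posterior size ``(c2 - c1)/L`` and anterior size
``1 - (c2 - c1)/L`` for a profile of length ``L`` (1 when normalized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

from .profiles import MembraneProfile

_LSQ_TOL = dict(ftol=1e-15, xtol=1e-15, gtol=1e-15, max_nfev=2000)


# --------------------------------------------------------------------------
# models
# --------------------------------------------------------------------------

def erf_boundary(x, a, b, m, c):
    """Single-boundary model a + (b/2) erf(m (x - c))."""
    return a + 0.5 * b * erf(m * (x - c))


def erf_two_boundaries(x, a, b, m, c1, c2):
    """Double-boundary model a + (b/2) [erf(m (x - c1)) - erf(m (x - c2))]."""
    return a + 0.5 * b * (erf(m * (x - c1)) - erf(m * (x - c2)))


# --------------------------------------------------------------------------
# fit containers
# --------------------------------------------------------------------------

@dataclass
class SingleBoundaryFit:
    a: float
    b: float
    m: float
    c: float
    rss: float
    converged: bool
    registered: bool = False

    def predict(self, x):
        return erf_boundary(np.asarray(x, float), self.a, self.b, self.m,
                            self.c)


@dataclass
class DoubleBoundaryFit:
    a: float
    b: float
    m: float
    c1: float
    c2: float
    rss: float
    converged: bool
    L: float = 1.0

    def predict(self, x):
        return erf_two_boundaries(np.asarray(x, float), self.a, self.b,
                                  self.m, self.c1, self.c2)


@dataclass
class DomainMetrics:
    posterior_size: float   # fraction of perimeter
    anterior_size: float
    posterior_center: float


# --------------------------------------------------------------------------
# single-boundary fitting
# --------------------------------------------------------------------------

def _minmax(y):
    lo, hi = float(np.min(y)), float(np.max(y))
    return (y - lo) / (hi - lo), lo, hi


def fit_single_boundary(x, y, normalize: bool = True,
                        flat_floor: float = 1e-8,
                        n_starts: int = 8) -> SingleBoundaryFit:
    """Least-squares single-erf fit of a half-profile boundary region.

    The segment is min-max normalized to [0, 1] first (the convention
    for fixed-cell profile comparison), so the returned ``a``, ``b`` are
    dimensionless.  Initialization comes from the half-maximum crossing;
    if the first fit is poor a multi-start over a coarse grid of
    candidate boundary positions (both transition directions) refines
    it.  A segment whose intensity range is below ``flat_floor`` has no
    defined boundary: ``converged`` is False and parameters are NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 8:
        raise ValueError("need at least 8 samples to fit a boundary")
    if np.ptp(y) <= flat_floor:
        return SingleBoundaryFit(np.nan, np.nan, np.nan, np.nan,
                                 rss=float(np.sum((y - y.mean()) ** 2)),
                                 converged=False)
    if normalize:
        y, _, _ = _minmax(y)

    span = x[-1] - x[0]
    rising = y[-len(y) // 4:].mean() > y[: len(y) // 4].mean()
    b0 = np.ptp(y) if rising else -np.ptp(y)
    a0 = float(np.mean([y.min(), y.max()]))
    mid = a0
    cross = np.nonzero(np.diff(np.sign(y - mid)))[0]
    c0 = float(x[cross[0]]) if len(cross) else float(x[len(x) // 2])
    m0 = 4.0 / max(span / 4, 1e-6)

    def resid(p):
        return erf_boundary(x, *p) - y

    bounds = ([-np.inf, -np.inf, 1e-3, x[0] - 0.25 * span],
              [np.inf, np.inf, 1e6, x[-1] + 0.25 * span])

    def run(p0):
        p0 = np.clip(p0, bounds[0], bounds[1])
        return least_squares(resid, p0, bounds=bounds, **_LSQ_TOL)

    best = run([a0, b0, m0, c0])
    if best.cost > 1e-12 * len(x):
        for cg in np.linspace(x[0] + 0.05 * span, x[-1] - 0.05 * span,
                              n_starts):
            for bs in (b0, -b0):
                for ms in (m0, 5 * m0, m0 / 5):
                    res = run([a0, bs, ms, cg])
                    if res.cost < best.cost:
                        best = res
    a, b, m, c = best.x
    rss = float(2 * best.cost)
    ok = bool(best.success) and x[0] <= c <= x[-1]
    return SingleBoundaryFit(float(a), float(b), float(m), float(c),
                             rss=rss, converged=ok)


# --------------------------------------------------------------------------
# registration and offsets
# --------------------------------------------------------------------------

def register_profiles(reference_fits, profile_pairs, canonical_c: float = 0.5):
    """Circularly align co-acquired profile pairs on a reference boundary.

    Each pair (reference channel, other channel) is shifted by the same
    number of samples so the reference channel's fitted boundary ``c``
    lands at ``canonical_c``.  Pairs whose reference fit did not
    converge are excluded (``None`` in the output) with a warning.

    Returns ``(aligned_pairs, shifts)`` where shifts are in normalized
    arclength units.
    """
    aligned, shifts = [], []
    for fit, (ref, other) in zip(reference_fits, profile_pairs, strict=True):
        if not fit.converged:
            warnings.warn("register_profiles: unconverged reference fit; "
                          "pair excluded")
            aligned.append(None)
            shifts.append(np.nan)
            continue
        ref = np.asarray(ref, float)
        other = np.asarray(other, float)
        n = len(ref)
        shift = (canonical_c - fit.c) % 1.0
        k = int(round(shift * n)) % n
        aligned.append((np.roll(ref, k), np.roll(other, k)))
        shifts.append(k / n)
    return aligned, shifts


def boundary_offset(fit_ref: SingleBoundaryFit, fit_other: SingleBoundaryFit,
                    perimeter_um: float) -> float:
    """Signed boundary displacement in um between two registered fits.

    ``(c_other - c_ref) * perimeter_um`` with x oriented so positive
    values point toward the posterior, i.e. reduced segregation of the
    other marker relative to the reference.
    """
    if not (fit_ref.converged and fit_other.converged):
        raise ValueError("both fits must be converged")
    if not (fit_ref.registered and fit_other.registered):
        raise ValueError("fits must be registered to a common frame "
                         "before computing an offset")
    return (fit_other.c - fit_ref.c) * perimeter_um


# --------------------------------------------------------------------------
# double-boundary fitting
# --------------------------------------------------------------------------

def _phase_starts(xs, ys):
    """Initial (a, b, c1, c2) guesses for one circular phase, both signs."""
    lo, hi = float(ys.min()), float(ys.max())
    mid = 0.5 * (lo + hi)
    guesses = []
    for sign in (1.0, -1.0):
        inside = ys > mid if sign > 0 else ys < mid
        idx = np.nonzero(inside)[0]
        if len(idx) == 0 or len(idx) == len(ys):
            continue
        c1 = xs[idx[0]]
        c2 = xs[idx[-1]] + (xs[1] - xs[0])
        if c2 <= c1:
            continue
        a0 = lo if sign > 0 else hi
        b0 = sign * (hi - lo)
        guesses.append((a0, b0, c1, c2))
    return guesses


def fit_double_boundary(profile, n_phases: int = 8,
                        flat_floor: float = 1e-8) -> DoubleBoundaryFit:
    """Fit the double-erf domain model to a circular normalized profile.

    ``profile`` is a :class:`~parquant.profiles.MembraneProfile` (its
    normalized values are used when present) or an ``(x, y)`` pair on a
    uniform grid over [0, 1).  Because the profile is circular, the fit
    is repeated from ``n_phases`` circular phase shifts (coarse scan)
    and the best-rss solution is kept; boundary positions are mapped
    back modulo 1 with ``c1 < c2`` canonicalized (swapping boundaries
    and negating ``b`` leaves the model invariant).

    A flat profile (range below ``flat_floor``) has undefined
    boundaries: ``converged`` is False.
    """
    if isinstance(profile, MembraneProfile):
        x, y = profile.x, profile.values()
    else:
        x, y = profile
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 16:
        raise ValueError("need at least 16 samples")
    if not np.allclose(np.diff(x), x[1] - x[0]):
        raise ValueError("circular fit requires a uniform x grid")
    finite = np.isfinite(y)
    if not finite.all():
        y = np.interp(x, x[finite], y[finite], period=1.0)
    if np.ptp(y) <= flat_floor:
        return DoubleBoundaryFit(float(np.mean(y)), 0.0, np.nan, np.nan,
                                 np.nan,
                                 rss=float(np.sum((y - y.mean()) ** 2)),
                                 converged=False)

    bounds = ([-np.inf, -np.inf, 1e-2, -0.25, -0.25],
              [np.inf, np.inf, 1e6, 1.25, 1.25])

    best = None
    best_delta = 0.0
    for k in range(n_phases):
        shift_idx = (k * n) // n_phases
        delta = shift_idx / n
        ys = np.roll(y, -shift_idx)
        for a0, b0, c1_0, c2_0 in _phase_starts(x, ys):
            width = max(c2_0 - c1_0, 0.02)
            for m0 in (8.0 / width, 40.0):
                def resid(p):
                    return erf_two_boundaries(x, *p) - ys
                p0 = np.clip([a0, b0, m0, c1_0, c2_0], bounds[0], bounds[1])
                res = least_squares(resid, p0, bounds=bounds, **_LSQ_TOL)
                if best is None or res.cost < best.cost:
                    best = res
                    best_delta = delta
    if best is None:
        return DoubleBoundaryFit(float(np.mean(y)), 0.0, np.nan, np.nan,
                                 np.nan,
                                 rss=float(np.sum((y - y.mean()) ** 2)),
                                 converged=False)
    a, b, m, c1, c2 = best.x
    c1 = (c1 + best_delta) % 1.0
    c2 = (c2 + best_delta) % 1.0
    if c1 > c2:
        c1, c2 = c2, c1
        b = -b
    rss = float(2 * best.cost)
    return DoubleBoundaryFit(float(a), float(b), float(m), float(c1),
                             float(c2), rss=rss,
                             converged=bool(best.success))


# --------------------------------------------------------------------------
# domain metrics
# --------------------------------------------------------------------------

def domain_metrics(fit: DoubleBoundaryFit) -> DomainMetrics:
    """Domain sizes and center from a converged double-boundary fit.

    ``[c1, c2]`` delimits the posterior domain (the profile is aligned
    so the posterior domain is interior to the fitted window; an
    anterior marker is simply depleted there, b < 0).  Sizes are
    fractions of the perimeter and sum to 1 exactly.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; domain undefined")
    post = (fit.c2 - fit.c1) / fit.L
    return DomainMetrics(posterior_size=post, anterior_size=1.0 - post,
                         posterior_center=(fit.c1 + fit.c2) / 2.0)


def domain_change_ratio(before: DomainMetrics, after: DomainMetrics) -> float:
    """Posterior domain size after / before (e.g. pre/post drug addition)."""
    if before.posterior_size == 0:
        warnings.warn("domain_change_ratio: zero before-size; undefined")
        return float("nan")
    return after.posterior_size / before.posterior_size


def segregation_efficiency(fit: DoubleBoundaryFit) -> float:
    """Relative anterior domain size of an anterior-marker fit.

    Smaller anterior domains mean more efficient segregation.  The fit
    is expected to come from an anterior marker (depleted in the
    posterior domain, b < 0); a non-negative amplitude triggers a
    warning.
    """
    if fit.b >= 0:
        warnings.warn("segregation_efficiency: expected an anterior-marker "
                      "fit (b < 0)")
    return domain_metrics(fit).anterior_size


# --------------------------------------------------------------------------
# retraction geometry (fixed-cell annotations)
# --------------------------------------------------------------------------

def retraction(pole_anterior, pole_posterior, domain_end_top,
               domain_end_bottom, pixel_size: float = 1.0) -> float:
    """Distance from a marker's posterior boundary to the posterior pole.

    The boundary is the intersection of the equatorial line (joining the
    two poles) with the line joining the cortical ends of the marker
    domain (top and bottom).  The returned distance is scaled by
    ``pixel_size`` (um per px).  Parallel lines raise; an intersection
    outside the pole-to-pole segment warns.
    """
    pa = np.asarray(pole_anterior, float)
    pp = np.asarray(pole_posterior, float)
    dt = np.asarray(domain_end_top, float)
    db = np.asarray(domain_end_bottom, float)
    u = pp - pa
    v = db - dt
    det = u[0] * (-v[1]) - (-v[0]) * u[1]
    if abs(det) < 1e-12 * max(np.linalg.norm(u) * np.linalg.norm(v), 1.0):
        raise ValueError("equatorial and domain-end lines are parallel")
    rhs = dt - pa
    t = (rhs[0] * (-v[1]) - (-v[0]) * rhs[1]) / det
    if not (0.0 <= t <= 1.0):
        warnings.warn("retraction: intersection outside the pole-to-pole "
                      "segment")
    inter = pa + t * u
    return float(np.linalg.norm(inter - pp) * pixel_size)


def mark_registered(fit: SingleBoundaryFit) -> SingleBoundaryFit:
    """Return a copy of ``fit`` stamped as being in the common registered
    frame (e.g. after refitting profiles aligned by register_profiles)."""
    return replace(fit, registered=True)
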