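"""Asymmetry index (ASI) and cluster index.

The ASI of a feature with anterior signal A and posterior signal P is

    ASI = (A - P) / (2 (A + P))

bounded in [-0.5, 0.5], antisymmetric under swapping halves, and 0 for
a symmetric cell.  Raw values are normalized to the mean raw ASI of the
control group, so 1 means wild-type asymmetry and 0 complete loss.  The
feature may be membrane intensity, cytoplasmic intensity, cross-
sectional area, or punctum density, computed from cell halves split by
the perpendicular bisector of the anterior-posterior axis.

The cluster index quantifies punctate vs diffuse organization: the
population variance of background-subtracted, mean-normalized cortical
intensity within an ROI.  It is 0 for a uniform ROI and invariant under
gain changes (the mean normalization) and offset changes (as long as
the supplied background tracks the offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FEATURE_KINDS = ("membrane_intensity", "cytoplasm_intensity", "cell_area",
                 "foci_density")


@dataclass
class AsymmetryInputs:
    """Anterior/posterior measurements of one feature (same units)."""

    A: float
    P: float
    feature_kind: str = "membrane_intensity"

    def __post_init__(self):
        if self.A < 0 or self.P < 0:
            raise ValueError("A and P must be non-negative")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")


@dataclass
class AsymmetryResult:
    raw: float
    normalized: float
    control_mean_raw: float
    n_control: int


def asi_raw(inputs, P: float | None = None) -> float:
    """(A - P) / (2 (A + P)); accepts AsymmetryInputs or (A, P)."""
    if P is None:
        A, P = inputs.A, inputs.P
    else:
        A = inputs
    if A < 0 or P < 0:
        raise ValueError("A and P must be non-negative")
    if A + P == 0:
        raise ValueError("A + P = 0: asymmetry undefined")
    return (A - P) / (2.0 * (A + P))


def asi_normalize(raw_values, control_raws) -> list[AsymmetryResult]:
    """Normalize raw ASI values to the control-group mean.

    By construction the mean normalized ASI of the control group itself
    is exactly 1.
    """
    control_raws = np.asarray(control_raws, float)
    if control_raws.size == 0:
        raise ValueError("empty control group")
    mean_c = float(control_raws.mean())
    if mean_c == 0:
        raise ValueError("zero control mean: normalization undefined")
    return [AsymmetryResult(raw=float(r), normalized=float(r) / mean_c,
                            control_mean_raw=mean_c,
                            n_control=control_raws.size)
            for r in np.asarray(raw_values, float)]


def _circular_distance(x, center):
    return np.abs(((np.asarray(x, float) - center + 0.5) % 1.0) - 0.5)


def halves_from_profile(profile, anterior_center: float = 0.5,
                        feature_kind: str = "membrane_intensity"
                        ) -> AsymmetryInputs:
    """Mean membrane signal over the anterior vs posterior half of an
    aligned circular profile.

    ``anterior_center`` is the normalized arclength of the anterior pole
    in the profile's frame (0.5 in the canonical orientation, with the
    posterior pole at 0).  The anterior half is the set of positions
    within circular distance 1/4 of the anterior pole.
    """
    if anterior_center is None:
        raise ValueError("profile alignment unknown: anterior_center "
                         "required")
    vals = profile.values()
    ant = _circular_distance(profile.x, anterior_center) < 0.25
    if ant.sum() == 0 or (~ant).sum() == 0:
        raise ValueError("empty half")
    return AsymmetryInputs(A=float(np.nanmean(vals[ant])),
                           P=float(np.nanmean(vals[~ant])),
                           feature_kind=feature_kind)


def halves_from_image(image, axis, mask, compartment: str = "cytoplasm"
                      ) -> AsymmetryInputs:
    """Split a cell mask by the perpendicular bisector of the pole axis.

    ``axis = (anterior_pole, posterior_pole)`` in (x, y) pixels.  For
    ``compartment="area"`` the half measurements are pixel counts; for
    ``"cytoplasm"`` or ``"membrane"`` they are mean intensities within
    the supplied mask (the caller provides the appropriate mask for the
    compartment).
    """
    image = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    (pa, pp) = (np.asarray(axis[0], float), np.asarray(axis[1], float))
    u = pp - pa
    if np.linalg.norm(u) == 0:
        raise ValueError("degenerate axis")
    mid = 0.5 * (pa + pp)
    ys, xs = np.nonzero(mask)
    proj = (xs - mid[0]) * u[0] + (ys - mid[1]) * u[1]
    ant = proj < 0
    if ant.sum() == 0 or (~ant).sum() == 0:
        raise ValueError("empty half after splitting the mask")
    if compartment == "area":
        A, P = float(ant.sum()), float((~ant).sum())
        kind = "cell_area"
    elif compartment in ("cytoplasm", "membrane"):
        vals = image[ys, xs]
        A = float(vals[ant].mean())
        P = float(vals[~ant].mean())
        kind = ("cytoplasm_intensity" if compartment == "cytoplasm"
                else "membrane_intensity")
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    return AsymmetryInputs(A=A, P=P, feature_kind=kind)


def cluster_index(image, roi, background: float = 0.0) -> float:
    """Population variance of background-subtracted, mean-normalized
    intensity within an ROI (boolean mask or flat value array)."""
    roi = np.asarray(roi)
    if roi.dtype == bool:
        vals = np.asarray(image, float)[roi]
    else:
        vals = np.asarray(roi, float).ravel()
    if vals.size == 0:
        raise ValueError("empty ROI")
    v = vals - background
    mv = v.mean()
    if mv <= 0:
        raise ValueError("non-positive ROI mean after background "
                         "subtraction")
    w = v / mv
    return float(np.var(w))
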