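"""Synthetic-embryo generator with attached ground truth.

Every analysis stage in this package is validated against synthetic
images whose generating parameters are known exactly.  The generator
emulates the statistical structure the measurements assume, not the
underlying biology:

* **midsection images** — an ellipsoidal cell seen at its midplane: a
  bright membrane ring (3-5 px) whose intensity along the perimeter
  follows the double-erf domain model over a uniform cytoplasm and a
  darker background;
* **cortical-plane images** — a diffuse membrane population plus
  Gaussian-blurred punctate clusters at known positions;
* **kymographs** — linear particle traces of known slope (cortical flow
  velocity) on a space x time canvas;
* **photobleach recovery stacks** — a uniform field with a central
  bleached stripe recovering exponentially with a known half-time.

Noise follows the standard fluorescence camera model: Poisson shot
noise on the photon signal followed by additive Gaussian read noise.
Either component can be disabled (``poisson_scale = 0`` and
``noise_gaussian_sd = 0`` respectively, the defaults).  All generators
are pure functions of their arguments: the same ``GroundTruth.seed``
yields bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .boundaries import erf_two_boundaries
from .kinetics import KymographTrace
from .profiles import GeometryError, MembraneProfile


# --------------------------------------------------------------------------
# ground truth record
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generating parameters of a synthetic embryo; the oracle for tests.

    Membrane intensity along the perimeter (normalized arclength
    ``x in [0, 1)``) follows
    ``I(x) = a + (b/2) [erf(m (x - c1)) - erf(m (x - c2))]`` in AU; the
    cell interior sits at ``cytoplasm_level`` and the exterior at
    ``background_level``.  Cortical images mix ``diffuse_level`` with
    ``cluster_count`` Gaussian spots.  ``flow_velocity`` (um/min) sets
    kymograph trace slopes via ``pixel_size`` and ``frame_interval``.
    """

    baseline_a: float = 120.0       # membrane AU outside the domain
    amplitude_b: float = 300.0      # signed enrichment inside [c1, c2]
    slope_m: float = 30.0           # boundary steepness, 1/x-units
    boundary_c1: float = 0.3        # normalized perimeter position
    boundary_c2: float = 0.7
    cytoplasm_level: float = 100.0  # AU
    background_level: float = 10.0  # AU
    cluster_count: int = 40
    cluster_sigma: float = 2.0      # px
    cluster_amplitude: float = 60.0  # AU peak
    diffuse_level: float = 20.0     # AU
    flow_velocity: float = 7.1      # um/min (wild-type cortical flow)
    pixel_size: float = 0.1         # um/px
    frame_interval: float = 1.0     # s
    noise_gaussian_sd: float = 0.0  # AU; 0 disables read noise
    poisson_scale: float = 0.0      # photons/AU; 0 disables shot noise
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.boundary_c1 < self.boundary_c2 < 1.0):
            raise ValueError("invalid boundary_c1/boundary_c2: "
                             "require 0 <= c1 < c2 < 1")
        if self.slope_m <= 0:
            raise ValueError("invalid slope_m: must be > 0")
        if self.cluster_sigma <= 0:
            raise ValueError("invalid cluster_sigma: must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("invalid pixel_size: must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("invalid frame_interval: must be > 0")
        if self.background_level >= self.cytoplasm_level:
            raise ValueError("invalid background_level: must be below "
                             "cytoplasm_level")
        if self.cluster_count < 0:
            raise ValueError("invalid cluster_count: must be >= 0")
        if self.noise_gaussian_sd < 0 or self.poisson_scale < 0:
            raise ValueError("invalid noise parameters: must be >= 0")


@dataclass
class SyntheticEmbryo:
    """A rendered synthetic image (or stack) with its generating truth."""

    image: np.ndarray
    truth: GroundTruth
    contour: np.ndarray | None = None       # (n, 2) points, (x, y)
    annotations: dict = field(default_factory=dict)


def _rng(truth: GroundTruth) -> np.random.Generator:
    return np.random.default_rng(truth.seed)


def apply_noise(arr: np.ndarray, truth: GroundTruth,
                rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise (on arr * poisson_scale photons) then Gaussian
    read noise; components with scale/sd = 0 are skipped."""
    out = np.asarray(arr, dtype=float)
    if truth.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) *
                          truth.poisson_scale) / truth.poisson_scale
    if truth.noise_gaussian_sd > 0:
        out = out + rng.normal(0.0, truth.noise_gaussian_sd, np.shape(out))
    return out


# --------------------------------------------------------------------------
# membrane profiles and midsection images
# --------------------------------------------------------------------------

def membrane_model(truth: GroundTruth, x: np.ndarray) -> np.ndarray:
    """Ideal (noiseless) membrane intensity at normalized arclength x."""
    return erf_two_boundaries(np.asarray(x, float), truth.baseline_a,
                              truth.amplitude_b, truth.slope_m,
                              truth.boundary_c1, truth.boundary_c2)


def gen_membrane_profile(truth: GroundTruth,
                         n_points: int = 360) -> MembraneProfile:
    """Sample the membrane model at x = k/n_points, with noise per truth."""
    truth.validate()
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    rng = _rng(truth)
    x = np.arange(n_points) / n_points
    membrane = apply_noise(membrane_model(truth, x), truth, rng)
    cyto = apply_noise(np.full(n_points, truth.cytoplasm_level), truth, rng)
    bg = apply_noise(np.full(n_points, truth.background_level), truth, rng)
    return MembraneProfile(x=x, membrane=membrane, cytoplasm_local=cyto,
                           background_local=bg, meta={"truth": truth})


def _ellipse_arc_points(cx, cy, rx, ry, spacing):
    """Ellipse boundary resampled to uniform arclength; returns
    (points (n,2), normalized arclength (n,), perimeter)."""
    t = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
    pts = np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    perimeter = s[-1] + seg[-1]
    n_out = max(int(round(perimeter / spacing)), 16)
    s_new = np.arange(n_out) * (perimeter / n_out)
    xo = np.interp(s_new, s, pts[:, 0], period=perimeter)
    yo = np.interp(s_new, s, pts[:, 1], period=perimeter)
    return np.column_stack([xo, yo]), s_new / perimeter, perimeter


def gen_midsection_image(truth: GroundTruth,
                         shape: tuple[int, int] = (256, 256),
                         ellipse: tuple[float, float, float, float]
                         | None = None,
                         ring_width: float = 5.0) -> SyntheticEmbryo:
    """Render a midsection cell: membrane ring over cytoplasm/background.

    ``ellipse = (cx, cy, rx, ry)`` in pixels; by default an elongated
    cell centred in the frame.  Ring pixels take the membrane model
    value at their arclength position; interior pixels are
    ``cytoplasm_level`` and exterior ``background_level``; noise is then
    applied.  Arclength x = 0 is the posterior pole (rightmost point,
    ``(cx + rx, cy)``), increasing counterclockwise in (x, y), so the
    anterior pole sits at x = 0.5.
    """
    truth.validate()
    h, w = shape
    if ellipse is None:
        ellipse = (w / 2, h / 2, 0.38 * w, 0.28 * h)
    cx, cy, rx, ry = ellipse
    margin = ring_width / 2 + 1
    if (cx - rx < margin or cx + rx > w - 1 - margin
            or cy - ry < margin or cy + ry > h - 1 - margin):
        raise GeometryError("ellipse too large: needs a margin of "
                            f"{margin} px inside a {shape} image")

    dense, arc_x, perimeter = _ellipse_arc_points(cx, cy, rx, ry, 0.25)
    tree = cKDTree(dense)
    Y, X = np.mgrid[0:h, 0:w]
    pix = np.column_stack([X.ravel(), Y.ravel()]).astype(float)
    dist, idx = tree.query(pix, workers=-1)
    dist = dist.reshape(h, w)
    arc = arc_x[idx].reshape(h, w)
    inside = ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 < 1.0
    img = np.where(inside, truth.cytoplasm_level, truth.background_level)
    ring = dist <= ring_width / 2
    img = np.where(ring, membrane_model(truth, arc), img).astype(float)
    img = apply_noise(img, truth, _rng(truth))

    contour, _, _ = _ellipse_arc_points(cx, cy, rx, ry, 1.0)
    annotations = {"posterior_pole": (cx + rx, cy),
                   "anterior_pole": (cx - rx, cy),
                   "perimeter_px": perimeter,
                   "ellipse": ellipse}
    return SyntheticEmbryo(image=img, truth=truth, contour=contour,
                           annotations=annotations)


# --------------------------------------------------------------------------
# cortical-plane images
# --------------------------------------------------------------------------

def gen_cortical_image(truth: GroundTruth,
                       shape: tuple[int, int] = (256, 256),
                       margin: float | None = None,
                       thirds_weights: tuple[float, float, float]
                       | None = None) -> SyntheticEmbryo:
    """Diffuse level plus Gaussian punctate clusters at recorded positions.

    Spot centres are drawn uniformly (within ``margin`` of the borders,
    default 4 sigma).  ``thirds_weights = (anterior, middle, posterior)``
    optionally biases placement across the three vertical thirds of the
    image (anterior = left), emulating asymmetric punctum distributions;
    positions are uniform within the chosen third.  Overlapping spots
    are permitted.  True spot coordinates are recorded in
    ``annotations["spots"]``.
    """
    truth.validate()
    h, w = shape
    rng = _rng(truth)
    if margin is None:
        margin = 4.0 * truth.cluster_sigma
    n = truth.cluster_count
    if thirds_weights is None:
        xs = rng.uniform(margin, w - 1 - margin, n)
        ys = rng.uniform(margin, h - 1 - margin, n)
    else:
        wgt = np.asarray(thirds_weights, float)
        wgt = wgt / wgt.sum()
        thirds = rng.choice(3, size=n, p=wgt)
        lo = thirds * (w / 3)
        xs = lo + rng.uniform(0, w / 3, n)
        ys = rng.uniform(0, h - 1, n)
    img = np.full(shape, truth.diffuse_level, dtype=float)
    sig = truth.cluster_sigma
    r = int(np.ceil(4 * sig)) + 1
    for x0, y0 in zip(xs, ys):
        xi, yi = int(round(x0)), int(round(y0))
        x_lo, x_hi = max(xi - r, 0), min(xi + r + 1, w)
        y_lo, y_hi = max(yi - r, 0), min(yi + r + 1, h)
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        img[y_lo:y_hi, x_lo:x_hi] += truth.cluster_amplitude * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sig ** 2))
    img = apply_noise(img, truth, rng)
    return SyntheticEmbryo(image=img, truth=truth,
                           annotations={"spots": np.column_stack([xs, ys])})


# --------------------------------------------------------------------------
# kymographs
# --------------------------------------------------------------------------

def gen_kymograph(truth: GroundTruth, n_traces: int = 12,
                  duration: float = 200.0, space_px: int = 256,
                  trace_amplitude: float | None = None) -> SyntheticEmbryo:
    """Space x time kymograph with linear traces of known slope.

    Trace slope is ``flow_velocity`` converted to px/frame via
    ``pixel_size`` and ``frame_interval``; start positions are random
    under the seed.  Traces that exit the spatial field are truncated
    and flagged.  True endpoints are recorded as
    :class:`~parquant.kinetics.KymographTrace` objects in
    ``annotations["traces"]``.
    """
    truth.validate()
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n_frames = int(round(duration / truth.frame_interval)) + 1
    if n_frames < 2:
        raise ValueError("duration shorter than one frame interval")
    if trace_amplitude is None:
        trace_amplitude = truth.cluster_amplitude
    rng = _rng(truth)
    slope = truth.flow_velocity / 60.0 * truth.frame_interval \
        / truth.pixel_size                                   # px / frame
    img = np.full((space_px, n_frames), truth.diffuse_level, dtype=float)
    traces = []
    frames = np.arange(n_frames)
    if abs(slope) > space_px - 1:
        raise ValueError("flow crosses the whole field within one frame; "
                         "enlarge space_px or shorten frame_interval")
    for _ in range(n_traces):
        # require at least one frame of motion inside the field
        while True:
            x0 = rng.uniform(0, space_px - 1)
            pos = x0 + slope * frames
            valid = (pos >= 0) & (pos <= space_px - 1)
            if valid[1]:
                break
        last = int(np.nonzero(valid)[0][-1])
        truncated = last < n_frames - 1
        idx = np.round(pos[: last + 1]).astype(int)
        np.add.at(img, (idx, frames[: last + 1]), trace_amplitude)
        traces.append(KymographTrace(start=(x0, 0.0),
                                     end=(float(pos[last]), float(last)),
                                     pixel_size=truth.pixel_size,
                                     frame_interval=truth.frame_interval,
                                     truncated=truncated))
    img = apply_noise(img, truth, rng)
    return SyntheticEmbryo(image=img, truth=truth,
                           annotations={"traces": traces})


# --------------------------------------------------------------------------
# FRAP stacks
# --------------------------------------------------------------------------

def gen_frap_stack(truth: GroundTruth, bleach_frame: int = 5,
                   recovery_halftime: float = 20.0, n_frames: int = 60,
                   shape: tuple[int, int] = (64, 128),
                   stripe_width: int = 20,
                   bleach_floor: float = 0.2) -> SyntheticEmbryo:
    """Uniform field with a central bleached stripe recovering exponentially.

    At ``bleach_frame`` a central ``stripe_width``-px column stripe drops
    to ``bleach_floor`` of the pre-bleach level, then recovers as
    ``floor + (1 - floor) (1 - 2^(-dt / half-time))`` toward the
    pre-bleach level.  At one half-time after the bleach the normalized
    stripe intensity is exactly halfway between floor and 1.
    """
    truth.validate()
    if bleach_frame < 1:
        raise ValueError("bleach_frame must be >= 1 (pre-bleach frames "
                         "required)")
    if recovery_halftime <= 0:
        raise ValueError("recovery_halftime must be > 0")
    h, w = shape
    c0 = w // 2 - stripe_width // 2
    c1 = c0 + stripe_width
    rng = _rng(truth)
    stack = np.full((n_frames, h, w), truth.cytoplasm_level, dtype=float)
    for f in range(bleach_frame, n_frames):
        dt = (f - bleach_frame) * truth.frame_interval
        frac = bleach_floor + (1 - bleach_floor) * (
            1.0 - 2.0 ** (-dt / recovery_halftime))
        stack[f, :, c0:c1] = truth.cytoplasm_level * frac
    stack = apply_noise(stack, truth, rng)
    annotations = {"bleach_frame": bleach_frame, "stripe_cols": (c0, c1),
                   "recovery_halftime": recovery_halftime,
                   "bleach_floor": bleach_floor}
    return SyntheticEmbryo(image=stack, truth=truth, annotations=annotations)


# --------------------------------------------------------------------------
# persistence (TIFF + JSON sidecar)
# --------------------------------------------------------------------------

def save_embryo(embryo: SyntheticEmbryo, path_base: str) -> tuple[str, str]:
    """Write ``<path_base>.tif`` and a ``<path_base>.json`` sidecar with
    the ground truth, contour and annotations."""
    import tifffile
    tif_path = f"{path_base}.tif"
    json_path = f"{path_base}.json"
    tifffile.imwrite(tif_path, np.asarray(embryo.image, dtype=np.float32))

    def _ser(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    sidecar = {"truth": dataclasses.asdict(embryo.truth),
               "contour": None if embryo.contour is None
               else embryo.contour.tolist(),
               "annotations": embryo.annotations}
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, default=_ser)
    return tif_path, json_path


def load_embryo(path_base: str) -> SyntheticEmbryo:
    """Read back an embryo written by :func:`save_embryo` (annotations are
    returned as plain JSON structures)."""
    import tifffile
    image = tifffile.imread(f"{path_base}.tif")
    with open(f"{path_base}.json") as fh:
        sidecar = json.load(fh)
    truth = GroundTruth(**sidecar["truth"])
    contour = (None if sidecar["contour"] is None
               else np.asarray(sidecar["contour"], float))
    return SyntheticEmbryo(image=np.asarray(image, float), truth=truth,
                           contour=contour,
                           annotations=sidecar["annotations"])
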