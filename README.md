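# parquant

Quantification of cortical PAR polarity in *C. elegans* zygote
microscopy: membrane intensity profiles, error-function domain-boundary
models, asymmetry and clustering statistics, punctum detection, and
cortical-flow / FRAP kinetics — together with a synthetic-embryo
generator that provides exact ground truth for every measurement.

## Who this is for

Labs measuring anterior–posterior polarity of membrane-associated
proteins in single cells: how asymmetric a marker is, where its domain
boundary sits, how clustered its cortical population is, and how the
cortex moves. The package turns midsection images, cortical-plane
images, kymographs and photobleaching stacks (plus user-supplied
contours/annotations) into per-embryo numbers.

## The core quantities

**Asymmetry index.** For anterior and posterior signals A and P of a
feature (membrane intensity, cytoplasm, cross-sectional area, or
punctum density):

    ASI = (A − P) / (2 (A + P))  ∈ [−0.5, 0.5]

normalized to the control-group mean so that 1 is control-like
asymmetry and 0 complete loss.

**Erf boundary models.** Membrane profiles I(x) along the normalized
perimeter are fitted with

    I(x) = a + (b/2) erf(m (x − c))                          (one boundary)
    I(x) = a + (b/2) [erf(m (x − c1)) − erf(m (x − c2))]     (one domain)

where c, c1, c2 are boundary positions, m the boundary steepness and
a, b scale/offset (b signed: > 0 enriched inside [c1, c2], < 0
depleted). Posterior domain size = (c2 − c1)/L, anterior size
= 1 − (c2 − c1)/L; segregation efficiency of an anterior marker is its
relative anterior domain size (smaller = more efficient).

**Cluster index.** Population variance of background-subtracted,
mean-normalized cortical intensity in an ROI — 0 for a uniform cortex,
larger for punctate organization.

**Kinetics.** Total membrane signal by reference cross-section
subtraction, retention ratios before/after treatment, straight-line
kymograph flow speeds in μm/min, and FRAP recovery curves with an
exponential half-time fit.

## Worked example

Generate a synthetic zygote with a known posterior domain, extract and
normalize its membrane profile, fit the domain model and score the
asymmetry:

```python
import numpy as np
from parquant import (GroundTruth, gen_midsection_image, extract_stripe,
                      membrane_from_stripe, normalize_profile,
                      fit_double_boundary, domain_metrics,
                      halves_from_profile, asi_raw)

truth = GroundTruth(boundary_c1=0.3, boundary_c2=0.7,   # true domain
                    amplitude_b=300.0, noise_gaussian_sd=30.0, seed=11)
embryo = gen_midsection_image(truth, shape=(256, 256))

stripe  = extract_stripe(embryo.image, embryo.contour, width=60)
profile = normalize_profile(membrane_from_stripe(stripe, top_k=4))
fit     = fit_double_boundary(profile)
dm      = domain_metrics(fit)
asi     = asi_raw(halves_from_profile(profile, anterior_center=0.0))

print(f"c1={fit.c1:.4f}  c2={fit.c2:.4f}  b={fit.b:+.2f}")
print(f"posterior size={dm.posterior_size:.4f}  (true 0.400)")
print(f"raw ASI={asi:.4f}")
```

Output:

```
c1=0.3025  c2=0.6988  b=+3.18
posterior size=0.3963  (true 0.400)
raw ASI=-0.2418
```

The fitted boundaries land within a few thousandths of the generating
positions despite read noise at a tenth of the membrane amplitude, and
the posterior domain size (fraction of perimeter between the
boundaries) recovers the true 0.4 to within 0.004. The negative raw
ASI says the marker is posterior-enriched when halves are split about
an anterior pole at x = 0 (the amplitude `b = +3.18` is on the
cytoplasm-normalized scale). Dividing by a control-group mean ASI
would put it on the 0–1 normalized scale.

## Layout

| module | contents |
|---|---|
| `parquant.synthgen` | ground-truth record, midsection/cortical/kymograph/FRAP generators, noise model, TIFF+JSON I/O |
| `parquant.profiles` | stripe extraction, membrane profiles, normalization, intensity ratios, temporal projection |
| `parquant.boundaries` | erf models, single/double fits, registration, domain metrics, retraction geometry |
| `parquant.asymmetry` | ASI, control normalization, half-splitting, cluster index |
| `parquant.puncta` | band-pass punctum detector, embryo partition, density ASI |
| `parquant.kinetics` | cross-section membrane signal, retention, flow speeds, FRAP curves |

See `docs/methods.md` for the measurement models, parameter defaults
and their rationale, and the generator's scope and limitations.
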