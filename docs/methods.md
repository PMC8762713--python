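# Methods

## Coordinate and counting conventions

Volumes are indexed `(b, a, z)`: slow axis (one index per B-scan), fast
axis (one index per A-line), depth increasing toward the sclera. The
choroid slab is the half-open interval `bm ≤ z < csi` of per-A-line
surface indices. Lateral pitch is `extent / n` (pixel-pitch convention),
so every volume statistic is literally `voxel count × db·da·dz`; no
partial-voxel weighting is used anywhere. Flattening to BM uses integer
per-A-line shifts, never interpolation, so slab voxel counts — and hence
all volumes — are identical before and after flattening.

## Enhancement stages

The four stages run in a fixed order; each is individually toggleable.

**Denoising.** OCT speckle is multiplicative with intensity-proportional
spread, so the default method works homomorphically: per-B-scan non-local
means on log-intensities (strength `h = 0.4`, about 0.75× the log-speckle
standard deviation of a 4-look Gamma field, patch 5, search radius 7),
followed by a 0.05 mm median that borrows strength across adjacent
B-scans. This is a classical, edge-preserving surrogate for the very
strong learned denoisers used on commercial scanners; plain `median` and
`gaussian` filters are available behind the same interface. The
behavioural contract is a ≥ 40% reduction of speckle contrast (sd/mean) on
homogeneous tissue; the default achieves ~80% on the standard phantom.

**Shadow reduction.** Retinal vessels cast narrow (~0.05–0.15 mm) columnar
shadows onto the choroid. Each A-line is rescaled by
`Ê(b,a) / max(E(b,a), ε)`, where `E` is the full-depth summed intensity
and `Ê` its 2-D lateral median over a 0.5 mm window — wide enough to treat
shadows as outliers, narrow enough to preserve genuine anatomy. Being a
single factor per A-line, the correction preserves within-A-line intensity
ratios exactly.

**Attenuation compensation.** `I_c(z) = I(z)ⁿ / (2·max(Σ_{z'≥z} I(z')ⁿ, ε))`
with default `n = 1`, `ε = 1e-8`. Outputs lie in `[0, 0.5]`; the deepest
voxel of a positive A-line maps to exactly 0.5. For an exponentially
attenuated A-line the output is depth-flattened up to the finite-tail
truncation term.

An exact algebraic consequence worth stating: the compensation normalises
each A-line by its own depth-integrated signal, so it is **invariant to any
per-A-line rescaling** — and shadow reduction *is* a per-A-line rescaling.
With compensation enabled the shadow stage therefore cannot change the
final enhanced volume (the test suite asserts the identity). The shadow
stage earns its keep in configurations that stop before compensation:
en-face previews, C-scan generation from partially processed volumes, or
pipelines with the compensation stage disabled. Even there its effect on
overall segmentation quality is mixed on the phantom: it removes roughly a
fifth of shadow-region false positives, but because the phantom's shadows
attenuate only the sub-BM signal while the energy profile integrates the
whole A-line (retina included), the single-factor correction systematically
under-corrects, and the profile smoothing also slightly flattens genuine
vessel-induced energy dips.

**Local contrast enhancement.** Slice-wise CLAHE per B-scan, tiles
2.0 mm (lateral) × 0.5 mm (depth), clip limit 0.002. The deliberately
gentle setting matters: aggressive equalisation maps each tile's histogram
toward uniform, which *flattens* the lumen/stroma bimodality (measured
Fisher separation drops by ~40% at clip 0.01) and destabilises the global
Otsu threshold downstream. At clip 0.002 the stage acts as a mild local
renormalisation that leaves the composite segmentation calibrated.

## Surface handling

For clinical data the BM/CSI surfaces are inputs, produced by the
scanner's layer segmentation with manual review. `detect_surfaces_phantom`
exists so that phantom experiments are self-contained: after a small
median and Gaussian smoothing it takes the per-A-line axial gradient, finds
the inner retinal surface (strongest positive edge), BM as the peak of the
first strong *negative* run below it (bright retina/RPE complex over darker
stroma), and CSI as the peak of the deepest strong *positive* run below BM
(stroma to brighter sclera), followed by a 0.33 mm lateral median of the
depth maps. On noiseless phantoms the recovery is exact, including tilted
layers; under 4-look speckle the median absolute error is ≤ 2 voxels
(isolated A-lines through large vessels can deviate further; they are
suppressed by the lateral median but not eliminated).

## Segmentation

Vessels are the hyporeflective phase, so every rule flags `I < T`, with
ties deterministically assigned to stroma.

- **B-scan Niblack**: `T = m + k·s` over 0.8 mm (fast) × 0.5 mm (depth)
  windows in each B-scan plane; `m`, `s` are slab-masked windowed mean and
  population standard deviation, so retina and sclera never leak into the
  local statistics. Default `k = −0.30`.
- **C-scan Niblack**: the same rule per en-face slice of the BM-flattened
  volume with 1.5 × 1.5 mm lateral windows; at one depth offset below BM
  vessels have similar calibre, which improves connectivity.
- **Global Otsu** on the pooled in-slab histogram, catching the large
  dilated vessels whose interiors defeat local windows.

The composite is a 2-of-3 majority vote followed by removal of
26-connected components under 27 voxels (speckle-scale debris below any
plausible capillary volume). Union and intersection are available as
configuration. The windows and `k` were calibrated once on the standard
phantom; window sizes need to exceed the largest vessel cross-section in
their plane so that local statistics always mix lumen and stroma — that,
not the exact `k`, is the load-bearing choice. Niblack's textbook failure
mode (flagging ~Φ(k) of any completely homogeneous window) is mitigated by
that choice and vetoed by the majority rule rather than patched with a
contrast floor.

On the standard phantom the defaults reach Dice 0.91 against truth with
total vessel volume ~+12% of the analytic value; raw (unenhanced)
segmentation reaches only Dice 0.46.

## Quantification

En-face maps multiply per-A-line counts by the voxel volume, so map sums
equal count × voxel volume exactly (integer arithmetic before one final
product). The ETDRS grid defaults to the lateral scan centre (no fovea
detection — configurable in mm), rings 1/3/6 mm, quadrants split at ±45°
to the fast axis, nasal/temporal orientation controlled by an OD/OS flag.
An A-line belongs to a region iff its footprint centre lies inside; the
nine disjoint subfields sum exactly to the 6-mm-circle aggregate. The
vessel index is reported on aggregated volumes (ratio of sums), not as a
mean of per-A-line ratios; cohort-level indices averaged per eye (as in
published group tables) are a different statistic and can differ in the
second decimal.

## Cohort model and ROC statistics

Published group data for the central 6-mm circle are means ± SE over n
eyes (healthy n = 77, CSC n = 34, VKH/SO n = 33; the "±" values are read
as standard errors — group SDs of 0.11 mm³ across 77 eyes would be
implausible, and the binormal AUCs under the SE reading reproduce the
published 0.84/0.84/0.69/0.72 within 0.02). The binormal completion
models each group as `Normal(mean, (SE·√n)²)`.

- Closed form: `AUC = Φ((μ₁−μ₀)/√(σ₀²+σ₁²))`.
- Empirical: per replicate, draw the published group sizes, compute the
  midrank Mann–Whitney AUC (exactly the trapezoidal area under the
  empirical ROC; the equivalence is property-tested against brute-force
  pair counting). 10,000 replicates give a Monte-Carlo SE of ~5·10⁻⁴.
- Operating points: at a fixed cutoff `c` with disease-high orientation,
  sensitivity `= P(disease > c)` and specificity `= P(healthy ≤ c)`, in
  closed form or per replicate.
- Youden cutoffs maximise `J = sens + spec − 1` over candidate thresholds
  at midpoints between consecutive distinct pooled scores; ties resolve to
  the lowest threshold, and perfectly separated groups yield the midpoint
  of the separating gap.

The binormal completion is the minimal model consistent with the printed
summaries; empirical patient-data AUCs can differ from it by a few
hundredths, which is why reproduction is assessed at ±0.05.

## The standard phantom

Grid 100 × 224 × 120 voxels at (0.03, 0.03, 0.01) mm — a 3.0 × 6.7 mm
patch of macula with 1.2 mm depth range, small enough to keep the full
test suite around a minute on one CPU while leaving ≥ 5 voxels across the
smallest vessel radius. Layers: vitreous 0.04, retina/RPE complex 0.85,
choroidal stroma 0.55, sclera 0.75 (arbitrary reflectivity units);
BM at 0.30 mm, CSI at 0.80 mm (0.5 mm choroid). Six parallel oblique
cylinders (radii 0.05–0.20 mm, lumen 0.25) span the fast axis while
sweeping ±0.3 mm across the slow axis, their slow-axis footprints tiling
the field the way a vascularised choroid leaves no B-scan vessel-free;
total analytic volume 2.074 mm³ (~26% vascularity). Degradations, applied
in order: per-voxel Gamma(L=4, 1/L) multiplicative speckle; two shadow
stripes (width 0.12 mm, transmission 0.35) multiplying all sub-BM voxels;
attenuation exp(−0.5/mm × depth from the retinal surface). A voxel is
truth-vessel iff its centre lies within the radius of a centerline, with
flat end caps, clipped to the slab.

What the phantom does **not** emulate: real speckle's spatial correlation
(modelled i.i.d. here), motion and blink artifacts, RPE detachments and
other pathology-induced surface errors, depth-dependent beam profile, and
sub-voxel partial-volume mixing at vessel walls. Passing tests demonstrate
the pipeline's internal consistency and its behaviour under the modelled
degradations, not clinical-grade accuracy on patient scans.

## Numerical choices and degenerate inputs

- Strict `I < T` everywhere; constant slabs make the global threshold
  undefined (an error), constant images pass through CLAHE unchanged.
- `ε = 1e-8` floors guard empty A-lines in shadow reduction and
  attenuation compensation; all-zero A-lines map to zero.
- Physical window/tile sizes convert to odd voxel counts (minimum 1) per
  axis; windows larger than the image plane are an error.
- Flattening picks `max(bm)` as the default reference depth and verifies
  the shifted slab stays inside the depth axis.
- Phantom rendering, cohort simulation and the pipeline are deterministic
  given their seeds; enhancement and segmentation contain no randomness.

## Known limitations

- Slab tilt is not corrected; volumes are counted along the depth axis.
- Sattler/Haller sublayers are not separated.
- The vessel segmentation is pixel-based; no centerline or graph topology
  is extracted.
- The shadow-reduction stage is a no-op whenever attenuation compensation
  is enabled (see the invariance argument above); demonstrating its
  benefit requires a pipeline configuration without compensation, and even
  there the phantom shows only a localized false-positive reduction, not a
  global Dice improvement.
- DICOM and vendor container formats are out of scope; NIfTI, TIFF and
  CSV cover the supported interchange.
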