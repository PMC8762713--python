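# chorovol

Quantification of the choroidal vasculature from volumetric swept-source
OCT: image enhancement, composite 3-D vessel segmentation, en-face
vessel-volume mapping with ETDRS regional aggregation, and ROC-based
diagnostic statistics.

The choroid — the vascular layer between Bruch's membrane (BM) and the
choroidal–scleral interface (CSI) — thickens and remodels in diseases such
as central serous chorioretinopathy (CSC) and Vogt–Koyanagi–Harada disease
/ sympathetic ophthalmia (VKH/SO). `chorovol` turns a single routine OCT
volume scan plus its layer surfaces into three per-region biomarkers:

- **choroidal volume** `Vc` — slab voxel count × voxel volume (mm³),
- **vessel volume** `Vv` — segmented vessel voxel count × voxel volume (mm³),
- **vessel index** `VI = 100 · Vv / Vc` (%), the fraction of the choroid
  occupied by vessels.

Because clinical per-eye data are not distributable, the package ships a
first-class synthetic phantom generator (layered tissue, oblique
hyporeflective cylindrical vessels, multiplicative speckle, retinal-vessel
shadows, depth attenuation) with exact per-voxel ground truth, used by the
test suite to validate the whole pipeline end to end.

## Pipeline

1. **Enhance** (`chorovol.enhance`) — fixed stage order:
   speckle denoising (homomorphic non-local means by default) →
   shadow reduction (each A-line rescaled by a median-filtered energy
   profile, `I' = I · Ê/E`, which preserves axial contrast exactly) →
   attenuation compensation (`I_c(z) = I(z)ⁿ / (2·Σ_{z'≥z} I(z')ⁿ)`,
   restoring deep-choroid contrast) → contrast-limited adaptive histogram
   equalisation per B-scan.
2. **Slab** (`chorovol.slab`) — flatten the volume to BM by integer
   per-A-line shifts, extract the `[bm, csi)` slab, produce C-scan views.
3. **Segment** (`chorovol.segment`) — composite of three views, each
   flagging hyporeflective voxels: Niblack local thresholding
   `T = m + k·s` in the B-scan view and per C-scan slice (slab-masked
   window statistics), plus global Otsu on the in-slab histogram; fused by
   majority vote with small-component removal. Stroma = slab complement.
4. **Quantify** (`chorovol.quantify`) — en-face `Vv`/`Vc` maps by pixel
   counting, ETDRS grid aggregation (1/3/6 mm rings, quadrants), map
   rendering.
5. **Statistics** (`chorovol.stats_roc`) — empirical ROC/Mann–Whitney AUC,
   Youden cutoffs, binormal closed forms `AUC = Φ((μ₁−μ₀)/√(σ₀²+σ₁²))`,
   and a cohort simulator parameterized by published group summaries
   (mean ± SE, n).

## Worked example

```sh
python examples/02_enhance_and_segment.py
```

```
Dice vs truth:            0.905
segmented vessel volume:  2.346 mm^3
analytic vessel volume:   2.074 mm^3
stroma voxels:            859383 (vessel + stroma = slab, exactly)
Dice without enhancement: 0.460 (the preprocessing stages are what make the segmentation work)
```

The standard phantom contains six vessels totalling 2.074 mm³ (Σ πr²L).
After enhancement the composite segmentation overlaps the truth at Dice
0.905 and recovers the total volume within ~13%; segmenting the raw,
speckled volume instead collapses to Dice 0.46.

```sh
python examples/04_roc_diagnostics.py
```

```
CSC vs healthy, vessel_volume   : AUC closed-form 0.820, simulated 0.820 (MC se 0.0005)
CSC vs healthy, choroidal_volume: AUC closed-form 0.823, simulated 0.824 (MC se 0.0005)
VKH vs healthy, vessel_volume   : AUC closed-form 0.685, simulated 0.685 (MC se 0.0006)
VKH vs healthy, choroidal_volume: AUC closed-form 0.721, simulated 0.721 (MC se 0.0005)

cutoff 4.14 mm^3 vessel volume for CSC: sensitivity 65.6%, specificity 84.3%
```

An AUC of 0.82 means a randomly chosen CSC eye shows a larger central-6-mm
vessel volume than a randomly chosen healthy eye about 82% of the time
under the binormal completion of the published summaries.

`examples/01_phantom_and_truth.py` and `examples/03_enface_maps_and_etdrs.py`
cover phantom generation and the en-face/ETDRS quantification.

## Command line

A thin CLI mirrors the library:

```sh
chorovol phantom --seed 0 --out scratch/phantom/
chorovol enhance in.nii.gz out.nii.gz --extent 9 12
chorovol segment out.nii.gz --surfaces surfaces.csv --out mask.nii.gz --extent 9 12
chorovol quantify mask.nii.gz --surfaces surfaces.csv --out metrics.csv --maps maps/
chorovol roc --disease csc --metric vessel_volume --cutoff 4.14 --reps 10000 --seed 7
chorovol run --config run.json
```

Volumes are NIfTI or multi-page TIFF indexed `(B-scan, A-line, depth)`;
surfaces are CSV grids of BM/CSI depth indices; metrics are CSV tables.

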