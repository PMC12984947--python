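# fivol — volumetric quantification of muscle fatty infiltration

Fatty infiltration (FI) of the rotator-cuff muscles is a key prognostic
factor after tendon repair. The conventional Goutallier–Fuchs grade is a
subjective 0–4 visual score on a single slice; `fivol` implements the
objective alternative: a 3D, MRI-based volumetric measurement of the fat
and muscle compartments of the supraspinatus, together with the
histologic machinery used to validate it and the synthetic phantoms used
to test it.

The measurement chain:

1. **Calibration.** Operator-labelled signal-intensity probes (muscle
   vs fat) are analysed by ROC: candidate cutoffs are midpoints between
   consecutive distinct sample values and the cutoff maximising Youden's
   *J* = sensitivity + specificity − 1 is selected (fat is the positive
   class). On probes whose muscle values span 1002–3448 and fat values
   span 3600–9652 (7.0T units), the classes separate perfectly and the
   cutoff falls in the (3448, 3600) gap.
2. **Segmentation.** Every voxel inside the manually delineated
   anatomical ROI is threshold-painted: muscle for intensities in
   [1000, 3500], fat for ≥ 3600, unclassified otherwise (the (3500, 3600)
   "gray zone" absorbs partial-volume interface voxels).
3. **Volumetrics.** Label statistics: compartment volume = voxel count ×
   voxel volume, and the fat-to-muscle proportion

   FTMP (%) = 100 · V_fat / V_muscle.

   "Total volume" is muscle + fat; the full ROI volume is reported
   separately so gray-zone loss stays visible.
4. **Histology.** On Oil Red O / H&E sections, lipid area is thresholded
   in HSB color space (red hue windows with saturation/brightness
   floors) and muscle fiber area from the green channel (eosin absorbs
   green; Otsu or fixed threshold).
5. **Statistics.** Spearman correlation between the radiologic and
   histologic measurements, ICC(2,1) for intra-observer reliability, and
   one-way ANOVA with Bonferroni post hoc contrasts across the study
   arms (repair / chronic tear / control).

Because no animal data are deposited, the package ships a first-class
phantom generator: 3D volumes with known composition drawn from the
observed per-tissue intensity ranges (with optional partial-volume
mixing and noise), group cohorts parameterised by the published group
tables, and synthetic stained sections with exactly known droplet
coverage.

## Worked example

```python
import dataclasses
from fivol import PhantomSpec, generate_phantom, segment_tissues, compute_volumes

spec = PhantomSpec(target_ftmp=2.5, seed=7, shape=(48, 48, 12), fat_pattern="clustered")
for s in (spec, dataclasses.replace(spec, partial_volume_width=1)):
    volume, roi, truth = generate_phantom(s)
    result = compute_volumes(segment_tissues(volume, roi))
    print(truth.true_ftmp, result.ftmp, result.unclassified_volume)
```

prints (see `examples/segment_phantom.py` for the annotated version):

```
sharp boundaries:       true FTMP 2.505 %   measured 2.505 %   gray zone 0.0 mm^3
partial-volume mixing:  true FTMP 2.505 %   measured 0.217 %   gray zone 5.4 mm^3
```

With sharp tissue boundaries the pipeline recovers the generated FTMP
exactly. With partial-volume mixing enabled, interface voxels carry
averaged signal that falls below the fat floor, so fat is lost to the
gray zone and the measured FTMP drops — the mechanism by which
threshold-based MRI quantification underestimates absolute fat content
relative to histology.

A complete synthetic study (18 specimens, three groups, histology and
agreement statistics) runs with `python examples/run_demo_study.py` or
`fivol demo --out DIR --seed 0`; on seed 0 it prints group FTMP means of
1.47 / 2.89 / 0.53 % (generating parameters 1.8 / 2.8 / 0.5 %), a
significant chronic-tear vs control contrast (adjusted p ≈ 1e-4), and
Spearman ρ = 0.990 between the radiologic and histologic arms.

## Command line

`fivol` exposes the chain as subcommands over NIfTI/PNG/CSV/JSON files:

```
fivol calibrate --samples samples.csv --out calibration.json
fivol segment   --volume V.nii.gz --roi M.nii.gz [--policy policy.json] --out L.nii.gz
fivol volumes   --labels L.nii.gz --out result.json
fivol histology --images DIR [--config c.json] --out hist.csv
fivol phantom   --spec spec.json --out DIR
fivol cohort    --preset chronic_tear --n 6 --seed 1 --out DIR
fivol validate  --config study.json
fivol demo      --out DIR --seed 0
```

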