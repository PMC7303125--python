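# bmatquant

Quantification of **bone marrow adipose tissue (BMAT)** from co-registered
CT/PET volumes.

Bone marrow adipocytes make up a large fraction of the adult marrow cavity,
and whether that fat behaves like brown/beige fat or is a metabolically
distinct depot is answered by measuring how much of it there is (on CT) and
how much glucose it takes up (on PET). `bmatquant` implements that analysis
chain for imaging scientists and physiologists:

1. **HU thresholding** — marrow voxels are classified by CT attenuation.
   Fat attenuates less than water, so fat-rich (yellow) marrow sits low on
   the Hounsfield scale. The diagnostic scheme partitions a marrow VOI as

   | class | HU interval |
   |---|---|
   | BMAT (yellow marrow) | −200 ≤ HU < 115 |
   | red marrow (RM) | 115 ≤ HU ≤ 300 |
   | bone | HU > 300 |
   | out of range (air/artefact) | HU < −200 |

   The fat/red-marrow cutpoint can also be *derived* from data: a per-voxel
   ROC between a fat-rich region (e.g. sternum) and a fat-deficient region
   (e.g. vertebrae), maximizing Youden's J = sensitivity + specificity − 1.
   For two equal-variance Gaussian HU populations the optimum is the
   midpoint of the class means.

2. **Adiposity volumetrics** — Ad.V/Ma.V, adipose volume as a percentage of
   total marrow cavity volume, plus absolute compartment volumes in mL.

3. **SUV quantification** — body-weight-normalized standardized uptake
   values, SUV = C / (D / BW) with C the activity concentration (kBq/mL),
   D the injected dose and BW the body mass; per marrow class within a VOI.

4. **Phantom calibration** (small-animal CT) — ordinary least squares of
   rod-mean HU on known rod mass density (tissue-equivalent-material
   phantom, 1.08–1.57 g/mL), inverted to map tissue HU to density and to
   derive a bone/marrow HU split at an explicit density cutoff.

5. **Gamma-count normalization** — ex vivo tissue counts converted to MBq,
   decay-corrected to injection time (¹⁸F half-life 109.77 min) and
   expressed as % injected dose per gram (%ID/g).

6. **Histomorphometry** — adipocyte density (N.Ad/Ma.Ar, mm⁻²), area
   fraction (Ad.Ar/Ma.Ar, %) and multilocular frequency (≥ 3 small lipid
   droplets) from 2-D annotations.

7. **Capacity model** — total-body tissue volumes from anthropometrics
   (marrow = 5% of body mass, split 70% BMAT / 30% RM by mass, divided by
   densities 0.92 and 1.06 g/mL; bone mass from height over 1.245 g/mL;
   muscle as an age/sex-specific % of body mass over 1.055 g/mL), each
   multiplied by its mean SUV to give a glucose-uptake-capacity index and
   its percentage of the skeletal-muscle index.

Because no clinical imaging data ship with the package, a synthetic-data
module generates every input: paired CT/PET phantoms with exact ground
truth, labeled voxel-class samples, rod phantoms, cohorts and adipocyte
annotations.

## Worked example

```python
import bmatquant as bq
from bmatquant import synthetic as syn

# a marrow VOI of 100,000 voxels generated at 70% adiposity
config = syn.PhantomConfig(
    grid_shape=(50, 50, 48),
    bm_regions=(syn.BMRegionSpec("bm", 100_000, 0.70),),
    seed=1,
)
ct, pet, masks, truth = syn.generate_human_phantom(config)

seg = bq.segment_bm(ct, masks, region="bm")
adip = bq.adiposity_fraction(seg)
print(round(adip.ad_v_over_ma_v_pct, 2))        # 69.71
suvs = bq.compartment_suv(pet, seg, bq.SUVParams(185.0, 59_700.0))
print({k.name: round(v, 3) for k, v in suvs.items()})
# {'BMAT': 0.646, 'RM': 0.899, 'BONE': 0.89}
```

The recovered Ad.V/Ma.V is 69.71% — slightly below the generating 70%
because the fat HU distribution loses its tail above 115 HU and gains the
red-marrow tail below it; it rounds to the generated 70%. The SUVs are the
per-class means of PET uptake normalized by dose per body mass (185 MBq,
59.7 kg).

Deriving the fat/red-marrow cutpoint from voxel populations:

```python
s = syn.sample_voxel_classes(100_000, 100_000, (42, 30), (188, 30), seed=1)
roc = bq.compute_roc(s.pos, s.neg)
print(bq.optimal_threshold(roc), round(roc.auc, 4))   # 115 0.9997
```

And the capacity model, at the body mass whose marrow-fat volume is 2.27 L:

```python
v_bmat, v_rm = bq.bm_volumes(59.67)
print(round(v_bmat, 2), round(v_rm, 2))   # 2.27 0.84
```

## Command line

```sh
bmatquant simulate --seed 1 --out run/          # phantom → full analysis
bmatquant calibrate --config cal.yaml           # rod-phantom fit only
bmatquant analyze-human --config human.yaml     # NIfTI CT/PET/masks from disk
bmatquant analyze-mouse --config mouse.yaml     # calibration-split + %ID/g
```

Each run writes CSV tables, a `manifest.json` recording every resolved
threshold, density, seed and a config hash, and a run log.

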