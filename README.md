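# calvaria

Skull and soft-head-tissue measures from T1-weighted head MRI.

Given a T1 volume and a six-class tissue segmentation (SPM c1–c6 order:
GM, WM, CSF, skull, soft head tissue, background), `calvaria`:

1. **repairs the skull class** — bright diploë marrow that intensity-driven
   segmentation misassigns to the soft-head class is reclaimed by
   morphological operations (closing, enclosure analysis, island pruning),
2. **computes thickness maps** — voxelwise bone thickness (CSF↔soft tissue)
   and soft-head-tissue thickness (skull↔background) from dual Euclidean
   distance transforms, with a 30 mm skull-distance exclusion and a
   lower-head exclusion,
3. **extracts the mid-skull surface** — marching cubes on the 0.5 level of a
   percentage position map, with per-vertex normal profiles separating
   cortical-plate intensity (profile minimum) from marrow intensity
   (triangular distance-weighted average),
4. **aggregates regionally** — over a procedural calvarial sector atlas
   (frontal, parietal L/R, occipital, temporal L/R, sphenoid) with a
   defacing-safe bone mask; an external atlas volume can be swapped in,
5. **reports four headline measures** (occipital sector by default):
   - `proxy_bmd` — negated WM-normalized skull intensity (bright marrow ⇒
     low density ⇒ low proxy),
   - `bone_thickness_mm`,
   - `iap` — intensity-based adiposity proxy (Gaussian-mixture peak
     composite of the soft-head class, WM-normalized),
   - `tap_mm` — thickness-based adiposity proxy (mean soft-tissue thickness).

A **synthetic head phantom** generator (layered ellipsoidal shells with
known ground truth, muscle/fat scalp mixture, Gaussian/Rician noise, bias
field, open inferior quarter) makes every stage testable without any
cohort data, and a statistics module provides ICC(A,1) retest reliability
and Spearman/Holm correlation panels.

## CLI

```sh
# full pipeline on one subject
calvaria run --t1 t1.nii.gz --seg c1.nii.gz c2.nii.gz c3.nii.gz c4.nii.gz \
    c5.nii.gz c6.nii.gz --out measures.json \
    [--kind probability|label] [--atlas atlas.nii.gz] [--gmm-k 4] [--seed 0] \
    [--close-radius-mm 3] [--no-intensity-guard] [--save-maps DIR] \
    [--save-surface surf.ply]

# synthetic phantom (t1.nii.gz, c1..c6.nii.gz, truth.json)
calvaria phantom --out phantom_dir --preset default --seed 1
# presets: default, thin-skull, obese, osteoporotic

# simulated retest reliability (ICC table)
calvaria reliability --n 20 --seed 7 --out icc.csv

# Spearman/Holm correlation panel
calvaria correlate --measures measures.csv --pairs pairs.json --out panel.csv
```

## API sketch

```python
from calvaria import (PhantomSpec, generate_phantom, compute_all,
                      MeasureConfig)

t1, seg, truth = generate_phantom(PhantomSpec(noise_sd=15, open_inferior=True))
measures = compute_all(t1, seg, config=MeasureConfig(seed=0))
print(measures.scalar_dict())     # proxy_bmd, bone_thickness_mm, iap, tap_mm
print(measures.region_table)      # per-sector means and counts
```

Conventions: world coordinates in mm (RAS), thicknesses in mm, 0-based
voxel indices. Intensity measures are WM-normalized and therefore
invariant to global intensity scaling; `proxy_bmd` is a relative measure,
not calibrated to DXA units.
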