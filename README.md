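# rnfl-quant

Quantification of peripapillary retinal nerve fiber layer (RNFL) thickness
from circumpapillary OCT B-scans, built around a U-Net segmentation of the
RNFL band.

The RNFL — the layer of ganglion-cell axons converging on the optic nerve
head — thins in optic neuropathies such as non-arteritic anterior ischemic
optic neuropathy (NAION) and optic neuritis (ON). Clinically it is measured
on a circle scan around the optic disc, unrolled into a B-scan whose columns
sweep the circle in TSNIT order (temporal → superior → nasal → inferior →
temporal). Built-in device segmentation frequently fails on atrophic or
artifact-laden scans (epiretinal membranes, posterior vitreous detachment),
which motivates a learned segmentation. This package implements the whole
measurement chain and, because clinical scans of this kind are generally not
redistributable, ships a seeded synthetic phantom generator so that every
stage is testable end to end without any data download.

## Pipeline

1. **Phantom generation** (`rnfl_quant.synthetic`) — circle-scan B-scans
   with a layered retina, a TSNIT double-hump RNFL band calibrated to
   cohort means (control ≈ 100.3 µm, NAION ≈ 69.7 µm, ON ≈ 76.1 µm),
   multiplicative gamma speckle, optional ERM/PVD artifacts, and exact
   ground-truth masks and thickness profiles.
2. **Preprocessing** (`rnfl_quant.preprocess`) — speckle reduction by
   grayscale morphological opening + closing with a 3×3 square kernel, and
   resize/zero-pad to the 256×256 network grid with an invertible
   `ScaleInfo` record.
3. **Segmentation** (`rnfl_quant.unet`) — a U-Net (encoder filter ladder
   16, 32, 64, 128, 256; two 3×3 convolutions + ReLU per level; 2×2
   max-pooling; symmetric decoder with up-convolutions and skip
   concatenations; 1×1 output convolution) trained with binary
   cross-entropy and Adam on an 80/20 scan-level split. The network is
   implemented directly in NumPy (channels-last shifted matrix
   multiplications with hand-derived backpropagation), so training is fully
   deterministic given a seed and requires no GPU.
4. **Post-processing & thickness** (`rnfl_quant.thickness`) — hole filling
   and small-component removal, then per-A-scan thickness
   `t(θ) = n_pixels(θ) · axial_spacing` (column method; a Euclidean
   distance-transform estimator, `2·max EDT per column · spacing`, serves
   as a cross-check), then the seven clinical read-outs: circle average
   plus six TSNIT sectors (temporal 90°, nasal 90°, four 45° oblique
   sectors), with OD/OS laterality mirroring.
5. **Evaluation** (`rnfl_quant.metrics`) — Dice `2TP/(2TP+FP+FN)`,
   sensitivity, specificity against reference masks; MAE and Pearson r for
   thickness.

## Worked example

```python
from rnfl_quant import (PhantomSpec, tsnit_profile, render_bscan,
                        thickness_profile, sector_thickness)

spec = PhantomSpec.for_group("NAION")          # calibrated to ≈69.7 µm
profile = tsnit_profile(spec, seed=7)          # ground-truth TSNIT curve
image, truth = render_bscan(spec, profile, seed=8)
measured = thickness_profile(truth.mask)        # column method
sectors = sector_thickness(measured, eye=spec.eye)
print(f"average {sectors.average_um:.1f} µm, "
      f"temporal inferior {sectors.temporal_inferior_um:.1f} µm")
```

prints

```
average 69.6 µm, temporal inferior 91.7 µm
```

i.e. this phantom eye has a circle-average RNFL of ~70 µm (thinned, as
expected for the NAION preset) with the inferior-temporal bundle still the
thickest sector. The full pipeline (generate → train → predict → thickness
→ evaluate) runs from a YAML config:

```bash
rnfl-quant generate --n 50 --group control --seed 1 --out data/
rnfl-quant run --config pipeline.yaml
rnfl-quant thickness --mask data/control_0000_mask.png --axial-um 3.87 --eye OD --out report.csv
```

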