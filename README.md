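# miiquant

Rapid quantification of fungal mycelial biomass from bright-field
micrographs.

Filamentous fungi such as *Cordyceps militaris* grow in submerged
fermentation as a mixture of spores, dispersed branching hyphae and dense
pellets. The standard biomass measure — dry cell weight (DCW), obtained by
centrifuging, washing, filtering and drying the broth — takes days, which
makes it useless for monitoring a running fermentation. `miiquant`
implements an optical proxy: each micrograph is reduced to a single
**microscopic image intensity** (MII) statistic by a segmentation /
transformation chain, and MII is calibrated against DCW by simple linear
regression,

```
DCW = β₀ + β₁·MII + ε,   ε ~ N(0, σ²)
```

so that once the calibration line is fitted, a fresh micrograph yields a
DCW estimate in seconds. The package is aimed at fermentation and
bioprocess groups working with filamentous organisms whose non-uniform
morphology defeats turbidity and cell-count methods.

## What it does

- **Image transformation** (`miiquant.transform`): grayscale conversion,
  primary global threshold (level 154, dark mycelium on bright medium),
  rolling-ball background subtraction (signal becomes bright-on-dark),
  quantile contrast stretch, secondary threshold (level 180) gated by the
  dilated primary mask, median filtering, speck removal, and measurement
  of the mean gray value of the background-zeroed frame — the MII. Every
  parameter lives in `PipelineConfig`; every stage is logged to the
  result's provenance.
- **Calibration** (`miiquant.calibration`): statsmodels-style
  `MIICalibration` model whose `fit()` returns a `CalibrationResults`
  with coefficients, standard errors, the standardized coefficient, t and
  F statistics with p-values, R², residuals, 95% CIs, `predict()`, and a
  `summary()` verification table. Includes the symmetric
  degree-of-accuracy statistic `100·min(pred, actual)/max(pred, actual)`
  and per-dilution-group R² analysis.
- **Synthetic micrographs** (`miiquant.synthetic`): seeded generators for
  scenes of branching hyphae, spores and pellets on an unevenly
  illuminated background with ground truth, growth series, calibration
  tables, and dilution experiments — so the whole pipeline is testable
  without proprietary image data.
- **CLI** (`miiquant`): subcommands `transform`, `calibrate`, `predict`,
  `dilution`, `simulate`, `simulate-calibration`, each writing a JSON run
  manifest for provenance.

## Worked example

```python
from miiquant import (SceneSpec, generate_scene, transform_image,
                      generate_calibration, fit_simple_regression,
                      predict_dcw, accuracy_pct)

# one synthetic micrograph through the transformation chain
scene = generate_scene(SceneSpec(n_hyphae=18, seed=7))
result = transform_image(scene.image)
print(f"MII = {result.mii:.2f}  (mask area: {result.mask_area_px} px, "
      f"true object area: {scene.true_biomass_px} px)")

# calibrate on 60 synthetic samples, validate on 3 held out
table = generate_calibration(n=63, seed=7)
train, held_out = table.samples[:60], table.samples[60:]
fit = fit_simple_regression(train)
print(fit.summary())
for s in held_out:
    pred = predict_dcw(fit, s.mii)
    print(f"{s.sample_id}: MII {s.mii:6.2f} -> predicted DCW {pred:6.1f} mg/L, "
          f"measured {s.dcw:6.1f} mg/L, accuracy {accuracy_pct(pred, s.dcw):.1f}%")
```

prints

```
MII = 18.36  (mask area: 5673 px, true object area: 5686 px)
Calibration model verification (simple linear regression)
==========================================================================
Variable             B        SE    Beta         t           F     R^2
--------------------------------------------------------------------------
(Constant)      55.405     7.670          7.224***  1459.826***  0.962
MII              6.269     0.164   0.981 38.208***
--------------------------------------------------------------------------
n = 60, residual df = 58, Y = 55.405 + 6.269X
*p < 0.05, **p < 0.01, ***p < 0.001
sim060: MII  50.25 -> predicted DCW  370.4 mg/L, measured  368.1 mg/L, accuracy 99.4%
sim061: MII  51.90 -> predicted DCW  380.8 mg/L, measured  336.6 mg/L, accuracy 88.4%
sim062: MII  53.82 -> predicted DCW  392.8 mg/L, measured  367.2 mg/L, accuracy 93.5%
```

The transformation recovers the true object area almost exactly (5673 vs
5686 px); the calibration fit explains 96% of the DCW variance in this
synthetic regime, and held-out predictions agree with the simulated
measurements to within 1–12%.

The same flow from a shell:

```
miiquant simulate-calibration --n 30 --seed 1 --out cal.csv
miiquant calibrate --samples cal.csv --out model.json --report table.txt
miiquant predict --model model.json --mii 38.645
```

## Limitations

The MII statistic is resolution- and magnification-dependent; no
physical-unit conversion is attempted, so a calibration line is only
valid for the optical setup it was fitted on. See `docs/methods.md` for
the model, the design choices behind each pipeline stage, and what the
synthetic tests do and do not demonstrate about real micrographs.
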