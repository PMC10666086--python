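# ir2dscreen

Screening for protein-bound drugs in blood serum with two-dimensional
infrared (2D-IR) spectroscopy, as a fully synthetic, testable pipeline.

2D-IR correlates an excitation (pump) and a detection (probe) vibrational
frequency across the protein amide I band (~1600–1700 cm⁻¹).  A serum
spectrum in this window is dominated by human serum albumin (HSA, a
negative v=0–1 bleach on the diagonal near 1660 cm⁻¹ paired with a
positive, anharmonically red-shifted v=1–2 band) and a weaker globulin
feature near 1640 cm⁻¹.  Drugs bound to HSA perturb this response subtly;
multivariate classification of the perturbations can detect and identify
the bound drug, and the concentration dependence of the spectral change
reports on the protein–drug binding equilibrium.

The package is aimed at chemometricians and spectroscopists who want a
reproducible, dependency-light reference implementation of this analysis
chain.  Since no public 2D-IR serum data set exists, the package ships a
physics-motivated generator that emulates the screening and verification
study designs end to end, so every stage is testable without downloads.

## What it implements

- **`synth`** — synthetic pump×probe amide I maps: rotated-Gaussian
  fundamental/overtone doublets, drug-specific perturbation patterns, a
  two-regime bound-fraction model f(c) = f_high + (f_low − f_high)/(1 +
  (c/c₅₀)^h), a pump-independent thermal-water reference at the 5 ps
  waiting time, path-length variation and additive noise; the 24-sample
  screening design (12 serum + 3 replicates × 4 drugs) and the 14-level
  cefazolin dilution series in triplicate.
- **`preprocess`** — thermal-reference baseline correction and
  normalisation (path-length invariant), Savitzky–Golay smoothing along
  the probe axis, PCA noise reduction, flattening to a samples × pixels
  matrix.
- **`pls`** — NIPALS partial least squares written from scratch, with
  PLS-DA (one-hot classes, argmax decision) and PLS-R front ends,
  optional mean-centering (off by default), leave-one-out
  cross-validation and RMSE-vs-LV curves.
- **`attribution`** — difference spectra, per-class latent-variable score
  summaries, LV→drug assignment by score separation, loading maps.
- **`binding`** — amplitude-ratio quantification at the (1656, 1649) /
  (1635, 1632) cm⁻¹ coordinates, U-shape detection on the dilution
  ladder, PLS regression on concentration, molar↔mass unit conversion.
- **`io` / `cli`** — a plain-text grid format for maps, CSV manifests,
  YAML configs with strict validation, and an `ir2d` command-line
  pipeline (`simulate`, `preprocess`, `crossval`, `attribute`,
  `quantify`, `report`).

## Worked example

```python
import ir2dscreen as ir

cfg = ir.RunConfig()
ds = ir.generate_screening_set(cfg, seed=1)          # 24 samples, 2 maps each
proc = ir.preprocess_dataset(ds)                     # X: 24 x 5751 pixels

binary = ["Serum" if l == "Serum" else "Drug-bound" for l in proc.labels]
cv2 = ir.loo_crossval(proc.X, binary, n_lv=7)        # uncentered PLS-DA
cv5 = ir.loo_crossval(proc.X, proc.labels, n_lv=9)
print("binary LOO-CV accuracy:", round(cv2.overall_accuracy, 3))
print("five-class LOO-CV accuracy:", round(cv5.overall_accuracy, 3))

model = ir.attribution_model(proc.X, proc.labels, n_lv=9)
assign = ir.lv_assignment(ir.lv_class_scores(model, proc.labels),
                          exclude=["Serum"])
print("LV assignment:", {c: l + 1 for c, l in assign.items()})

ver = ir.generate_verification_set(cfg, seed=1)      # 14 conc levels x 3
maps = ir.pca_denoise([ir.smooth_sg(ir.correct_and_normalize(a, b), 7, 3)
                       for a, b in zip(ver.maps_250fs, ver.maps_5ps)], 0.99)
curve = ir.binding_curve(maps, [r.drug_conc for r in ver.records])
print("U-shaped:", curve.u_shaped, "minimum at",
      round(curve.extremum[0], 3), "mM")
```

prints

```
binary LOO-CV accuracy: 0.958
five-class LOO-CV accuracy: 1.0
LV assignment: {'Serum+Cefazolin': 1, 'Serum+Ibuprofen': 2, 'Serum+Paracetamol': 3, 'Serum+Warfarin': 4}
U-shaped: True minimum at 0.129 mM
```

At seed 1 the binary classifier misses one of the 24 held-out samples and
the five-class model identifies every drug; each drug class is assigned
its own latent variable, whose loading is its estimated spectral
signature.  The dilution series shows the characteristic
decline-then-rise (U-shaped) amplitude-ratio profile of dose-dependent
binding, with the minimum at 0.129 mM — just below the configured
0.2 mM crossover of the two-regime bound-fraction curve.

The same analysis from a shell:

```sh
ir2d simulate screening --seed 1 --out-dir run
ir2d preprocess --out-dir run
ir2d crossval --classes five --out-dir run
ir2d attribute --out-dir run
ir2d report --out-dir run
```

## Documentation

`docs/methods.md` describes the spectral and binding models, every
tunable parameter with its default and rationale, the preprocessing and
model choices, and the known limitations of the synthetic benchmark.
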