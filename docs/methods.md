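# Methods

## The spectral model

A 2D-IR measurement in the amide I window is represented as a signed
amplitude grid over pump × probe wavenumbers.  The default grid covers
1580–1720 cm⁻¹ (pump) × 1560–1720 cm⁻¹ (probe) in 2 cm⁻¹ steps (71 × 81 =
5751 pixels) — fine enough to resolve the 16 cm⁻¹ anharmonic shift while
keeping full leave-one-out cross-validation essentially instantaneous.

Every band is a **doublet**: a negative fundamental (v=0–1 bleach) centred
on the diagonal, plus a positive overtone (v=1–2 induced absorption) at a
probe frequency lowered by the anharmonic shift, with amplitude reduced by
the overtone ratio.  Lineshapes are 2D Gaussians rotated 45°, elongated
along the diagonal (σ_diag > σ_anti), mimicking the inhomogeneous
broadening seen at short waiting times before spectral diffusion
decorrelates pump and probe frequencies.  A pseudo-Voigt profile would add
parameters without changing anything the downstream statistics are
sensitive to.

Neat serum is the sum of two doublets:

| band | centre (cm⁻¹) | amplitude | σ_diag | σ_anti | shift | overtone ratio |
|---|---|---|---|---|---|---|
| HSA (α-helix) | 1660 | 1.0 (unit) | 18 | 8 | 16 | 0.85 |
| globulins (β-sheet) | 1640 | 0.3 | 18 | 8 | 16 | 0.85 |

The anharmonic shift is fixed at the canonical amide I value of 16 cm⁻¹
and the overtone ratio at 0.85; both are config-exposed.

At the 5 ps waiting time the response is dominated by a **thermal water
signal**, modelled as a pump-independent Gaussian probe profile (centre
1640 cm⁻¹, σ = 70 cm⁻¹) whose peak amplitude equals the configured scale
(1.0 by default, i.e. comparable to the HSA fundamental).  A residual 5%
of this thermal profile leaks into the 0.25 ps map, giving the baseline
correction stage real work to do.

## Drug signatures

Each drug perturbs the serum response with a low-amplitude pattern whose
components are (centre_pump, centre_probe, signed fraction, σ_diag,
σ_anti) tuples, the fraction expressed relative to the HSA fundamental.
The default pattern amplitude is 0.06 — the drug signatures are subtle
against the protein response, an order of magnitude above the noise per
pixel but far below the serum bands:

- **cefazolin**: negative at (1635, 1632), positive at (1656, 1649),
  σ = (12, 7) — the two coordinates later used for amplitude-ratio
  quantification;
- **warfarin**: the same two-component motif displaced +6 cm⁻¹ in pump
  (σ = 9, 5) — similar site-I chemistry at slightly different
  frequencies;
- **ibuprofen**: a single positive feature below the diagonal at
  (1660, 1644), σ = (20, 10);
- **paracetamol**: a diagonally elongated deepening of the HSA band at
  (1660, 1660) with σ_diag = 54 (3× the HSA width), σ_anti = 6.

Widths were chosen to give the four signatures distinct total energies
(norm hierarchy paracetamol < warfarin < ibuprofen < cefazolin+secondary
in the screening conditions) and limited mutual overlap, which is what
lets the latent-variable analysis attribute one LV per drug; the centre
coordinates themselves are anchored to the measurement points and band
positions above and are not free.

## Binding model and injected signal

The primary-site bound fraction follows a two-level logistic in
log-concentration (Hill form):

    f(c) = f_high + (f_low − f_high) / (1 + (c / c_crossover)^h)

with defaults f_low = 0.8, f_high = 0.3, c_crossover = 0.2 mM, h = 3 —
flat at trace doses, declining through the crossover into a dose-dependent
regime.  The injected primary signal scale is

    s₁(c) = min(c / c_sat, 1) · f(c)

the product of a site-occupancy ramp (the protein site fills from zero
drug and saturates at c_sat, 0.1 mM for cefazolin) and the bound
fraction.  For a two-regime f this product is non-monotone: it peaks just
below the crossover and falls as f declines — the mechanism behind the
U-shaped amplitude-ratio profile of the dilution series.  A **secondary
binding mode**, populated only at mM doses (logistic occupancy with
midpoint 0.5 mM, steepness 2, weight 2.0 relative to the pattern
amplitude), adds a doublet-shaped change at pump frequencies below the
protein bands (1628 cm⁻¹).  It embodies the weak second mechanism that
dominates the cefazolin response at high dose, keeps the 1.2 mM screening
samples detectable even though their primary-site fraction has declined
to 0.3, and pushes the amplitude ratio back up on the high-concentration
arm.

Per-drug defaults reflect the known affinity hierarchy: ibuprofen and
warfarin (sub-µM/µM Kd) are effectively fully bound at their clinical
spikes (f_low = 1.0); paracetamol, the weakest binder, gets f_low = 0.65;
their crossovers sit at 10 mM, far above the screening doses, because no
dose-dependent decline is documented for them in the clinical range —
the two-regime behaviour is specific to cefazolin.  Only single-number
summaries of these equilibria are modelled; no site-level thermodynamics.

Each sample yields two maps:

    map(0.25 ps) = pf · [serum + injected(c) + 0.05 · thermal] + noise
    map(5 ps)    = pf · thermal + noise

with pf a lognormal path-length factor (σ_log = 0.1) and iid Gaussian
noise of σ = 0.01 (relative to the HSA fundamental) on every cell of both
maps.  `injected_signal()` exposes the exact perturbation added to any
sample, making the generator its own oracle for the attribution layer
(verified to 1e-10 in the noiseless limit).

Study designs: the screening set has 12 neat-serum measurements and three
replicates of each drug (cefazolin/ibuprofen/paracetamol at 1.2 mM — a
2:1 molar ratio to the 0.6 mM HSA — and warfarin at 0.03 mM); the
verification series dilutes cefazolin log-uniformly over 13 steps from
6 mM to 0.6 µM (factor ≈ 2.15) plus neat serum, each level in triplicate.

## Preprocessing

Fixed stage order: thermal-reference correction → Savitzky–Golay
smoothing → PCA noise reduction → flattening.

1. **Thermal-reference correction/normalisation.**  The 5 ps map is the
   reference.  Because the thermal response is pump-independent, its
   probe profile is estimated by averaging over pump rows (√71 ≈ 8×
   less noise than any single cell); the profile's peak sets the
   normalisation scale s.  The unit-scaled profile is least-squares
   fitted to the 0.25 ps map over off-amide cells (probe < 1600 or
   > 1700 cm⁻¹) and subtracted, removing the thermal leak; the result is
   divided by s.  Since s is proportional to the path length, the output
   is invariant under any common scaling of the raw pair (tested to
   1e-6 over factors 0.5–2).  The pump-averaged estimator matters
   quantitatively: a single-cell maximum carries ~3% noise which,
   multiplied by the norm-30 serum spectrum, would dominate the
   across-sample covariance.
2. **Smoothing** along the probe (read-out) axis only: Savitzky–Golay,
   window 7, order 3, polynomial edge handling.  2D smoothing is
   deliberately avoided — it would blur the fundamental/overtone
   structure across the anharmonic shift.
3. **PCA noise reduction** across samples (pixel means centred),
   reconstructing from the smallest number of components explaining
   ≥ 99% of variance.  On the default 24-sample set the noise floor is
   broad, so this threshold retains nearly all components; the stage
   becomes consequential for larger or cleaner data sets and the
   threshold is exposed.
4. **Flattening**: row-major (pump outer, probe inner), with an explicit
   pixel ↔ (pump, probe) bijection carried by the `ProcessedDataset`.

Whether the original workflow smooths before or after normalisation is
not documented; the order above is fixed and tested.

## PLS, classification, cross-validation

The PLS core is classic NIPALS with X- and Y-deflation, written from
scratch (scikit-learn's implementation serves only as an independent
cross-check in the tests, where predictions agree to better than 1e-6 in
centered mode).  NIPALS was chosen over SIMPLS because it handles
uncentered operation transparently: with no centering there is no
intercept and the coefficient matrix B alone reconstructs ŷ = XB.
Convergence: successive score change < 1e-13, max 2000 iterations;
extraction stops early when X deflates to numerical rank zero.  Sign
convention: the first (relative-to-scale) nonzero element of each weight
vector is positive, making LVs comparable across runs.

PLS-DA uses one-hot class membership with an argmax decision; ties break
to the earliest class in sorted order.  The working model settings are 7
LVs for the binary serum vs drug-bound task and 9 LVs for the five-class
task, both **uncentered** — the settings reported as best-performing for
this analysis.  Leave-one-out cross-validation refits from scratch
(including any centering) for each held-out sample and is fully
deterministic.  The RMSE-vs-LV curve is returned without automatic elbow
selection; the LV count is configuration.

## Attribution

The five-class model's x-scores are summarised per (class, LV) as mean ±
1σ.  An LV is assigned to a class iff that class has the largest absolute
mean score on it **and** its 1σ interval does not overlap any other
class's interval; classes can stay unassigned, and the serum background
class is excluded from receiving assignments.  The assigned LV's loading,
un-flattened to the (pump, probe) grid, is the model's estimate of the
drug's spectral signature.

Attribution fits are **mean-centered** even though classification is not:
the serum common mode is ~50× larger than any drug pattern, and in an
uncentered fit it contaminates every loading.  Centering affects
interpretation only; all accuracy figures use the uncentered models.

A quantitative note on signature recovery under the default conditions
(3 replicates per drug, noise σ 0.01, pattern amplitude 0.06): an LV
loading is a noise-bearing estimate whose error norm scales as
σ_eff·√(n_pixels/Σt²) ≈ 0.6 in these units, comparable to the pattern
norms themselves, and the spectrally overlapping signatures (the
warfarin/ibuprofen positive lobes sit 2–5 cm⁻¹ apart; paracetamol's
elongated feature crosses every other signature) split partially across
neighbouring LVs.  The assigned loadings therefore correlate with the
injected signatures at |cosine| ≈ 0.6 (warfarin, paracetamol, ibuprofen)
to 0.85 (cefazolin), seed-averaged, while the direct class-mean
difference spectra reach 0.83–0.93 — the information is present but
distributed.  Visual resemblance (the paper-style loadings-vs-difference
comparison) is unambiguous at these levels; exact per-LV isolation of
each signature would require more replicates or lower noise than the
emulated design provides.

## Binding quantification

The univariate readout is the amplitude ratio of the preprocessed
0.25 ps map at (1656, 1649) over (1635, 1632) cm⁻¹, sampled at the
nearest grid cell (ties toward the lower wavenumber; bilinear
interpolation behind a flag).  Per concentration, replicate ratios are
averaged; the interior extremum is the discrete minimum over the ladder
excluding both endpoints, and the profile is flagged U-shaped iff both
arms rise at least two pooled standard deviations above it.  On the
default two-regime generator the minimum lands on the 0.129 mM ladder
point, within a factor 2 of the configured 0.2 mM crossover; a
single-regime configuration (f_high = f_low, secondary weight 0)
produces a monotone profile and no flag.  Recovery is checked against
the generator's own binding parameters; no external binding curve is
tabulated for comparison.

Unit conversions are exact: µg/mL = mM × g/mol, mM = mg/mL × 1000 /
(g/mol); rounding happens only at presentation.

## Numerical and interface choices

- Maps are stored in a bespoke plain-text grid format (comment header,
  probe-axis line, one row per pump value; 12 significant digits, round
  trips faithful to 1e-10) — diffable, and no community standard exists
  for 2D-IR maps.  Axes are ascending in files regardless of plotting
  convention.
- Configs are strict YAML: unknown keys are rejected, and every written
  artifact embeds a 12-hex-digit config hash for provenance.
- Degenerate inputs raise: zero thermal reference, singleton classes in
  LOO, zero ratio denominators, non-monotone axes, ragged rows (with
  line numbers).

## Problem sizes

The default benchmark protocol generates the 24-sample screening design
for ten seeds and runs both LOO tasks plus attribution per seed
(~15 s total), and one 42-sample verification series for the binding
curve; the full test suite completes in well under a minute.  These sizes
follow the emulated study designs directly; nothing is scaled down.

## Limitations

- The generator is a statistical twin, not a physical simulation: no
  response-function lineshapes, solvent dynamics, pulse-shaper or
  phase-cycling effects; path length enters only as a scalar factor; the
  water combination-band absorbance calibration is not modelled.
- Drug-only DMSO controls are simple isolated doublets placed below the
  protein window (1592–1612 cm⁻¹) and are not part of either generated
  design.
- The two-regime binding parameters are plausible rather than fitted to
  any published isotherm; the secondary mode's geometry is a modelling
  device consistent with a weak high-dose mechanism, not a structural
  claim.
- Classification accuracies on synthetic data should be read as evidence
  that the pipeline recovers what was injected under realistic noise —
  not as predictions of performance on real serum spectra, whose
  covariance structure (correlated baselines, sample chemistry,
  instrument drift) is richer than iid noise plus a path-length factor.
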