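# Methods

This note documents the models, procedures and numerical choices behind
`conespec`, in the order data flow through the package.

## Opsin absorbance templates

Pigment absorbance spectra are represented as a fixed, peak-normalized
shape function of the reciprocal-wavelength offset `c = 1/wl − 1/wlmax`
(the Dartnall nomogram convention).  Because only the offset enters,
translation invariance across peak positions is exact by construction:
two pigments at equal reciprocal offsets from their peaks have identical
absorbance.

Two template families are provided:

- **GovardovskiiTemplate** (default): the Govardovskii et al. (2000)
  A1-pigment alpha-band expression, evaluated at a fixed anchor peak and
  translated rigidly in 1/wavelength.  The template's internal maximum is
  located numerically at construction (bounded scalar minimization,
  xatol 1e−12) so the shape is exactly 1.0 at zero offset.  The anchor
  determines the shape width: 360 nm for the UV class (UV pigments are
  narrower), 500 nm for all blue/green/red classes.  The beta
  (cis-band) absorbance is omitted; for the 330–650 nm stimulus range and
  the peaks in the catalog the alpha band dominates, and the model
  selection machinery is template-agnostic in any case.
- **PolynomialTemplate**: user-supplied coefficients `c_0..c_8` giving
  log10 absorbance as a polynomial in `u = 1000·c` (inverse micrometres).
  The polynomial is re-anchored so the shape is exactly 1 at `u = 0`.
  This is the slot for published 8th-order pigment-template polynomials;
  coefficient provenance is the user's responsibility.

Absorbance is clipped to `[ε, 1]` with floor `ε = 1e−6`, and to `ε`
outside the 300–750 nm validity window.  The floor keeps the effective
semi-saturation `k/A` finite arbitrarily far from peak, where a cone
simply never responds at realizable irradiances.

## Cone catalog

The default catalog orders the eight classes by peak wavelength: UV 358,
B1 415, B2 440, G1 460, G3 480, G4 500, R2 556, R1 575 nm.  Each entry
carries `Δ_i`, its log10 semi-saturation offset relative to the UV cone
(`Δ_UV = 0` by definition; R1 and R2 share one value, so a single
long-wavelength semi-saturation `log k_R1R2 = log k_UV + Δ_R` exists).
**The shipped Δ values are illustrative placeholders** chosen to give
realistic-looking synthetic data (short-wavelength classes more
sensitive, red classes ~0.45 log units less sensitive than UV); they are
not calibrated measurements, and `data/catalog.yaml` documents how to
substitute literature values.

## Stimulus protocol

Nine wavelengths (330–650 nm in 40-nm steps) × seven irradiances
descending in 0.5-log-unit steps from per-wavelength maxima
(5.2, 5.7, 5.7, 6.1, 6.4, 6.3, 6.4, 6.3, 7.2 log quanta·μm⁻²·s⁻¹
respectively) give 63 ladder conditions.  The protocol records 64
unique-condition slots; the 64th is a configurable extra slot, by default
a second presentation of the brightest 650-nm flash (the long-wavelength
end of the spectrum is where doubled sampling is most useful, red cones
being the least sensitive class).  Six ladder conditions are re-presented
late in the run as stability replicates.  63 + 1 + 6 = 70 averaged
responses; at four sweeps per average the protocol delivers 280 raw
stimuli.  Downstream fitting consumes (wavelength, irradiance, amplitude)
triplets and is insensitive to which condition occupies the extra slot.

## Waveform preprocessing

- **Averaging**: pointwise mean of the four replicate sweeps per
  condition; sweeps must agree in length, timing and condition.
- **Boxcar filter**: centered moving average of width 17 ms — one 60-Hz
  line cycle, i.e. 34 samples at the 2-kHz digitization rate — with
  truncated windows at the edges (no padding).  Amplitude and latency
  extrema lie far from trace edges, so the edge policy is immaterial.
- **Trough-to-peak amplitude**: the maximum rise `max_{i≤j}(v_j − v_i)`
  within the 850 ms following stimulus onset, computed in O(n) with a
  running minimum.  This definition forces the trough to precede the peak
  and equals depth-plus-height on a clean biphasic PIII shape
  (hyperpolarizing ON trough, repolarizing OFF peak); it is 0 for flat or
  monotonically falling traces and invariant to constant offsets.
- **Dataset metrics**: latencies are measured on the grand-mean waveform
  of all sweeps in a dataset, where noise interferes least with extrema
  timing: ON-trough latency = onset to the minimum between onset and
  offset; OFF-peak latency = offset to the maximum after offset.
  `dataset_vmax` is the largest trough-to-peak amplitude in the dataset.
- **Stability check**: a dataset is rejected when any replicate pair
  drifts by more than a fractional tolerance (default 25%, configurable —
  no published threshold exists, so the default is deliberately lenient
  and every rejection is logged rather than silently dropped).
- **Normalization and pooling**: each eye's amplitudes are divided by the
  dataset maximum (stored in metadata) before pooling, so each eye enters
  the cumulative dataset with equal weight and its own point count.

## Spectral model and fitting

The model is `V(wl, I) = Σ_{i∈S} Vm_i · x_i/(x_i + k_i)` with
`x_i = I·A_i(wl)` and `k_i = 10^(log k_UV + Δ_i)`.  Irradiance is stored
in log10 units (the protocol's currency) and converted to linear inside
the prediction, since the summation is written in linear quanta.  The
Hill exponent is fixed at 1; with one shared `log k_UV` the full model
has nine free parameters (eight `Vm_i` + `log k_UV`).

Each of the 255 cone subsets is fit by bounded least squares
(scipy `least_squares`, trust-region-reflective, analytic Jacobian,
ftol = xtol = gtol = 1e−12).  Bounds — `Vm ∈ [0, 10]`,
`log k_UV ∈ [2, 8]` — are optimizer guards only; the model admissibility
constraints (significance, the 2.0 amplitude cap) are applied after the
fit, as selection rules rather than optimizer bounds.  Multi-start:
five deterministic starts at `log k_UV ∈ {3.5, 4.0, 4.5, 5.0, 5.5}`, each
seeding the `Vm` vector from a nonnegative-least-squares solve at that
fixed semi-saturation; the best local optimum is kept.  Standard errors
come from `cov = s²(JᵀJ)⁻¹` with `s² = SS_res/df`, `df = n − p`; a
condition number above 1e12 (or a singular matrix) marks the fit
non-converged rather than raising.

## Selection and statistics

Admissibility requires convergence, every `Vm_i` significant at
p ≤ 0.05, and every `Vm_i < 2.0` (excluding degenerate near-flat fits
that trade an enormous amplitude against an enormous semi-saturation).
Among admissible models the maximal r² wins; exact ties go to the
smaller subset (parsimony), then the smaller id.

- **Vm significance**: one-sample t = Vm/SE on the per-fit residual df.
  Default two-sided p with a positivity requirement (a negative estimate
  is never a significant cone signal); a one-sided option exists.  The
  convention `se = 0 → p = 0 if vm > 0 else 1` handles noiseless data.
- **F comparison**: for residual variances (v_A, df_A), (v_B, df_B) the
  package reports `F = v_A/v_B`, the cumulative probability
  `cdf = P(F ≤ F_obs)`, the upper-tail p, and a two-sided
  `p = 2·min(cdf, 1−cdf)`.  Equivalence is declared on the two-sided p
  ≥ 0.95 — a variance ratio so close to 1 that neither tail is informative
  — and inferiority appears as a two-sided p near 0.  Both tails are
  always emitted so either convention can be read off a report.
- **Cross-fitting** fits one dataset with another dataset's best
  combination and F-compares against the dataset's own best model,
  the between-condition comparison used to show two datasets arise from
  different cone complements.

Model ids are a bitmask over catalog order (UV = bit 0 … R1 = bit 7), so
id 111 = {UV, B1, B2, G1, G4, R2}, id 192 = {R2, R1}, id 255 = all eight.

## Chromatic adaptation fits

Irradiance-response series recorded under different adapting backgrounds
are fit jointly with Hill functions sharing `Vmax` and exponent across
backgrounds while `log σ` is free per background, in the numerically
stable form `V = Vmax/(1 + 10^{n(log σ − log I)})`.  The exponent is free
(initialized at 1) since these are generic Hill fits, unlike the
exponent-1 spectral model.  Fits are SE-weighted when every series
carries per-point standard errors, unweighted otherwise.  Background
shifts are assessed by `t = Δlog σ / sqrt(SE_A² + SE_B²)` on the pooled
residual df.  Non-overlapping irradiance ranges set a warning flag but do
not abort the fit.

## Synthetic data generator

`simulate_dataset` draws one eye's 70 amplitudes as
`predict(truth) + N(0, noise_sd)` truncated at zero — additive Gaussian
noise is the simplest model consistent with symmetric SE bars on real
irradiance-response points, and truncation mirrors the nonnegativity of
trough-to-peak amplitudes.  Truth parameters are rescaled so the maximum
prediction over the protocol grid is exactly 1, making truth `Vm` directly
comparable to estimates from max-normalized data; empirical per-eye max
normalization then biases estimates downward only by the expected
maximum of the noise at the near-saturated conditions (~2–4% at
noise 0.02), well inside the recovery tolerances.

`simulate_waveforms` builds biphasic traces from two gamma kernels
(`(t/τ)^4 e^{4(1−t/τ)}`): an ON trough peaking 135 ms after onset holding
70% of the trough-to-peak amplitude, and an OFF peak 310 ms after offset
with the remaining 30%, at 2 kHz with optional white trace noise.  The
noiseless trough-to-peak amplitude equals the scenario's predicted
amplitude within 1% (kernel overlap accounts for the remainder).

`simulate_adaptation_series` tabulates mean ± SE irradiance-response
points: at each of seven 0.5-log-step irradiances the amplitude is the
mean over 30 eyes of truth + N(0, 0.02) — the same amplitude noise model
as the spectral generator, at a pooling depth typical of adaptation
datasets.

What the generator does **not** emulate: correlated noise across
conditions within an eye, eye-to-eye parameter heterogeneity (every eye
shares one truth), rod intrusion, electrode drift, and any temporal
dependence between stimuli.  Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the model's
own assumptions, not robustness to these real-data violations.

Preset scenarios (`wt-larva-like`, `red-dichromat-adult-like`,
`red-shifted-tetrachromat-like`) sketch qualitative cone-amplitude
profiles for demonstrations; their values are illustrative.

## Problem sizes and determinism

The parameter-recovery experiment uses the spec conditions throughout:
six-cone truth, 28 pooled eyes (1960 points), amplitude noise SD 0.02,
20 seeds, full 255-model selection per seed (~7 s per selection, a few
minutes in total).  All randomness flows from a single seed:
`numpy.random.default_rng` streams are spawned per eye, and the
multi-start grid is deterministic, so selections, reports and CSV outputs
are byte-identical across reruns with the same seed.

## Known limitations

- The spectral model assumes strictly linear summation of cone
  photocurrents and identical Hill exponents of 1 for all classes.
- `log k_UV` is the only free sensitivity parameter; mis-specified Δ_i
  offsets bias the inferred amplitudes of the affected classes.
- Selection significance is not corrected for the multiplicity of 255
  candidate fits; with noisy data a superset of the true combination
  passes all constraints in roughly the per-model false-positive rate,
  which is why equivalence classes and the per-model table are part of
  every report.
- The amplitude cap (2.0) and stability tolerance (25%) are pragmatic
  defaults, exposed in `FitOptions`/`stability_check` for adjustment.
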