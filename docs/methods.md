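# Methods

This note documents the models, numerical choices, and limitations behind
`paox`. It is the package's own account of its science; every number quoted
here is computed by the test suite or the acceptance script, not copied
from elsewhere.

## Problem

Multispectral photoacoustic imaging measures, per pixel, an amplitude
proportional to the product of the local optical absorption and the local
light fluence. Blood oxygen saturation (sO₂) could in principle be read off
from the absorption spectrum of hemoglobin, but the fluence term colors the
measured spectra in a depth- and tissue-dependent way ("spectral
coloring"), which breaks naive linear unmixing. Data-driven regressors
trained on simulated tissue can learn to invert the coloring, but they
inherit two problems: they are inflexible about which wavelengths are
available at inference time, and their accuracy depends strongly on how
well the training distribution matches the target data. `paox` addresses
both: a wavelength-masked recurrent regressor that accepts any subset of a
fixed 41-channel grid, and a per-wavelength Jensen–Shannon distance that
ranks candidate training distributions against an unlabeled target dataset.

All spectra live on a fixed grid of 41 wavelengths, 700–900 nm in 5 nm
steps. A spectrum with fewer wavelengths is stored in the full 41-slot
representation with a boolean presence mask; masked slots hold zeros.

## Chromophore tables

The embedded optical properties are anchor tables at 10 nm spacing,
linearly interpolated to the 5 nm grid:

- Whole-blood absorption for fully oxygenated and deoxygenated blood,
  derived from standard tabulated hemoglobin molar extinction values
  assuming 150 g/L total hemoglobin and 64,500 g/mol:
  μa [mm⁻¹] = ln(10)·ε·(150/64500)/10. The tables reproduce the expected
  qualitative structure: deoxyhemoglobin dominates at 760 nm,
  oxyhemoglobin beyond the near-isosbestic point (the two coefficients
  differ by <7% at 800 nm).
- Pure water absorption (the NIR shoulder near 740–760 nm and the rise
  toward 900 nm).
- Melanosome absorption from the standard power law
  μa = 1.70·10¹²·λ⁻³·⁴⁸ cm⁻¹.
- Background reduced scattering μs′ is constant at 1.0 mm⁻¹; the tissue
  variants do not vary scattering.

Different published compilations differ by a few percent; all tests in
this repository are self-consistent against the embedded table, so the
exact compilation does not affect any result computed here.

The pO₂ → sO₂ reference conversion uses the standard single-equation
dissociation curve S = 1/(23400·(p³ + 150p)⁻¹ + 1), monotone on p ≥ 0 with
S(0) = 0.

## Synthetic data: a layered fluence surrogate

The generator replaces volumetric Monte Carlo photon transport (and any
acoustic modeling) with a 1-D layered diffusion-approximation surrogate.
For a vessel at depth z below the tissue surface, the relative fluence at
wavelength λ is

    Φ(λ, z) = G(z) · exp(−μa,water(λ)·d_water − μeff,skin(λ)·d_skin − μeff,bg(λ)·z)

with μeff = √(3 μa (μa + μs′)), a non-scattering water coupling layer of
thickness d_water, an optional melanin skin layer of thickness d_skin whose
absorption is the melanosome reference scaled by a per-sample melanosome
volume fraction, and a blood-perfused background (blood volume fraction
`bg_bvf` at background oxygenation, plus a water fraction of 0.8 standing
in for the aqueous tissue matrix). G(z) = (1 + z/z₀)^(−k) is a geometric
divergence proxy for the illumination: a broad beam has k = 0, a narrow
beam k = 1 with z₀ = 5 mm, a point source k = 2 with z₀ = 1 mm.

The simulated amplitude of a vessel with saturation s and radius r is

    p₀(λ) = Φ(λ, z) · μa,blood(λ, s) · V(r, λ) · (1 + ε(λ)),

where μa,blood mixes the oxy/deoxy spectra linearly, V(r, λ) =
(1 − e^(−2 μa r)) / (2 μa r) is the mean fluence inside an absorbing slab
of thickness 2r (capturing the self-coloring of larger vessels, and the
difference between normal and halved-radius vessel populations), and ε is
i.i.d. Gaussian multiplicative noise with σ = 0.02 by default. Vessel sO₂
is uniform on [0, 1]; vessel depth uniform on [0.5, 9.0] mm; vessel radii
uniform on [0.15, 1.0] mm in the baseline tissue.

Named variants perturb exactly one aspect of the baseline: background
oxygenation ranges (fixed 70%, U(0,100)%, U(60,80)%, water-only),
heterogeneous backgrounds (a depth-correlated first-order autoregressive
jitter with 1.2 mm correlation length, integrated bin-by-bin along the
depth column), a melanin skin layer (0.3 mm, melanosome fraction
U(0.1%, 5%)), halved vessel radii, coarser/finer grid quantization of
depth and radius (0.15/0.6/1.2 mm), beam-geometry proxies, and 2 cm or
4 cm water coupling layers. Variants that exist only through acoustic
forward modeling or commercial-device digital twins are out of scope of
the surrogate and deliberately absent.

Randomness: every random field (sO₂, radius, depth, background sO₂,
melanosome fraction, noise, heterogeneity) draws from its own
counter-based Philox stream keyed by (seed, field id). Generation is a
pure function of the config, and requesting more spectra extends the
dataset without changing earlier draws.

What the surrogate does *not* emulate: 3-D fluence structure and shadowing
between vessels, acoustic propagation, transducer bandwidth, image
reconstruction artifacts, negative reconstructed amplitudes. Passing tests
on surrogate data therefore demonstrate the correctness and internal
behaviour of the method (masking flexibility, training-distribution
sensitivity, distance-based dataset ranking) — not accuracy on real
photoacoustic measurements.

## Preprocessing

Pipeline order: high-signal selection → wavelength subsetting →
per-spectrum z-scoring → resampling.

- Selection keeps spectra whose 800 nm amplitude is at least 10% of the
  dataset maximum; if that retains fewer than 10% of the spectra, the top
  10% by 800 nm amplitude are kept instead (ties broken by input order).
  The fallback operates per dataset.
- Z-scoring sets each spectrum's mean to 0 and population variance
  (divide-by-N) to 1 over its *present* wavelengths; masked slots stay 0.
  Constant spectra are rejected rather than zero-filled — a flat spectrum
  carries no shape information and would be a silent out-of-distribution
  input.
- Dataset-size stratification resamples uniformly with replacement using
  an explicit counter-based generator.
- The canonical wavelength subset for a count N is evenly spaced over the
  41 slots with both endpoints included, nearest-slot rounding, and ties
  going to the lower slot, so a subset is reproducible from N alone.

## The masked-LSTM regressor

The spectrum is consumed as a 41-step sequence of scalar amplitudes with a
per-step presence flag. An LSTM with hidden size 100 processes the
sequence; at a masked step the recurrent state passes through unchanged
and the emitted hidden vector repeats the previously emitted one (steps
before the first present wavelength emit zeros), so stored values at
masked slots can never influence the output — this is asserted by test.
The per-step hidden vectors are flattened into a 4100-unit encoding
(41 × 100; the head consumes exactly T·H units) feeding a three-layer
fully connected head (4100 → 1000 → 1000 → 1) with leaky-rectifier
activations (slope 0.01) and a final sigmoid that constrains estimates to
[0, 1].

Training: mean absolute error loss, Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8),
initial learning rate 1e-3 halved whenever the validation loss fails to
improve for 5 consecutive epochs (floor 1e-6), batch size 1024, a 20%
random validation split (the schedule needs a validation signal), default
100 epochs at full scale. The engine is written directly in numpy
(float32, single-threaded BLAS): forward pass, analytic backpropagation
(verified against central-difference gradients to ~1e-4 relative), and the
optimizer/scheduler. Training is deterministic given the seed. The
unidirectional LSTM was chosen as the simplest architecture satisfying
the masking contract.

Baselines:

- **Linear unmixing (LU)**: non-negative least squares of the raw
  amplitudes against the oxy/deoxyhemoglobin basis over the present
  wavelengths; the estimate is a/(a+b). Scale-invariant; the degenerate
  all-zero fit returns 0.5; if NNLS fails to converge a 1e-4 grid search
  over s with unit-normalized model spectra (ties toward lower s) stands
  in.
- **Learned spectral decoloring (LSD)**: a dense regressor
  (41 → two hidden layers → 1, same activations, loss and schedule) that
  requires the full wavelength set and rejects masked input by design —
  this inflexibility is precisely what the recurrent architecture removes.

## Jensen–Shannon dataset distance

To compare two z-scored spectra collections, each wavelength's values
across spectra are binned into 100 uniform bins on [−3, +3] z-units
(right-closed last bin). Values outside the range are excluded before
normalization; no pseudo-counts are added (the Jensen–Shannon construction
is finite regardless). For each wavelength shared by the two datasets the
Jensen–Shannon divergence

    D_JS(P‖Q) = ½ D_KL(P‖M) + ½ D_KL(Q‖M),  M = ½(P+Q)

is computed in natural log, and the reported per-wavelength score is its
square root — the metric ("distance") convention, bounded by
√ln 2 ≈ 0.8326. The aggregate score is the mean over the shared
wavelengths; wavelengths with no in-range samples in either dataset are
dropped from the mean with a warning. Subsampled estimation (default
10,000 spectra without replacement, 10 repeats, seeded) reports the mean
and the per-repeat scores.

Ranking candidate training sets by ascending aggregate distance to an
unlabeled target picks the distribution a model should be trained on; the
correlation of this distance with the actual estimation error is
positive on the surrogate suite (asserted as r > 0 over 3 seeds and 8
variants). Off-trend candidates are flagged as outliers when their
residual from the least-squares distance/error line exceeds 2 interquartile
ranges — a codification of outlier removal that would otherwise be done by
inspection.

Note the finite-sample floor: two independent n-sample draws of the *same*
distribution have an expected JS divergence of roughly (bins−1)/(4n) nats,
so subsampled self-distances are not zero; identity comparisons are exact
(0) only under full sampling. Tests that assert identity use full
sampling for this reason.

## Experiment runners and desk-scale defaults

Three seeded, manifest-writing runners reproduce the package's headline
behaviours: a wavelength sweep (train and test at each wavelength count),
a train/test cross-validation matrix over tissue variants (plus an
equal-proportion mixed training set), and the distance-vs-error study.

Problem sizes are the package's desk-scale defaults, chosen so each study
runs in minutes on one CPU core: the in-distribution accuracy check trains
on 50,000 spectra for 30 epochs and evaluates 10,000 held-out spectra
(full 100/1000-unit architecture); the qualitative studies use reduced
widths (hidden 24, head 64), 5,000–8,000 training spectra and 12–15
epochs per model. Full-scale settings (300,000 spectra, 100 epochs)
remain available through the hyperparameter object.

## Error metric

The headline metric is the median absolute error
ϵ = median(|sO₂ − ŝO₂|), reported in percentage points (the median of an
even count is the mean of the two central order statistics). The median is
deliberately robust to the heavy error tails that deep, strongly colored
spectra produce.

## Known limitations

- The surrogate's absolute error levels are not comparable to errors
  measured on Monte Carlo or experimental data; only orderings and
  qualitative effects transfer.
- The 1-D fluence model has no lateral structure, so variants whose
  physical meaning is inherently 2-D/3-D (acoustic modeling, device
  geometries, image reconstruction) cannot be represented.
- The amplitude scale is arbitrary (no Grüneisen factor); per-spectrum
  z-scoring removes it by construction.
- Noise characteristics of extracted simulation spectra are not published
  for the pipeline this surrogate emulates; σ = 0.02 multiplicative noise
  is a package default, configurable per variant.
- Training determinism holds for single-threaded BLAS; multi-threaded
  runs can differ in late decimals.
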