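# paox — wavelength-flexible data-driven photoacoustic oximetry

`paox` estimates blood oxygen saturation (sO₂) from per-pixel multispectral
photoacoustic amplitude spectra. It is aimed at researchers in quantitative
photoacoustic imaging who need (a) a data-driven unmixing method that still
works when the set of acquired wavelengths changes between training and
deployment, and (b) a principled way to choose *which* simulated training
distribution to use for a given target dataset when no ground truth is
available.

## What it implements

**The masked-LSTM regressor.** Spectra live on a fixed 41-channel grid
(700–900 nm, 5 nm steps) with a per-wavelength presence mask. An LSTM
(hidden size 100) consumes the spectrum as a sequence; masked steps leave
the recurrent state untouched and repeat the previously emitted hidden
vector, so missing wavelengths genuinely do not influence the estimate.
The flattened encoding feeds a dense head (4100 → 1000 → 1000 → 1, leaky
ReLU, final sigmoid), trained with mean-absolute-error loss and Adam
(lr 10⁻³, halved on a 5-epoch validation plateau). The whole engine —
forward pass, analytic backprop, optimizer — is implemented in numpy and
verified against numerical gradients.

**Baselines.** Non-negative-least-squares linear unmixing against the
oxy-/deoxyhemoglobin basis (ŝ = a/(a+b)), and a fixed-wavelength
feedforward "learned spectral decoloring" regressor that rejects masked
input by design.

**The dataset-distance selector.** For two z-scored spectra collections,
each shared wavelength λ contributes the Jensen–Shannon distance between
100-bin histograms of its values on [−3σ, +3σ]:

    D̄_JS = (1/N_λ) Σ_λ √( ½ D_KL(P_λ‖M_λ) + ½ D_KL(Q_λ‖M_λ) ),  M = ½(P+Q)

bounded by √ln 2 ≈ 0.83. Candidate training sets are ranked by ascending
D̄_JS to an unlabeled target; the score correlates positively with the
estimation error a model trained on each candidate achieves on that
target, so the lowest-distance candidate is the recommended training set.

**The synthetic-data generator.** A fast 1-D layered fluence surrogate
(effective attenuation μ_eff = √(3μa(μa+μs′)) through water, melanin skin
and blood-perfused background layers, geometric beam divergence, vessel
self-absorption) produces labeled, spectrally colored vessel spectra for a
baseline tissue and 15 named single-parameter variants (background
oxygenation, heterogeneity, skin melanin, vessel size, grid resolution,
illumination geometry, water coupling layers). See `docs/methods.md` for
the model, its assumptions and its limits.

## Worked example

```python
from paox import (LstmOximeter, LstmHyperparams, generate_dataset, variant,
                  zscore, median_abs_error, rank_training_sets)

train = zscore(generate_dataset(variant("BASE", n_spectra=6000, seed=7)))
test  = zscore(generate_dataset(variant("BASE", n_spectra=2000, seed=8)))

hyper = LstmHyperparams(lstm_hidden=24, fc_hidden=64, epochs=15, batch_size=512)
res = LstmOximeter(train, hyper).fit(seed=0)
print(res.summary())
print(f"held-out error = {median_abs_error(res.predict(test), test.so2):.2f} pp")

cands = [zscore(generate_dataset(variant(v, n_spectra=4000, seed=21 + i)))
         for i, v in enumerate(("BASE", "SKIN", "WATER_4cm"))]
for name, score in rank_training_sets(test, cands, n_subsample=2000, repeats=5, seed=0):
    print(f"{name:10s} aggregate JS distance = {score:.3f}")
```

prints (exactly this, on one CPU in about half a minute):

```
==========================================================
        Photoacoustic oximetry regression results
==========================================================
Estimator:          LSTM
Training variant:   BASE
Trained N_lambda:   41
Parameters:         69,761
Epochs:             15
Final train MAE:    0.0374
Final val MAE:      0.0371
Best val MAE:       0.0366 (epoch 14)
Final lr:           1.00e-03
Seed:               0
==========================================================
held-out error = 2.36 pp
BASE       aggregate JS distance = 0.094
SKIN       aggregate JS distance = 0.159
WATER_4cm  aggregate JS distance = 0.249
```

The summary is the training record of a deliberately small network: mean
absolute error on the training and validation splits (in sO₂ fraction
units) after 15 epochs. The held-out error of 2.36 percentage points says
the model recovers vessel sO₂ to within ~2 pp for half the spectra despite
depth-dependent spectral coloring. The ranking then shows the
distribution-match logic: the target is baseline tissue, and the baseline
candidate earns the lowest Jensen–Shannon distance (its nonzero value is
the finite-sample floor of subsampled histograms), while a melanin skin
layer and a 4 cm water coupling layer push the distributions progressively
further away — so a model for this target should be trained on the first
candidate.

A command-line interface mirrors the library (`paox generate`,
`preprocess`, `train`, `predict`, `unmix`, `jsd`, `experiment`); every
run that writes outputs writes a JSON manifest beside them.

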