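"""Jensen-Shannon dataset distance on per-wavelength histograms.

To quantify how well a candidate training distribution matches a target
dataset without ground-truth labels, each dataset's spectra are z-scored
per spectrum, each wavelength's values across spectra are binned into a
100-bin histogram over [-3, +3] z-units, and the Jensen-Shannon distance
(square root of the JS divergence, natural log) between the two datasets'
histograms is averaged over the wavelengths both datasets share.  The
aggregate score lies in [0, sqrt(ln 2) ~ 0.8326]; lower means a better
distributional match, and it correlates with the sO2 estimation error of a
model trained on the candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chromophores import WavelengthGrid, N_CHANNELS
from .synthgen import SpectraDataset

N_BINS = 100
Z_RANGE = 3.0
BIN_EDGES = np.linspace(-Z_RANGE, Z_RANGE, N_BINS + 1)
MAX_JS_DISTANCE = float(np.sqrt(np.log(2.0)))


@dataclass
class WavelengthHistogramSet:
    """Per-wavelength 100-bin densities of z-scored amplitudes.

    ``densities[w]`` sums to 1 for each covered wavelength with at least one
    in-range sample; wavelengths with no in-range samples are flagged empty.
    """

    densities: np.ndarray  # (41, 100)
    n_samples: np.ndarray  # (41,) in-range counts
    present: np.ndarray  # (41,) bool: wavelength covered by the dataset
    grid: WavelengthGrid

    @property
    def empty(self) -> np.ndarray:
        return self.present & (self.n_samples == 0)


def build_histograms(dataset: SpectraDataset) -> WavelengthHistogramSet:
    """Histogram each present wavelength's z-scored values across spectra.

    Values outside [-3, 3] are excluded before normalization; the last bin
    is right-closed so a value exactly at +3 is counted.
    """
    if len(dataset) == 0:
        raise ValueError("cannot histogram an empty dataset")
    densities = np.zeros((N_CHANNELS, N_BINS))
    n_samples = np.zeros(N_CHANNELS, dtype=int)
    present = np.zeros(N_CHANNELS, dtype=bool)
    for w in range(N_CHANNELS):
        col_mask = dataset.mask[:, w]
        if not np.any(col_mask):
            continue
        present[w] = True
        vals = dataset.amplitudes[col_mask, w]
        vals = vals[(vals >= -Z_RANGE) & (vals <= Z_RANGE)]
        n_samples[w] = vals.size
        if vals.size:
            counts, _ = np.histogram(vals, bins=BIN_EDGES)
            densities[w] = counts / counts.sum()
    return WavelengthHistogramSet(densities=densities, n_samples=n_samples,
                                  present=present, grid=dataset.grid)


def kl_divergence(p, q) -> float:
    """Relative entropy sum_x p(x) log(p(x)/q(x)) in nats; +inf where the
    support of p escapes q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("densities must share one binning")
    nz = p > 0
    if np.any(q[nz] == 0):
        return float("inf")
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


def js_divergence(p, q, *, distance: bool = False) -> float:
    """Jensen-Shannon divergence (nats); with ``distance=True`` its square
    root, the metric convention used for reported scores."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("densities must share one binning")
    m = 0.5 * (p + q)
    d = 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)
    d = max(d, 0.0)  # clip tiny negative rounding
    return float(np.sqrt(d)) if distance else float(d)


@dataclass
class DivergenceResult:
    """Aggregate per-wavelength JS distance between two datasets."""

    djs_bar: float
    per_wavelength: np.ndarray  # (41,), nan where not compared
    n_lambda_used: int
    repeats: np.ndarray = field(default_factory=lambda: np.array([]))


def _djs_bar_once(hp: WavelengthHistogramSet, hq: WavelengthHistogramSet) -> DivergenceResult:
    both = hp.present & hq.present
    if not np.any(both):
        raise ValueError("the two datasets share no wavelengths")
    usable = both & (hp.n_samples > 0) & (hq.n_samples > 0)
    if usable.sum() < both.sum():
        warnings.warn("dropping wavelengths with no in-range samples from the aggregate")
    if not np.any(usable):
        raise ValueError("no shared wavelength has in-range samples")
    per = np.full(N_CHANNELS, np.nan)
    for w in np.flatnonzero(usable):
        per[w] = js_divergence(hp.densities[w], hq.densities[w], distance=True)
    return DivergenceResult(djs_bar=float(np.nanmean(per)), per_wavelength=per,
                            n_lambda_used=int(usable.sum()))


def djs_bar(reference: SpectraDataset, target: SpectraDataset,
            n_subsample: int | None = 10_000, repeats: int = 10,
            seed: int = 0) -> DivergenceResult:
    """Mean per-wavelength JS distance between two z-scored datasets.

    With ``n_subsample`` set, both datasets are subsampled without
    replacement (capped at dataset size) ``repeats`` times and the scores
    averaged; ``n_subsample=None`` compares the full datasets once.
    Only the wavelength intersection is compared.
    """
    if n_subsample is None:
        res = _djs_bar_once(build_histograms(reference), build_histograms(target))
        res.repeats = np.array([res.djs_bar])
        return res
    rng = np.random.Generator(np.random.Philox(
        key=np.random.SeedSequence((int(seed), 0xd15)).generate_state(2, np.uint64)))
    scores = []
    per_acc = np.zeros(N_CHANNELS)
    per_cnt = np.zeros(N_CHANNELS)
    n_used = 0
    for _ in range(int(repeats)):
        ia = rng.choice(len(reference), size=min(n_subsample, len(reference)), replace=False)
        ib = rng.choice(len(target), size=min(n_subsample, len(target)), replace=False)
        res = _djs_bar_once(build_histograms(reference.take(ia)),
                            build_histograms(target.take(ib)))
        scores.append(res.djs_bar)
        ok = ~np.isnan(res.per_wavelength)
        per_acc[ok] += res.per_wavelength[ok]
        per_cnt[ok] += 1
        n_used = max(n_used, res.n_lambda_used)
    per = np.where(per_cnt > 0, per_acc / np.maximum(per_cnt, 1), np.nan)
    return DivergenceResult(djs_bar=float(np.mean(scores)), per_wavelength=per,
                            n_lambda_used=n_used, repeats=np.array(scores))


def rank_training_sets(target: SpectraDataset, candidates: list[SpectraDataset],
                       n_subsample: int | None = 10_000, repeats: int = 10,
                       seed: int = 0) -> list[tuple[str, float]]:
    """Candidates ordered by ascending aggregate JS distance to the target.

    Stable sort: ties keep candidate input order.  Returns (variant name,
    score) pairs; the best-matching training distribution comes first.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    scores = [djs_bar(c, target, n_subsample=n_subsample, repeats=repeats, seed=seed).djs_bar
              for c in candidates]
    order = np.argsort(scores, kind="stable")
    return [(candidates[i].variant, scores[i]) for i in order]


def correlate_djs_error(scores, errors) -> float:
    """Pearson correlation between dataset-distance scores and estimation errors."""
    from scipy.stats import pearsonr

    scores = np.asarray(scores, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if scores.shape != errors.shape or scores.size < 3:
        raise ValueError("need equal-length sequences of at least 3 pairs")
    if np.ptp(scores) == 0 or np.ptp(errors) == 0:
        raise ValueError("Pearson correlation is undefined for constant input")
    return float(pearsonr(scores, errors).statistic)
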