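"""Spectra selection, z-score normalization, stratified resampling, and
wavelength subsetting.

The pipeline order is selection -> wavelength subsetting -> per-spectrum
z-scoring -> resampling; the same operations are applied to synthetic and
external datasets so that models trained on simulations transfer to
measured spectra without intensity calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import math

import numpy as np

from .synthgen import SpectraDataset

ZSCORE_TOL = 1e-10


@dataclass
class SelectionReport:
    """Bookkeeping of the two-step high-signal voxel selection."""

    n_input: int
    n_kept_threshold: int
    fallback_used: bool
    n_final: int

    def to_dict(self) -> dict:
        return asdict(self)


def select_spectra(dataset: SpectraDataset, reference_nm: float = 800.0,
                   threshold: float = 0.10) -> tuple[SpectraDataset, SelectionReport]:
    """Keep high-signal spectra: amplitude at 800 nm at least 10% of the
    dataset maximum; if that keeps fewer than 10% of the spectra, fall back
    to the top 10% by 800 nm amplitude (ties broken by input order)."""
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot select from an empty dataset")
    ref_idx = dataset.grid.index_of(reference_nm)
    present = dataset.mask[:, ref_idx]
    if not np.any(present):
        raise ValueError(f"{reference_nm} nm is masked out in every spectrum")
    ref_amp = np.where(present, dataset.amplitudes[:, ref_idx], -np.inf)
    cutoff = threshold * np.max(ref_amp)
    keep = ref_amp >= cutoff
    n_thresh = int(np.count_nonzero(keep))
    n_min = math.ceil(threshold * n)
    fallback = n_thresh < n_min
    if fallback:
        # stable top-k by amplitude, earlier input index wins ties
        order = np.argsort(-ref_amp, kind="stable")
        keep = np.zeros(n, dtype=bool)
        keep[order[:n_min]] = True
    idx = np.flatnonzero(keep)
    report = SelectionReport(n_input=n, n_kept_threshold=n_thresh,
                             fallback_used=bool(fallback), n_final=int(idx.size))
    return dataset.take(idx), report


def zscore(dataset: SpectraDataset) -> SpectraDataset:
    """Z-score each spectrum over its present wavelengths (population sigma).

    Masked slots stay exactly 0.  Spectra that are constant over their
    present wavelengths carry no shape information and are rejected.
    """
    m = dataset.mask
    if np.any(m.sum(axis=1) < 2):
        raise ValueError("each spectrum needs at least 2 present wavelengths to z-score")
    amps = dataset.amplitudes
    counts = m.sum(axis=1)
    mean = (amps * m).sum(axis=1) / counts
    var = (((amps - mean[:, None]) * m) ** 2).sum(axis=1) / counts
    if np.any(var <= 0):
        bad = np.flatnonzero(var <= 0)
        raise ValueError(
            f"{bad.size} constant spectra cannot be z-scored (first at index {bad[0]})")
    z = (amps - mean[:, None]) / np.sqrt(var)[:, None]
    z = np.where(m, z, 0.0)
    out = dataset.take(slice(None))
    out.amplitudes = z
    return out


def is_zscored(dataset: SpectraDataset, tol: float = 1e-6) -> bool:
    """Check the per-spectrum zero-mean/unit-variance contract."""
    m = dataset.mask
    counts = m.sum(axis=1)
    mean = (dataset.amplitudes * m).sum(axis=1) / counts
    var = ((dataset.amplitudes ** 2) * m).sum(axis=1) / counts
    return bool(np.all(np.abs(mean) < tol) and np.all(np.abs(var - 1.0) < tol))


def stratified_resample(dataset: SpectraDataset, n: int, seed: int) -> SpectraDataset:
    """Uniform resampling with replacement to a fixed size (dataset-size
    stratification), deterministic given the seed."""
    if len(dataset) == 0:
        raise ValueError("cannot resample an empty dataset")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.Generator(np.random.Philox(key=np.random.SeedSequence((int(seed), 0x7e5a)).generate_state(2, np.uint64)))
    idx = rng.integers(0, len(dataset), size=n)
    return dataset.take(idx)


def subset_wavelengths(dataset: SpectraDataset, keep) -> SpectraDataset:
    """Restrict spectra to a subset of wavelengths.

    The 41-slot representation is preserved: removed slots are masked and
    their stored amplitudes zeroed.
    """
    keep_mask = dataset.grid.mask_for(keep)
    if keep_mask.sum() < 2:
        raise ValueError("need at least 2 wavelengths")
    out = dataset.take(slice(None))
    out.mask = dataset.mask & keep_mask
    out.amplitudes = np.where(out.mask, dataset.amplitudes, 0.0)
    return out


def evenly_spaced_subset(n_lambda: int, grid=None) -> list[float]:
    """The canonical wavelength subset for a given wavelength count.

    Evenly spaced over the 41 slots with both endpoints included, rounding
    to the nearest slot (ties toward the lower index); reproducible from
    the count alone.
    """
    from .chromophores import default_grid, N_CHANNELS

    grid = grid if grid is not None else default_grid()
    if not 2 <= n_lambda <= N_CHANNELS:
        raise ValueError(f"n_lambda must be in [2, {N_CHANNELS}]")
    positions = np.linspace(0, N_CHANNELS - 1, n_lambda)
    idx = np.ceil(positions - 0.5).astype(int)  # exact .5 ties round to the lower slot
    idx = np.unique(idx)
    return [float(grid.wavelengths[i]) for i in idx]
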