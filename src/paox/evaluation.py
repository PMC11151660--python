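"""Estimation metrics and the reproducible experiment runners.

Provides the headline metric (median absolute sO2 error in percentage
points), the wavelength-sweep experiment (how error depends on the number
of wavelengths used in training and inference), the train/test
cross-validation matrix over tissue variants, and the study correlating
the Jensen-Shannon dataset distance with the estimation error.

Every runner is fully determined by its arguments (configs and seeds), and
the CSV-writing entry points emit a JSON manifest alongside each output.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from . import __version__
from .distribution import djs_bar, correlate_djs_error
from .models import LstmHyperparams, LstmOximeter, OximeterResults
from .preprocess import (evenly_spaced_subset, select_spectra, stratified_resample,
                         subset_wavelengths, zscore)
from .synthgen import SpectraDataset, TissueVariantConfig, generate_dataset, variant


@dataclass
class MetricsReport:
    """Error metrics of one estimator on one dataset (or stratum)."""

    median_abs_error: float  # percentage points
    mean_squared_error: float  # fraction^2
    n: int
    stratum: str | None = None


def median_abs_error(estimates, truths) -> float:
    """Median absolute sO2 error in percentage points.

    The median of an even count is the mean of the two central order
    statistics.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.size == 0:
        raise ValueError("estimates and truths must have equal non-zero length")
    return float(100.0 * np.median(np.abs(est - tru)))


def metrics_report(estimates, truths, stratum: str | None = None) -> MetricsReport:
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    return MetricsReport(
        median_abs_error=median_abs_error(est, tru),
        mean_squared_error=float(np.mean((est - tru) ** 2)),
        n=est.size, stratum=stratum)


# --- shared plumbing --------------------------------------------------------

def prepare_training_set(config: TissueVariantConfig, n: int, seed: int,
                         apply_selection: bool = True) -> SpectraDataset:
    """Generate, select, stratify-resample and z-score one training set.

    Oversamples the generator so that the high-signal selection still
    leaves enough spectra before resampling to exactly ``n``.
    """
    factor = 3 if apply_selection else 1
    raw = generate_dataset(replace(config, n_spectra=n * factor, seed=seed))
    if apply_selection:
        raw, _ = select_spectra(raw)
    ds = stratified_resample(raw, n, seed=seed + 1)
    return zscore(ds)


def train_lstm(train_set: SpectraDataset, hyper: LstmHyperparams, seed: int) -> OximeterResults:
    return LstmOximeter(train_set, hyper).fit(seed=seed)


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path, config: dict, seeds) -> None:
    manifest = {
        "tool_version": __version__,
        "config": config,
        "config_hash": _config_hash(config),
        "seeds": list(np.asarray(seeds).tolist()) if np.ndim(seeds) else [int(seeds)],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, default=str)


# --- experiment 1: wavelength sweep ----------------------------------------

def run_wavelength_sweep(base_config: TissueVariantConfig, nlambda_list,
                         hyper: LstmHyperparams, n_train: int = 50_000,
                         n_test: int = 10_000, seeds=(0, 1, 2),
                         apply_selection: bool = True) -> pd.DataFrame:
    """Train one model per wavelength count per seed on the baseline tissue
    and evaluate it at every wavelength count.

    Returns a long table (seed, nl_train, nl_test, epsilon_pp) with
    |nlambda_list|^2 rows per seed.
    """
    rows = []
    for s in seeds:
        train_full = prepare_training_set(base_config, n_train, seed=base_config.seed + 10_000 + s,
                                          apply_selection=apply_selection)
        test_raw = generate_dataset(replace(base_config, n_spectra=n_test,
                                            seed=base_config.seed + 20_000 + s))
        for nl_train in nlambda_list:
            sub = subset_wavelengths(train_full, evenly_spaced_subset(nl_train))
            res = train_lstm(zscore(sub), hyper, seed=s)
            for nl_test in nlambda_list:
                tsub = zscore(subset_wavelengths(test_raw, evenly_spaced_subset(nl_test)))
                rows.append({"seed": s, "nl_train": nl_train, "nl_test": nl_test,
                             "epsilon_pp": median_abs_error(res.predict(tsub), tsub.so2)})
    return pd.DataFrame(rows)


# --- experiment 2: cross-validation matrix ----------------------------------

@dataclass
class CrossValMatrix:
    """Median-absolute-error matrix: rows = training variant, cols = test variant."""

    table: pd.DataFrame  # mean over seeds, percentage points
    seeds: tuple

    def cell(self, train: str, test: str) -> float:
        return float(self.table.loc[train, test])


def run_crossval(variant_names, hyper: LstmHyperparams, n_train: int = 10_000,
                 n_test: int = 5_000, seeds=(0,), include_all: bool = True,
                 apply_selection: bool = True) -> CrossValMatrix:
    """Train one model per tissue variant (plus an equal-mixture ALL row) and
    evaluate every model on every variant's held-out data."""
    if len(variant_names) < 2:
        raise ValueError("need at least two variants")
    acc = None
    for s in seeds:
        train_sets = {}
        for name in variant_names:
            cfg = variant(name)
            train_sets[name] = prepare_training_set(cfg, n_train, seed=cfg.seed + 30_000 + s,
                                                    apply_selection=apply_selection)
        if include_all:
            n_each = max(1, n_train // len(variant_names))
            parts = [ts.take(np.arange(n_each)) for ts in train_sets.values()]
            train_sets["ALL"] = SpectraDataset.concatenate(parts, variant="ALL")
        test_sets = {}
        for name in variant_names:
            cfg = variant(name)
            raw = generate_dataset(replace(cfg, n_spectra=n_test, seed=cfg.seed + 40_000 + s))
            test_sets[name] = zscore(raw)
        mat = pd.DataFrame(index=list(train_sets), columns=list(test_sets), dtype=float)
        for tr_name, ts in train_sets.items():
            res = train_lstm(ts, hyper, seed=s)
            for te_name, te in test_sets.items():
                mat.loc[tr_name, te_name] = median_abs_error(res.predict(te), te.so2)
        acc = mat if acc is None else acc + mat
    return CrossValMatrix(table=acc / len(seeds), seeds=tuple(seeds))


# --- experiment 3: JS-distance vs error study -------------------------------

def flag_outliers(scores, errors, k_iqr: float = 2.0) -> np.ndarray:
    """Flag points whose residual from the least-squares score-error line
    exceeds ``k_iqr`` interquartile ranges."""
    scores = np.asarray(scores, dtype=float)
    errors = np.asarray(errors, dtype=float)
    slope, intercept = np.polyfit(scores, errors, 1)
    resid = errors - (slope * scores + intercept)
    q1, q3 = np.percentile(resid, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return np.zeros(scores.size, dtype=bool)
    return np.abs(resid - np.median(resid)) > k_iqr * iqr


def run_djs_study(variant_names, target_variant: str, hyper: LstmHyperparams,
                  n_train: int = 10_000, n_test: int = 5_000,
                  n_subsample: int = 5_000, repeats: int = 5, seeds=(0,),
                  apply_selection: bool = True) -> dict:
    """For each candidate variant, compute its JS distance to the target and
    the error of a model trained on it, then correlate the two.

    Returns {"table": DataFrame (candidate, djs_bar, epsilon_pp, outlier,
    per-seed columns), "pearson_r": float, "pearson_r_clean": float}.
    """
    target_cfg = variant(target_variant)
    per_seed = []
    for s in seeds:
        target_raw = generate_dataset(replace(target_cfg, n_spectra=n_test,
                                              seed=target_cfg.seed + 50_000 + s))
        target_z = zscore(target_raw)
        rows = []
        for name in variant_names:
            cfg = variant(name)
            ts = prepare_training_set(cfg, n_train, seed=cfg.seed + 60_000 + s,
                                      apply_selection=apply_selection)
            score = djs_bar(ts, target_z, n_subsample=n_subsample,
                            repeats=repeats, seed=s).djs_bar
            res = train_lstm(ts, hyper, seed=s)
            eps = median_abs_error(res.predict(target_z), target_z.so2)
            rows.append({"candidate": name, "djs_bar": score, "epsilon_pp": eps, "seed": s})
        per_seed.append(pd.DataFrame(rows))
    df = pd.concat(per_seed, ignore_index=True)
    agg = df.groupby("candidate", sort=False).mean(numeric_only=True).drop(columns="seed").reset_index()
    agg["outlier"] = flag_outliers(agg["djs_bar"], agg["epsilon_pp"])
    r = correlate_djs_error(agg["djs_bar"], agg["epsilon_pp"])
    clean = agg[~agg["outlier"]]
    r_clean = (correlate_djs_error(clean["djs_bar"], clean["epsilon_pp"])
               if len(clean) >= 3 and clean["djs_bar"].nunique() > 1 else r)
    agg = agg.sort_values("djs_bar", kind="stable").reset_index(drop=True)
    return {"table": agg, "per_seed": df, "pearson_r": r, "pearson_r_clean": r_clean}


# --- optional plots ---------------------------------------------------------

def plot_crossval_heatmap(matrix: CrossValMatrix, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(matrix.table.values.astype(float), cmap="viridis")
    ax.set_xticks(range(len(matrix.table.columns)), matrix.table.columns, rotation=90)
    ax.set_yticks(range(len(matrix.table.index)), matrix.table.index)
    ax.set_xlabel("test variant")
    ax.set_ylabel("training variant")
    fig.colorbar(im, label="median |sO2 error| (pp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_djs_scatter(study: dict, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = study["table"]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(tab["djs_bar"], tab["epsilon_pp"],
               c=np.where(tab["outlier"], "tab:red", "tab:blue"))
    for _, row in tab.iterrows():
        ax.annotate(row["candidate"], (row["djs_bar"], row["epsilon_pp"]), fontsize=7)
    ax.set_xlabel("aggregate JS distance")
    ax.set_ylabel("median |sO2 error| (pp)")
    ax.set_title(f"Pearson r = {study['pearson_r']:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
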