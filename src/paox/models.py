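"""sO2 estimators: the wavelength-flexible masked-LSTM regressor, the
fixed-wavelength learned-spectral-decoloring (LSD) baseline, and linear
unmixing.

The learned estimators follow the model/results convention: a model object
is built from a training dataset, ``fit()`` runs the training schedule and
returns an :class:`OximeterResults` carrying the trained weights, the
per-epoch history, and prediction/summary/checkpoint methods.

Both learned estimators regress sO2 from per-spectrum z-scored amplitude
spectra with a mean-absolute-error loss; a final sigmoid constrains
estimates to [0, 1].  The LSTM consumes the 41-slot spectrum as a sequence
and ignores masked wavelengths, so one trained network can be applied to
any wavelength subset.  The LSD baseline deliberately rejects masked input:
its inflexibility is what the recurrent architecture removes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import nn
from .chromophores import ChromophoreTable, WavelengthGrid, default_table, N_CHANNELS
from .preprocess import is_zscored
from .synthgen import SpectraDataset


@dataclass
class LstmHyperparams:
    """Architecture and training-schedule constants.

    ``fc_input`` is the flattened encoding width: 41 steps x 100 hidden
    = 4100 units feeding the dense head.
    """

    input_slots: int = N_CHANNELS
    lstm_hidden: int = 100
    fc_hidden: int = 1000
    epochs: int = 100
    initial_lr: float = 1e-3
    lr_factor: float = 0.5
    lr_patience: int = 5
    min_lr: float = 1e-6
    batch_size: int = 1024
    val_fraction: float = 0.2
    leaky_alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must be in (0, 1)")

    @property
    def fc_input(self) -> int:
        return self.input_slots * self.lstm_hidden


def _check_training_inputs(dataset: SpectraDataset) -> None:
    if not is_zscored(dataset, tol=1e-4):
        raise ValueError("training spectra must be z-scored per spectrum")
    if np.any((dataset.so2 < 0) | (dataset.so2 > 1)):
        raise ValueError("labels must be sO2 fractions in [0, 1]")


def _check_predict_inputs(dataset: SpectraDataset, grid: WavelengthGrid) -> None:
    if not np.array_equal(dataset.grid.wavelengths, grid.wavelengths):
        raise ValueError("dataset wavelength grid does not match the model grid")
    if np.any(dataset.mask.sum(axis=1) == 0):
        raise ValueError("dataset contains fully masked spectra")


class LstmOximeter:
    """Masked-LSTM sO2 regression model built from a z-scored training set."""

    kind = "lstm"

    def __init__(self, train_set: SpectraDataset, hyperparams: LstmHyperparams | None = None):
        _check_training_inputs(train_set)
        self.train_set = train_set
        self.hyper = hyperparams or LstmHyperparams()

    def fit(self, seed: int | None = None, verbose: bool = False) -> "OximeterResults":
        h = self.hyper
        seed = h.seed if seed is None else int(seed)
        net = nn.MaskedLstmNet(n_steps=h.input_slots, hidden=h.lstm_hidden,
                               fc_hidden=h.fc_hidden, leaky_alpha=h.leaky_alpha, seed=seed)
        history = nn.fit_network(
            net, self.train_set.amplitudes, self.train_set.mask, self.train_set.so2,
            epochs=h.epochs, batch_size=h.batch_size, initial_lr=h.initial_lr,
            lr_factor=h.lr_factor, lr_patience=h.lr_patience, min_lr=h.min_lr,
            val_fraction=h.val_fraction, seed=seed, verbose=verbose)
        return OximeterResults(
            kind=self.kind, net=net, hyper=h, grid=self.train_set.grid,
            history=pd.DataFrame(history),
            trained_nlambda=int(round(self.train_set.mask.sum(axis=1).mean())),
            trained_variant=self.train_set.variant, seed=seed)


class LsdOximeter:
    """Learned-spectral-decoloring baseline: dense net on the full spectrum."""

    kind = "lsd"

    def __init__(self, train_set: SpectraDataset, hidden: tuple[int, int] = (1000, 1000),
                 hyperparams: LstmHyperparams | None = None):
        _check_training_inputs(train_set)
        if not np.all(train_set.mask):
            raise ValueError("LSD requires the full wavelength set (no masked slots)")
        self.train_set = train_set
        self.hidden = tuple(hidden)
        self.hyper = hyperparams or LstmHyperparams()

    def fit(self, seed: int | None = None, verbose: bool = False) -> "OximeterResults":
        h = self.hyper
        seed = h.seed if seed is None else int(seed)
        net = nn.FeedforwardNet(n_inputs=h.input_slots, hidden=self.hidden,
                                leaky_alpha=h.leaky_alpha, seed=seed)
        history = nn.fit_network(
            net, self.train_set.amplitudes, self.train_set.mask, self.train_set.so2,
            epochs=h.epochs, batch_size=h.batch_size, initial_lr=h.initial_lr,
            lr_factor=h.lr_factor, lr_patience=h.lr_patience, min_lr=h.min_lr,
            val_fraction=h.val_fraction, seed=seed, verbose=verbose)
        return OximeterResults(
            kind=self.kind, net=net, hyper=h, grid=self.train_set.grid,
            history=pd.DataFrame(history),
            trained_nlambda=h.input_slots,
            trained_variant=self.train_set.variant, seed=seed, lsd_hidden=self.hidden)


@dataclass
class OximeterResults:
    """A trained sO2 estimator with its training history and provenance."""

    kind: str
    net: object
    hyper: LstmHyperparams
    grid: WavelengthGrid
    history: pd.DataFrame
    trained_nlambda: int
    trained_variant: str
    seed: int
    lsd_hidden: tuple[int, int] | None = None

    def predict(self, dataset: SpectraDataset) -> np.ndarray:
        """sO2 estimates (fractions in [0, 1]), one per spectrum.

        Requires per-spectrum z-scored amplitudes; the LSTM accepts any
        mask pattern regardless of the wavelength count seen in training.
        """
        _check_predict_inputs(dataset, self.grid)
        if not is_zscored(dataset, tol=1e-4):
            raise ValueError("spectra must be z-scored before prediction")
        return nn.predict_network(self.net, dataset.amplitudes, dataset.mask)

    def epsilon_so2(self, dataset: SpectraDataset) -> float:
        """Median absolute estimation error in percentage points."""
        from .evaluation import median_abs_error

        return median_abs_error(self.predict(dataset), dataset.so2)

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.net.params.values()))

    def summary(self) -> str:
        h = self.history
        lines = [
            f"{'=' * 58}",
            f"{'Photoacoustic oximetry regression results':^58}",
            f"{'=' * 58}",
            f"Estimator:          {self.kind.upper()}",
            f"Training variant:   {self.trained_variant}",
            f"Trained N_lambda:   {self.trained_nlambda}",
            f"Parameters:         {self.n_parameters:,}",
            f"Epochs:             {len(h)}",
            f"Final train MAE:    {h['train_loss'].iloc[-1]:.4f}",
            f"Final val MAE:      {h['val_loss'].iloc[-1]:.4f}",
            f"Best val MAE:       {h['val_loss'].min():.4f} (epoch {int(h.loc[h['val_loss'].idxmin(), 'epoch'])})",
            f"Final lr:           {h['lr'].iloc[-1]:.2e}",
            f"Seed:               {self.seed}",
            f"{'=' * 58}",
        ]
        return "\n".join(lines)

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "kind": self.kind,
            "hyper": asdict(self.hyper),
            "trained_nlambda": self.trained_nlambda,
            "trained_variant": self.trained_variant,
            "seed": self.seed,
            "lsd_hidden": list(self.lsd_hidden) if self.lsd_hidden else None,
            "history": self.history.to_dict(orient="list"),
        }
        arrays = {f"param_{k}": v for k, v in self.net.params.items()}
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "OximeterResults":
        from .chromophores import default_grid

        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            params = {k[len("param_"):]: f[k] for k in f.files if k.startswith("param_")}
        h = LstmHyperparams(**meta["hyper"])
        if meta["kind"] == "lstm":
            net = nn.MaskedLstmNet(n_steps=h.input_slots, hidden=h.lstm_hidden,
                                   fc_hidden=h.fc_hidden, leaky_alpha=h.leaky_alpha, seed=0)
        else:
            net = nn.FeedforwardNet(n_inputs=h.input_slots, hidden=tuple(meta["lsd_hidden"]),
                                    leaky_alpha=h.leaky_alpha, seed=0)
        net.params = params
        return cls(kind=meta["kind"], net=net, hyper=h, grid=default_grid(),
                   history=pd.DataFrame(meta["history"]),
                   trained_nlambda=meta["trained_nlambda"],
                   trained_variant=meta["trained_variant"], seed=meta["seed"],
                   lsd_hidden=tuple(meta["lsd_hidden"]) if meta["lsd_hidden"] else None)


# --- linear unmixing --------------------------------------------------------

def linear_unmixing(amplitudes, mask=None, table: ChromophoreTable | None = None) -> float:
    """Estimate sO2 of one spectrum by non-negative least squares against the
    oxy-/deoxyhemoglobin basis over the present wavelengths.

    Fits amplitudes ~ a*mu_a_HbO2 + b*mu_a_Hb with a, b >= 0 and returns
    a/(a+b); scale-invariant in the input.  Returns 0.5 for the degenerate
    all-zero fit.  Falls back to a fine grid search over s when NNLS fails
    to converge.
    """
    table = table if table is not None else default_table()
    amps = np.asarray(amplitudes, dtype=float)
    m = np.ones(amps.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if m.sum() < 2:
        raise ValueError("need at least 2 present wavelengths")
    y = amps[m]
    if np.ptp(y) == 0:
        raise ValueError("constant spectrum cannot be unmixed")
    A = np.column_stack([table.mu_a_hbo2[m], table.mu_a_hb[m]])
    try:
        coef, _ = nnls(A, y)
    except RuntimeError:
        return _lu_grid_search(A, y)
    a, b = coef
    if a == 0.0 and b == 0.0:
        return 0.5
    return float(a / (a + b))


def _lu_grid_search(A, y, step=1e-4):
    # residual of the unit-normalized model spectrum, tie-break toward lower s
    s_grid = np.arange(0.0, 1.0 + step / 2, step)
    models = np.outer(A[:, 0], s_grid) + np.outer(A[:, 1], 1.0 - s_grid)
    models /= np.linalg.norm(models, axis=0, keepdims=True)
    yn = y / np.linalg.norm(y)
    resid = np.linalg.norm(models - yn[:, None], axis=0)
    return float(s_grid[int(np.argmin(resid))])


def linear_unmixing_dataset(dataset: SpectraDataset, table: ChromophoreTable | None = None) -> np.ndarray:
    """Linear unmixing applied row-wise to a dataset (raw amplitudes)."""
    table = table if table is not None else default_table()
    return np.array([
        linear_unmixing(dataset.amplitudes[i], dataset.mask[i], table)
        for i in range(len(dataset))
    ])
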