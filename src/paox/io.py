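"""Dataset readers/writers (HDF5 and CSV) and the bundled test fixtures.

HDF5 layout: /spectra (n x 41 float), /mask (n x 41 uint8), /labels (n sO2
fractions), /depth (n mm), and dataset-level attrs carrying variant name,
seed, generator version, and the wavelength grid.  The flat CSV export has
one row per spectrum: 41 amplitude columns, so2_true, depth, variant.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .chromophores import N_CHANNELS, default_grid
from .synthgen import (GENERATOR_VERSION, SpectraDataset, analytic_config,
                       generate_dataset, variant)

_AMP_COLS = [f"amp_{int(w)}" for w in default_grid().wavelengths]


def write_dataset(dataset: SpectraDataset, path) -> None:
    path = Path(path)
    if path.suffix in (".csv", ".txt"):
        _write_csv(dataset, path)
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=dataset.amplitudes)
        f.create_dataset("mask", data=dataset.mask.astype(np.uint8))
        f.create_dataset("labels", data=dataset.so2)
        f.create_dataset("depth", data=dataset.depth)
        f.attrs["variant"] = dataset.variant
        f.attrs["grid_nm"] = dataset.grid.wavelengths
        f.attrs["provenance"] = json.dumps(dataset.provenance, default=str)


def read_dataset(path) -> SpectraDataset:
    path = Path(path)
    if path.suffix in (".csv", ".txt"):
        return _read_csv(path)
    with h5py.File(path, "r") as f:
        for key in ("spectra", "mask", "labels"):
            if key not in f:
                raise ValueError(f"dataset file {path} is missing required group /{key}")
        amps = f["spectra"][()]
        if amps.ndim != 2 or amps.shape[1] != N_CHANNELS:
            raise ValueError(
                f"/spectra must have {N_CHANNELS} spectral columns, got {amps.shape}")
        mask = f["mask"][()].astype(bool)
        so2 = f["labels"][()]
        depth = f["depth"][()] if "depth" in f else np.zeros(amps.shape[0])
        provenance = json.loads(f.attrs.get("provenance", "{}")) or {"source": str(path)}
        return SpectraDataset(amplitudes=amps, mask=mask, so2=so2, depth=depth,
                              grid=default_grid(), variant=str(f.attrs.get("variant", "unknown")),
                              provenance=provenance)


def _write_csv(dataset: SpectraDataset, path) -> None:
    df = pd.DataFrame(np.where(dataset.mask, dataset.amplitudes, 0.0), columns=_AMP_COLS)
    df["so2_true"] = dataset.so2
    df["depth"] = dataset.depth
    df["variant"] = dataset.variant
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({"provenance": dataset.provenance,
                                   "mask_note": "zeros in amplitude columns at masked slots"},
                                  default=str))


def _read_csv(path) -> SpectraDataset:
    df = pd.read_csv(path)
    missing = [c for c in _AMP_COLS + ["so2_true"] if c not in df.columns]
    if missing:
        raise ValueError(f"CSV dataset {path} is missing columns: {missing[:3]}...")
    amps = df[_AMP_COLS].to_numpy(dtype=float)
    sidecar = Path(str(path) + ".json")
    provenance = (json.loads(sidecar.read_text()).get("provenance", {})
                  if sidecar.exists() else {"source": str(path)})
    variant_name = str(df["variant"].iloc[0]) if "variant" in df.columns else "unknown"
    # masked slots are stored as exact zeros in the flat export
    mask = amps != 0.0
    return SpectraDataset(
        amplitudes=amps, mask=mask, so2=df["so2_true"].to_numpy(dtype=float),
        depth=df["depth"].to_numpy(dtype=float) if "depth" in df.columns else np.zeros(len(df)),
        grid=default_grid(), variant=variant_name,
        provenance=provenance or {"source": str(path)})


def write_estimates(path, estimates, so2_true=None, model_id: str = "") -> None:
    """Estimates CSV: spectrum_id, so2_estimate, so2_true (blank if unknown), model_id."""
    n = len(estimates)
    df = pd.DataFrame({
        "spectrum_id": np.arange(n),
        "so2_estimate": np.asarray(estimates, dtype=float),
        "so2_true": (np.asarray(so2_true, dtype=float) if so2_true is not None
                     else np.full(n, np.nan)),
        "model_id": model_id,
    })
    df.to_csv(path, index=False, float_format="%.6g")


def make_fixtures(out_dir, seed: int = 1234, n_spectra: int = 500) -> dict[str, Path]:
    """Small deterministic datasets for offline testing.

    BASE, SKIN and WATER_4cm surrogates plus a noiseless attenuation-free
    ``analytic`` set whose spectra are exactly blood-absorption shaped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    configs = [variant(n, n_spectra=n_spectra, seed=seed) for n in ("BASE", "SKIN", "WATER_4cm")]
    configs.append(analytic_config(n_spectra=n_spectra, seed=seed))
    manifest = {}
    for cfg in configs:
        ds = generate_dataset(cfg)
        p = out_dir / f"{cfg.name}.h5"
        write_dataset(ds, p)
        paths[cfg.name] = p
        manifest[cfg.name] = {"file": p.name, "n": n_spectra, "seed": seed,
                              "generator_version": GENERATOR_VERSION}
    (out_dir / "fixtures_manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths
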