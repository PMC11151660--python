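"""Analytic surrogate generator for spectrally colored vessel spectra.

Replaces the Monte Carlo + acoustic simulation pipeline that would normally
produce photoacoustic training data with a 1-D layered diffusion-approximation
model.  Light entering the tissue is attenuated by (optionally) a water
coupling layer, a melanin-bearing skin layer, and a blood-perfused background,
each with an effective attenuation mu_eff = sqrt(3 mu_a (mu_a + mu_s')); a
geometric divergence factor stands in for the illumination geometry.  The
initial-pressure amplitude of a vessel at depth z is then

    p0(lambda) = G(z) * exp(-tau(lambda, z)) * mu_a_blood(lambda, sO2) * V(r, lambda)

where V is a mean intra-vessel fluence factor capturing the radius-dependent
self-coloring of larger vessels.  Each named tissue variant perturbs exactly
one aspect of the BASE tissue assumption (background oxygenation, skin,
water coupling, vessel size, illumination, or grid resolution), mirroring
the structure of a family of simulated training datasets.

Everything is deterministic given the config (including its seed): every
random field draws from its own counter-based Philox stream keyed by
(seed, field id), so draws for spectrum i do not depend on how many spectra
are requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterator

import numpy as np
import yaml

from .chromophores import ChromophoreTable, WavelengthGrid, default_table, blood_absorption

GENERATOR_VERSION = "1.0"

_FIELD_IDS = {
    "so2": 1,
    "radius": 2,
    "depth": 3,
    "bg_so2": 4,
    "melanosome": 5,
    "noise": 6,
    "het": 7,
}


def _stream(seed: int, fieldname: str) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=np.random.SeedSequence((int(seed), _FIELD_IDS[fieldname])).generate_state(2, np.uint64)))


@dataclass
class TissueVariantConfig:
    """Parameters of one simulated tissue variant.

    Distributions are (low, high) uniform bounds; a point value is encoded
    as low == high.  Thicknesses and depths in mm; fractions in [0, 1].
    """

    name: str = "BASE"
    bg_so2_dist: tuple[float, float] = (0.70, 0.70)
    bg_heterogeneous: bool = False
    bg_bvf: float = 0.01
    bg_water_fraction: float = 0.8
    skin_thickness: float = 0.0  # mm, 0 = no skin layer
    melanosome_fraction_dist: tuple[float, float] = (0.0, 0.0)
    water_layer: float = 0.0  # mm of coupling water above the tissue
    vessel_radius_dist: tuple[float, float] = (0.15, 1.0)  # mm
    vessel_depth_dist: tuple[float, float] = (0.5, 9.0)  # mm below tissue surface
    illumination_spread: float = 0.0  # geometric divergence exponent, 0 = broad beam
    illumination_z0: float = 1.0  # mm divergence length scale
    grid_spacing: float = 0.3  # mm, depth/radius quantization
    quantize_to_grid: bool = True
    het_correlation_mm: float = 1.2  # depth correlation length of background jitter
    noise_sigma: float = 0.02  # relative multiplicative noise
    n_spectra: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for dname in ("bg_so2_dist", "melanosome_fraction_dist", "vessel_radius_dist", "vessel_depth_dist"):
            lo, hi = getattr(self, dname)
            if lo > hi:
                raise ValueError(f"{dname}: low {lo} > high {hi}")
        for dname in ("bg_so2_dist", "melanosome_fraction_dist"):
            lo, hi = getattr(self, dname)
            if lo < 0.0 or hi > 1.0:
                raise ValueError(f"{dname} bounds must lie in [0, 1]")
        if not 0.0 <= self.bg_bvf <= 1.0:
            raise ValueError("bg_bvf must be in [0, 1]")
        if not 0.0 <= self.bg_water_fraction <= 1.0:
            raise ValueError("bg_water_fraction must be in [0, 1]")
        for sname in ("skin_thickness", "water_layer", "illumination_spread", "noise_sigma"):
            if getattr(self, sname) < 0:
                raise ValueError(f"{sname} must be non-negative")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.illumination_z0 <= 0:
            raise ValueError("illumination_z0 must be positive")
        if self.vessel_depth_dist[0] < self.skin_thickness:
            raise ValueError("vessel depth range must start below the skin layer")

    # -- structured-text round trip ---------------------------------------
    def to_yaml(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TissueVariantConfig":
        d = yaml.safe_load(text)
        for k in ("bg_so2_dist", "melanosome_fraction_dist", "vessel_radius_dist", "vessel_depth_dist"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class LabeledSpectrum:
    """One per-pixel amplitude spectrum with its ground-truth label."""

    amplitudes: np.ndarray  # 41 values, masked-out slots stored as 0
    mask: np.ndarray  # 41 booleans
    so2_true: float
    depth: float
    variant: str


@dataclass
class SpectraDataset:
    """A collection of labeled spectra sharing one wavelength grid."""

    amplitudes: np.ndarray  # (n, 41)
    mask: np.ndarray  # (n, 41) bool
    so2: np.ndarray  # (n,)
    depth: np.ndarray  # (n,)
    grid: WavelengthGrid
    variant: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.so2 = np.asarray(self.so2, dtype=np.float64)
        self.depth = np.asarray(self.depth, dtype=np.float64)
        n = self.amplitudes.shape[0]
        if self.amplitudes.shape != (n, len(self.grid)) or self.mask.shape != (n, len(self.grid)):
            raise ValueError("amplitudes/mask must be (n, 41)")
        if self.so2.shape != (n,) or self.depth.shape != (n,):
            raise ValueError("labels must be (n,)")
        if not self.provenance:
            raise ValueError("provenance must be non-empty")
        if np.any((self.so2 < 0) | (self.so2 > 1)):
            raise ValueError("sO2 labels must lie in [0, 1]")

    def __len__(self) -> int:
        return self.amplitudes.shape[0]

    def __getitem__(self, i: int) -> LabeledSpectrum:
        return LabeledSpectrum(self.amplitudes[i], self.mask[i], float(self.so2[i]), float(self.depth[i]), self.variant)

    def __iter__(self) -> Iterator[LabeledSpectrum]:
        for i in range(len(self)):
            yield self[i]

    def take(self, idx) -> "SpectraDataset":
        """Row subset/reorder preserving provenance."""
        return SpectraDataset(
            self.amplitudes[idx], self.mask[idx], self.so2[idx], self.depth[idx],
            self.grid, self.variant, dict(self.provenance),
        )

    @staticmethod
    def concatenate(datasets: list["SpectraDataset"], variant: str = "ALL") -> "SpectraDataset":
        grid = datasets[0].grid
        return SpectraDataset(
            np.concatenate([d.amplitudes for d in datasets]),
            np.concatenate([d.mask for d in datasets]),
            np.concatenate([d.so2 for d in datasets]),
            np.concatenate([d.depth for d in datasets]),
            grid, variant,
            {"variant": variant, "members": [d.variant for d in datasets],
             "generator_version": GENERATOR_VERSION},
        )


# --- physics helpers --------------------------------------------------------

def _mu_eff(mu_a: np.ndarray, mu_s_prime: np.ndarray) -> np.ndarray:
    return np.sqrt(3.0 * mu_a * (mu_a + mu_s_prime))


def _bg_mu_a(so2_bg, config: TissueVariantConfig, table: ChromophoreTable) -> np.ndarray:
    """Background absorption: perfusing blood plus tissue water. Broadcasts so2_bg."""
    s = np.asarray(so2_bg, dtype=float)[..., None]
    blood = config.bg_bvf * (s * table.mu_a_hbo2 + (1.0 - s) * table.mu_a_hb)
    return blood + config.bg_water_fraction * table.mu_a_water


def _geometry_factor(depth, config: TissueVariantConfig) -> np.ndarray:
    z = np.asarray(depth, dtype=float)
    return (1.0 + z / config.illumination_z0) ** (-config.illumination_spread)


def fluence_at_depth(depth: float, lam_index: int, config: TissueVariantConfig,
                     table: ChromophoreTable, bg_so2_sample: float,
                     melanosome_sample: float) -> float:
    """Relative fluence at one depth and wavelength for a homogeneous background.

    Phi(lambda, z) = G(z) * exp(-mu_a_water d_water - mu_eff_skin d_skin
                                - mu_eff_bg z),  G(z) = (1 + z/z0)^(-spread).
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    mu_sp = table.mu_s_prime_bg[lam_index]
    tau = config.water_layer * table.mu_a_water[lam_index]
    if config.skin_thickness > 0:
        mua_skin = melanosome_sample * table.mu_a_melanin_ref[lam_index]
        tau += config.skin_thickness * _mu_eff(mua_skin, mu_sp)
    mua_bg = _bg_mu_a(float(bg_so2_sample), config, table)[lam_index]
    tau += depth * _mu_eff(mua_bg, mu_sp)
    return float(_geometry_factor(depth, config) * np.exp(-tau))


def _vessel_size_factor(mu_a_vessel: np.ndarray, radius: np.ndarray) -> np.ndarray:
    """Mean intra-vessel fluence of an absorbing slab of thickness 2r.

    V = (1 - exp(-2 mu_a r)) / (2 mu_a r), with the r -> 0 limit V = 1.
    """
    x = 2.0 * mu_a_vessel * radius[:, None]
    out = np.ones_like(x)
    nz = x > 1e-12
    out[nz] = -np.expm1(-x[nz]) / x[nz]
    return out


def _quantize(values: np.ndarray, spacing: float, minimum: float) -> np.ndarray:
    q = np.round(values / spacing) * spacing
    return np.maximum(q, minimum)


def generate_dataset(config: TissueVariantConfig, table: ChromophoreTable | None = None) -> SpectraDataset:
    """Generate ``config.n_spectra`` labeled, spectrally colored vessel spectra."""
    if config.n_spectra <= 0:
        raise ValueError("n_spectra must be positive")
    table = table if table is not None else default_table()
    grid = table.grid
    n = config.n_spectra
    nl = len(grid)

    so2 = _stream(config.seed, "so2").random(n)
    rlo, rhi = config.vessel_radius_dist
    radius = rlo + (rhi - rlo) * _stream(config.seed, "radius").random(n)
    dlo, dhi = config.vessel_depth_dist
    depth = dlo + (dhi - dlo) * _stream(config.seed, "depth").random(n)
    blo, bhi = config.bg_so2_dist
    bg_so2 = blo + (bhi - blo) * _stream(config.seed, "bg_so2").random(n)
    mlo, mhi = config.melanosome_fraction_dist
    melano = mlo + (mhi - mlo) * _stream(config.seed, "melanosome").random(n)

    if config.quantize_to_grid:
        depth = _quantize(depth, config.grid_spacing, config.grid_spacing / 2.0)
        radius = _quantize(radius, config.grid_spacing / 2.0, config.grid_spacing / 4.0)

    mu_sp = table.mu_s_prime_bg  # (41,)
    # optical depth through coupling water and skin
    tau = np.zeros((n, nl))
    tau += config.water_layer * table.mu_a_water
    if config.skin_thickness > 0:
        mua_skin = melano[:, None] * table.mu_a_melanin_ref
        tau += config.skin_thickness * _mu_eff(mua_skin, mu_sp)

    if config.bg_heterogeneous:
        # depth-correlated AR(1) jitter of the background oxygenation,
        # integrated bin-by-bin over the quantized depth column
        dz = config.grid_spacing
        n_bins = int(np.ceil(config.vessel_depth_dist[1] / dz))
        rho = np.exp(-dz / config.het_correlation_mm)
        eps = _stream(config.seed, "het").standard_normal((n, n_bins))
        ar = np.empty((n, n_bins))
        ar[:, 0] = eps[:, 0]
        for k in range(1, n_bins):
            ar[:, k] = rho * ar[:, k - 1] + np.sqrt(1.0 - rho ** 2) * eps[:, k]
        half_range = (bhi - blo) / 2.0
        s_prof = np.clip(bg_so2[:, None] + half_range * 0.5 * ar, 0.0, 1.0)
        weights = np.clip(depth[:, None] - np.arange(n_bins) * dz, 0.0, dz)  # (n, K)
        mua_prof = _bg_mu_a(s_prof, config, table)  # (n, K, 41)
        tau += np.einsum("nk,nkl->nl", weights, _mu_eff(mua_prof, mu_sp))
    else:
        mua_bg = _bg_mu_a(bg_so2, config, table)  # (n, 41)
        tau += depth[:, None] * _mu_eff(mua_bg, mu_sp)

    fluence = _geometry_factor(depth, config)[:, None] * np.exp(-tau)
    mu_a_vessel = so2[:, None] * table.mu_a_hbo2 + (1.0 - so2[:, None]) * table.mu_a_hb
    amplitudes = fluence * mu_a_vessel * _vessel_size_factor(mu_a_vessel, radius)

    if config.noise_sigma > 0:
        noise = _stream(config.seed, "noise").standard_normal((n, nl))
        amplitudes = amplitudes * (1.0 + config.noise_sigma * noise)
    amplitudes = np.maximum(amplitudes, 0.0)

    return SpectraDataset(
        amplitudes=amplitudes,
        mask=np.ones((n, nl), dtype=bool),
        so2=so2,
        depth=depth,
        grid=grid,
        variant=config.name,
        provenance={"variant": config.name, "seed": int(config.seed),
                    "generator_version": GENERATOR_VERSION},
    )


# --- built-in tissue variants ----------------------------------------------

def builtin_variants(n_spectra: int = 1000, seed: int = 0) -> list[TissueVariantConfig]:
    """The named tissue variants representable in the 1-D surrogate.

    Acoustic-modeling and device-twin variants are out of surrogate scope
    and deliberately absent.
    """
    base = TissueVariantConfig(name="BASE", n_spectra=n_spectra, seed=seed)
    mk = lambda name, **kw: replace(base, name=name, **kw)
    return [
        base,
        mk("BG_0-100", bg_so2_dist=(0.0, 1.0)),
        mk("BG_60-80", bg_so2_dist=(0.6, 0.8)),
        mk("BG_H2O", bg_bvf=0.0, bg_water_fraction=1.0),
        mk("HET_0-100", bg_so2_dist=(0.0, 1.0), bg_heterogeneous=True),
        mk("HET_60-80", bg_so2_dist=(0.6, 0.8), bg_heterogeneous=True),
        mk("RES_0.15", grid_spacing=0.15),
        mk("RES_0.15_SMALL", grid_spacing=0.15, vessel_radius_dist=(0.075, 0.5)),
        mk("RES_0.6", grid_spacing=0.6),
        mk("RES_1.2", grid_spacing=1.2),
        mk("SKIN", skin_thickness=0.3, melanosome_fraction_dist=(0.001, 0.05)),
        mk("ILLUM_5mm", illumination_spread=1.0, illumination_z0=5.0),
        mk("ILLUM_POINT", illumination_spread=2.0, illumination_z0=1.0),
        mk("SMALL", vessel_radius_dist=(0.075, 0.5)),
        mk("WATER_2cm", water_layer=20.0),
        mk("WATER_4cm", water_layer=40.0),
    ]


def variant(name: str, n_spectra: int = 1000, seed: int = 0) -> TissueVariantConfig:
    """Look up one built-in variant by name."""
    for cfg in builtin_variants(n_spectra=n_spectra, seed=seed):
        if cfg.name == name:
            return cfg
    raise KeyError(f"unknown variant {name!r}")


def analytic_config(n_spectra: int = 1000, seed: int = 0) -> TissueVariantConfig:
    """Noiseless, attenuation-free configuration: spectra are exactly
    proportional to the blood absorption at the drawn sO2 (linear-unmixing
    oracle fixture)."""
    return TissueVariantConfig(
        name="ANALYTIC", bg_so2_dist=(0.7, 0.7), bg_bvf=0.0, bg_water_fraction=0.0,
        skin_thickness=0.0, water_layer=0.0, vessel_radius_dist=(0.0, 0.0),
        vessel_depth_dist=(0.5, 9.0), illumination_spread=0.0, quantize_to_grid=False,
        noise_sigma=0.0, n_spectra=n_spectra, seed=seed,
    )
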