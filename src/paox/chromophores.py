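"""Optical properties of the tissue chromophores used in photoacoustic oximetry.

The package works on a fixed 41-channel wavelength lattice covering
700-900 nm in 5 nm steps, the range where oxy- and deoxyhemoglobin
differences drive sO2 contrast.  This module embeds absorption spectra for
whole blood (150 g/L hemoglobin), pure water and melanosomes on that grid,
provides the linear blood-absorption mixing model, and the Severinghaus
conversion from oxygen partial pressure to hemoglobin saturation.

Units: wavelengths in nm, absorption and reduced scattering coefficients in
mm^-1, sO2 as a fraction in [0, 1].
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "ChromophoreTable",
    "default_grid",
    "default_table",
    "blood_absorption",
    "severinghaus_so2",
]

GRID_START_NM = 700.0
GRID_STOP_NM = 900.0
GRID_STEP_NM = 5.0
N_CHANNELS = 41


@dataclass(frozen=True)
class WavelengthGrid:
    """The fixed 700-900 nm, 5 nm lattice every spectrum in the package lives on.

    Spectra with fewer wavelengths are represented on the full 41-slot grid
    with a boolean presence mask, so a single model can consume any subset.
    """

    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(GRID_START_NM, GRID_STOP_NM + GRID_STEP_NM, GRID_STEP_NM)
    )

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.shape != (N_CHANNELS,):
            raise ValueError(f"wavelength grid must have {N_CHANNELS} entries, got {wl.shape}")
        if not np.allclose(np.diff(wl), GRID_STEP_NM):
            raise ValueError("wavelength grid must be uniform with 5 nm step")
        if wl[0] != GRID_START_NM or wl[-1] != GRID_STOP_NM:
            raise ValueError("wavelength grid must span 700-900 nm inclusive")
        object.__setattr__(self, "wavelengths", wl)

    @property
    def step(self) -> float:
        return GRID_STEP_NM

    def __len__(self) -> int:
        return N_CHANNELS

    def index_of(self, wavelength_nm: float) -> int:
        """Slot index of an on-grid wavelength; raises if off-grid."""
        idx = (float(wavelength_nm) - GRID_START_NM) / GRID_STEP_NM
        if idx != int(idx) or not 0 <= idx < N_CHANNELS:
            raise ValueError(f"{wavelength_nm} nm is not on the 700-900 nm / 5 nm grid")
        return int(idx)

    def mask_for(self, keep) -> np.ndarray:
        """Boolean mask over the 41 slots for a set of wavelengths."""
        mask = np.zeros(N_CHANNELS, dtype=bool)
        for w in keep:
            mask[self.index_of(w)] = True
        return mask


def default_grid() -> WavelengthGrid:
    return WavelengthGrid()


# --- embedded optical-property anchors -------------------------------------
#
# Molar extinction coefficients of hemoglobin (cm^-1 / M) at 10 nm anchors,
# from the standard tabulated hemoglobin compilation, linearly interpolated
# to the 5 nm grid.  Converted to whole-blood absorption assuming 150 g/L
# total hemoglobin and 64,500 g/mol:
#   mu_a [mm^-1] = ln(10) * eps * (150/64500) / 10.
_ANCHOR_NM = np.arange(700.0, 901.0, 10.0)

_EPS_HBO2 = np.array([
    290.0, 334.0, 376.0, 412.0, 456.0, 518.0, 586.0, 650.0, 710.0, 766.0,
    816.0, 864.0, 916.0, 974.0, 1022.0, 1058.0, 1086.0, 1118.0, 1154.0,
    1186.0, 1198.0,
])
_EPS_HB = np.array([
    1794.0, 1640.0, 1464.0, 1336.0, 1323.0, 1405.0, 1549.0, 1312.0, 1075.0,
    904.0, 762.0, 717.0, 693.0, 694.0, 692.0, 691.0, 691.0, 672.0, 668.0,
    690.0, 762.0,
])

# Pure-water absorption (cm^-1) at the same anchors (standard NIR water
# spectrum: shoulder near 740-760 nm, monotone rise toward 900 nm).
_MUA_WATER_CM = np.array([
    0.0060, 0.0074, 0.0104, 0.0168, 0.0266, 0.0288, 0.0256, 0.0240, 0.0232,
    0.0224, 0.0204, 0.0216, 0.0244, 0.0293, 0.0350, 0.0430, 0.0460, 0.0500,
    0.0550, 0.0600, 0.0679,
])

_HB_MOLAR_MASS = 64500.0  # g/mol
_HB_CONC = 150.0  # g/L whole blood
_EPS_TO_MM = np.log(10.0) * (_HB_CONC / _HB_MOLAR_MASS) / 10.0


@dataclass(frozen=True)
class ChromophoreTable:
    """Absorption spectra (mm^-1) of the model chromophores on the 41-slot grid.

    ``mu_a_hbo2``/``mu_a_hb`` are whole-blood coefficients at 150 g/L
    hemoglobin; ``mu_a_melanin_ref`` is the melanosome-interior reference
    (scaled by the melanosome volume fraction in use); ``mu_s_prime_bg`` is
    the background reduced scattering, flat by default.
    """

    grid: WavelengthGrid
    mu_a_hbo2: np.ndarray
    mu_a_hb: np.ndarray
    mu_a_water: np.ndarray
    mu_a_melanin_ref: np.ndarray
    mu_s_prime_bg: np.ndarray
    source: str = "embedded anchor tables, linear interpolation to 5 nm"

    def __post_init__(self) -> None:
        for name in ("mu_a_hbo2", "mu_a_hb", "mu_a_water", "mu_a_melanin_ref", "mu_s_prime_bg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_CHANNELS,):
                raise ValueError(f"{name} must have {N_CHANNELS} entries")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive and finite")
            object.__setattr__(self, name, arr)

    # -- two-column text round trip -----------------------------------------
    def to_text(self, chromophore: str) -> str:
        """Two-column delimited export (wavelength_nm, value_per_mm)."""
        values = getattr(self, chromophore)
        buf = io.StringIO()
        for wl, v in zip(self.grid.wavelengths, values):
            buf.write(f"{wl:.1f}\t{v:.10g}\n")
        return buf.getvalue()

    @staticmethod
    def column_from_text(text: str) -> tuple[np.ndarray, np.ndarray]:
        """Parse a two-column export back into (wavelengths, values)."""
        rows = [line.split() for line in text.strip().splitlines() if line.strip()]
        arr = np.array(rows, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected two-column wavelength/value text")
        return arr[:, 0], arr[:, 1]


def _melanosome_mua_mm(wavelengths_nm: np.ndarray) -> np.ndarray:
    # standard melanosome power law: mu_a = 1.70e12 * lambda^-3.48 cm^-1
    return 1.70e12 * np.asarray(wavelengths_nm, dtype=float) ** (-3.48) / 10.0


def default_table(mu_s_prime_bg: float = 1.0) -> ChromophoreTable:
    """Build the embedded chromophore table on the default grid.

    ``mu_s_prime_bg`` is constant in wavelength (default 1.0 mm^-1); the
    tissue variants do not vary scattering.
    """
    grid = default_grid()
    wl = grid.wavelengths
    hbo2 = np.interp(wl, _ANCHOR_NM, _EPS_HBO2) * _EPS_TO_MM
    hb = np.interp(wl, _ANCHOR_NM, _EPS_HB) * _EPS_TO_MM
    water = np.interp(wl, _ANCHOR_NM, _MUA_WATER_CM) / 10.0
    return ChromophoreTable(
        grid=grid,
        mu_a_hbo2=hbo2,
        mu_a_hb=hb,
        mu_a_water=water,
        mu_a_melanin_ref=_melanosome_mua_mm(wl),
        mu_s_prime_bg=np.full(N_CHANNELS, float(mu_s_prime_bg)),
    )


def blood_absorption(s, bvf, table: ChromophoreTable) -> np.ndarray:
    """Absorption spectrum of partially oxygenated blood at a volume fraction.

    mu_a(lambda) = bvf * [s * mu_a_HbO2(lambda) + (1 - s) * mu_a_Hb(lambda)],
    exactly linear in both the saturation ``s`` and the blood volume
    fraction ``bvf``.
    """
    s = float(s)
    bvf = float(bvf)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"sO2 fraction must be in [0, 1], got {s}")
    if not 0.0 <= bvf <= 1.0:
        raise ValueError(f"blood volume fraction must be in [0, 1], got {bvf}")
    return bvf * (s * table.mu_a_hbo2 + (1.0 - s) * table.mu_a_hb)


def severinghaus_so2(po2_mmhg):
    """Hemoglobin saturation from oxygen partial pressure (mmHg).

    Standard closed-form dissociation curve
    S = 1 / (23400 / (pO2^3 + 150 pO2) + 1); monotone increasing, S(0) = 0,
    bounded above by 1.  Accepts scalars or arrays.
    """
    p = np.asarray(po2_mmhg, dtype=float)
    if np.any(p < 0):
        raise ValueError("pO2 must be non-negative")
    poly = p ** 3 + 150.0 * p
    with np.errstate(divide="ignore"):
        s = 1.0 / (23400.0 / poly + 1.0)
    s = np.where(poly == 0.0, 0.0, s)
    return float(s) if np.isscalar(po2_mmhg) or np.ndim(po2_mmhg) == 0 else s
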