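"""Broadband spectral analysis: chromophore decomposition and scattering power law.

Absorption spectra are interpreted with the Beer-Lambert law as a non-negative
linear combination of five tissue absorbers — deoxy-hemoglobin (Hb, uM),
oxy-hemoglobin (HbO2, uM), water, lipid and collagen (g/cm^3) — and reduced
scattering spectra with the empirical Mie-type power law
mus'(lambda) = a * (lambda/600 nm)^-b, where the amplitude a reflects the
density of scattering centres and the power b their size.

The bundled chromophore basis is SYNTHETIC: a smooth Gaussian-band
parametrisation with realistic band positions and magnitudes (Hb band near
760 nm, HbO2 rising beyond 800 nm, the dominant water band at 975 nm, the
lipid band at 930 nm, a broad collagen band near 1030 nm). It reproduces the
qualitative spectroscopy of the 600-1100 nm window but is not a literature
compilation; analyses on real data should swap in measured extinction tables
via :class:`ChromophoreBasis`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.stats import linregress

__all__ = [
    "SpectralDataset",
    "ChromophoreBasis",
    "TissueComposition",
    "PowerLawFit",
    "synthetic_chromophore_basis",
    "fit_composition",
    "fit_power_law",
    "eval_power_law",
]

CHROMOPHORES = ("Hb", "HbO2", "water", "lipid", "collagen")

#: Reference wavelength of the scattering power law, nm.
LAMBDA0_NM = 600.0


@dataclass(frozen=True)
class SpectralDataset:
    """Per-wavelength fitted optical properties (the broadband measurement)."""

    wavelengths: np.ndarray
    mua_spectrum: np.ndarray
    musp_spectrum: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        mua = np.asarray(self.mua_spectrum, dtype=float)
        musp = np.asarray(self.musp_spectrum, dtype=float)
        if not (wl.size == mua.size == musp.size):
            raise ValueError("wavelengths, mua and musp must have equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "mua_spectrum", mua)
        object.__setattr__(self, "musp_spectrum", musp)


@dataclass(frozen=True)
class TissueComposition:
    """Absorber concentrations: hemoglobins in uM, the rest in g/cm^3."""

    Hb: float
    HbO2: float
    water: float
    lipid: float
    collagen: float

    def __post_init__(self) -> None:
        for name in CHROMOPHORES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in CHROMOPHORES])

    @classmethod
    def from_array(cls, values) -> "TissueComposition":
        return cls(**dict(zip(CHROMOPHORES, map(float, values))))


@dataclass(frozen=True)
class ChromophoreBasis:
    """Specific absorption spectra of the five absorbers on a wavelength grid.

    Columns of ``specific_absorption`` follow :data:`CHROMOPHORES`; units are
    cm^-1 per uM for the hemoglobins and cm^-1 per (g/cm^3) for water, lipid
    and collagen, so that mua = basis @ concentrations. Linear interpolation
    onto other grids inside the covered range is allowed.
    """

    wavelengths: np.ndarray
    specific_absorption: np.ndarray  # (n_wavelengths, 5)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        eps = np.asarray(self.specific_absorption, dtype=float)
        if eps.shape != (wl.size, len(CHROMOPHORES)):
            raise ValueError(f"basis must be (n_wl, 5), got {eps.shape}")
        if np.any(eps < 0):
            raise ValueError("specific absorption spectra must be nonnegative")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "specific_absorption", eps)

    def on_grid(self, wavelengths) -> np.ndarray:
        """Interpolated basis matrix on an arbitrary grid inside the range."""
        wl = np.asarray(wavelengths, dtype=float)
        if wl.min() < self.wavelengths[0] - 1e-9 or wl.max() > self.wavelengths[-1] + 1e-9:
            raise ValueError(
                f"grid [{wl.min()}, {wl.max()}] nm outside basis range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        cols = [
            np.interp(wl, self.wavelengths, self.specific_absorption[:, j])
            for j in range(len(CHROMOPHORES))
        ]
        return np.column_stack(cols)

    def mua(self, wavelengths, composition: TissueComposition) -> np.ndarray:
        """Beer-Lambert forward model: mua(lambda) for a given composition."""
        return self.on_grid(wavelengths) @ composition.as_array()


def _gauss(wl: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / 2.35482
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def synthetic_chromophore_basis(
    wl_min: float = 590.0, wl_max: float = 1110.0, step: float = 2.0
) -> ChromophoreBasis:
    """Synthetic five-absorber basis for the 600-1100 nm window.

    Smooth sums of Gaussian bands plus gentle baselines, scaled so that
    physiological compositions (a few uM Hb, 10-30 uM HbO2, water 0.1-0.5,
    lipid 0.4-0.9, collagen ~0.1-0.2 g/cm^3) yield chest-like absorption of
    order 0.05-0.3 cm^-1 across the window, with the water band dominating
    near 975 nm and the lipid band visible at 930 nm.
    """
    wl = np.arange(wl_min, wl_max + step / 2, step)

    # deoxy-hemoglobin: steep red decay plus the 760 nm band (cm^-1 / uM)
    hb = 0.011 * np.exp(-(wl - 600.0) / 55.0) + 9.0e-4 * _gauss(wl, 758.0, 50.0) + 4.5e-4
    # oxy-hemoglobin: minimum near 690 nm then a broad rise past 800 nm (cm^-1 / uM)
    hbo2 = (
        2.0e-3 * np.exp(-(wl - 600.0) / 40.0)
        + 1.15e-3 * _gauss(wl, 910.0, 260.0)
        + 2.0e-4
    )
    # water: dominant 975 nm band plus the weak 740 nm overtone (cm^-1 per g/cm^3)
    water = (
        0.62 * _gauss(wl, 975.0, 85.0)
        + 0.022 * _gauss(wl, 740.0, 80.0)
        + 0.06 * _gauss(wl, 1130.0, 120.0)
        + 0.004
    )
    # lipid: 930 nm band with a shoulder near 1040 nm (cm^-1 per g/cm^3)
    lipid = (
        0.115 * _gauss(wl, 928.0, 55.0)
        + 0.035 * _gauss(wl, 1040.0, 90.0)
        + 0.012 * _gauss(wl, 760.0, 70.0)
        + 0.002
    )
    # collagen: broad bands near 910 and 1030 nm (cm^-1 per g/cm^3)
    collagen = (
        0.18 * _gauss(wl, 1030.0, 70.0)
        + 0.065 * _gauss(wl, 910.0, 90.0)
        + 0.03 * np.exp(-(wl - 600.0) / 150.0)
        + 0.005
    )
    basis = np.column_stack([hb, hbo2, water, lipid, collagen])
    return ChromophoreBasis(wavelengths=wl, specific_absorption=basis)


def fit_composition(
    mua: SpectralDataset,
    basis: ChromophoreBasis,
) -> tuple[TissueComposition, float]:
    """Non-negative Beer-Lambert decomposition of an absorption spectrum.

    Solves min ||E c - mua||_2 subject to c >= 0 with E the basis interpolated
    onto the dataset's grid. Returns the composition and the residual norm.
    A rank-deficient basis on the provided grid is rejected.
    """
    wl = mua.wavelengths
    if wl.size < len(CHROMOPHORES):
        raise ValueError(
            f"need at least {len(CHROMOPHORES)} wavelengths, got {wl.size}"
        )
    E = basis.on_grid(wl)
    rank = np.linalg.matrix_rank(E, tol=1e-10 * np.linalg.norm(E))
    if rank < len(CHROMOPHORES):
        raise ValueError(
            f"chromophore basis is rank-deficient (rank {rank}) on the provided grid"
        )
    c, resid = nnls(E, mua.mua_spectrum)
    return TissueComposition.from_array(c), float(resid)


@dataclass(frozen=True)
class PowerLawFit:
    """mus'(lambda) = a * (lambda/lambda0)^-b with lambda0 fixed at 600 nm."""

    a: float
    b: float
    lambda0: float = LAMBDA0_NM

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"scattering amplitude must be > 0, got a={self.a}")


def eval_power_law(fit: PowerLawFit, wavelength) -> np.ndarray | float:
    """Reduced scattering at ``wavelength`` (nm) from a power-law fit."""
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl <= 0):
        raise ValueError("wavelength must be positive")
    out = fit.a * (wl / fit.lambda0) ** (-fit.b)
    return float(out) if np.isscalar(wavelength) else out


def fit_power_law(musp: SpectralDataset) -> PowerLawFit:
    """Least-squares power-law fit of a reduced scattering spectrum.

    Linear regression of ln mus' on ln(lambda/600 nm): a = exp(intercept),
    b = -slope. Exact on noiseless power-law inputs.
    """
    if musp.wavelengths.size < 3:
        raise ValueError("need at least 3 wavelengths for a power-law fit")
    if np.any(musp.musp_spectrum <= 0):
        raise ValueError("reduced scattering must be positive for a log-log fit")
    x = np.log(musp.wavelengths / LAMBDA0_NM)
    y = np.log(musp.musp_spectrum)
    res = linregress(x, y)
    return PowerLawFit(a=float(np.exp(res.intercept)), b=float(-res.slope))
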