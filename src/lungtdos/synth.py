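"""Synthetic-data generation for every pipeline stage.

Emulates what a TCSPC lung-sensing acquisition produces — finite-width IRFs,
Poisson-count DTOFs at ~1 Mcounts/s, broadband spectral series built from a
five-chromophore composition plus a power-law scattering spectrum, and
paced-breathing protocol series in which the lung layer's optical properties
are modulated by the respiratory phase. Every generated dataset carries its
ground truth so recovery experiments are self-contained.

Protocol series use the layered Monte Carlo with microscopic Lambert-Beer
reweighting as their forward model: one absorption-free run per distinct
scattering state, reweighted per acquisition for that phase's lung
absorption. This reproduces the depth selectivity of late time gates that a
homogeneous analytic model cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .curves import DTOFCurve, IRFCurve, OpticalProperties, TimeAxis
from .forward import convolve_with_irf, tr_reflectance
from .montecarlo import DetectionGeometry, LayeredSlabMedium, MCResult, apply_absorption, run_mc
from .protocol import BreathingProtocol, ProtocolSeries
from .spectra import (
    ChromophoreBasis,
    PowerLawFit,
    SpectralDataset,
    TissueComposition,
    eval_power_law,
)

__all__ = [
    "NoiseModel",
    "SyntheticScenario",
    "generate_irf",
    "generate_dtof",
    "generate_spectral_series",
    "generate_protocol_series",
]


@dataclass(frozen=True)
class NoiseModel:
    """TCSPC counting statistics: total rate, duration, background, seed.

    The default rate of 1e6 counts/s is the single-photon-statistics operating
    point of a TCSPC chain; background is dark + ambient counts per channel
    per second (default 0).
    """

    total_count_rate: float = 1.0e6
    acq_time: float = 1.0
    background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_count_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.acq_time <= 0:
            raise ValueError(f"acquisition time must be > 0, got {self.acq_time}")


@dataclass(frozen=True)
class PhaseModulation:
    """Per-phase multiplicative factors on the lung layer's optical properties.

    Applied during the IN (inhaled) phase; OUT keeps the baseline. The default
    mirrors a 10% reduction of lung absorption on inhalation with unchanged
    scattering.
    """

    mua_factor_in: float = 0.9
    musp_factor_in: float = 1.0

    def __post_init__(self) -> None:
        if self.mua_factor_in <= 0 or self.musp_factor_in <= 0:
            raise ValueError("modulation factors must be > 0")


@dataclass(frozen=True)
class SyntheticScenario:
    """Everything defining one synthetic breathing-protocol measurement."""

    medium: LayeredSlabMedium
    protocol: BreathingProtocol
    modulation: PhaseModulation = PhaseModulation()
    rho: float = 8.0
    irf_fwhm_ps: float = 150.0
    cadence: float = 1.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.medium.n_layers < 2:
            raise ValueError("scenario needs a chest + lung two-layer medium")


def generate_irf(
    axis: TimeAxis,
    fwhm_ps: float = 150.0,
    total_counts: float = 1.0e6,
    seed: int = 0,
    tail_tau_ps: float | None = None,
    poisson: bool = True,
) -> IRFCurve:
    """Synthetic instrument response: Gaussian rise with an exponential tail.

    The shape is an exponentially modified Gaussian (Gaussian core of the
    requested FWHM convolved with a decay of time constant ``tail_tau_ps``,
    default equal to the FWHM), shifted so its peak falls in the channel
    containing t = 0, then Poisson-sampled to ``total_counts`` expected total.
    """
    if fwhm_ps <= 0:
        raise ValueError(f"fwhm must be > 0, got {fwhm_ps}")
    fwhm_ns = fwhm_ps * 1e-3
    span = axis.t_end - axis.t0
    if fwhm_ns >= span:
        raise ValueError(f"IRF FWHM {fwhm_ns} ns does not fit the {span} ns axis")
    tau = (tail_tau_ps if tail_tau_ps is not None else fwhm_ps) * 1e-3
    sigma = fwhm_ns / 2.35482

    t = axis.centers
    # EMG via explicit convolution on the channel grid
    kernel_t = np.arange(0.0, 6.0 * tau + axis.dt, axis.dt)
    kernel = np.exp(-kernel_t / tau)
    gauss = np.exp(-0.5 * ((t - t.mean()) / sigma) ** 2)
    shape = np.convolve(gauss, kernel)[: t.size]
    # place the peak in the channel containing t = 0
    i_zero = int(np.argmin(np.abs(t)))
    shape = np.roll(shape, i_zero - int(np.argmax(shape)))
    shape = np.clip(shape, 0.0, None)
    expected = shape / shape.sum() * total_counts
    if poisson:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
        if counts.sum() == 0:
            counts = expected
    else:
        counts = expected
    return IRFCurve(axis=axis, counts=counts)


def _sample_curve(
    expected: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scale a model curve to the noise model's expected counts and sample."""
    total = noise.total_count_rate * noise.acq_time
    s = expected.sum()
    scaled = expected / s * total if s > 0 else np.zeros_like(expected)
    scaled = scaled + noise.background_rate * noise.acq_time
    return rng.poisson(scaled).astype(float)


def generate_dtof(
    props: OpticalProperties,
    rho: float,
    irf: IRFCurve,
    noise: NoiseModel,
    axis: TimeAxis | None = None,
    wavelength: float | None = None,
) -> DTOFCurve:
    """One synthetic DTOF: diffusion model, IRF convolution, Poisson counts."""
    if axis is None:
        axis = TimeAxis.default(dt=irf.axis.dt)
    refl = tr_reflectance(rho, axis, props)
    model = convolve_with_irf(refl, irf, axis)
    rng = np.random.default_rng(noise.seed)
    counts = _sample_curve(model, noise, rng)
    return DTOFCurve(
        axis=axis, counts=counts, rho=rho, wavelength=wavelength, acq_time=noise.acq_time
    )


def generate_spectral_series(
    composition: TissueComposition,
    power_law: PowerLawFit,
    basis: ChromophoreBasis,
    rho: float = 3.0,
    irf: IRFCurve | None = None,
    noise: NoiseModel | None = None,
    wavelengths: np.ndarray | None = None,
    axis: TimeAxis | None = None,
) -> tuple[list[DTOFCurve], SpectralDataset]:
    """Broadband DTOF series plus its ground-truth optical-property spectra.

    Wavelengths default to the 600-1100 nm grid in 10 nm steps with 4 s
    acquisitions at 1 Mcounts/s; mua(lambda) comes from the Beer-Lambert
    forward model, mus'(lambda) from the scattering power law.
    """
    if wavelengths is None:
        wavelengths = np.arange(600.0, 1101.0, 10.0)
    if noise is None:
        noise = NoiseModel(acq_time=4.0)
    if axis is None:
        axis = TimeAxis.default()
    if irf is None:
        irf_axis = TimeAxis(t0=-1.0, dt=axis.dt, n_channels=int(round(2.0 / axis.dt)))
        irf = generate_irf(irf_axis, seed=noise.seed)

    mua_truth = basis.mua(wavelengths, composition)
    musp_truth = np.asarray(eval_power_law(power_law, wavelengths))
    truth = SpectralDataset(wavelengths, mua_truth, musp_truth)

    curves = []
    for k, wl in enumerate(wavelengths):
        props = OpticalProperties(mua=float(mua_truth[k]), musp=float(musp_truth[k]))
        noise_k = replace(noise, seed=(noise.seed * 100003 + k) & 0x7FFFFFFF)
        curves.append(
            generate_dtof(props, rho, irf, noise_k, axis=axis, wavelength=float(wl))
        )
    return curves, truth


def generate_protocol_series(
    scenario: SyntheticScenario,
    noise: NoiseModel,
    n_detected: int = 50_000,
    axis: TimeAxis | None = None,
    irf: IRFCurve | None = None,
    mc_baseline: MCResult | None = None,
    mc_inhaled: MCResult | None = None,
) -> tuple[ProtocolSeries, dict]:
    """Synthetic breathing-protocol series with its ground-truth phase trace.

    One absorption-free Monte Carlo run serves every acquisition of a given
    scattering state: the OUT (baseline) run, plus a second run only when the
    IN phase modulates lung scattering. Per acquisition, the run is reweighted
    with that phase's lung absorption, convolved with the IRF, scaled to the
    noise model's count rate and Poisson-sampled. Precomputed runs may be
    passed in to amortise the transport cost across seeds.

    Returns the series and a ground-truth dict with the per-acquisition lung
    (mua, musp) trace and phase labels.
    """
    if axis is None:
        axis = TimeAxis.default(dt=0.050)
    if irf is None:
        irf_axis = TimeAxis(t0=-1.0, dt=axis.dt, n_channels=int(round(2.0 / axis.dt)))
        irf = generate_irf(irf_axis, fwhm_ps=scenario.irf_fwhm_ps, seed=noise.seed)

    med = scenario.medium
    geometry = DetectionGeometry(rho=scenario.rho, t_max_record=axis.t_end + axis.dt)
    if mc_baseline is None:
        mc_baseline = run_mc(med, geometry, n_detected, seed=noise.seed + 7)
    runs = {"OUT": mc_baseline, "REF": mc_baseline}

    mod = scenario.modulation
    if mod.musp_factor_in != 1.0:
        if mc_inhaled is None:
            lung_t, lung_p = med.layers[-1]
            med_in = LayeredSlabMedium(
                layers=med.layers[:-1]
                + ((lung_t, replace(lung_p, musp=lung_p.musp * mod.musp_factor_in)),)
            )
            mc_inhaled = run_mc(med_in, geometry, n_detected, seed=noise.seed + 7)
        runs["IN"] = mc_inhaled
    else:
        runs["IN"] = mc_baseline
    for r in runs.values():
        if not r.complete:
            raise RuntimeError(
                "Monte Carlo launch budget exhausted before reaching the detection target"
            )

    mua_layers = med.mua_per_layer
    labels = scenario.protocol.label_sequence(scenario.cadence)
    timestamps = np.arange(len(labels)) / scenario.cadence
    rng = np.random.default_rng(noise.seed)

    lung_mua_truth = np.empty(len(labels))
    lung_musp_truth = np.empty(len(labels))
    acquisitions: list[DTOFCurve] = []
    hist_cache: dict[tuple, np.ndarray] = {}
    for i, lab in enumerate(labels):
        mua = mua_layers.copy()
        if lab == "IN":
            mua[-1] *= mod.mua_factor_in
        lung_mua_truth[i] = mua[-1]
        lung_musp_truth[i] = (
            med.layers[-1][1].musp * (mod.musp_factor_in if lab == "IN" else 1.0)
        )
        key = (lab if lab == "IN" else "OUT", tuple(mua))
        if key not in hist_cache:
            hist = apply_absorption(runs[lab], mua, t_axis=axis).counts
            hist_cache[key] = convolve_with_irf(hist, irf, axis)
        model = hist_cache[key]
        counts = _sample_curve(model, noise, rng)
        acquisitions.append(
            DTOFCurve(
                axis=axis, counts=counts, rho=scenario.rho,
                wavelength=820.0, acq_time=noise.acq_time, label=lab,
            )
        )

    series = ProtocolSeries(
        acquisitions=acquisitions,
        timestamps=timestamps,
        labels=labels,
        protocol=scenario.protocol,
    )
    truth = {
        "labels": labels,
        "lung_mua": lung_mua_truth,
        "lung_musp": lung_musp_truth,
        "timestamps": timestamps,
    }
    return series, truth
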