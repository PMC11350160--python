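"""Synthetic-data generators: IRFs, DTOFs, spectral series, protocol series."""

import numpy as np
import pytest

from lungtdos import (
    GateSpec,
    NoiseModel,
    OpticalProperties,
    PROT5,
    PROT10,
    PowerLawFit,
    SpectralDataset,
    SyntheticScenario,
    TissueComposition,
    TimeAxis,
    fit_composition,
    fit_power_law,
    folding_average,
    gated_contrast,
    generate_dtof,
    generate_irf,
    generate_protocol_series,
    generate_spectral_series,
    synthetic_chromophore_basis,
)
from lungtdos.synth import PhaseModulation


IRF_AXIS = TimeAxis(t0=-1.0, dt=0.010, n_channels=300)


class TestGenerateIRF:
    def test_peak_channel_contains_time_zero(self):
        irf = generate_irf(IRF_AXIS, fwhm_ps=150.0, seed=1)
        assert abs(irf.peak_time) <= IRF_AXIS.dt / 2

    def test_total_counts_in_expectation(self):
        totals = [
            generate_irf(IRF_AXIS, fwhm_ps=150.0, total_counts=1e5, seed=s).total_counts
            for s in range(20)
        ]
        assert np.mean(totals) == pytest.approx(1e5, rel=0.01)

    def test_narrow_noiseless_irf_is_a_spike(self):
        irf = generate_irf(IRF_AXIS, fwhm_ps=2.0, tail_tau_ps=2.0, poisson=False)
        frac_peak3 = np.sort(irf.counts)[-3:].sum() / irf.total_counts
        assert frac_peak3 > 0.95

    def test_fwhm_wider_than_axis_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            generate_irf(IRF_AXIS, fwhm_ps=5.0e3)

    def test_reproducible(self):
        a = generate_irf(IRF_AXIS, seed=9)
        b = generate_irf(IRF_AXIS, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestGenerateDTOF:
    PROPS = OpticalProperties(0.15, 8.0)

    def test_vanishing_acq_time_gives_empty_histogram(self, irf_10ps):
        d = generate_dtof(self.PROPS, 3.0, irf_10ps, NoiseModel(acq_time=1e-12, seed=0))
        assert d.total_counts == 0

    def test_doubling_acq_time_doubles_totals(self, irf_10ps):
        t1 = [
            generate_dtof(self.PROPS, 3.0, irf_10ps, NoiseModel(acq_time=1.0, seed=s)).total_counts
            for s in range(10)
        ]
        t2 = [
            generate_dtof(self.PROPS, 3.0, irf_10ps, NoiseModel(acq_time=2.0, seed=s + 50)).total_counts
            for s in range(10)
        ]
        assert np.mean(t2) / np.mean(t1) == pytest.approx(2.0, rel=0.02)

    def test_background_adds_counts_everywhere(self, irf_10ps):
        clean = generate_dtof(self.PROPS, 3.0, irf_10ps, NoiseModel(seed=2))
        noisy = generate_dtof(
            self.PROPS, 3.0, irf_10ps, NoiseModel(background_rate=50.0, seed=2)
        )
        extra = noisy.total_counts - clean.total_counts
        assert extra == pytest.approx(50.0 * clean.axis.n_channels, rel=0.05)


class TestSpectralSeries:
    COMP = TissueComposition(Hb=3.0, HbO2=15.5, water=0.29, lipid=0.63, collagen=0.11)
    PL = PowerLawFit(a=9.0, b=0.78)

    def test_default_grid_has_51_wavelengths(self):
        basis = synthetic_chromophore_basis()
        curves, truth = generate_spectral_series(
            self.COMP, self.PL, basis, noise=NoiseModel(acq_time=1e-12, seed=0)
        )
        assert len(curves) == 51
        assert truth.wavelengths.size == 51

    def test_zero_noise_round_trip_recovers_truth(self, irf_10ps):
        """Fitting the noiseless spectral series recovers composition and
        scattering power law to optimizer tolerance."""
        from lungtdos import fit_homogeneous

        basis = synthetic_chromophore_basis()
        wl = np.arange(600.0, 1101.0, 50.0)
        curves, truth = generate_spectral_series(
            self.COMP, self.PL, basis, rho=3.0, irf=irf_10ps,
            noise=NoiseModel(acq_time=4.0, seed=1), wavelengths=wl,
        )
        mua = np.empty(wl.size)
        musp = np.empty(wl.size)
        for i, c in enumerate(curves):
            # replace Poisson counts by their expectation for the zero-noise check
            exact = _expected_counts(c, truth, i, irf_10ps)
            res = fit_homogeneous(exact, irf_10ps, init=(truth.mua_spectrum[i], truth.musp_spectrum[i]))
            mua[i], musp[i] = res.mua, res.musp
        np.testing.assert_allclose(mua, truth.mua_spectrum, rtol=0.01)
        np.testing.assert_allclose(musp, truth.musp_spectrum, rtol=0.01)
        comp, _ = fit_composition(SpectralDataset(wl, mua, musp), basis)
        np.testing.assert_allclose(comp.as_array(), self.COMP.as_array(), rtol=0.05)
        pl = fit_power_law(SpectralDataset(wl, mua, musp))
        assert pl.a == pytest.approx(self.PL.a, rel=0.02)
        assert pl.b == pytest.approx(self.PL.b, abs=0.03)


def _expected_counts(curve, truth, i, irf):
    """Noiseless counterpart of a generated spectral DTOF."""
    from lungtdos import DTOFCurve, OpticalProperties
    from lungtdos.forward import convolve_with_irf, tr_reflectance

    props = OpticalProperties(truth.mua_spectrum[i], truth.musp_spectrum[i])
    model = convolve_with_irf(tr_reflectance(curve.rho, curve.axis, props), irf, curve.axis)
    scaled = model / model.sum() * 4e6
    return DTOFCurve(
        axis=curve.axis, counts=scaled, rho=curve.rho,
        wavelength=curve.wavelength, acq_time=curve.acq_time,
    )


class TestProtocolSeries:
    def _scenario(self, mc_run, **mod):
        return SyntheticScenario(
            medium=mc_run.medium,
            protocol=PROT10,
            rho=mc_run.geometry.rho,
            modulation=PhaseModulation(**mod),
        )

    def test_prot5_timing_yields_110_acquisitions(self, mc_protocol_run, protocol_axis):
        scen = SyntheticScenario(
            medium=mc_protocol_run.medium, protocol=PROT5,
            rho=mc_protocol_run.geometry.rho,
        )
        series, truth = generate_protocol_series(
            scen, NoiseModel(seed=3), axis=protocol_axis, mc_baseline=mc_protocol_run
        )
        # one normal-breathing repetition (2 x 5 s) + 10 cycles of 2 x 5 s
        assert len(series) == 110
        assert series.labels[:10] == ["REF"] * 10
        assert series.labels[10:15] == ["IN"] * 5

    def test_stationary_series_contrast_within_noise(self, mc_protocol_run, protocol_axis):
        scen = self._scenario(mc_protocol_run, mua_factor_in=1.0)
        series, _ = generate_protocol_series(
            scen, NoiseModel(seed=4), axis=protocol_axis, mc_baseline=mc_protocol_run
        )
        cs = gated_contrast(series, [GateSpec(1.0), GateSpec(3.0)])
        # per-gate counting noise bound: 3 sigma of 1/sqrt(gate counts)
        for j, g in enumerate(cs.gates):
            gate_counts = np.array(
                [a.gate_sum(g.t_start, g.width) for a in series.acquisitions]
            )
            sigma = 1.0 / np.sqrt(np.maximum(gate_counts.mean(), 1.0))
            assert np.abs(cs.contrast[:, j]).max() < 5 * sigma

    def test_inhalation_raises_late_gate_signal(self, mc_protocol_run, protocol_axis):
        """10% lung-absorption drop during IN: folded late-gate contrast is
        positive in the IN half-cycle for every tested seed (sign test)."""
        scen = self._scenario(mc_protocol_run, mua_factor_in=0.9)
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            series, _ = generate_protocol_series(
                scen, NoiseModel(seed=100 + seed), axis=protocol_axis,
                mc_baseline=mc_protocol_run,
            )
            cs = gated_contrast(series, [GateSpec(4.5)])
            folded = folding_average(cs.contrast[:, 0], PROT10)
            in_half = folded[:10].mean()
            out_half = folded[10:].mean()
            wins += int(in_half > 0 and in_half > out_half)
        # one-sided binomial: >= 9/10 successes rejects p=0.5 at the 5% level
        assert wins >= 9

    def test_ground_truth_trace_matches_labels(self, mc_protocol_run, protocol_axis):
        scen = self._scenario(mc_protocol_run, mua_factor_in=0.9)
        series, truth = generate_protocol_series(
            scen, NoiseModel(seed=5), axis=protocol_axis, mc_baseline=mc_protocol_run
        )
        lung_mua = mc_protocol_run.medium.mua_per_layer[-1]
        for lab, mua in zip(truth["labels"], truth["lung_mua"]):
            assert mua == pytest.approx(lung_mua * (0.9 if lab == "IN" else 1.0))

    def test_square_wave_lung_absorption_recovered_by_fits(
        self, mc_protocol_run, protocol_axis, irf_10ps
    ):
        """Homogeneous fits over the series separate the IN and OUT phases of
        a square-wave lung absorption (positive OUT-IN separation in fitted
        mua for most seeds)."""
        from lungtdos import fit_timeseries, generate_irf

        irf = generate_irf(
            TimeAxis(t0=-1.0, dt=protocol_axis.dt, n_channels=60), seed=2
        )
        scen = self._scenario(mc_protocol_run, mua_factor_in=0.9)
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            series, _ = generate_protocol_series(
                scen, NoiseModel(seed=300 + seed), axis=protocol_axis,
                mc_baseline=mc_protocol_run,
            )
            fits = fit_timeseries(series, irf, init=(0.15, 8.0))
            mua = np.array([f.mua for f in fits])
            lab = np.array(series.labels)
            sep = mua[lab == "OUT"].mean() - mua[lab == "IN"].mean()
            wins += int(sep > 0)
        assert wins == n_seeds  # sign test: 6/6 rejects chance at the 2% level
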