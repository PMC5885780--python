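"""Global exponential fitting: recovery, invariances, model comparison."""

import numpy as np
import pytest

from photokin import globalfit as gf
from photokin import photocycle as pc
from photokin import synthgen as sg


def make_traceset(times, data, irf_fwhm=0.0, wavelengths=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] != times.size:
        data = data.T
    wl = wavelengths or tuple(450.0 + 10 * i for i in range(data.shape[1]))
    setup = sg.InstrumentSetup(regime="ns_us", wavelengths=wl,
                               irf_fwhm=irf_fwhm, time_grid=times, seed=0)
    return sg.TraceSet(times=times, wavelengths=wl, data=data, setup=setup)


class TestRecovery:
    def test_noiseless_monoexponential_recovered_to_1e9(self):
        t = np.geomspace(1e-5, 2e-2, 150)
        ts = make_traceset(t, -0.01 * np.exp(-t / 1e-3))
        fit = gf.fit_global(ts, 1, allow_offset=True, seed=0)
        assert fit.converged
        assert fit.time_constants[0] == pytest.approx(1e-3, rel=1e-9)
        assert fit.offsets[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.amplitudes[0, 0] == pytest.approx(-0.01, rel=1e-9)

    def test_noiseless_preset_data_recovered_to_1e6(self, registry):
        """ms-regime presets are exactly in the fitted model class."""
        cases = [
            ("WT", 2, (pc.parallel_observed_tau([300e-6, 1e-3]), 1.1e-3)),
            ("W388F", 1, (2.7e-3,)),
            ("Y345F", 1, (250e-6,)),
        ]
        for variant, n, expected in cases:
            scheme = pc.preset_scheme(variant)
            setup = sg.InstrumentSetup(
                regime="ms_s", wavelengths=sg.PROBE_WAVELENGTHS["wt_ms"],
                irf_fwhm=0.0,
                time_grid=np.geomspace(1e-5, 5 * scheme.slowest_tau(), 250), seed=0)
            ts = sg.generate_dataset(scheme, setup, registry)
            fit = gf.fit_global(ts, n, seed=0)
            assert fit.converged, variant
            np.testing.assert_allclose(fit.time_constants, expected, rtol=1e-6,
                                       err_msg=variant)

    def test_noiseless_irf_convolved_single_exponential_recovered(self):
        t = np.geomspace(10e-12, 20e-9, 200)
        curve = sg.gaussian_convolved_decay(t, 1.0 / 350e-12, 200e-12)
        ts = make_traceset(t, 0.005 * curve, irf_fwhm=200e-12)
        fit = gf.fit_global(ts, 1, irf_fwhm=200e-12, seed=0)
        assert fit.time_constants[0] == pytest.approx(350e-12, rel=1e-6)

    def test_wt_biexponential_recovery_with_noise(self, wt_scheme, registry):
        """1 % noise: shared biexponential fit lands within 5 % of the
        parallel-channel fast constant and the slow 1.1 ms constant."""
        setup = sg.InstrumentSetup(regime="ms_s",
                                   wavelengths=sg.PROBE_WAVELENGTHS["wt_ms"], seed=42)
        ts = sg.generate_dataset(wt_scheme, setup, registry, noise_fraction=0.01)
        fit = gf.fit_global(ts, 2, seed=1)
        fast_expected = pc.parallel_observed_tau([300e-6, 1e-3])
        assert fit.time_constants[0] == pytest.approx(fast_expected, rel=0.05)
        assert fit.time_constants[1] == pytest.approx(1.1e-3, rel=0.05)

    def test_recovery_success_rate_at_one_percent_noise(self, registry):
        """≥ 90 % of seeds recover the generating τ within 10 % at 1 % noise."""
        scheme = pc.preset_scheme("W388F")
        ok = 0
        for seed in range(20):
            setup = sg.InstrumentSetup(
                regime="ms_s", wavelengths=sg.PROBE_WAVELENGTHS["w388f_ms"],
                seed=seed)
            ts = sg.generate_dataset(scheme, setup, registry, noise_fraction=0.01)
            fit = gf.fit_global(ts, 1, seed=seed)
            if fit.converged and abs(fit.time_constants[0] / 2.7e-3 - 1.0) < 0.10:
                ok += 1
        assert ok >= 18

    def test_mono_fit_of_ten_to_one_biexponential_lands_near_half_nanosecond(self):
        """A 400 ps / 3 ns mixture at 10:1 amplitudes fits mono near 0.5 ns
        (the fitter is its own oracle; the value is frozen from it)."""
        t = np.geomspace(10e-12, 20e-9, 200)
        y = 1e-3 * (10 * np.exp(-t / 400e-12) + np.exp(-t / 3e-9))
        fit = gf.fit_global(make_traceset(t, y), 1, seed=0)
        assert fit.time_constants[0] == pytest.approx(4.500e-10, rel=1e-2)
        assert 0.4e-9 < fit.time_constants[0] < 0.6e-9


class TestInvariances:
    def test_wavelength_permutation_does_not_change_taus(self, wt_scheme, registry):
        setup = sg.InstrumentSetup(regime="ms_s",
                                   wavelengths=sg.PROBE_WAVELENGTHS["wt_ms"], seed=4)
        ts = sg.generate_dataset(wt_scheme, setup, registry, noise_fraction=0.01)
        perm = [2, 0, 3, 1]
        shuffled = sg.TraceSet(
            times=ts.times, wavelengths=tuple(ts.wavelengths[i] for i in perm),
            data=ts.data[:, perm], setup=ts.setup, meta=ts.meta)
        f1 = gf.fit_global(ts, 2, seed=1)
        f2 = gf.fit_global(shuffled, 2, seed=1)
        np.testing.assert_allclose(f1.time_constants, f2.time_constants, rtol=1e-12)

    def test_refitting_from_solution_is_stationary(self, wt_scheme, registry):
        setup = sg.InstrumentSetup(regime="ms_s",
                                   wavelengths=sg.PROBE_WAVELENGTHS["wt_ms"], seed=4)
        ts = sg.generate_dataset(wt_scheme, setup, registry, noise_fraction=0.01)
        fit = gf.fit_global(ts, 2, seed=1)
        _, R = gf._project(fit._times, fit._data, fit.time_constants,
                           fit.irf_fwhm, fit.offsets is not None)
        assert abs(np.sqrt(np.mean(R * R)) - fit.residual_rmsd) < 1e-10

    def test_error_grows_monotonically_with_noise(self):
        """Median |τ̂ − τ|/τ is non-decreasing over σ ∈ {0, 0.5, 1, 2} %."""
        t = np.geomspace(1e-5, 1e-2, 120)
        clean = -0.01 * np.exp(-t / 1e-3)
        medians = []
        for frac in (0.0, 0.005, 0.01, 0.02):
            errs = []
            for seed in range(9):
                rng = np.random.default_rng(1000 + seed)
                y = clean + rng.normal(0.0, frac * 0.01, t.size)
                fit = gf.fit_global(make_traceset(t, y), 1, seed=seed)
                errs.append(abs(fit.time_constants[0] / 1e-3 - 1.0))
            medians.append(np.median(errs))
        assert all(b >= a - 1e-12 for a, b in zip(medians, medians[1:]))

    def test_time_constants_reported_ascending(self, wt_scheme, registry):
        setup = sg.InstrumentSetup(regime="ms_s",
                                   wavelengths=sg.PROBE_WAVELENGTHS["wt_ms"], seed=4)
        ts = sg.generate_dataset(wt_scheme, setup, registry, noise_fraction=0.01)
        fit = gf.fit_global(ts, 2, seed=1)
        assert np.all(np.diff(fit.time_constants) > 0)
        assert np.all(fit.time_constants > 0)
        assert fit.residual_rmsd >= 0


class TestDegenerateAndComparison:
    def test_constant_traces_flagged_zero_component(self):
        t = np.geomspace(1e-6, 1e-3, 60)
        ts = make_traceset(t, np.full_like(t, 0.004))
        fit = gf.fit_global(ts, 1, seed=0)
        assert not fit.converged
        assert "degenerate_constant_data" in fit.flags
        assert fit.n_components == 0

    def test_identical_fits_compare_marginal(self, wt_scheme, registry):
        setup = sg.InstrumentSetup(regime="ms_s",
                                   wavelengths=sg.PROBE_WAVELENGTHS["wt_ms"], seed=4)
        ts = sg.generate_dataset(wt_scheme, setup, registry, noise_fraction=0.01)
        fit = gf.fit_global(ts, 2, seed=1)
        cmp_ = gf.compare_models(fit, fit)
        assert cmp_.rmsd_ratio == 1.0
        assert cmp_.verdict == "marginal"

    def test_strongly_biexponential_data_yield_substantial_verdict(self):
        t = np.geomspace(10e-12, 20e-9, 200)
        rng = np.random.default_rng(12)
        y = 1e-3 * (5 * np.exp(-t / 200e-12) + 5 * np.exp(-t / 2e-9)
                    + rng.normal(0, 0.1, t.size))
        ts = make_traceset(t, y)
        verdict = gf.compare_models(gf.fit_global(ts, 1, seed=1),
                                    gf.fit_global(ts, 2, seed=1)).verdict
        assert verdict == "substantial"

    def test_ten_to_one_amplitudes_with_realistic_noise_compare_marginal(self):
        """A weak (9 %) slow component inside noisy single-wavelength data
        does not warrant the extra exponential — mirrors mono-vs-bi analyses
        on biphasic deprotonation candidates."""
        t = np.geomspace(10e-12, 20e-9, 200)
        rng = np.random.default_rng(12)
        y = 1e-3 * (10 * np.exp(-t / 400e-12) + np.exp(-t / 3e-9)
                    + rng.normal(0, 0.05 * 11, t.size))
        ts = make_traceset(t, y)
        cmp_ = gf.compare_models(gf.fit_global(ts, 1, seed=1),
                                 gf.fit_global(ts, 2, seed=1))
        assert cmp_.verdict == "marginal"

    def test_mismatched_data_rejected(self, wt_scheme, registry):
        setup = sg.InstrumentSetup(regime="ms_s",
                                   wavelengths=sg.PROBE_WAVELENGTHS["wt_ms"], seed=4)
        ts1 = sg.generate_dataset(wt_scheme, setup, registry, noise_fraction=0.01)
        setup2 = sg.InstrumentSetup(regime="ms_s",
                                    wavelengths=sg.PROBE_WAVELENGTHS["wt_ms"], seed=5)
        ts2 = sg.generate_dataset(wt_scheme, setup2, registry, noise_fraction=0.01)
        with pytest.raises(ValueError, match="identical data"):
            gf.compare_models(gf.fit_global(ts1, 1, seed=1),
                              gf.fit_global(ts2, 2, seed=1))


class TestAmplitudeSpectrum:
    def test_single_component_t0_equals_amplitude_column(self):
        t = np.geomspace(1e-5, 1e-2, 100)
        data = np.column_stack([-0.01 * np.exp(-t / 1e-3), 0.004 * np.exp(-t / 1e-3)])
        fit = gf.fit_global(make_traceset(t, data), 1, seed=0)
        spec = gf.amplitude_spectrum(fit)
        np.testing.assert_allclose(spec["amplitude"], fit.amplitudes[:, 0], rtol=1e-12)

    def test_offsets_excluded_from_t0_extrapolation(self):
        t = np.geomspace(1e-5, 1e-2, 100)
        data = (-0.01 * np.exp(-t / 1e-3) + 0.02)[:, None]
        fit = gf.fit_global(make_traceset(t, data), 1, allow_offset=True, seed=0)
        spec = gf.amplitude_spectrum(fit)
        assert spec["amplitude"][0] == pytest.approx(-0.01, rel=1e-6)

    def test_slow_component_amplitude_near_zero_at_540nm(self, wt_scheme, registry):
        """The 1.1 ms phase (FAD˙⁻Tyr˙ recombination) has almost no
        amplitude at 540 nm, unlike a tryptophan-radical partner."""
        setup = sg.InstrumentSetup(regime="ms_s",
                                   wavelengths=(408.0, 450.0, 510.0, 540.0), seed=11)
        ts = sg.generate_dataset(wt_scheme, setup, registry, noise_fraction=0.005)
        fit = gf.fit_global(ts, 2, seed=1)
        slow = gf.amplitude_spectrum(fit, component=1)["amplitude"].to_numpy()
        a540 = slow[list(ts.wavelengths).index(540.0)]
        a450 = slow[list(ts.wavelengths).index(450.0)]
        assert abs(a540) < 0.15 * abs(a450)

    def test_component_index_out_of_range(self):
        t = np.geomspace(1e-5, 1e-2, 100)
        fit = gf.fit_global(make_traceset(t, -0.01 * np.exp(-t / 1e-3)), 1, seed=0)
        with pytest.raises(IndexError):
            gf.amplitude_spectrum(fit, component=3)
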