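import numpy as np
import pytest

from lamellipid import melting_curves as mc
from lamellipid import synthetic_data as sd
from lamellipid.errors import ParseError


# ---------------------------------------------------------------------------
# smoothing and baseline
# ---------------------------------------------------------------------------


class TestSmoothSG:
    def test_cubic_reproduced_exactly(self):
        x = np.linspace(0, 5, 80)
        y = 0.3 * x**3 - 1.2 * x**2 + x - 4
        out = mc.smooth_sg(y, 11, 3)
        assert np.allclose(out, y, atol=1e-10)

    def test_even_window_widened(self):
        # the 10-point window convention maps onto an 11-point odd window
        x = np.linspace(0, 5, 60)
        y = x**2
        assert np.allclose(mc.smooth_sg(y, 10, 3), mc.smooth_sg(y, 11, 3))

    def test_constant_unchanged(self):
        out = mc.smooth_sg(np.full(40, 2.5), 9, 3)
        assert np.allclose(out, 2.5, atol=1e-12)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 500)
        out = mc.smooth_sg(y, 21, 3)
        assert out.var() < y.var()

    def test_window_checks(self):
        with pytest.raises(ParseError):
            mc.smooth_sg(np.ones(5), 3, 3)
        with pytest.raises(ParseError):
            mc.smooth_sg(np.ones(5), 11, 3)


class TestBaselineCorrect:
    def test_pure_line_zeroed(self):
        x = np.linspace(0, 10, 101)
        y = 2.0 * x + 1.0
        out = mc.baseline_correct(x, y, [(0, 1), (9, 10)])
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_peak_preserved_wings_zero(self):
        x = np.linspace(0, 10, 501)
        peak = 3.0 * np.exp(-0.5 * ((x - 5) / 0.3) ** 2)
        y = peak + 0.5 * x - 1.0
        out = mc.baseline_correct(x, y, [(0, 2), (8, 10)])
        assert out[np.argmin(np.abs(x - 5))] == pytest.approx(3.0, abs=1e-6)
        wings = (x < 2) | (x > 8)
        assert np.allclose(out[wings], 0.0, atol=1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 10, 200)
        y = rng.normal(0, 1, 200) + x
        once = mc.baseline_correct(x, y, [(0, 2), (8, 10)])
        twice = mc.baseline_correct(x, once, [(0, 2), (8, 10)])
        assert np.allclose(once, twice, atol=1e-10)

    def test_insufficient_anchors(self):
        with pytest.raises(ParseError):
            mc.baseline_correct(np.arange(10.0), np.arange(10.0), [(100, 101)])


# ---------------------------------------------------------------------------
# bilinear decomposition
# ---------------------------------------------------------------------------


class TestMcaDecompose:
    def test_exact_rank_one(self):
        rng = np.random.default_rng(2)
        wl = np.arange(250.0, 301.0)
        t = np.arange(40.0, 66.0)
        s = np.abs(rng.normal(1, 0.2, len(wl)))
        c = 2.0 - 0.01 * (t - 40)
        spectra = mc.SpectraMatrix(wl, t, np.outer(s, c))
        dec = mc.mca_decompose(spectra, 1)
        assert dec.explained_variance == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(dec.E) < 1e-10
        # recovered concentration profile proportional to the truth
        corr = np.corrcoef(dec.C[:, 0], c)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-10)

    def test_rank_two_explained_variance_oracle(self):
        rng = np.random.default_rng(3)
        d = np.outer(rng.normal(size=30), rng.normal(size=20)) + 0.3 * np.outer(
            rng.normal(size=30), rng.normal(size=20)
        )
        spectra = mc.SpectraMatrix(np.arange(30.0), np.arange(20.0), d)
        dec = mc.mca_decompose(spectra, 1)
        sv = np.linalg.svd(d, compute_uv=False)
        assert dec.explained_variance == pytest.approx(
            sv[0] ** 2 / np.sum(sv**2), rel=1e-12
        )

    def test_wavelength_permutation_symmetry(self):
        rng = np.random.default_rng(4)
        d = rng.normal(size=(25, 15))
        spectra = mc.SpectraMatrix(np.arange(25.0), np.arange(15.0), d)
        dec = mc.mca_decompose(spectra, 1)
        perm = rng.permutation(25)
        spectra_p = mc.SpectraMatrix(np.arange(25.0), np.arange(15.0), d[perm])
        dec_p = mc.mca_decompose(spectra_p, 1)
        assert np.allclose(dec_p.S[:, 0], dec.S[perm, 0], atol=1e-10)
        assert np.allclose(dec_p.C, dec.C, atol=1e-10)

    def test_energy_partition(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=(40, 30))
        spectra = mc.SpectraMatrix(np.arange(40.0), np.arange(30.0), d)
        for k in (1, 2, 5):
            dec = mc.mca_decompose(spectra, k)
            lhs = np.linalg.norm(d) ** 2
            rhs = np.linalg.norm(dec.S @ dec.C.T) ** 2 + np.linalg.norm(dec.E) ** 2
            assert abs(lhs - rhs) / lhs < 1e-8

    def test_too_many_components(self):
        spectra = mc.SpectraMatrix(np.arange(4.0), np.arange(3.0), np.ones((4, 3)))
        with pytest.raises(ParseError):
            mc.mca_decompose(spectra, 4)


# ---------------------------------------------------------------------------
# Boltzmann fitting
# ---------------------------------------------------------------------------


class TestFitBoltzmann:
    def test_noise_free_single_exact(self):
        t = np.arange(40.0, 65.25, 0.25)
        y = mc.boltzmann_profile(t, 2.0, [53.9], [0.8], [-1.0])
        fit = mc.fit_boltzmann(t, y, 1)
        assert fit.centers[0] == pytest.approx(53.9, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_double_recovery_under_noise(self):
        # 100 seeds, 1% amplitude noise: median center error < 0.2 C
        t = np.arange(40.0, 65.25, 0.25)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = mc.boltzmann_profile(t, 2.0, [51.5, 53.3], [0.6, 0.5], [-0.6, -0.8])
            y = y + rng.normal(0, 0.014, len(t))
            fit = mc.fit_boltzmann(t, y, 2, seed=seed)
            errs.append(np.abs(fit.centers - np.array([51.5, 53.3])).max())
        assert np.median(errs) < 0.2

    def test_se_coverage(self):
        # reported center SEs cover the truth for >= 80% of noisy replicates
        t = np.arange(40.0, 65.25, 0.25)
        covered = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            y = mc.boltzmann_profile(t, 2.0, [53.9], [0.8], [-1.0])
            y = y + rng.normal(0, 0.01, len(t))
            fit = mc.fit_boltzmann(t, y, 1, seed=seed)
            if abs(fit.centers[0] - 53.9) <= 2 * fit.center_se[0]:
                covered += 1
        assert covered / n_rep >= 0.8

    def test_double_on_single_profile_model_selection(self):
        t = np.arange(40.0, 65.25, 0.25)
        rng = np.random.default_rng(9)
        y = mc.boltzmann_profile(t, 2.0, [53.9], [0.9], [-1.0]) + rng.normal(
            0, 0.005, len(t)
        )
        single = mc.fit_boltzmann(t, y, 1)
        double = mc.fit_boltzmann(t, y, 2)
        small_amp = np.min(np.abs(double.amplitudes)) < 0.05 * np.max(
            np.abs(double.amplitudes)
        )
        delta_r2 = double.r_squared - single.r_squared
        assert small_amp or delta_r2 < 1e-3 or not double.resolved

    def test_unresolved_flagged(self):
        t = np.arange(40.0, 65.25, 0.25)
        y = mc.boltzmann_profile(t, 2.0, [53.0], [2.0], [-1.0])
        fit = mc.fit_boltzmann(t, y, 2)
        if abs(fit.centers[1] - fit.centers[0]) < 2 * fit.widths.max() / 5:
            assert not fit.resolved

    def test_too_few_points(self):
        with pytest.raises(ParseError):
            mc.fit_boltzmann(np.arange(4.0), np.arange(4.0), 1)

    def test_widths_positive_and_sorted_centers(self):
        t = np.arange(40.0, 65.25, 0.5)
        y = mc.boltzmann_profile(t, 1.0, [51.5, 53.3], [0.6, 0.5], [-0.5, -0.7])
        fit = mc.fit_boltzmann(t, y, 2)
        assert np.all(fit.widths > 0)
        assert fit.centers[0] < fit.centers[1]


# ---------------------------------------------------------------------------
# DSC features
# ---------------------------------------------------------------------------


class TestDscFeatures:
    def test_symmetric_peak_tmax(self):
        th = sd.make_dsc([{"center": 52.4, "area": 10.0, "width": 0.5}])
        feats = mc.dsc_features(th)
        assert feats["t_max"] == pytest.approx(52.4, abs=0.05)

    def test_triangular_onset_geometry_oracle(self):
        # leading edge is an exact line: the tangent construction must return
        # the line's intersection with the (zero) baseline
        t = np.arange(40.0, 60.01, 0.02)
        y = np.zeros_like(t)
        rise = (t >= 50.0) & (t <= 52.0)
        fall = (t > 52.0) & (t <= 53.0)
        y[rise] = (t[rise] - 50.0) * 2.0
        y[fall] = (53.0 - t[fall]) * 4.0
        feats = mc.dsc_features(mc.Thermogram(t, y))
        assert feats["t_onset"] == pytest.approx(50.0, abs=0.05)

    def test_weak_satellite_reported(self):
        th = sd.make_dsc(
            [
                {"center": 52.4, "area": 10.0, "width": 0.5},
                {"center": 60.0, "area": 0.3, "width": 0.8},
            ]
        )
        feats = mc.dsc_features(th)
        assert any(abs(e - 60.0) < 0.5 for e in feats["minor_events"])

    def test_flat_trace_rejected(self):
        with pytest.raises(ParseError):
            mc.dsc_features(mc.Thermogram(np.arange(40.0, 60.0), np.ones(20)))

    def test_onset_below_tmax(self):
        th = sd.make_dsc(
            [{"center": 52.4, "area": 8.0, "width_left": 0.4, "width_right": 0.9}]
        )
        feats = mc.dsc_features(th)
        assert feats["t_onset"] < feats["t_max"]


class TestBandMaxima:
    def test_single_lorentzian(self):
        x = np.arange(1700.0, 1780.0, 0.5)
        y = 1.0 / (1.0 + ((x - 1742.0) / 6.0) ** 2)
        peaks = mc.band_maxima(x, y)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(1742.0, abs=0.5)

    def test_two_overlapping_bands_in_order(self):
        x = np.arange(1690.0, 1780.0, 0.5)
        y = np.exp(-0.5 * ((x - 1716.0) / 5.0) ** 2) + 0.9 * np.exp(
            -0.5 * ((x - 1742.0) / 5.0) ** 2
        )
        peaks = mc.band_maxima(x, y)
        assert len(peaks) == 2
        assert peaks[0] == pytest.approx(1716.0, abs=1.0)
        assert peaks[1] == pytest.approx(1742.0, abs=1.0)

    def test_flat_spectrum_empty(self):
        assert mc.band_maxima(np.arange(100.0), np.ones(100)) == []

    def test_window_applied(self):
        x = np.arange(1500.0, 1800.0, 1.0)
        y = np.exp(-0.5 * ((x - 1550.0) / 5.0) ** 2) + np.exp(
            -0.5 * ((x - 1742.0) / 5.0) ** 2
        )
        peaks = mc.band_maxima(x, y, window=(1700.0, 1780.0))
        assert len(peaks) == 1 and peaks[0] == pytest.approx(1742.0, abs=1.0)


# ---------------------------------------------------------------------------
# fluctuation mechanics
# ---------------------------------------------------------------------------


class TestFluctuationEstimators:
    def test_constant_enthalpy_zero(self):
        series = mc.FluctuationSeries(np.full(100, 500.0), 300.0)
        assert mc.heat_capacity_fluct(series) == 0.0

    def test_gaussian_closed_form(self):
        # variance 1 (kJ/mol)^2 at 300 K -> 1.34 J mol^-1 K^-1
        rng = np.random.default_rng(6)
        h = rng.normal(100.0, 1.0, 100_000)
        series = mc.FluctuationSeries(h, 300.0)
        got_j = mc.heat_capacity_fluct(series) * 1000.0
        expected = 1.0 / (8.314462618e-3 * 300.0**2) * 1000.0
        assert expected == pytest.approx(1.336, abs=0.01)
        se = expected * np.sqrt(2 / (len(h) - 1))
        assert abs(got_j - expected) < 3 * se

    def test_variance_linearity(self):
        rng = np.random.default_rng(7)
        h = rng.normal(0, 1, 50_000)
        c1 = mc.heat_capacity_fluct(mc.FluctuationSeries(h, 310.0))
        c2 = mc.heat_capacity_fluct(mc.FluctuationSeries(h * np.sqrt(2), 310.0))
        assert c2 == pytest.approx(2 * c1, rel=1e-9)

    def test_constant_area_zero(self):
        series = mc.FluctuationSeries(np.full(50, 29.3), 310.0)
        assert mc.area_compressibility(series) == 0.0

    def test_area_closed_form(self):
        rng = np.random.default_rng(8)
        a = rng.normal(29.3, 0.2, 100_000)
        series = mc.FluctuationSeries(a, 310.0)
        got = mc.area_compressibility(series)
        expected = 0.2**2 / (29.3 * 8.314462618e-3 * 310.0)
        se = expected * np.sqrt(2 / len(a))
        assert abs(got - expected) < 3 * se

    def test_area_scaling_law(self):
        rng = np.random.default_rng(9)
        a = rng.normal(30.0, 0.5, 10_000)
        k1 = mc.area_compressibility(mc.FluctuationSeries(a, 300.0))
        k3 = mc.area_compressibility(mc.FluctuationSeries(3 * a, 300.0))
        assert k3 == pytest.approx(3 * k1, rel=1e-9)

    def test_two_samples_minimum(self):
        with pytest.raises(ParseError):
            mc.FluctuationSeries(np.array([1.0]), 300.0)


class TestBendingModulus:
    def test_unit_case(self):
        assert mc.bending_modulus(4.0, 1.0) == pytest.approx(1.0)

    def test_quadratic_in_thickness(self):
        k1 = mc.bending_modulus(2.0, 0.7)
        k2 = mc.bending_modulus(4.0, 0.7)
        assert k2 == pytest.approx(4 * k1)

    def test_table_thickness_arithmetic(self):
        kappa = 0.37
        assert mc.bending_modulus(4.514, kappa) == pytest.approx(
            4.514**2 / 16 / kappa, rel=1e-12
        )
        assert 4.514**2 / 16 == pytest.approx(1.2735, abs=2e-4)

    def test_zero_kappa_rejected(self):
        with pytest.raises(ParseError):
            mc.bending_modulus(4.0, 0.0)


# ---------------------------------------------------------------------------
# pipeline closure: make_spectra -> mca -> fit
# ---------------------------------------------------------------------------


class TestPipelineClosure:
    def test_single_center_recovered(self):
        spec = sd.MeltingSpec(transitions=((53.9, 0.8, -1.0),), noise_sd=0.01, seed=21)
        dec = mc.mca_decompose(sd.make_spectra(spec), 1)
        fit = mc.fit_boltzmann(dec.temperatures, dec.C[:, 0], 1)
        assert fit.centers[0] == pytest.approx(53.9, abs=0.2)

    def test_double_centers_recovered(self):
        spec = sd.MeltingSpec(
            transitions=((51.5, 0.6, -0.6), (53.3, 0.5, -0.8)), noise_sd=0.01, seed=22
        )
        dec = mc.mca_decompose(sd.make_spectra(spec), 1)
        fit = mc.fit_boltzmann(dec.temperatures, dec.C[:, 0], 2)
        assert fit.centers[0] == pytest.approx(51.5, abs=0.2)
        assert fit.centers[1] == pytest.approx(53.3, abs=0.2)

    def test_spectra_csv_round_trip(self, tmp_path):
        spec = sd.MeltingSpec(noise_sd=0.002, seed=23)
        sp = sd.make_spectra(spec)
        path = tmp_path / "spectra.csv"
        mc.write_spectra_csv(path, sp)
        back = mc.read_spectra_csv(path)
        assert np.allclose(back.absorbance, sp.absorbance)
        assert np.allclose(back.temperatures, sp.temperatures)
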