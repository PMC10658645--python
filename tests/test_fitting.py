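"""Time-domain fitting, CRLBs, SNR and metabolite corrections."""

import numpy as np
import pytest

from cmrsi.fitting import (
    CorrectionConfig,
    FitModel,
    FitParams,
    ResonanceFitSpec,
    blood_correct,
    compute_crlb,
    compute_snr,
    fit_time_domain,
    model_fid,
    pcr_atp_ratio,
    saturation_correct,
    saturation_factor,
)

DWELL = 2.0e-4


def lorentzian_fid(n, dwell, lines):
    t = np.arange(n) * dwell
    out = np.zeros(n, dtype=complex)
    for a, f, lw, ph in lines:
        out += a * np.exp(1j * ph) * np.exp((2j * np.pi * f - np.pi * lw) * t)
    return out


class TestFit:
    def test_noiseless_single_lorentzian_recovered(self):
        model = FitModel((ResonanceFitSpec("PCr", 0.0, (-50, 50), 25.0),), DWELL)
        fid = lorentzian_fid(256, DWELL, [(1.0, 0.0, 30.0, 0.0)])
        r = fit_time_domain(fid, model)
        assert r.amplitudes["PCr"] == pytest.approx(1.0, rel=1e-6)
        assert r.frequencies_hz["PCr"] == pytest.approx(0.0, abs=1e-4)
        assert r.linewidths_hz["PCr"] == pytest.approx(30.0, rel=1e-6)

    def test_two_resonance_amplitude_ratio(self):
        model = FitModel(
            (
                ResonanceFitSpec("A", 0.0, (-50, 50), 30.0),
                ResonanceFitSpec("B", -150.0, (-200, -100), 30.0),
            ),
            DWELL,
        )
        fid = lorentzian_fid(256, DWELL, [(2.0, 0.0, 30.0, 0.0), (1.0, -150.0, 30.0, 0.0)])
        r = fit_time_domain(fid, model)
        assert r.amplitudes["A"] / r.amplitudes["B"] == pytest.approx(2.0, rel=1e-6)

    def test_randomized_noiseless_multiresonance_recovery(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            n_res = int(rng.integers(1, 4))
            freqs = rng.choice(np.arange(-900, 901, 300), size=n_res, replace=False)
            truth = [
                (rng.uniform(0.5, 3.0), f + rng.uniform(-20, 20), rng.uniform(15, 60), 0.0)
                for f in freqs
            ]
            model = FitModel(
                tuple(
                    ResonanceFitSpec(f"r{i}", float(f), (float(f) - 40, float(f) + 40), 35.0)
                    for i, f in enumerate(freqs)
                ),
                DWELL,
            )
            fid = lorentzian_fid(512, DWELL, truth)
            r = fit_time_domain(fid, model)
            for i, (a, f, lw, _) in enumerate(truth):
                assert r.amplitudes[f"r{i}"] == pytest.approx(a, rel=1e-5)
                assert r.linewidths_hz[f"r{i}"] == pytest.approx(lw, rel=1e-4)

    def test_phase_recovered_in_shared_mode(self):
        model = FitModel((ResonanceFitSpec("PCr", 0.0, (-50, 50), 25.0),), DWELL)
        fid = lorentzian_fid(256, DWELL, [(1.5, 10.0, 30.0, 0.6)])
        r = fit_time_domain(fid, model)
        assert r.params.phases_rad[0] == pytest.approx(0.6, abs=1e-5)

    def test_too_short_fid_rejected(self):
        model = FitModel(
            tuple(ResonanceFitSpec(f"r{i}", 100.0 * i, (100.0 * i - 10, 100.0 * i + 10)) for i in range(4)),
            DWELL,
        )
        with pytest.raises(ValueError, match="under-determined"):
            fit_time_domain(np.ones(16, dtype=complex), model)


class TestCrlb:
    def test_crlb_scales_linearly_with_noise(self):
        model = FitModel((ResonanceFitSpec("PCr", 0.0, (-50, 50), 30.0),), DWELL)
        p = FitParams(np.array([1.0]), np.array([0.0]), np.array([30.0]), np.array([0.0]))
        c1 = compute_crlb(model, p, 0.05, 256)
        c2 = compute_crlb(model, p, 0.10, 256)
        for key in c1:
            assert c2[key] == pytest.approx(2 * c1[key], rel=1e-9)

    def test_undamped_amplitude_crlb_closed_form(self):
        # amplitude orthogonal to frequency and phase at the true point;
        # with the linewidth held fixed the bound is sigma / sqrt(N)
        sigma, n = 0.1, 256
        model = FitModel(
            (ResonanceFitSpec("X", 0.0, (-50, 50), 1e-6, (1e-7, 1.0)),), DWELL
        )
        p = FitParams(np.array([1.0]), np.array([0.0]), np.array([1e-6]), np.array([0.0]))
        crlb = compute_crlb(model, p, sigma, n, fixed={"X.linewidth"})
        assert crlb["X.amplitude"] == pytest.approx(sigma / np.sqrt(n), rel=0.01)
        assert crlb["X.linewidth"] == 0.0

    def test_overlapping_resonances_inflate_bounds(self):
        sigma = 0.05
        p = FitParams(np.ones(2), np.array([0.0, 0.0]), np.array([30.0, 30.0]), np.zeros(2))
        prev = 0.0
        for df in (64.0, 32.0, 16.0, 8.0):
            model = FitModel(
                (
                    ResonanceFitSpec("a", 0.0, (-100, 100), 30.0),
                    ResonanceFitSpec("b", df, (-100, 200), 30.0),
                ),
                DWELL,
                phase_mode="free",
            )
            params = FitParams(np.ones(2), np.array([0.0, df]), np.array([30.0, 30.0]), np.zeros(2))
            crlb = compute_crlb(model, params, sigma, 256)
            assert crlb["a.amplitude"] > prev
            prev = crlb["a.amplitude"]

    def test_monte_carlo_sd_attains_crlb(self):
        # moderately long check kept small: criterion-scale version lives in
        # the acceptance suite
        rng = np.random.default_rng(17)
        sigma = 1.0 / 15.0
        model = FitModel((ResonanceFitSpec("PCr", 0.0, (-50, 50), 30.0),), DWELL)
        truth = FitParams(np.array([1.0]), np.array([0.0]), np.array([30.0]), np.array([0.0]))
        clean = model_fid(model, truth, 256)
        amps = []
        for _ in range(120):
            noise = sigma * (rng.standard_normal(256) + 1j * rng.standard_normal(256))
            r = fit_time_domain(clean + noise, model, n_starts=1)
            amps.append(r.amplitudes["PCr"])
        crlb = compute_crlb(model, truth, sigma, 256)
        assert np.std(amps, ddof=1) >= 0.7 * crlb["PCr.amplitude"]
        assert np.std(amps, ddof=1) == pytest.approx(crlb["PCr.amplitude"], rel=0.25)


class TestSnr:
    def test_snr_is_amplitude_over_noise_sd(self):
        model = FitModel((ResonanceFitSpec("PCr", 0.0, (-50, 50), 30.0),), DWELL)
        rng = np.random.default_rng(3)
        fid = lorentzian_fid(256, DWELL, [(20.0, 0.0, 30.0, 0.0)])
        fid += rng.standard_normal(256) + 1j * rng.standard_normal(256)  # sigma = 1 per component
        r = fit_time_domain(fid, model, n_starts=1)
        assert compute_snr(r, "PCr") == pytest.approx(r.amplitudes["PCr"] / r.noise_sd)
        assert compute_snr(r, "PCr") == pytest.approx(20.0, rel=0.25)

    def test_scaling_data_preserves_snr_definition(self):
        model = FitModel((ResonanceFitSpec("PCr", 0.0, (-50, 50), 30.0),), DWELL)
        rng = np.random.default_rng(4)
        noise = 0.5 * (rng.standard_normal(256) + 1j * rng.standard_normal(256))
        fid = lorentzian_fid(256, DWELL, [(10.0, 0.0, 30.0, 0.0)]) + noise
        r1 = fit_time_domain(fid, model, n_starts=1)
        r2 = fit_time_domain(2 * fid, model, n_starts=1)
        assert compute_snr(r2, "PCr") == pytest.approx(compute_snr(r1, "PCr"), rel=1e-6)

    def test_noise_estimator_unbiased_on_noise_tails(self):
        # estimator calibration: pure-noise tail, known sigma
        rng = np.random.default_rng(9)
        sigma = 0.8
        ests = []
        for _ in range(200):
            tail = sigma * (rng.standard_normal(64) + 1j * rng.standard_normal(64))
            ests.append(np.sqrt((np.sum(tail.real**2) + np.sum(tail.imag**2)) / 128))
        assert np.mean(ests) == pytest.approx(sigma, rel=0.03)


class TestCorrections:
    def test_blood_correction_disabled_and_no_dpg(self):
        cfg0 = CorrectionConfig(blood_atp_per_dpg=0.0)
        amps = {"PCr": 2.0, "gamma-ATP": 1.0, "2,3-DPG2": 0.5, "2,3-DPG3": 0.7}
        assert blood_correct(amps, cfg0) == 1.0
        cfg = CorrectionConfig(blood_atp_per_dpg=0.3)
        assert blood_correct({"PCr": 2.0, "gamma-ATP": 1.0}, cfg) == 1.0

    def test_blood_correction_arithmetic(self):
        cfg = CorrectionConfig(blood_atp_per_dpg=0.3)
        assert blood_correct({"gamma-ATP": 1.0, "2,3-DPG2": 1.0, "2,3-DPG3": 1.0}, cfg) == pytest.approx(0.7)

    def test_negative_blood_correction_clamped_with_warning(self):
        cfg = CorrectionConfig(blood_atp_per_dpg=1.0)
        with pytest.warns(RuntimeWarning):
            out = blood_correct({"gamma-ATP": 0.1, "2,3-DPG2": 1.0}, cfg)
        assert out == 0.0

    def test_saturation_factor_limits_and_closed_form(self):
        assert saturation_factor(1000.0, 1.0, 90.0) == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ValueError):
            saturation_factor(1.0, 1.0, 0.0)
        e = np.exp(-1.0 / 3.0)
        expected = (1 - e) * np.sin(np.deg2rad(30)) / (1 - np.cos(np.deg2rad(30)) * e)
        assert saturation_factor(1.0, 3.0, 30.0) == pytest.approx(expected, rel=1e-12)

    def test_saturation_factor_matches_bloch_steady_state(self):
        # independent oracle: iterate the longitudinal Bloch recursion
        tr, t1, alpha = 1.0, 3.0, np.deg2rad(30.0)
        mz = 1.0
        for _ in range(5000):
            mz = 1.0 + (mz * np.cos(alpha) - 1.0) * np.exp(-tr / t1)
        assert saturation_factor(tr, t1, 30.0) == pytest.approx(mz * np.sin(alpha), rel=1e-9)

    def test_ratio_invariances(self):
        cfg = CorrectionConfig(blood_atp_per_dpg=0.0, tr_s=1000.0, flip_angle_deg=90.0)
        amps = {"PCr": 1.7, "gamma-ATP": 1.7}
        assert pcr_atp_ratio(amps, cfg) == pytest.approx(1.0)
        scaled = {k: 3.1 * v for k, v in amps.items()}
        assert pcr_atp_ratio(scaled, cfg) == pytest.approx(pcr_atp_ratio(amps, cfg))

    def test_saturation_correct_divides_each_metabolite(self):
        cfg = CorrectionConfig(tr_s=1.0, flip_angle_deg=30.0, t1_s={"PCr": 3.0, "gamma-ATP": 1.5})
        amps = {"PCr": 1.0, "gamma-ATP": 1.0}
        out = saturation_correct(amps, cfg)
        assert out["PCr"] == pytest.approx(1.0 / saturation_factor(1.0, 3.0, 30.0))
        assert out["gamma-ATP"] == pytest.approx(1.0 / saturation_factor(1.0, 1.5, 30.0))
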