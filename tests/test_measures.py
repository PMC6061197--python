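"""Rates, spectra, spectral entropy, PLV, balance estimate, power-law fits."""

import numpy as np
import pytest

from updownnet.measures import (
    RateSeries,
    Spectrum,
    average_spectrum,
    balance_estimate,
    entropy_of_spectrum,
    firing_rate,
    fit_powerlaw,
    moving_average,
    plv,
    power_spectrum,
    spectral_entropy,
    spectral_peak,
)
from updownnet.raster import Raster
from updownnet.synthetic import make_periodic_raster, make_poisson_raster


def _raster(times, ids, N, t_end):
    return Raster(times=np.asarray(times, float), ids=np.asarray(ids), N=N, t_end=t_end)


class TestFiringRate:
    def test_fifty_spikes_in_one_bin(self):
        r = _raster(np.full(50, 0.5), np.arange(50), 1000, 1.0)
        out = firing_rate(r, delta_t=1.0)
        assert out.r[0] == pytest.approx(50.0)  # 50 / (1000 * 1 ms) in Hz

    def test_empty_raster(self):
        out = firing_rate(_raster([], [], 100, 10.0))
        assert np.all(out.r == 0) and len(out) == 10

    def test_everyone_every_bin(self):
        N, T = 20, 5
        times = np.repeat(np.arange(T) + 0.5, N)
        ids = np.tile(np.arange(N), T)
        out = firing_rate(_raster(times, ids, N, float(T)))
        np.testing.assert_allclose(out.r, 1000.0)  # 1 spike / neuron / ms

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            firing_rate(_raster([], [], 10, 1.0), delta_t=0.0)


class TestPowerSpectrum:
    def test_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1024)
        spec = power_spectrum(x, 1.0, kind="spikes")
        # two-sided energy: sum |X_k|^2 = n * sum x^2 (numpy convention)
        S_full = np.abs(np.fft.fft(x)) ** 2 / spec.T
        assert np.sum(S_full) == pytest.approx(
            np.sum(x**2) * len(x) / spec.T, rel=1e-6
        )

    def test_poisson_plateau_equals_rate(self):
        nu = 100.0
        raster = make_poisson_raster(200, nu, 20000.0, seed=3)
        specs = [
            power_spectrum(raster.binned(j), 1.0, kind="spikes") for j in range(200)
        ]
        avg = average_spectrum(specs)
        plateau = avg.S[avg.f > 100].mean()
        assert plateau == pytest.approx(nu, rel=0.05)

    def test_sinusoid_peak(self):
        t = np.arange(2000) * 1e-3
        v = np.sin(2 * np.pi * 25 * t)
        spec = power_spectrum(v, 1.0, kind="voltage")
        assert spec.f[np.argmax(spec.S)] == pytest.approx(25.0)
        assert spec.units_tag == "mV2_per_Hz"

    def test_too_short(self):
        with pytest.raises(ValueError):
            power_spectrum(np.array([1.0]), 1.0)


class TestAverageSpectrum:
    def test_identical_spectra_unchanged(self):
        s = power_spectrum(np.sin(np.arange(100.0)), 1.0)
        out = average_spectrum([s, s, s])
        np.testing.assert_allclose(out.S, s.S)

    def test_pointwise_mean(self):
        f = np.array([0.0, 1.0])
        a = Spectrum(f=f, S=np.array([0.0, 2.0]), units_tag="per_s", T=1.0)
        b = Spectrum(f=f, S=np.array([2.0, 0.0]), units_tag="per_s", T=1.0)
        np.testing.assert_allclose(average_spectrum([a, b]).S, [1.0, 1.0])

    def test_grid_mismatch(self):
        a = Spectrum(f=np.array([0.0, 1.0]), S=np.zeros(2), units_tag="per_s", T=1.0)
        b = Spectrum(f=np.array([0.0, 2.0]), S=np.zeros(2), units_tag="per_s", T=1.0)
        with pytest.raises(ValueError):
            average_spectrum([a, b])


class TestMovingAverage:
    def test_constant_unchanged(self):
        s = Spectrum(f=np.arange(50.0), S=np.full(50, 3.0), units_tag="per_s", T=1.0)
        np.testing.assert_allclose(moving_average(s, 20).S, 3.0)

    def test_window_one_is_identity(self):
        s = Spectrum(f=np.arange(10.0), S=np.arange(10.0), units_tag="per_s", T=1.0)
        np.testing.assert_allclose(moving_average(s, 1).S, s.S)

    def test_impulse_spreads_to_plateau(self):
        S = np.zeros(101)
        S[50] = 1.0
        s = Spectrum(f=np.arange(101.0), S=S, units_tag="per_s", T=1.0)
        out = moving_average(s, 20)
        assert out.S[50] == pytest.approx(1 / 20)


class TestSpectralEntropy:
    def test_white_noise_near_one(self):
        rng = np.random.default_rng(1)
        r = RateSeries(t=np.arange(20000.0), r=rng.normal(10, 2, 20000), delta_t=1.0)
        assert spectral_entropy(r).H_s > 0.95

    def test_pure_sinusoid_near_zero(self):
        t = np.arange(2000.0)
        r = RateSeries(t=t, r=10 + 5 * np.sin(2 * np.pi * 0.01 * t), delta_t=1.0)
        assert spectral_entropy(r).H_s < 0.05

    def test_uniform_spectrum_is_exactly_one(self):
        assert entropy_of_spectrum(np.full(1000, 0.123)) == pytest.approx(1.0, abs=1e-12)

    def test_concentration_lowers_entropy(self):
        S = np.full(1000, 1.0)
        base = entropy_of_spectrum(S)
        S2 = S.copy()
        S2[10] += S2[20] + S2[30]
        S2[20] = S2[30] = 0.0
        assert entropy_of_spectrum(S2) < base

    def test_constant_rate_rejected(self):
        r = RateSeries(t=np.arange(100.0), r=np.zeros(100), delta_t=1.0)
        with pytest.raises(ValueError):
            spectral_entropy(r)

    def test_jitter_broadening_raises_entropy(self):
        """Once jitter starts washing out the rhythm, H_s grows toward 1.

        (The dependence is not monotone from zero: a near-delta burst train
        spreads power over many harmonics, so small jitter first *lowers*
        H_s by suppressing harmonics; the broadening regime starts around
        jitter ~ tau_burst.)
        """
        values = []
        for jitter in (5.0, 25.0, 50.0):
            h = []
            for seed in range(3):
                raster = make_periodic_raster(200, 10.0, jitter, 1.0, 4000.0, seed=seed)
                rate = firing_rate(raster)
                h.append(spectral_entropy(rate).H_s)
            values.append(np.mean(h))
        assert values[0] < values[1] < values[2]
        assert values[-1] > 0.9


class TestPLV:
    def test_identical_trains_give_one(self):
        raster = make_poisson_raster(1, 20.0, 2000.0, seed=0)
        times, ids = raster.times, raster.ids
        r2 = Raster(
            times=np.concatenate([times, times]),
            ids=np.concatenate([np.zeros_like(ids), np.ones_like(ids)]),
            N=2,
            t_end=2000.0,
        )
        assert plv(r2, K=1, seed=0).plv == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self):
        raster = make_poisson_raster(300, 50.0, 2000.0, seed=2)
        assert plv(raster, K=60, seed=1).plv < 0.1

    def test_bounds_and_saturation_in_K(self, weak_noise_sim):
        a = plv(weak_noise_sim.raster, K=60, t_start=500.0, seed=3)
        b = plv(weak_noise_sim.raster, K=120, t_start=500.0, seed=4)
        assert 0 <= a.plv <= 1 and 0 <= b.plv <= 1
        assert abs(a.plv - b.plv) < 0.05

    def test_synchronized_bursts_beat_poisson(self):
        sync = make_periodic_raster(100, 10.0, 2.0, 0.9, 2000.0, seed=5)
        poisson = make_poisson_raster(100, 10.0, 2000.0, seed=6)
        assert plv(sync, K=60, seed=0).plv > 3 * plv(poisson, K=60, seed=0).plv

    def test_no_spikes_rejected(self):
        with pytest.raises(ValueError):
            plv(_raster([], [], 10, 2000.0))


class TestBalanceEstimate:
    def test_zero_rates(self):
        out = balance_estimate(0.15, 1.0, 8, 2, 0.0, 0.0)
        assert out.I_est == 0.0

    def test_zero_at_excitatory_reversal_without_inhibition(self):
        out = balance_estimate(0.15, 0.0, 8, 2, 5.0, 5.0, v_ref=0.0)
        assert out.I_est == 0.0

    def test_lif_style_balance_at_ratio_four(self):
        """nu and tau equal, C_ex/C_in = 4: summed-convention input vanishes
        at g_in/g_ex = 4 for the voltage midway between the reversals."""
        out = balance_estimate(
            g_ex=0.1, g_in=0.4, C_ex=8, C_in=2, nu_ex=5.0, nu_in=5.0,
            tau_ex=5.0, tau_in=5.0, v_ref=-40.0, sign_convention="sum",
        )
        assert out.I_est == pytest.approx(0.0, abs=1e-12)

    def test_subtract_sign_convention_verbatim(self):
        # I = g_ex C_ex nu_ex tau_ex (E_ex - v) - g_in C_in nu_in tau_in (E_in - v)
        out = balance_estimate(
            g_ex=0.1, g_in=0.2, C_ex=10, C_in=5, nu_ex=2.0, nu_in=4.0,
            tau_ex=5.0, tau_in=6.0, E_ex=0.0, E_in=-80.0, v_ref=-60.0,
        )
        ex = 0.1 * 10 * 2e-3 * 5.0 * 60.0
        inh = 0.2 * 5 * 4e-3 * 6.0 * (-20.0)
        assert out.I_est == pytest.approx(ex - inh)


class TestPowerlawFit:
    def test_exact_inverse_square(self):
        f = np.arange(0.0, 300.0)
        S = np.zeros_like(f)
        S[1:] = f[1:] ** -2.0
        spec = Spectrum(f=f, S=S, units_tag="mV2_per_Hz", T=1.0)
        assert fit_powerlaw(spec, smooth_window=1) == pytest.approx(2.0, abs=1e-9)

    def test_flat_spectrum(self):
        spec = Spectrum(
            f=np.arange(0.0, 300.0), S=np.ones(300), units_tag="per_s", T=1.0
        )
        assert fit_powerlaw(spec, smooth_window=1) == pytest.approx(0.0, abs=1e-9)

    def test_noisy_power_law_recovered(self):
        rng = np.random.default_rng(7)
        f = np.arange(0.0, 500.0)
        S = np.zeros_like(f)
        S[1:] = 3.0 * f[1:] ** -1.5 * np.exp(rng.normal(0, 0.05, f.size - 1))
        spec = Spectrum(f=f, S=S, units_tag="mV2_per_Hz", T=1.0)
        assert fit_powerlaw(spec) == pytest.approx(1.5, abs=0.15)

    def test_band_too_narrow(self):
        spec = Spectrum(f=np.array([0.0, 1.0]), S=np.ones(2), units_tag="per_s", T=1.0)
        with pytest.raises(ValueError):
            fit_powerlaw(spec)


class TestSpectralPeak:
    def test_skips_zero_bin(self):
        f = np.arange(0.0, 100.0)
        S = np.exp(-f / 30)
        S[0] = 100.0
        S[10] += 1.0
        spec = Spectrum(f=f, S=S, units_tag="per_s", T=1.0)
        assert spectral_peak(spec, smooth_window=1) == pytest.approx(10.0)
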