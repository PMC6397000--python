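"""Theta phase estimation, phase precession, spectral shift, speed
modulation and pair CCG offsets."""

import numpy as np
import pytest
from scipy.special import iv

from placecode import LfpSignal, SpikeTrain
from placecode.placefields import LapField, PlaceField
from placecode.ratemaps import RateMap
from placecode.simulate import LfpSpec, simulate_lfp
from placecode.theta import (PhaseSeries, circular_mean, circ_circ_corr,
                             instantaneous_frequency, in_field_spike_data,
                             lfp_self_shift, pair_theta_offsets,
                             phase_locking, precession_fit, rayleigh_p,
                             resultant_length, rotate_to_population_peak,
                             single_lap_precession, spike_phases,
                             spatially_stable_trials, speed_theta_modulation,
                             theta_filter_phase, unit_lfp_shift)
from tests.test_ratemaps import uniform_sweep_traj

FS = 1250.0


def make_lfp(f=8.0, T=30.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, T, 1.0 / FS)
    return LfpSignal(t, np.cos(2 * np.pi * f * t)
                     + noise * rng.standard_normal(len(t)), FS)


class TestPhaseEstimation:
    def test_pure_cosine_phase_rate(self):
        ps = theta_filter_phase(make_lfp(8.0))
        sl = slice(int(2 * FS), int(28 * FS))
        expect = 2 * np.pi * 8.0 * ps.t[sl]
        dev = np.angle(np.exp(1j * (ps.unwrapped[sl] - expect)))
        assert np.max(np.abs(dev)) < 0.05

    def test_waveform_agrees_with_hilbert_on_symmetric_wave(self, traj30):
        lfp, _ = simulate_lfp(traj30, LfpSpec(noise_sd=0.1), seed=8)
        h = theta_filter_phase(lfp, method="hilbert")
        w = theta_filter_phase(lfp, method="waveform")
        sl = slice(int(2 * FS), len(lfp.t) - int(2 * FS))
        d = np.angle(np.exp(1j * (h.unwrapped[sl] - w.unwrapped[sl])))
        assert np.sqrt(np.mean(d ** 2)) < 0.15

    def test_waveform_tracks_asymmetry(self, traj30):
        rms = {}
        for a in (0.0, 0.3):
            lfp, _ = simulate_lfp(traj30, LfpSpec(noise_sd=0.05,
                                                  asymmetry=a), seed=9)
            h = theta_filter_phase(lfp, method="hilbert")
            w = theta_filter_phase(lfp, method="waveform")
            sl = slice(int(2 * FS), len(lfp.t) - int(2 * FS))
            d = np.angle(np.exp(1j * (h.unwrapped[sl] - w.unwrapped[sl])))
            rms[a] = np.sqrt(np.mean(d ** 2))
        assert rms[0.3] > 1.3 * rms[0.0]

    def test_band_validation(self):
        with pytest.raises(ValueError):
            theta_filter_phase(make_lfp(), band=(4.0, 700.0))


class TestSpikePhases:
    def test_exact_at_sample_times(self):
        ps = PhaseSeries(np.arange(0, 1, 0.001),
                         2 * np.pi * 7 * np.arange(0, 1, 0.001), 1000.0,
                         "hilbert")
        st = ps.t[::100]
        np.testing.assert_allclose(spike_phases(st, ps),
                                   np.mod(ps.unwrapped[::100], 2 * np.pi),
                                   atol=1e-9)

    def test_empty_train(self):
        ps = PhaseSeries(np.arange(0, 1, 0.001),
                         np.arange(0, 1, 0.001) * 40.0, 1000.0, "hilbert")
        assert len(spike_phases(np.array([]), ps)) == 0

    def test_out_of_span_spikes_dropped(self):
        ps = PhaseSeries(np.arange(0, 1, 0.001),
                         np.arange(0, 1, 0.001) * 40.0, 1000.0, "hilbert")
        assert len(spike_phases(np.array([-0.5, 0.5, 2.0]), ps)) == 1

    def test_rotation_puts_population_peak_at_180(self):
        rng = np.random.default_rng(10)
        ps = PhaseSeries(np.arange(0, 10, 0.001),
                         2 * np.pi * 7 * np.arange(0, 10, 0.001), 1000.0,
                         "hilbert")
        # spikes locked near an arbitrary unrotated phase
        spikes = rng.uniform(0, 10, 3000)
        raw = np.interp(spikes, ps.t, ps.unwrapped)
        locked = spikes[np.mod(raw - 0.7, 2 * np.pi) < 0.5]
        pooled = spike_phases(locked, ps)
        rotate_to_population_peak(ps, pooled)
        mu = np.degrees(np.mod(circular_mean(spike_phases(locked, ps)),
                               2 * np.pi))
        assert abs(mu - 180.0) < 10.0


class TestPhaseLocking:
    def test_perfect_locking(self):
        mu, r, p = phase_locking(np.full(100, np.pi / 2))
        assert mu == pytest.approx(90.0)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_uniform_phases_not_locked(self):
        rng = np.random.default_rng(11)
        ps = [rayleigh_p(rng.uniform(0, 2 * np.pi, 500)) for _ in range(20)]
        assert np.mean(np.array(ps) > 0.05) >= 0.9

    def test_von_mises_resultant_length(self):
        rng = np.random.default_rng(12)
        phases = rng.vonmises(0.0, 1.0, 1000)
        assert abs(resultant_length(phases) - iv(1, 1.0) / iv(0, 1.0)) < 0.05

    def test_too_few_spikes_undefined(self):
        assert np.isnan(phase_locking(np.ones(5))[0])


class TestPrecessionFit:
    def test_noiseless_line_recovered(self):
        rng = np.random.default_rng(13)
        u = rng.uniform(0, 1, 200)
        phi = np.mod(1.0 - 2.0 * u, 2 * np.pi)
        fit = precession_fit(u, phi, n_perm=200, seed=14)
        assert fit.slope == pytest.approx(-2.0, abs=0.05)
        assert fit.correlation < -0.95
        assert fit.p < 0.01

    def test_shift_equivariance(self):
        rng = np.random.default_rng(15)
        u = rng.uniform(0, 1, 300)
        phi = np.mod(1.0 - 2.0 * u + rng.vonmises(0, 3, 300), 2 * np.pi)
        f1 = precession_fit(u, phi, n_perm=100, seed=16)
        f2 = precession_fit(u, np.mod(phi + 1.3, 2 * np.pi), n_perm=100,
                            seed=16)
        assert f1.slope == pytest.approx(f2.slope, abs=1e-3)
        assert abs(f1.correlation) == pytest.approx(abs(f2.correlation),
                                                    abs=1e-6)

    def test_fewer_than_four_spikes_rejected(self):
        assert precession_fit(np.ones(3), np.ones(3)) is None

    def test_circ_circ_corr_sign(self):
        u = np.linspace(0.1, 0.9, 50)
        assert circ_circ_corr(np.mod(-2 * u, 2 * np.pi),
                              np.mod(2 * u, 2 * np.pi)) < -0.9


def synthetic_precessing_session(n_spikes_per_lap=(8, 8, 8, 3)):
    """Forth/back sweeps with hand-placed spikes obeying phi = pi - 2u
    inside the field x in [90, 110] on every forth lap."""
    traj = uniform_sweep_traj(n_trials=8)
    f_theta = 7.0
    ps = PhaseSeries(traj.t, 2 * np.pi * f_theta * traj.t, 50.0, "hilbert")
    spikes = []
    forth_trials = [1, 3, 5, 7]
    for lap, n_sp in zip(forth_trials, n_spikes_per_lap):
        t_lap0 = traj.t[traj.trial_id == lap][0]
        for u in np.linspace(0.05, 0.95, n_sp):
            x = 90.0 + 20.0 * u
            t_x = t_lap0 + x / 15.0
            target = np.mod(np.pi - 2.0 * u, 2 * np.pi)
            k = np.round(f_theta * t_x - target / (2 * np.pi))
            spikes.append((k + target / (2 * np.pi)) / f_theta)
    train = SpikeTrain(0, np.sort(np.array(spikes)))
    field = PlaceField(0, "forth", 45, 54, 50, 8.0)
    field.lap_fields = [LapField(i, 45, 54, 50, 8.0)
                        for i in range(len(forth_trials))]
    grid_rate = np.zeros((len(forth_trials), 100))
    grid_rate[:, 45:55] = 5.0
    occ = np.ones_like(grid_rate) * 0.1
    rm = RateMap(0, "forth", __import__("placecode").BinGrid(),
                 np.array(forth_trials), grid_rate, grid_rate * occ, occ,
                 occ, np.ones(len(forth_trials)), 10.0)
    return traj, train, ps, field, rm


class TestSingleLapPrecession:
    def test_mean_matches_pooled_fit(self, grid):
        traj, train, ps, field, rm = synthetic_precessing_session(
            (8, 8, 8, 8))
        u, phi, _ = in_field_spike_data(traj, train, ps, field, grid)
        pooled = precession_fit(u, phi, n_perm=100, seed=17)
        out = single_lap_precession(traj, train, ps, field, rm, grid,
                                    n_perm=200, seed=18)
        assert out is not None
        mean_slope, mean_corr, n_laps = out
        assert n_laps == 4
        assert abs(mean_slope - pooled.slope) <= 0.2

    def test_three_spike_lap_skipped(self, grid):
        traj, train, ps, field, rm = synthetic_precessing_session(
            (8, 8, 8, 3))
        out = single_lap_precession(traj, train, ps, field, rm, grid,
                                    n_perm=200, seed=19)
        assert out is not None and out[2] == 3

    def test_fewer_than_three_laps_excluded(self, grid):
        traj, train, ps, field, rm = synthetic_precessing_session(
            (8, 8, 3, 3))
        assert single_lap_precession(traj, train, ps, field, rm, grid,
                                     n_perm=200, seed=20) is None


def test_spatially_stable_trials(grid):
    rng = np.random.default_rng(21)
    tmpl = np.zeros(100)
    tmpl[45:55] = np.hanning(10) * 8
    rows = np.tile(tmpl, (5, 1)) + 0.1 * rng.standard_normal((5, 100))
    rows[2] = rng.uniform(0, 8, 100)   # one unstable trial
    occ = np.ones_like(rows) * 0.1
    rm = RateMap(0, "forth", grid, np.arange(1, 6), rows, rows * occ, occ,
                 occ, np.ones(5), 10.0)
    field = PlaceField(0, "forth", 45, 54, 49, 8.0)
    sst = spatially_stable_trials(rm, field)
    assert 3 not in sst and len(sst) == 4


class TestSpectralShift:
    def test_known_frequency_gap(self):
        rng = np.random.default_rng(22)
        lfp = make_lfp(8.0, T=300.0, noise=0.3, seed=22)
        tf = np.arange(0.0, 300.0, 0.001)
        lam = 5.0 * (1.0 + 0.7 * np.cos(2 * np.pi * 8.5 * tf))
        spk = tf[rng.poisson(lam * 0.001) > 0]
        sh = unit_lfp_shift(SpikeTrain(0, spk), lfp)
        assert sh.qualified
        assert sh.shift == pytest.approx(0.5, abs=0.1)

    def test_locked_spikes_no_shift(self):
        rng = np.random.default_rng(23)
        lfp = make_lfp(8.0, T=300.0, noise=0.3, seed=23)
        tf = np.arange(0.0, 300.0, 0.001)
        lam = 5.0 * (1.0 + 0.7 * np.cos(2 * np.pi * 8.0 * tf))
        spk = tf[rng.poisson(lam * 0.001) > 0]
        sh = unit_lfp_shift(SpikeTrain(0, spk), lfp)
        assert sh.shift is not None and sh.shift < 0.1

    def test_unmodulated_cell_not_qualified(self):
        rng = np.random.default_rng(24)
        lfp = make_lfp(8.0, T=300.0, noise=0.3, seed=24)
        flags = []
        for k in range(5):
            spk = np.sort(rng.uniform(0, 300.0, 1500))
            flags.append(unit_lfp_shift(SpikeTrain(0, spk), lfp).qualified)
        assert np.mean(flags) <= 0.2

    def test_lfp_self_shift_is_zero(self):
        assert lfp_self_shift(make_lfp(8.0, T=120.0, noise=0.2)) == 0.0


class TestSpeedModulation:
    def test_gain_sign_recovered(self, traj30):
        lfp, _ = simulate_lfp(traj30, LfpSpec(freq_speed_gain=0.02), seed=25)
        r_freq, _ = speed_theta_modulation(lfp, traj30)
        assert r_freq > 0.02

    def test_no_gain_no_correlation(self, traj30):
        lfp, _ = simulate_lfp(traj30, LfpSpec(), seed=26)
        r_freq, _ = speed_theta_modulation(lfp, traj30)
        assert abs(r_freq) < 0.05

    def test_frequency_estimators_agree_on_chirp(self):
        t = np.arange(0.0, 120.0, 1.0 / FS)
        f = 6.2 + (7.8 - 6.2) * t / 120.0
        phase = 2 * np.pi * np.cumsum(f) / FS
        ps = PhaseSeries(t, phase, FS, "hilbert")
        f1 = instantaneous_frequency(ps, "phase")
        f2 = instantaneous_frequency(ps, "cycle")
        ok = np.isfinite(f2)
        assert np.sqrt(np.mean((f1[ok] - f2[ok]) ** 2)) < 0.1


class TestPairOffsets:
    def test_identical_trains_zero_offsets(self):
        rng = np.random.default_rng(27)
        t = np.sort(rng.uniform(0, 200, 3000))
        po = pair_theta_offsets(t, t)
        assert po.included
        assert abs(po.ccg_offset) < 0.005
        assert abs(po.theta_offset) < 0.002

    def test_delayed_copy_recovers_delay(self):
        rng = np.random.default_rng(28)
        t = np.sort(rng.uniform(0, 300, 4000))
        po = pair_theta_offsets(t, t + 0.030)
        assert po.theta_offset == pytest.approx(0.030, abs=0.003)

    def test_sparse_pair_gated_out(self):
        rng = np.random.default_rng(29)
        a = np.sort(rng.uniform(0, 300, 150))
        b = np.sort(rng.uniform(0, 300, 150))
        po = pair_theta_offsets(a, b)
        assert not po.included and po.ccg_offset is None
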