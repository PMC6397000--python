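"""Theta-band LFP processing and temporal-coding analyses.

Covers instantaneous theta phase estimation (Hilbert and waveform-based),
spike phase assignment and phase locking, circular-linear phase-precession
fits, the spike/LFP spectral frequency shift, speed modulation of theta
frequency and amplitude, and theta-timescale cross-correlogram offsets for
pairs of cells with overlapping place fields.

Phase convention: phase 0 at the peak of the filtered theta wave; after
session-level rotation the pooled pyramidal spike-phase histogram peaks at
180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr

from .placefields import PlaceField, _pearson
from .ratemaps import RateMap, spikes_to_samples
from .session import BinGrid, LfpSignal, SpikeTrain, Trajectory

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseSeries:
    t: np.ndarray
    unwrapped: np.ndarray    # monotone phase, radians
    fs: float
    method: str
    rotation_offset: float = 0.0

    @property
    def phase(self) -> np.ndarray:
        return np.mod(self.unwrapped + self.rotation_offset, TWO_PI)


@dataclass
class PrecessionFit:
    slope: float             # rad per normalized field unit
    correlation: float       # circular-circular r, sign = direction
    p: float                 # permutation p-value
    n_spikes: int
    phi0: float = np.nan
    at_boundary: bool = False


@dataclass
class SpectralShift:
    shift: float | None      # Hz; None when the cell does not qualify
    theta_mod_index: float
    spike_peak_freq: float
    lfp_peak_freq: float
    qualified: bool


@dataclass
class PairOffsets:
    ccg_offset: float | None     # s, behavioral-scale CCG peak
    theta_offset: float | None   # s, theta-scale CCG peak
    included: bool
    mean_bin_count: float = 0.0


# ---------------------------------------------------------------------------
# phase estimation
# ---------------------------------------------------------------------------

def theta_filter_phase(lfp: LfpSignal, band=(4.0, 12.0),
                       method: str = "hilbert") -> PhaseSeries:
    """Instantaneous theta phase of the LFP.

    ``hilbert``: zero-phase 4th-order Chebyshev type II band-pass (40 dB
    stopband) then analytic-signal phase.  ``waveform``: half-cycles from
    zero crossings of a 4-10 Hz narrow-band signal, extrema located in the
    1-40 Hz wide-band signal, phase linearly interpolated between peak and
    trough landmarks, preserving cycle asymmetry.
    """
    fs = lfp.fs
    if not (0 < band[0] < band[1] < fs / 2):
        raise ValueError(f"band {band} outside (0, fs/2)")
    if method == "hilbert":
        sos = signal.cheby2(4, 40.0, band, btype="bandpass", fs=fs,
                            output="sos")
        filt = signal.sosfiltfilt(sos, lfp.v)
        unwrapped = np.unwrap(np.angle(signal.hilbert(filt)))
        return PhaseSeries(lfp.t, unwrapped, fs, "hilbert")
    if method == "waveform":
        return _waveform_phase(lfp)
    raise ValueError(f"unknown phase method {method!r}")


def _waveform_phase(lfp: LfpSignal) -> PhaseSeries:
    fs = lfp.fs
    sos_n = signal.butter(2, (4.0, 10.0), btype="bandpass", fs=fs,
                          output="sos")
    narrow = signal.sosfiltfilt(sos_n, lfp.v)
    sos_w = signal.butter(2, (1.0, 40.0), btype="bandpass", fs=fs,
                          output="sos")
    wide = signal.sosfiltfilt(sos_w, lfp.v)
    zc = np.flatnonzero(np.diff(np.signbit(narrow)))
    if len(zc) < 3:
        raise ValueError("no theta cycles found")
    # one extremum of the wide-band signal per half cycle
    landmark_t, landmark_kind = [], []   # kind: +1 peak, -1 trough
    for a, b in zip(zc[:-1], zc[1:]):
        seg = wide[a:b + 1]
        if narrow[a + 1] >= 0:
            i = a + int(np.argmax(seg))
            landmark_kind.append(+1)
        else:
            i = a + int(np.argmin(seg))
            landmark_kind.append(-1)
        landmark_t.append(lfp.t[i])
    # cumulative phase: peaks at 2*pi*k, troughs pi later
    lt = np.array(landmark_t)
    kinds = np.array(landmark_kind)
    keep = np.flatnonzero(np.diff(kinds) != 0)
    keep = np.concatenate([[0], keep + 1])
    lt, kinds = lt[keep], kinds[keep]
    ph0 = 0.0 if kinds[0] == 1 else np.pi
    cum = ph0 + np.pi * np.arange(len(lt))
    unwrapped = np.interp(lfp.t, lt, cum)
    return PhaseSeries(lfp.t, unwrapped, fs, "waveform")


def rotate_to_population_peak(ps: PhaseSeries,
                              pooled_spike_phases: np.ndarray) -> PhaseSeries:
    """Rotate the session phase so the pooled pyramidal spike-phase
    distribution has its peak (circular mean) at 180 degrees."""
    mu = circular_mean(pooled_spike_phases)
    ps.rotation_offset = float(np.mod(np.pi - mu, TWO_PI))
    return ps


def spike_phases(spikes: SpikeTrain | np.ndarray,
                 ps: PhaseSeries) -> np.ndarray:
    """Theta phase at each spike time (linear interpolation on the
    unwrapped phase); spikes outside the LFP span are dropped."""
    st = spikes.spike_times if isinstance(spikes, SpikeTrain) \
        else np.asarray(spikes)
    inside = (st >= ps.t[0]) & (st <= ps.t[-1])
    u = np.interp(st[inside], ps.t, ps.unwrapped)
    return np.mod(u + ps.rotation_offset, TWO_PI)


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def circular_mean(phases: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * np.asarray(phases)))))


def resultant_length(phases: np.ndarray) -> float:
    return float(np.abs(np.mean(np.exp(1j * np.asarray(phases)))))


def rayleigh_p(phases: np.ndarray) -> float:
    """Rayleigh test of circular uniformity (Zar's approximation)."""
    n = len(phases)
    R = resultant_length(phases) * n
    z = R ** 2 / n
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - R ** 2)) - (1 + 2 * n))
    return float(min(max(p, 0.0), 1.0))


def phase_locking(phases: np.ndarray,
                  min_spikes: int = 10) -> tuple[float, float, float]:
    """(preferred phase in degrees, mean resultant length, Rayleigh p)."""
    phases = np.asarray(phases)
    if len(phases) < min_spikes:
        return np.nan, np.nan, np.nan
    mu = np.degrees(np.mod(circular_mean(phases), TWO_PI))
    return float(mu), resultant_length(phases), rayleigh_p(phases)


# ---------------------------------------------------------------------------
# phase precession
# ---------------------------------------------------------------------------

def _circ_lin_slope(u: np.ndarray, phi: np.ndarray,
                    bound: float = 4 * np.pi,
                    grid_step_cycles: float = 0.01,
                    refine: bool = True) -> tuple[float, bool]:
    """Slope (rad per unit) maximizing the resultant length of
    ``phi - s*u``; coarse grid then bounded refinement."""
    slopes = np.arange(-bound, bound + 1e-9, TWO_PI * grid_step_cycles)
    R = np.abs(np.exp(1j * (phi[None, :] - slopes[:, None] * u[None, :]))
               .mean(axis=1))
    s0 = slopes[int(np.argmax(R))]
    if not refine:
        return float(s0), bool(abs(abs(s0) - bound) < TWO_PI
                               * grid_step_cycles)

    def neg_r(s):
        return -np.abs(np.mean(np.exp(1j * (phi - s * u))))

    lo = max(-bound, s0 - TWO_PI * grid_step_cycles)
    hi = min(bound, s0 + TWO_PI * grid_step_cycles)
    res = minimize_scalar(neg_r, bounds=(lo, hi), method="bounded")
    s = float(res.x)
    at_boundary = bool(abs(abs(s) - bound) < TWO_PI * grid_step_cycles)
    return s, at_boundary


def circ_circ_corr(phi: np.ndarray, theta: np.ndarray) -> float:
    """Circular-circular correlation (Jammalamadaka & SenGupta)."""
    sp = np.sin(phi - circular_mean(phi))
    st = np.sin(theta - circular_mean(theta))
    denom = np.sqrt(np.sum(sp ** 2) * np.sum(st ** 2))
    if denom == 0:
        return 0.0
    return float(np.sum(sp * st) / denom)


def precession_fit(u: np.ndarray, phi: np.ndarray, n_perm: int = 1000,
                   seed=None, slope_bound: float = 4 * np.pi,
                   min_spikes: int = 4) -> PrecessionFit | None:
    """Circular-linear regression of spike phase on normalized position.

    The slope maximizes the resultant length of ``phi - s*u``; the
    correlation is circular-circular between ``phi`` and ``|s|*u`` (its
    sign carries the precession direction).  Significance comes from
    permuting spike positions and re-running the whole fit (slope
    included), so the p-value is exact under the null.
    """
    u = np.asarray(u, float)
    phi = np.asarray(phi, float)
    if len(u) < min_spikes:
        return None
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    s, at_boundary = _circ_lin_slope(u, phi, slope_bound)
    theta = np.mod(abs(s) * u, TWO_PI)
    r = circ_circ_corr(phi, theta)
    phi0 = circular_mean(phi - s * u)
    count = 0
    for _ in range(n_perm):
        up = rng.permutation(u)
        sp, _ = _circ_lin_slope(up, phi, slope_bound,
                                grid_step_cycles=0.02, refine=False)
        rp = circ_circ_corr(phi, np.mod(abs(sp) * up, TWO_PI))
        if abs(rp) >= abs(r) - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return PrecessionFit(s, r, p, len(u), float(phi0), at_boundary)


def in_field_spike_data(traj: Trajectory, spikes: SpikeTrain,
                        ps: PhaseSeries, field: PlaceField, grid: BinGrid,
                        speed_threshold: float = 2.0,
                        trial_ids: np.ndarray | None = None,
                        bin_range: tuple | None = None):
    """(normalized position in [0,1] along travel, phase) of in-field
    spikes during locomotion, optionally restricted to given trials or to
    an explicit bin extent (for lap fields)."""
    a, b = bin_range if bin_range is not None else (field.start, field.stop)
    x0, x1 = a * grid.bin_size, (b + 1) * grid.bin_size
    idx = spikes_to_samples(traj, spikes.spike_times)
    ok = (traj.speed[idx] > speed_threshold) & \
        (traj.direction[idx] == field.direction) & \
        (traj.x[idx] >= x0) & (traj.x[idx] < x1)
    if trial_ids is not None:
        ok &= np.isin(traj.trial_id[idx], trial_ids)
    st = spikes.spike_times[ok]
    x = traj.x[idx[ok]]
    u = (x - x0) / (x1 - x0)
    if field.direction == "back":
        u = 1.0 - u
    inside = (st >= ps.t[0]) & (st <= ps.t[-1])
    phi = np.mod(np.interp(st[inside], ps.t, ps.unwrapped)
                 + ps.rotation_offset, TWO_PI)
    return u[inside], phi, st[inside]


def spatially_stable_trials(rate_map: RateMap, field: PlaceField,
                            r_thresh: float = 0.6) -> np.ndarray:
    """Trial ids whose in-field rate vector correlates > r_thresh with the
    mean field (used to equalize stability before precession analysis)."""
    bins = field.bins
    mv = rate_map.mean_rate_vector[bins]
    ok = []
    for row, tr in enumerate(rate_map.trial_ids):
        r = _pearson(rate_map.per_trial_rate[row, bins], mv)
        if r is not None and r > r_thresh:
            ok.append(tr)
    return np.asarray(ok)


def single_lap_precession(traj: Trajectory, spikes: SpikeTrain,
                          ps: PhaseSeries, field: PlaceField,
                          rate_map: RateMap, grid: BinGrid,
                          n_perm: int = 200, seed=None,
                          min_laps: int = 3, min_spikes: int = 4,
                          speed_threshold: float = 2.0):
    """Average slope/correlation over significantly precessing laps.

    Fits each lap field separately; a lap qualifies with >= ``min_spikes``
    spikes and a significant (p < 0.05) negative-slope fit.  Returns
    ``(mean_slope, mean_corr, n_qualifying)`` or ``None`` when fewer than
    ``min_laps`` laps qualify.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    slopes, corrs = [], []
    for lf in field.lap_fields:
        tr = rate_map.trial_ids[lf.trial_index]
        u, phi, _ = in_field_spike_data(traj, spikes, ps, field, grid,
                                        speed_threshold,
                                        trial_ids=np.array([tr]),
                                        bin_range=(lf.start, lf.stop))
        fit = precession_fit(u, phi, n_perm, rng, min_spikes=min_spikes)
        if fit is not None and fit.p < 0.05 and fit.slope < 0:
            slopes.append(fit.slope)
            corrs.append(fit.correlation)
    if len(slopes) < min_laps:
        return None
    return float(np.mean(slopes)), float(np.mean(corrs)), len(slopes)


# ---------------------------------------------------------------------------
# spike/LFP spectral shift
# ---------------------------------------------------------------------------

def _multitaper_psd(x: np.ndarray, fs: float, nw: float = 3.0,
                    n_tapers: int = 5):
    n = len(x)
    tapers = signal.windows.dpss(n, nw, n_tapers)
    spec = np.abs(np.fft.rfft(tapers * (x - x.mean()), axis=1)) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, spec.mean(axis=0)


def _band_spectrum(x: np.ndarray, fs: float, band=(4.0, 12.0),
                   grid_df: float = 0.02):
    freqs, psd = _multitaper_psd(x, fs)
    grid = np.arange(band[0], band[1] + grid_df / 2, grid_df)
    return grid, np.interp(grid, freqs, psd)


def theta_modulation_index(freqs: np.ndarray, psd: np.ndarray,
                           half: float = 0.5) -> tuple[float, float]:
    """(index, peak frequency): mean power within +/-0.5 Hz of the theta
    peak divided by mean power below 5 Hz or above 9 Hz."""
    pk = freqs[int(np.argmax(psd))]
    near = np.abs(freqs - pk) <= half
    far = (freqs < 5.0) | (freqs > 9.0)
    if not far.any() or psd[far].mean() == 0:
        return np.nan, float(pk)
    return float(psd[near].mean() / psd[far].mean()), float(pk)


def unit_lfp_shift(spikes: SpikeTrain, lfp: LfpSignal,
                   band=(4.0, 12.0), mod_threshold: float = 1.4,
                   fs_spec: float = 125.0, max_shift: float = 2.0,
                   grid_df: float = 0.02) -> SpectralShift:
    """Frequency shift between a cell's spike spectrum and the LFP theta
    spectrum; positive when the cell oscillates faster than the LFP.

    The spike train is binned at ``1/fs_spec`` s and both multitaper
    spectra (time-bandwidth 3, 5 tapers) are interpolated to a 0.02 Hz
    grid over the theta band before cross-correlation.  Cells with a
    spike-spectrum theta modulation index <= ``mod_threshold`` do not
    qualify and get ``shift=None``.
    """
    t0, t1 = lfp.t[0], lfp.t[-1]
    n = int(np.floor((t1 - t0) * fs_spec))
    edges = t0 + np.arange(n + 1) / fs_spec
    binned, _ = np.histogram(spikes.spike_times, bins=edges)
    fgrid, spk = _band_spectrum(binned.astype(float), fs_spec, band, grid_df)
    dec = max(1, int(round(lfp.fs / fs_spec)))
    v = signal.decimate(lfp.v, dec, zero_phase=True) if dec > 1 else lfp.v
    _, lf = _band_spectrum(v, lfp.fs / dec, band, grid_df)
    tmi, spk_peak = theta_modulation_index(fgrid, spk)
    lfp_peak = float(fgrid[int(np.argmax(lf))])
    qualified = bool(np.isfinite(tmi) and tmi > mod_threshold)
    shift = spectrum_shift(spk, lf, grid_df, max_shift) if qualified else None
    return SpectralShift(shift, float(tmi), spk_peak, lfp_peak, qualified)


def spectrum_shift(psd_a: np.ndarray, psd_b: np.ndarray,
                   grid_df: float = 0.02, max_shift: float = 2.0) -> float:
    """Non-negative frequency lag maximizing the cross-correlation of two
    z-scored band spectra (a leading b)."""
    a = (psd_a - psd_a.mean()) / psd_a.std()
    b = (psd_b - psd_b.mean()) / psd_b.std()
    xc = signal.correlate(a, b, mode="full")
    lags = signal.correlation_lags(len(a), len(b)) * grid_df
    ok = (lags >= 0.0) & (lags <= max_shift)
    return float(lags[ok][int(np.argmax(xc[ok]))])


def lfp_self_shift(lfp: LfpSignal, band=(4.0, 12.0),
                   fs_spec: float = 125.0) -> float:
    """Spectral shift of the LFP against itself (identically 0; sanity
    anchor for the shift estimator)."""
    dec = max(1, int(round(lfp.fs / fs_spec)))
    v = signal.decimate(lfp.v, dec, zero_phase=True) if dec > 1 else lfp.v
    _, psd = _band_spectrum(v, lfp.fs / dec, band)
    return spectrum_shift(psd, psd)


def lfp_theta_index(lfp: LfpSignal, band=(4.0, 12.0),
                    fs_spec: float = 125.0) -> float:
    """Theta power index of the LFP itself: the cell theta-modulation-index
    formula applied to the LFP spectrum."""
    dec = max(1, int(round(lfp.fs / fs_spec)))
    v = signal.decimate(lfp.v, dec, zero_phase=True) if dec > 1 else lfp.v
    fgrid, psd = _band_spectrum(v, lfp.fs / dec, band)
    return theta_modulation_index(fgrid, psd)[0]


# ---------------------------------------------------------------------------
# speed modulation of theta
# ---------------------------------------------------------------------------

def instantaneous_frequency(ps: PhaseSeries,
                            method: str = "phase") -> np.ndarray:
    """Instantaneous theta frequency (Hz) from unwrapped-phase differences
    (``"phase"``) or from peak-to-peak cycle durations (``"cycle"``)."""
    if method == "phase":
        f = np.diff(ps.unwrapped) / TWO_PI * ps.fs
        return np.append(f, f[-1])
    if method == "cycle":
        # cycle boundaries where the unwrapped phase crosses 2*pi*k
        k = np.floor(ps.unwrapped / TWO_PI)
        starts = np.flatnonzero(np.diff(k) >= 1) + 1
        f = np.full(len(ps.t), np.nan)
        for a, b in zip(starts[:-1], starts[1:]):
            f[a:b] = ps.fs / (b - a)
        return f
    raise ValueError(f"unknown method {method!r}")


def speed_theta_modulation(lfp: LfpSignal, traj: Trajectory,
                           band=(4.0, 12.0),
                           speed_threshold: float = 2.0):
    """(r_freq, r_amp): Pearson correlations of instantaneous theta
    frequency and normalized amplitude with running speed over locomotion
    samples."""
    ps = theta_filter_phase(lfp, band, "hilbert")
    sos = signal.cheby2(4, 40.0, band, btype="bandpass", fs=lfp.fs,
                        output="sos")
    filt = signal.sosfiltfilt(sos, lfp.v)
    amp = np.abs(signal.hilbert(filt))
    amp = amp / amp.mean()
    freq = instantaneous_frequency(ps, "phase")
    speed = np.interp(lfp.t, traj.t, traj.speed)
    run = speed > speed_threshold
    r_freq = pearsonr(speed[run], freq[run]).statistic
    r_amp = pearsonr(speed[run], amp[run]).statistic
    return float(r_freq), float(r_amp)


# ---------------------------------------------------------------------------
# theta-timescale pair offsets
# ---------------------------------------------------------------------------

def cross_correlogram(times_a: np.ndarray, times_b: np.ndarray,
                      window: float, bin_width: float):
    """Histogram of ``t_b - t_a`` spike-time differences in ±window."""
    edges = np.arange(-window, window + bin_width / 2, bin_width)
    diffs = []
    lo = np.searchsorted(times_b, times_a - window)
    hi = np.searchsorted(times_b, times_a + window)
    for ta, a, b in zip(times_a, lo, hi):
        if b > a:
            diffs.append(times_b[a:b] - ta)
    d = np.concatenate(diffs) if diffs else np.array([])
    counts, _ = np.histogram(d, bins=edges)
    centers = edges[:-1] + bin_width / 2
    return centers, counts.astype(float)


def _lowpass_peak(centers, counts, cutoff_hz, bin_width, search_half=None):
    fs = 1.0 / bin_width
    ntaps = min(101, 2 * (len(counts) // 4) + 1)
    taps = signal.firwin(ntaps, cutoff_hz, fs=fs)
    filt = signal.filtfilt(taps, [1.0], counts,
                           padlen=min(len(counts) - 1, 3 * ntaps))
    if search_half is not None:
        m = np.abs(centers) <= search_half
    else:
        m = np.ones(len(centers), bool)
    return float(centers[m][int(np.argmax(filt[m]))])


def pair_theta_offsets(times_a: np.ndarray, times_b: np.ndarray,
                       min_mean_count: float = 1.0) -> PairOffsets:
    """Behavioral- and theta-timescale CCG peak offsets for one cell pair.

    The behavioral offset is the peak of the 0-2 Hz low-passed CCG
    (±1 s window, 3 ms bins); the theta offset is the peak of the
    0-20 Hz low-passed CCG (±200 ms window, 1 ms bins, peak searched
    within ±100 ms).  Pairs whose theta-scale CCG mean bin count is below
    1 count/ms are excluded.
    """
    c1, h1 = cross_correlogram(times_a, times_b, 1.0, 0.003)
    c2, h2 = cross_correlogram(times_a, times_b, 0.2, 0.001)
    mean_count = float(h2.mean())
    if mean_count < min_mean_count or h1.sum() == 0:
        return PairOffsets(None, None, False, mean_count)
    ccg_off = _lowpass_peak(c1, h1, 2.0, 0.003)
    theta_off = _lowpass_peak(c2, h2, 20.0, 0.001, search_half=0.1)
    return PairOffsets(ccg_off, theta_off, True, mean_count)


def in_field_spike_times(traj: Trajectory, spikes: SpikeTrain,
                         field: PlaceField, grid: BinGrid,
                         speed_threshold: float = 2.0) -> np.ndarray:
    """Spike times emitted inside a field during locomotion in its
    direction (used for pair CCGs)."""
    x0 = field.start * grid.bin_size
    x1 = (field.stop + 1) * grid.bin_size
    idx = spikes_to_samples(traj, spikes.spike_times)
    ok = (traj.speed[idx] > speed_threshold) & \
        (traj.direction[idx] == field.direction) & \
        (traj.x[idx] >= x0) & (traj.x[idx] < x1)
    return spikes.spike_times[ok]


def offset_offset_correlation(pairs: list) -> tuple[float, float, int]:
    """Pearson correlation between behavioral and theta CCG offsets across
    included pairs: (r, p, n)."""
    inc = [p for p in pairs if p.included]
    if len(inc) < 3:
        return np.nan, np.nan, len(inc)
    a = np.array([p.ccg_offset for p in inc])
    b = np.array([p.theta_offset for p in inc])
    res = pearsonr(a, b)
    return float(res.statistic), float(res.pvalue), len(inc)
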