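"""Population position decoding: memoryless Bayesian and rate-vector methods.

The Bayesian decoder evaluates, per non-overlapping time window of length
tau restricted to locomotion epochs,

    P(x | n) ∝ P(x) * prod_i f_i(x)^{n_i} * exp(-tau * sum_i f_i(x))

with a uniform prior over the analyzed bins, assuming Poisson spiking and
cell independence.  Tuning curves f_i(x) are cross-validated with a
leave-one-out scheme: the decoded trial never contributes to its own
tuning curves.  Rates are clamped at a small floor inside the likelihood
so a single silent bin cannot zero out the posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.special import logsumexp

from .ratemaps import RateMap
from .session import BinGrid, Trajectory

RATE_FLOOR = 1e-3  # Hz


@dataclass
class DecodingResult:
    analyzed_bins: np.ndarray
    posterior: np.ndarray       # [n_windows, n_analyzed_bins]
    decoded_bin: np.ndarray     # global bin indices
    real_bin: np.ndarray
    error: np.ndarray           # cm
    accuracy: np.ndarray        # posterior at the real bin
    window_t: np.ndarray        # window start times
    window_dir: np.ndarray
    correlation: np.ndarray | None = None   # FRV only
    n_excluded_windows: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.decoded_bin)

    @property
    def median_error(self) -> float:
        return float(np.median(self.error))

    @property
    def mean_accuracy(self) -> float:
        return float(np.nanmean(self.accuracy))


@dataclass
class _Windows:
    counts: np.ndarray          # [n_windows, n_cells]
    real_bin: np.ndarray        # global indices
    real_x: np.ndarray
    t0: np.ndarray
    direction: np.ndarray
    trial_row: np.ndarray       # row within the direction's rate maps
    cell_ids: list


def _build_windows(traj: Trajectory, spike_trains: list, grid: BinGrid,
                   tau: float, speed_threshold: float) -> _Windows:
    """Tile non-overlapping windows over run epochs of every trial."""
    if traj.speed is None:
        raise ValueError("speed: call compute_speed first")
    dt = traj.dt
    w = max(1, int(round(tau / dt)))
    lo = traj.track_length * 0.10
    hi = traj.track_length * 0.90
    run = (traj.speed > speed_threshold) & (traj.x > lo) & (traj.x < hi)
    counts_l, rb_l, rx_l, t0_l, dir_l, row_l = [], [], [], [], [], []
    trains = [st.spike_times for st in spike_trains]
    row_counter = {}
    for tr in traj.trials:
        tmask = traj.trial_id == tr
        d = str(traj.direction[tmask][0])
        row = row_counter.get(d, 0)
        row_counter[d] = row + 1
        idx = np.flatnonzero(tmask & run)
        if len(idx) < w:
            continue
        # contiguous run segments inside the trial
        brk = np.flatnonzero(np.diff(idx) > 1)
        seg_starts = np.concatenate([[0], brk + 1])
        seg_stops = np.concatenate([brk, [len(idx) - 1]])
        for s0, s1 in zip(seg_starts, seg_stops):
            seg = idx[s0:s1 + 1]
            n_win = len(seg) // w
            for k in range(n_win):
                sl = seg[k * w:(k + 1) * w]
                t_start = traj.t[sl[0]]
                c = [np.searchsorted(st, t_start + tau) -
                     np.searchsorted(st, t_start) for st in trains]
                xc = traj.x[sl[len(sl) // 2]]
                counts_l.append(c)
                rx_l.append(xc)
                rb_l.append(grid.x_to_bin(np.array([xc]))[0])
                t0_l.append(t_start)
                dir_l.append(d)
                row_l.append(row)
    return _Windows(np.array(counts_l, float), np.array(rb_l, int),
                    np.array(rx_l), np.array(t0_l),
                    np.array(dir_l, dtype="U5"), np.array(row_l, int),
                    [st.cell_id for st in spike_trains])


def _loo_tuning(maps: dict, direction: str, row: int,
                cell_ids: list, bins: np.ndarray,
                floor: float = RATE_FLOOR) -> np.ndarray:
    """Leave-one-out tuning curves [n_cells, n_bins] for one trial."""
    F = np.empty((len(cell_ids), len(bins)))
    for i, cid in enumerate(cell_ids):
        rm: RateMap = maps[cid][direction]
        rows = rm.per_trial_rate[:, bins]
        n = len(rows)
        if n > 1 and row < n:
            F[i] = (rows.sum(axis=0) - rows[row]) / (n - 1)
        else:
            F[i] = rows.mean(axis=0)
    return np.maximum(F, floor)


def bayesian_decode(traj: Trajectory, spike_trains: list, maps: dict,
                    grid: BinGrid, tau: float = 0.150,
                    speed_threshold: float = 2.0,
                    rate_floor: float = RATE_FLOOR,
                    windows: _Windows | None = None,
                    cell_subset: np.ndarray | None = None) -> DecodingResult:
    """Memoryless Bayesian decoding over the analyzed bins.

    ``maps`` maps cell_id -> {direction: RateMap}.  Requires >= 1 cell.
    """
    if not spike_trains:
        raise ValueError("need at least one cell")
    wins = windows or _build_windows(traj, spike_trains, grid, tau,
                                     speed_threshold)
    bins = grid.analyzed_bins
    sel = np.arange(len(wins.cell_ids)) if cell_subset is None \
        else np.asarray(cell_subset)
    cell_ids = [wins.cell_ids[i] for i in sel]
    post = np.empty((len(wins.t0), len(bins)))
    for d in np.unique(wins.direction):
        for row in np.unique(wins.trial_row[wins.direction == d]):
            m = (wins.direction == d) & (wins.trial_row == row)
            F = _loo_tuning(maps, d, int(row), cell_ids, bins, rate_floor)
            logp = wins.counts[m][:, sel] @ np.log(F) - tau * F.sum(axis=0)
            post[m] = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    return _result_from_posterior(post, wins, grid)


def _result_from_posterior(post: np.ndarray, wins: _Windows,
                           grid: BinGrid) -> DecodingResult:
    bins = grid.analyzed_bins
    dec = bins[np.argmax(post, axis=1)]
    pos_in_analyzed = np.searchsorted(bins, wins.real_bin)
    pos_in_analyzed = np.clip(pos_in_analyzed, 0, len(bins) - 1)
    acc = post[np.arange(len(post)), pos_in_analyzed]
    err = np.abs(grid.centers[dec] - grid.centers[wins.real_bin])
    return DecodingResult(bins, post, dec, wins.real_bin, err, acc,
                          wins.t0, wins.direction)


def drop_cell_decode(traj: Trajectory, spike_trains: list, maps: dict,
                     grid: BinGrid, k_subset: int, n_repeats: int = 50,
                     tau: float = 0.150, seed=None,
                     speed_threshold: float = 2.0) -> DecodingResult:
    """Decoding with ``5*k_subset`` randomly chosen cells, repeated
    ``n_repeats`` times; per (window, bin) the median posterior is kept and
    rows are renormalized."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_cells = len(spike_trains)
    size = 5 * k_subset
    if size > n_cells:
        raise ValueError(f"5*k = {size} exceeds the {n_cells} available cells")
    wins = _build_windows(traj, spike_trains, grid, tau, speed_threshold)
    stack = np.empty((n_repeats, len(wins.t0), len(grid.analyzed_bins)),
                     dtype=np.float32)
    for r in range(n_repeats):
        sub = rng.choice(n_cells, size=size, replace=False)
        res = bayesian_decode(traj, spike_trains, maps, grid, tau,
                              speed_threshold, windows=wins, cell_subset=sub)
        stack[r] = res.posterior
    med = np.median(stack, axis=0).astype(float)
    med /= med.sum(axis=1, keepdims=True)
    return _result_from_posterior(med, wins, grid)


def frv_decode(traj: Trajectory, spike_trains: list, maps: dict,
               grid: BinGrid, window: float = 0.100,
               speed_threshold: float = 2.0) -> DecodingResult:
    """Firing-rate-vector decoding: per window, the decoded bin maximizes
    the Pearson correlation (across cells) between the instantaneous
    population rate vector and each bin's leave-one-out template.

    Windows whose population vector is constant are excluded (their count
    is reported in ``n_excluded_windows``)."""
    wins = _build_windows(traj, spike_trains, grid, window, speed_threshold)
    bins = grid.analyzed_bins
    n_win = len(wins.t0)
    corr = np.full((n_win, len(bins)), np.nan)
    for d in np.unique(wins.direction):
        for row in np.unique(wins.trial_row[wins.direction == d]):
            m = (wins.direction == d) & (wins.trial_row == row)
            F = _loo_tuning(maps, d, int(row), wins.cell_ids, bins, 0.0)
            Fz = F - F.mean(axis=0, keepdims=True)
            Fn = np.linalg.norm(Fz, axis=0)
            C = wins.counts[m]
            Cz = C - C.mean(axis=1, keepdims=True)
            Cn = np.linalg.norm(Cz, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr[m] = (Cz @ Fz) / np.outer(Cn, Fn)
    valid = ~np.all(~np.isfinite(corr), axis=1)
    n_excluded = int((~valid).sum())
    corr_v = np.where(np.isfinite(corr), corr, -np.inf)[valid]
    dec = bins[np.argmax(corr_v, axis=1)]
    real = wins.real_bin[valid]
    err = np.abs(grid.centers[dec] - grid.centers[real])
    best = corr_v[np.arange(len(corr_v)), np.argmax(corr_v, axis=1)]
    res = DecodingResult(bins, corr_v, dec, real, err,
                         np.full(len(dec), np.nan), wins.t0[valid],
                         wins.direction[valid], correlation=best,
                         n_excluded_windows=n_excluded)
    return res


def decoding_summaries(result: DecodingResult, grid: BinGrid) -> dict:
    """Per-bin accuracy profile, object-zone means, confusion matrix."""
    bins = result.analyzed_bins
    acc_by_bin = np.full(grid.n_bins, np.nan)
    confusion = np.full((len(bins), len(bins)), np.nan)
    for i, b in enumerate(bins):
        m = result.real_bin == b
        if not m.any():
            continue
        acc_by_bin[b] = np.nanmean(result.accuracy[m])
        confusion[:, i] = result.posterior[m].mean(axis=0)
    oz, noz = grid.oz_bins, grid.noz_bins
    return {
        "accuracy_by_bin": acc_by_bin,
        "oz_accuracy": float(np.nanmean(acc_by_bin[oz])) if len(oz) else np.nan,
        "noz_accuracy": float(np.nanmean(acc_by_bin[noz])),
        "confusion": confusion,
        "median_error": result.median_error,
        "mean_accuracy": result.mean_accuracy,
    }
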