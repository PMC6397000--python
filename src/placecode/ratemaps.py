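"""Firing-rate maps on the spatial bin grid and cell classifications.

Rate maps are built per trial and per running direction: spike counts and
occupancy time are accumulated in 2 cm bins from locomotion samples
(speed > 2 cm/s), each vector is smoothed with a Gaussian kernel, and the
smoothed count vector is divided by the smoothed occupancy vector.  The
Gaussian kernel half-width is the kernel standard deviation (10 bins by
default, truncated at +/-3 sigma) and the smoothing is mass-preserving at
the track edges: each source bin's kernel column is renormalized to unit
sum, so smoothing conserves total spike count and total occupancy time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .session import (BinGrid, CellMeta, SpikeTrain, Trajectory,
                      ValidationError)

OCCUPANCY_EPS = 1e-3  # s; bins with less smoothed occupancy get rate 0


@lru_cache(maxsize=16)
def smoothing_matrix(n_bins: int, sigma_bins: float,
                     truncate: float = 3.0) -> np.ndarray:
    """Column-normalized Gaussian smoothing matrix ``S`` (n_bins x n_bins).

    ``(S @ v).sum() == v.sum()`` for any nonnegative ``v`` (edge
    renormalization preserves mass rather than reflecting it).
    """
    i = np.arange(n_bins)
    d = i[:, None] - i[None, :]
    k = np.exp(-0.5 * (d / sigma_bins) ** 2)
    k[np.abs(d) > truncate * sigma_bins] = 0.0
    return k / k.sum(axis=0, keepdims=True)


def halfwidth_to_sigma(halfwidth_bins: float, mode: str = "sigma") -> float:
    """Interpret the smoothing 'half-width' parameter.

    ``"sigma"``: the half-width is the kernel standard deviation (default).
    ``"fwhm"``: the half-width is half the full width at half maximum.
    """
    if mode == "sigma":
        return float(halfwidth_bins)
    if mode == "fwhm":
        return 2.0 * halfwidth_bins / 2.354820045
    raise ValueError(f"unknown half-width mode {mode!r}")


@dataclass
class RateMap:
    """Per-trial and mean firing-rate vectors for one cell and direction."""

    cell_id: int
    direction: str
    grid: BinGrid
    trial_ids: np.ndarray            # trials of this direction, in order
    per_trial_rate: np.ndarray       # [n_trials, n_bins] Hz (smoothed)
    per_trial_counts: np.ndarray     # raw spike counts
    per_trial_occupancy: np.ndarray  # raw occupancy, s
    per_trial_occ_smooth: np.ndarray
    trial_mean_rate: np.ndarray      # Hz, per trial (masked samples)
    sigma_bins: float

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)

    @property
    def mean_rate_vector(self) -> np.ndarray:
        return self.per_trial_rate.mean(axis=0)

    @property
    def mean_occupancy_vector(self) -> np.ndarray:
        return self.per_trial_occupancy.mean(axis=0)

    @property
    def mean_rate(self) -> float:
        """Overall rate: total spikes / total locomotion time."""
        tot = self.per_trial_occupancy.sum()
        return self.per_trial_counts.sum() / tot if tot > 0 else 0.0

    @property
    def peak_rate(self) -> float:
        return float(self.mean_rate_vector.max())


def bin_samples(traj: Trajectory, mask: np.ndarray, grid: BinGrid):
    """Bin index per trajectory sample plus the selection mask."""
    return grid.x_to_bin(traj.x), mask


def spikes_to_samples(traj: Trajectory, spike_times: np.ndarray) -> np.ndarray:
    """Index of the trajectory sample each spike falls in (previous sample)."""
    idx = np.searchsorted(traj.t, spike_times, side="right") - 1
    return np.clip(idx, 0, len(traj.t) - 1)


def firing_rate_map(traj: Trajectory, spikes: SpikeTrain, grid: BinGrid,
                    direction: str, smoothing_halfwidth_bins: float = 10.0,
                    speed_threshold: float = 2.0,
                    halfwidth_mode: str = "sigma") -> RateMap:
    """Build the per-trial and mean rate map of one cell in one direction.

    Low-speed epochs are removed before binning; reward-zone bins are kept
    in storage (analysis stages restrict to ``grid.analyzed_bins``).
    """
    if traj.speed is None:
        raise ValidationError("speed: call compute_speed first")
    sigma = halfwidth_to_sigma(smoothing_halfwidth_bins, halfwidth_mode)
    S = smoothing_matrix(grid.n_bins, sigma)
    dt = traj.dt
    dir_mask = traj.direction == direction
    run = (traj.speed > speed_threshold) & dir_mask
    sample_bin = grid.x_to_bin(traj.x)
    spike_idx = spikes_to_samples(traj, spikes.spike_times)
    trial_ids = np.unique(traj.trial_id[dir_mask])
    n = grid.n_bins
    counts = np.zeros((len(trial_ids), n))
    occ = np.zeros((len(trial_ids), n))
    lam = np.zeros(len(trial_ids))
    for k, tr in enumerate(trial_ids):
        m = run & (traj.trial_id == tr)
        if not m.any():
            warnings.warn(f"trial {tr}: no locomotion time; zero rate row")
            continue
        np.add.at(occ[k], sample_bin[m], dt)
        sm = m[spike_idx]
        np.add.at(counts[k], sample_bin[spike_idx[sm]], 1.0)
        lam[k] = counts[k].sum() / occ[k].sum()
    counts_s = counts @ S.T
    occ_s = occ @ S.T
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ_s >= OCCUPANCY_EPS, counts_s / occ_s, 0.0)
    return RateMap(spikes.cell_id, direction, grid, trial_ids, rate,
                   counts, occ, occ_s, lam, sigma)


def rate_maps_by_direction(traj, spikes, grid, **kw) -> dict:
    from .session import DIRECTIONS
    return {d: firing_rate_map(traj, spikes, grid, d, **kw)
            for d in DIRECTIONS}


# ---------------------------------------------------------------------------
# classifications
# ---------------------------------------------------------------------------

def classify_pyramidal(meta: CellMeta) -> str:
    """Putative pyramidal cell vs interneuron from waveform metadata.

    Pyramidal iff mean rate < 20 Hz and (burst index > 0 or spike duration
    > 0.4 ms); interneuron otherwise.
    """
    for f in ("mean_rate", "burst_index", "spike_duration"):
        v = getattr(meta, f)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValidationError(f"{f}: missing for cell {meta.cell_id}")
    if meta.mean_rate < 20.0 and (meta.burst_index > 0.0 or
                                  meta.spike_duration > 0.4):
        return "pyramidal"
    return "interneuron"


def classify_active(maps_by_direction: dict) -> str:
    """Track-active vs silent.

    Active iff in at least one direction: mean locomotion firing rate
    > 0.5 Hz, peak of the mean rate vector > 1.5 Hz, and at least one spike
    in at least 50% of that direction's trials.
    """
    for rm in maps_by_direction.values():
        if rm.n_trials == 0:
            continue
        frac = np.mean(rm.per_trial_counts.sum(axis=1) > 0)
        if (rm.mean_rate > 0.5 and rm.peak_rate > 1.5 and frac >= 0.5):
            return "active"
    return "silent"


def behavior_metrics(traj: Trajectory, reward_events=None,
                     speed_threshold: float = 2.0) -> tuple[float, float]:
    """(rewards per minute, mean running speed in cm/s).

    Reward events default to trial completions (one reward per trial end).
    """
    duration_min = (traj.t[-1] - traj.t[0]) / 60.0
    n_rewards = len(reward_events) if reward_events is not None \
        else len(traj.trials)
    run = traj.speed > speed_threshold
    mean_speed = float(traj.speed[run].mean()) if run.any() else 0.0
    return n_rewards / duration_min, mean_speed
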