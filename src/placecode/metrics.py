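"""Cell- and bin-level spatial coding metrics.

All spatial correlations are Pearson correlations computed over the
analyzed bins only (reward zones excluded), matching field detection.
"""

from __future__ import annotations

import warnings

import numpy as np

from .placefields import _pearson
from .ratemaps import RateMap, smoothing_matrix
from .session import BinGrid, SpikeTrain, Trajectory


def stability_index(rate_map: RateMap) -> float:
    """Mean Pearson correlation over all pairs of per-trial rate vectors.

    Pairs involving a constant vector are skipped; NaN when no valid pair
    remains.
    """
    ab = rate_map.grid.analyzed_bins
    rows = rate_map.per_trial_rate[:, ab]
    n = len(rows)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            r = _pearson(rows[i], rows[j])
            if r is not None:
                vals.append(r)
    return float(np.mean(vals)) if vals else np.nan


def spatial_information(mean_rate_vector: np.ndarray,
                        mean_occupancy_vector: np.ndarray,
                        grid: BinGrid) -> float:
    """Skaggs spatial information in bits/spike.

    SI = sum_i (FR_i/FR) (OT_i/OT_T) log2(FR_i/FR) with FR the
    occupancy-weighted mean rate; zero-rate bins contribute 0.
    """
    ab = grid.analyzed_bins
    fr = np.asarray(mean_rate_vector, float)[ab]
    ot = np.asarray(mean_occupancy_vector, float)[ab]
    ott = ot.sum()
    if ott <= 0:
        raise ValueError("occupancy must be positive on analyzed bins")
    w = ot / ott
    mean_fr = float(np.sum(fr * w))
    if mean_fr == 0:
        return np.nan
    ratio = fr / mean_fr
    terms = np.where(fr > 0, ratio * w * np.log2(np.maximum(ratio, 1e-300)),
                     0.0)
    return float(terms.sum())


# ---------------------------------------------------------------------------
# mutual information with surrogate normalization
# ---------------------------------------------------------------------------

def mutual_information(per_trial_rate: np.ndarray,
                       per_trial_occupancy: np.ndarray,
                       grid: BinGrid, n_quartiles: int = 4) -> float:
    """Mutual information (bits) between spatial bin and rate quartile.

    Samples are the (trial, bin) rate entries over analyzed bins, weighted
    by their occupancy; the quartile edges come from the pooled empirical
    rate distribution (interpolated quantiles, zeros included).
    """
    ab = grid.analyzed_bins
    r = per_trial_rate[:, ab]
    occ = per_trial_occupancy[:, ab]
    tot = occ.sum()
    if tot <= 0:
        return np.nan
    w = occ / tot
    qs = np.quantile(r, np.arange(1, n_quartiles) / n_quartiles)
    if len(np.unique(qs)) < n_quartiles - 1:
        warnings.warn("degenerate rate quartiles (many ties)")
    j = np.searchsorted(qs, r, side="right")          # 0..3
    p_ij = np.zeros((len(ab), n_quartiles))
    for q in range(n_quartiles):
        p_ij[:, q] = np.where(j == q, w, 0.0).sum(axis=0)
    p_i = p_ij.sum(axis=1, keepdims=True)
    p_j = p_ij.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = p_ij * np.log2(p_ij / (p_i * p_j))
    return float(np.nansum(terms))


def mutual_information_z(rate_map: RateMap, traj: Trajectory,
                         spikes: SpikeTrain, n_surrogates: int = 1000,
                         seed=None, speed_threshold: float = 2.0,
                         min_shift: float = 1.0) -> float:
    """MI z-scored against circular time-shift surrogates.

    Each surrogate shifts the whole spike train by a uniform offset
    >= ``min_shift`` s (circularly within the session), re-bins it through
    the real trajectory and recomputes MI; z = (MI - mean) / sd.  The
    circular shift preserves the train's ISI structure while destroying
    its alignment to position.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    grid = rate_map.grid
    obs = mutual_information(rate_map.per_trial_rate,
                             rate_map.per_trial_occ_smooth, grid)
    # precompute sample -> (trial row, bin) lookup for fast re-binning
    run = (traj.speed > speed_threshold) & \
        (traj.direction == rate_map.direction)
    sample_bin = grid.x_to_bin(traj.x)
    row_of_trial = {tr: k for k, tr in enumerate(rate_map.trial_ids)}
    sample_row = np.array([row_of_trial.get(tr, -1) for tr in traj.trial_id])
    S = smoothing_matrix(grid.n_bins, rate_map.sigma_bins)
    occ_s = rate_map.per_trial_occ_smooth
    good = occ_s >= 1e-3
    t0, t1 = traj.t[0], traj.t[-1]
    T = t1 - t0
    st = spikes.spike_times
    vals = np.empty(n_surrogates)
    for k in range(n_surrogates):
        delta = rng.uniform(min_shift, T - min_shift)
        ts = t0 + np.mod(st - t0 + delta, T)
        idx = np.clip(np.searchsorted(traj.t, ts, side="right") - 1,
                      0, len(traj.t) - 1)
        keep = run[idx] & (sample_row[idx] >= 0)
        counts = np.zeros((rate_map.n_trials, grid.n_bins))
        np.add.at(counts, (sample_row[idx[keep]], sample_bin[idx[keep]]), 1.0)
        sm = counts @ S.T
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(good, sm / occ_s, 0.0)
        vals[k] = mutual_information(rate, occ_s, grid)
    sd = vals.std()
    if sd == 0:
        return np.nan
    return float((obs - vals.mean()) / sd)


# ---------------------------------------------------------------------------
# local stability / field-position uniformity / map similarity
# ---------------------------------------------------------------------------

def local_stability(rate_map: RateMap, half_window: int = 2) -> np.ndarray:
    """Even/odd-trial correlation in a 5-bin neighborhood of each bin.

    Returns a vector over ``grid.n_bins`` (NaN outside the analyzed region
    or where a window is constant).  Needs >= 4 trials.
    """
    if rate_map.n_trials < 4:
        raise ValueError("local stability needs >= 4 trials")
    ab = rate_map.grid.analyzed_bins
    even = rate_map.per_trial_rate[0::2].mean(axis=0)
    odd = rate_map.per_trial_rate[1::2].mean(axis=0)
    out = np.full(rate_map.grid.n_bins, np.nan)
    lo, hi = ab[0], ab[-1]
    for b in ab:
        w = np.arange(max(lo, b - half_window), min(hi, b + half_window) + 1)
        r = _pearson(even[w], odd[w])
        out[b] = np.nan if r is None else r
    return out


def uniformity_test(field_bins: np.ndarray, n_bins_total: int,
                    n_boot: int = 1000, seed=None,
                    pct_hi: float = 93.0, pct_lo: float = 6.0) -> float:
    """Bootstrap test of uniform field placement over coarse spatial bins.

    ``field_bins`` holds one coarse-bin label per field (directions pooled
    as separate bins).  The statistic is the SD of per-bin field
    percentages after excluding values above the 93rd and below the 6th
    percentile; the null redistributes the field count uniformly.  Returns
    the probability of the observed SD under uniformity (small p =>
    non-uniform).
    """
    field_bins = np.asarray(field_bins, int)
    n = len(field_bins)
    if n < 5:
        raise ValueError("need >= 5 fields")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    counts = np.bincount(field_bins, minlength=n_bins_total)
    obs_sd = _trimmed_sd(100.0 * counts / n, pct_lo, pct_hi)
    null = rng.multinomial(n, np.full(n_bins_total, 1.0 / n_bins_total),
                           size=n_boot) * (100.0 / n)
    null_sd = _trimmed_sd_rows(null, pct_lo, pct_hi)
    return float(np.mean(null_sd >= obs_sd))


def _trimmed_sd(v: np.ndarray, lo: float, hi: float) -> float:
    a, b = np.percentile(v, [lo, hi])
    keep = (v >= a) & (v <= b)
    return float(v[keep].std())


def _trimmed_sd_rows(m: np.ndarray, lo: float, hi: float) -> np.ndarray:
    a = np.percentile(m, lo, axis=1, keepdims=True)
    b = np.percentile(m, hi, axis=1, keepdims=True)
    x = np.where((m >= a) & (m <= b), m, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.nanstd(x, axis=1)


def map_similarity(trial_maps_by_dir: dict, template_maps_by_dir: dict,
                   grid: BinGrid, template_is_self: bool = False) -> np.ndarray:
    """Per back-and-forth-trial correlation with a template map.

    For trial pair k the forth (back) trial map is correlated with the
    same-direction template mean over analyzed bins, and the two values are
    averaged.  When the trial belongs to the template condition
    (``template_is_self``), the template mean excludes that lap.
    """
    ab = grid.analyzed_bins
    n_pairs = min(len(m) for m in trial_maps_by_dir.values())
    out = np.full(n_pairs, np.nan)
    for k in range(n_pairs):
        vals = []
        for d, maps in trial_maps_by_dir.items():
            tmpl = np.asarray(template_maps_by_dir[d], float)
            if template_is_self:
                sel = np.ones(len(tmpl), bool)
                sel[k] = False
                mean_t = tmpl[sel].mean(axis=0)
            else:
                mean_t = tmpl.mean(axis=0)
            r = _pearson(np.asarray(maps)[k][ab], mean_t[ab])
            if r is not None:
                vals.append(r)
        if vals:
            out[k] = np.mean(vals)
    return out
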