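"""Self-contained benchmark computations exercised by the acceptance
script and the acceptance test suite.

Every function generates its own synthetic inputs from an integer seed and
recomputes the quantity of interest from scratch by running the package's
analysis stack.  Problem sizes are chosen to resolve each effect on a
single CPU in seconds-to-minutes; the methods note documents them.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import pearsonr, spearmanr

from . import decoding, metrics, placefields, ratemaps, theta
from .session import BinGrid, SpikeTrain, LfpSignal
from .simulate import (LfpSpec, PlaceCellSpec, simulate_lfp,
                       simulate_place_cell, simulate_poisson_cell,
                       simulate_trajectory)


def zone_geometry() -> dict:
    """Bin counts of the standard track partition at 2 cm and 10 cm."""
    g2 = BinGrid(bin_size=2.0)
    g10 = BinGrid(bin_size=10.0)
    return {
        "n_bins_2cm": g2.n_bins,
        "analyzed_bins_per_direction_2cm": len(g2.analyzed_bins),
        "oz_bins_both_directions_2cm": 2 * len(g2.oz_bins),
        "noz_bins_both_directions_2cm": 2 * len(g2.noz_bins),
        "oz_bins_both_directions_10cm": 2 * len(g10.oz_bins),
        "noz_bins_both_directions_10cm": 2 * len(g10.noz_bins),
    }


def chance_accuracy(seed: int = 0) -> float:
    """Decoding accuracy of an information-free posterior.

    A single untuned (homogeneous Poisson) cell on a full-track grid
    yields an exactly uniform posterior over the 100 bins; the accuracy at
    the real position is then the chance level.
    """
    traj = simulate_trajectory(4, seed=seed)
    grid = BinGrid(reward_fraction=0.0)
    st = simulate_poisson_cell(traj, 3.0, seed=seed + 1)
    maps = {0: ratemaps.rate_maps_by_direction(traj, st, grid)}
    # flatten the tuning curves so no bin is preferred
    for rm in maps[0].values():
        rm.per_trial_rate[:] = 3.0
    res = decoding.bayesian_decode(traj, [st], maps, grid)
    return float(np.mean(res.accuracy))


def si_limits() -> dict:
    """Analytic limits of the Skaggs spatial-information measure."""
    grid = BinGrid(reward_fraction=0.0, object_zones=())
    occ = np.ones(grid.n_bins)
    uniform = metrics.spatial_information(np.full(grid.n_bins, 3.0), occ,
                                          grid)
    single = np.zeros(grid.n_bins)
    single[37] = 5.0
    one_bin = metrics.spatial_information(single, occ, grid)
    return {"si_uniform": float(uniform), "si_single_bin": float(one_bin)}


def field_recovery(seed: int = 0, n_cells: int = 50, n_trials: int = 30,
                   n_boot: int = 1000) -> dict:
    """Planted-field recovery and specificity of the bootstrap detector.

    ``n_cells`` place cells (center 100 cm, sigma 8 cm, peak 8 Hz,
    baseline 0.5 Hz) and as many spatially uniform 3 Hz cells are
    simulated on a shared 30-trial session.
    """
    rng = np.random.default_rng(seed)
    traj = simulate_trajectory(n_trials, seed=rng)
    lfp, phase = simulate_lfp(traj, seed=rng)
    grid = BinGrid()
    spec = PlaceCellSpec(center_forth=100.0, center_back=None,
                         width_sigma=8.0, peak_rate=8.0, baseline_rate=0.5)
    errors, n_fields = [], []
    for i in range(n_cells):
        st = simulate_place_cell(traj, spec, rng, (lfp.t, phase), cell_id=i)
        rm = ratemaps.firing_rate_map(traj, st, grid, "forth")
        fields = placefields.detect_place_fields(rm, n_boot=n_boot, seed=rng)
        n_fields.append(len(fields))
        if fields:
            prim = next(f for f in fields if f.is_primary)
            errors.append(abs(grid.centers[prim.peak_bin] - 100.0))
    false_pos = 0
    for i in range(n_cells):
        st = simulate_poisson_cell(traj, 3.0, rng, cell_id=i)
        rm = ratemaps.firing_rate_map(traj, st, grid, "forth")
        if placefields.detect_place_fields(rm, n_boot=n_boot, seed=rng):
            false_pos += 1
    return {
        "detection_rate": float(np.mean(np.array(n_fields) >= 1)),
        "single_field_rate": float(np.mean(np.array(n_fields) == 1)),
        "mean_center_error_cm": float(np.mean(errors)),
        "max_center_error_cm": float(np.max(errors)),
        "specificity": 1.0 - false_pos / n_cells,
    }


def _tiled_ensemble(rng, n_cells=20, n_trials=25, **spec_kw):
    traj = simulate_trajectory(n_trials, seed=rng)
    lfp, phase = simulate_lfp(traj, seed=rng)
    grid = BinGrid()
    centers = np.linspace(35.0, 165.0, n_cells)
    trains, maps = [], {}
    kw = dict(width_sigma=8.0, peak_rate=8.0, baseline_rate=0.5)
    kw.update(spec_kw)
    for i, c in enumerate(centers):
        sp = PlaceCellSpec(center_forth=c, center_back=c, **kw)
        st = simulate_place_cell(traj, sp, rng, (lfp.t, phase), cell_id=i)
        trains.append(st)
        maps[i] = ratemaps.rate_maps_by_direction(traj, st, grid)
    return traj, lfp, phase, grid, trains, maps


def decoder_benchmark(seed: int = 0, n_cells: int = 20,
                      n_trials: int = 25) -> dict:
    """Bayesian decoding recovery, shuffled-train null and drop-cell
    monotonicity on a tiled place-cell ensemble."""
    rng = np.random.default_rng(seed)
    traj, lfp, phase, grid, trains, maps = _tiled_ensemble(
        rng, n_cells, n_trials)
    res = decoding.bayesian_decode(traj, trains, maps, grid)
    frv = decoding.frv_decode(traj, trains, maps, grid)
    # null: ISI-shuffled spike trains (rate kept, position coding destroyed),
    # maps rebuilt from the shuffled trains
    sh_trains, sh_maps = [], {}
    for st in trains:
        isi = np.diff(st.spike_times)
        ts = st.spike_times[0] + np.concatenate(
            [[0.0], np.cumsum(rng.permutation(isi))])
        sh = SpikeTrain(st.cell_id, ts)
        sh_trains.append(sh)
        sh_maps[st.cell_id] = ratemaps.rate_maps_by_direction(traj, sh, grid)
    null = decoding.bayesian_decode(traj, sh_trains, sh_maps, grid)
    ks = np.arange(1, n_cells // 5 + 1)
    acc_k = [decoding.drop_cell_decode(traj, trains, maps, grid, int(k),
                                       n_repeats=15, seed=rng).mean_accuracy
             for k in ks]
    rho = spearmanr(ks, acc_k).statistic if len(ks) > 2 else np.nan
    return {
        "bayes_median_error_cm": res.median_error,
        "bayes_mean_accuracy": res.mean_accuracy,
        "frv_median_error_cm": frv.median_error,
        "shuffled_mean_accuracy": null.mean_accuracy,
        "chance_level": 1.0 / len(grid.analyzed_bins),
        "dropcell_accuracy_by_k": [float(a) for a in acc_k],
        "dropcell_spearman_rho": float(rho),
    }


def precession_benchmark(seed: int = 0, n_trials: int = 100,
                         n_cells: int = 8, n_null: int = 20) -> dict:
    """Recovery of the generator's phase-precession slope and the
    permutation-test null behavior.

    The recovered slope is averaged over ``n_cells`` simulated place cells
    (each contributing well over 300 in-field spikes); with the default
    theta modulation depth the per-cell phase dispersion makes a single
    cell's slope estimate noisy, and the ensemble mean is the quantity the
    generator pins down.
    """
    rng = np.random.default_rng(seed)
    traj = simulate_trajectory(n_trials, seed=rng)
    lfp, phase = simulate_lfp(traj, seed=rng)
    ps = theta.theta_filter_phase(lfp)
    sig = 8.0
    centers = np.linspace(60.0, 140.0, n_cells)
    slopes, corrs, pvals, u_first = [], [], [], None
    for c in centers:
        spec = PlaceCellSpec(center_forth=float(c), center_back=None,
                             width_sigma=sig, peak_rate=10.0,
                             baseline_rate=0.3, precession_slope=-2.0,
                             theta_mod_depth=0.6)
        st = simulate_place_cell(traj, spec, rng, (lfp.t, phase))
        idx = ratemaps.spikes_to_samples(traj, st.spike_times)
        # normalized position over the generator's span (center +/- 2 sigma)
        ok = (traj.direction[idx] == "forth") & (traj.speed[idx] > 2.0) & \
            (np.abs(traj.x[idx] - c) < 2 * sig)
        u = (traj.x[idx[ok]] - (c - 2 * sig)) / (4 * sig)
        phi = theta.spike_phases(st.spike_times[ok], ps)
        fit = theta.precession_fit(u, phi, n_perm=200, seed=rng)
        slopes.append(fit.slope)
        corrs.append(fit.correlation)
        pvals.append(fit.p)
        if u_first is None:
            u_first = u
    null_ok = 0
    for _ in range(n_null):
        nf = theta.precession_fit(u_first,
                                  rng.uniform(0, 2 * np.pi, len(u_first)),
                                  n_perm=200, seed=rng)
        if abs(nf.correlation) < 0.1 and nf.p > 0.05:
            null_ok += 1
    mean_slope = float(np.mean(slopes))
    return {
        "n_in_field_spikes": int(len(u_first)),
        "recovered_slope_rad_per_unit": mean_slope,
        "slope_error": abs(mean_slope - (-2.0)),
        "per_cell_slopes": [float(s) for s in slopes],
        "mean_correlation": float(np.mean(corrs)),
        "significant_fraction": float(np.mean(np.array(pvals) < 0.05)),
        "null_pass_fraction": null_ok / n_null,
    }


def spectral_shift_benchmark(seed: int = 0, duration: float = 300.0) -> dict:
    """Spike/LFP spectral shift oracle: spikes rate-modulated at 8.5 Hz
    against an 8.0 Hz LFP, plus the LFP self-shift anchor."""
    rng = np.random.default_rng(seed)
    fs = 1250.0
    t = np.arange(0.0, duration, 1.0 / fs)
    lfp = LfpSignal(t, np.cos(2 * np.pi * 8.0 * t)
                    + 0.3 * rng.standard_normal(len(t)), fs)
    tf = np.arange(0.0, duration, 0.001)
    lam = 5.0 * (1.0 + 0.7 * np.cos(2 * np.pi * 8.5 * tf))
    spk = tf[rng.poisson(lam * 0.001) > 0]
    sh = theta.unit_lfp_shift(SpikeTrain(0, spk), lfp)
    return {
        "shift_hz": sh.shift,
        "theta_mod_index": sh.theta_mod_index,
        "lfp_self_shift_hz": theta.lfp_self_shift(lfp),
    }


def ccg_benchmark(seed: int = 0, n_cells: int = 24,
                  n_trials: int = 80) -> dict:
    """Theta-timescale CCG offsets: a 30 ms-delayed train oracle and the
    emergent offset-offset correlation in a tiled precessing ensemble.

    The ensemble tiles deeply theta-modulated, strongly precessing fields
    every ~2 cm over the track center so that pair separations span
    0-20 cm; the theta-scale offset each pair inherits from precession is
    then resolvable against CCG noise.
    """
    rng = np.random.default_rng(seed)
    base = np.sort(rng.uniform(0.0, 300.0, 4000))
    po = theta.pair_theta_offsets(base, base + 0.030)
    delay_ms = po.theta_offset * 1000.0
    traj = simulate_trajectory(n_trials, seed=rng)
    lfp, phase = simulate_lfp(traj, seed=rng)
    grid = BinGrid()
    centers = np.linspace(75.0, 125.0, n_cells)
    trains, fields = [], {}
    for i, c in enumerate(centers):
        sp = PlaceCellSpec(center_forth=float(c), center_back=None,
                           width_sigma=9.0, peak_rate=10.0,
                           baseline_rate=0.3, precession_slope=-2.0,
                           theta_mod_depth=0.85, center_jitter_sd=1.0)
        st = simulate_place_cell(traj, sp, rng, (lfp.t, phase), cell_id=i)
        trains.append(st)
        fs = placefields.detect_place_fields(
            ratemaps.firing_rate_map(traj, st, grid, "forth"),
            n_boot=300, seed=rng)
        fields[st.cell_id] = next((f for f in fs if f.is_primary), None)
    pairs = []
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            fi, fj = fields.get(i), fields.get(j)
            if fi is None or fj is None:
                continue
            if fi.start <= fj.stop and fj.start <= fi.stop:
                ta = theta.in_field_spike_times(traj, trains[i], fi, grid)
                tb = theta.in_field_spike_times(traj, trains[j], fj, grid)
                pairs.append(theta.pair_theta_offsets(ta, tb))
    r, p, n = theta.offset_offset_correlation(pairs)
    return {
        "delayed_train_theta_offset_ms": float(delay_ms),
        "ensemble_offset_correlation": r,
        "ensemble_offset_p": p,
        "n_pairs": n,
    }


def uniformity_calibration(seed: int = 0, n_replicates: int = 500,
                           n_fields: int = 50, n_bins: int = 32,
                           alpha: float = 0.05) -> dict:
    """Type-I error rate of the field-distribution uniformity test under
    a uniform null (fields drawn uniformly over the 10 cm bins)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        fb = rng.integers(0, n_bins, n_fields)
        p = metrics.uniformity_test(fb, n_bins, n_boot=1000, seed=rng)
        if p < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_replicates,
            "n_replicates": n_replicates}


def condition_contrast(seed: int = 0, n_trials: int = 20,
                       n_cells_scale: float = 0.5) -> dict:
    """End-to-end two-condition pipeline run (cue-rich vs cue-poor
    presets); returns the per-condition summary axes."""
    from .pipeline import run_pipeline
    cfg = {"conditions": {
        "OT-like": {"n_trials": n_trials, "n_cells_scale": n_cells_scale},
        "NT-like": {"n_trials": n_trials, "n_cells_scale": n_cells_scale}},
        "stage": {"n_boot": 300, "n_perm": 100, "lap_fields": False}}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_pipeline(cfg, seed=seed)
    rep = res["report"].set_index("condition")
    out = {}
    for cond, tag in [("OT-like", "ot"), ("NT-like", "nt")]:
        row = rep.loc[cond]
        out.update({
            f"pct_place_{tag}": float(row.pct_place),
            f"stability_{tag}": float(row.mean_stability),
            f"si_{tag}": float(row.mean_si),
            f"out_in_ratio_{tag}": float(row.mean_out_in_ratio),
            f"decode_error_{tag}": float(row.decode_median_error),
            f"pct_precessing_{tag}": float(row.pct_precessing),
        })
    return out
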