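"""End-to-end orchestration: simulate/load -> classify -> map -> detect ->
metrics -> decode -> theta, with per-session and per-condition summaries.

Session-inclusion filters for proportion statistics follow the recording
conventions: the active-cell percentage (of putative pyramidal cells) is
reported only for sessions with at least 15 recorded neurons, and the
place-cell percentage (of active cells) only for sessions with at least
9 active cells.

All standard hypothesis tests in the condition-comparison table delegate
to scipy; only the bespoke statistics (bootstrap field detection,
permutation nulls, surrogate-normalized MI) are implemented in this
package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from . import decoding, metrics, placefields, ratemaps, theta
from .session import DIRECTIONS, BinGrid, Session, compute_speed
from .simulate import PRESETS, EnsembleSpec, LfpSpec, simulate_session

MIN_NEURONS_FOR_ACTIVE_PCT = 15
MIN_ACTIVE_FOR_PLACE_PCT = 9


def build_condition_session(preset: str, n_trials: int = 30,
                            seed: int = 0, n_cells_scale: float = 1.0,
                            bidirectional: bool = False,
                            **overrides) -> Session:
    """Simulate a session from a named condition preset."""
    p = dict(PRESETS[preset])
    p.update(overrides)
    ens = EnsembleSpec(
        n_place=int(round(p.pop("n_place") * n_cells_scale)),
        n_active_nonspatial=int(round(p.pop("n_active_nonspatial")
                                      * n_cells_scale)),
        n_silent=int(round(p.pop("n_silent") * n_cells_scale)),
        n_interneuron=int(round(p.pop("n_interneuron") * n_cells_scale)),
        seed=seed)
    lfp_spec = LfpSpec(freq_speed_gain=p.pop("freq_speed_gain", 0.0))
    sess = simulate_session(ens, n_trials=n_trials, place_spec=p,
                            lfp_spec=lfp_spec, seed=seed,
                            bidirectional=bidirectional)
    sess.manifest.condition = preset
    return sess


def analyze_session(session: Session, seed: int = 0, n_boot: int = 500,
                    run_decoding: bool = True, run_theta: bool = True,
                    run_mi: bool = False, n_surrogates: int = 200,
                    n_perm: int = 200, lap_fields: bool = True) -> dict:
    """Run the full analysis stack on one session.

    Returns ``{"cells": DataFrame, "fields": DataFrame, "session": dict,
    "maps": ..., "decoding": ...}``.
    """
    rng = np.random.default_rng(seed)
    traj = session.trajectory
    if traj.speed is None:
        compute_speed(traj)
    grid = BinGrid.from_manifest(session.manifest)
    rewards_per_min, mean_speed = ratemaps.behavior_metrics(traj)

    cell_rows, field_rows = [], []
    maps_all, fields_all = {}, {}
    for st in session.spikes:
        cm = session.cell_meta(st.cell_id)
        ptype = ratemaps.classify_pyramidal(cm)
        maps = ratemaps.rate_maps_by_direction(traj, st, grid)
        maps_all[st.cell_id] = maps
        active = ratemaps.classify_active(maps) if ptype == "pyramidal" \
            else "silent"
        row = dict(cell_id=st.cell_id, cell_type=ptype, active=active,
                   n_spikes=len(st.spike_times))
        fbd = {}
        if active == "active":
            for d in DIRECTIONS:
                fbd[d] = placefields.detect_place_fields(
                    maps[d], n_boot=n_boot, seed=rng)
                if lap_fields and fbd[d]:
                    placefields.detect_lap_fields(maps[d], fbd[d],
                                                  n_boot=n_boot, seed=rng)
        fields_all[st.cell_id] = fbd
        all_fields = [f for fs in fbd.values() for f in fs]
        row["is_place_cell"] = bool(all_fields)
        if all_fields:
            prim = max(all_fields, key=lambda f: f.peak_rate)
            d = prim.direction
            row.update(
                stability=metrics.stability_index(maps[d]),
                spatial_info=metrics.spatial_information(
                    maps[d].mean_rate_vector,
                    maps[d].mean_occupancy_vector, grid),
                out_in_ratio=prim.out_in_ratio,
                dispersion=prim.dispersion,
                width=prim.width if prim.complete else np.nan,
                primary_direction=d, primary_peak_bin=prim.peak_bin)
            if run_mi:
                row["mi_z"] = metrics.mutual_information_z(
                    maps[d], traj, st, n_surrogates, rng)
            if session.manifest.individual_object_zones:
                row["object_responsive"] = \
                    placefields.classify_object_responsive(
                        fbd, session.manifest, grid)
            for f in all_fields:
                field_rows.append(dict(
                    cell_id=st.cell_id, direction=f.direction,
                    start=f.start, stop=f.stop, peak_bin=f.peak_bin,
                    peak_rate=f.peak_rate, is_primary=f.is_primary,
                    complete=f.complete, width=f.width,
                    dispersion=f.dispersion, out_in_ratio=f.out_in_ratio,
                    track_class=f.track_class,
                    in_oz=f.peak_bin in set(grid.oz_bins.tolist())))
        cell_rows.append(row)
    cells = pd.DataFrame(cell_rows)
    fields_df = pd.DataFrame(field_rows)

    n_neurons = len(cells)
    n_pyr = int((cells.cell_type == "pyramidal").sum())
    n_active = int((cells.active == "active").sum())
    n_place = int(cells.is_place_cell.sum()) if len(cells) else 0
    sess_row = dict(
        condition=session.manifest.condition, n_neurons=n_neurons,
        n_pyramidal=n_pyr, n_active=n_active, n_place=n_place,
        rewards_per_min=rewards_per_min, mean_speed=mean_speed,
        pct_active=100.0 * n_active / n_pyr
        if n_neurons >= MIN_NEURONS_FOR_ACTIVE_PCT and n_pyr else np.nan,
        pct_place=100.0 * n_place / n_active
        if n_active >= MIN_ACTIVE_FOR_PLACE_PCT else np.nan,
    )
    for col, name in [("stability", "mean_stability"),
                      ("spatial_info", "mean_si"),
                      ("out_in_ratio", "mean_out_in_ratio"),
                      ("dispersion", "mean_dispersion"),
                      ("width", "mean_width")]:
        sess_row[name] = float(cells[col].mean()) \
            if col in cells and cells[col].notna().any() else np.nan
    if len(fields_df):
        sess_row["n_fields_oz"] = int(fields_df.in_oz.sum())
        sess_row["n_fields_noz"] = int((~fields_df.in_oz).sum())
        sess_row["pct_on_track"] = 100.0 * float(
            (fields_df.track_class == "OnTrack").mean())

    out = {"cells": cells, "fields": fields_df, "session": sess_row,
           "maps": maps_all, "place_fields": fields_all, "grid": grid}

    if run_decoding and n_active >= 1:
        act_ids = cells.loc[cells.active == "active", "cell_id"].tolist()
        act_trains = [session.spike_train(c) for c in act_ids]
        act_maps = {c: maps_all[c] for c in act_ids}
        res = decoding.bayesian_decode(traj, act_trains, act_maps, grid)
        summ = decoding.decoding_summaries(res, grid)
        sess_row.update(decode_median_error=summ["median_error"],
                        decode_mean_accuracy=summ["mean_accuracy"],
                        decode_oz_accuracy=summ["oz_accuracy"],
                        decode_noz_accuracy=summ["noz_accuracy"])
        out["decoding"] = res
        out["decoding_summaries"] = summ

    if run_theta and session.lfp is not None:
        out.update(_theta_stage(session, cells, maps_all, fields_all,
                                grid, sess_row, rng, n_perm))
    return out


def _theta_stage(session, cells, maps_all, fields_all, grid, sess_row,
                 rng, n_perm):
    traj = session.trajectory
    ps = theta.theta_filter_phase(session.lfp)
    pyr_ids = cells.loc[cells.cell_type == "pyramidal", "cell_id"].tolist()
    pooled = np.concatenate([
        theta.spike_phases(session.spike_train(c), ps) for c in pyr_ids
    ]) if pyr_ids else np.array([])
    if len(pooled):
        theta.rotate_to_population_peak(ps, pooled)
    fits, theta_rows = [], []
    for cid, fbd in fields_all.items():
        for d, fs in fbd.items():
            rm = maps_all[cid][d]
            for f in fs:
                if not f.is_primary:
                    continue
                kw = {}
                if session.manifest.condition.startswith("NT"):
                    sst = theta.spatially_stable_trials(rm, f)
                    if len(sst) < 3:
                        continue
                    kw["trial_ids"] = sst
                u, phi, _ = theta.in_field_spike_data(
                    traj, session.spike_train(cid), ps, f, grid, **kw)
                fit = theta.precession_fit(u, phi, n_perm, rng)
                if fit is not None:
                    fits.append((cid, d, fit))
    for cid in cells.loc[cells.active == "active", "cell_id"]:
        phases = theta.spike_phases(session.spike_train(cid), ps)
        mu, r, p = theta.phase_locking(phases)
        shift = theta.unit_lfp_shift(session.spike_train(cid), session.lfp)
        theta_rows.append(dict(cell_id=cid, preferred_phase=mu,
                               resultant_length=r, rayleigh_p=p,
                               theta_mod_index=shift.theta_mod_index,
                               spectral_shift=shift.shift))
    r_freq, r_amp = theta.speed_theta_modulation(session.lfp, traj)
    sig = [f for _, _, f in fits if f.p < 0.05 and f.slope < 0]
    sess_row.update(
        pct_precessing=100.0 * len(sig) / len(fits) if fits else np.nan,
        mean_precession_slope=float(np.mean([f.slope for f in sig]))
        if sig else np.nan,
        r_freq_speed=r_freq, r_amp_speed=r_amp,
        lfp_theta_index=theta.lfp_theta_index(session.lfp))
    shifts = [r["spectral_shift"] for r in theta_rows
              if r["spectral_shift"] is not None]
    sess_row["mean_spectral_shift"] = float(np.mean(shifts)) \
        if shifts else np.nan
    return {"phase_series": ps, "precession_fits": fits,
            "theta_cells": pd.DataFrame(theta_rows)}


def run_pipeline(config: dict, seed: int = 0) -> dict:
    """Run simulate -> analyze for every configured condition/session.

    ``config["conditions"]`` maps a condition name to its parameters
    (preset name plus overrides, ``n_trials``, ``n_sessions``).  Returns a
    report with per-session rows and, for two-condition configs, a
    rank-sum comparison table of the per-cell metrics.
    """
    conds = config.get("conditions")
    if not conds:
        raise ValueError("config lists no conditions/sessions")
    stage = config.get("stage", {})
    rows, per_cond_cells = [], {}
    for name, cfg in conds.items():
        cfg = dict(cfg)
        preset = cfg.pop("preset", name)
        n_sessions = cfg.pop("n_sessions", 1)
        n_trials = cfg.pop("n_trials", 30)
        cells_frames = []
        for s in range(n_sessions):
            s_seed = seed + 1000 * s + sum(ord(c) for c in name) % 997
            sess = build_condition_session(preset, n_trials, s_seed, **cfg)
            try:
                res = analyze_session(sess, seed=s_seed, **stage)
            except Exception as e:  # pragma: no cover
                raise RuntimeError(
                    f"stage failure in condition {name}, session {s}: {e}"
                ) from e
            row = dict(res["session"])
            row.update(condition=name, session=s, seed=s_seed)
            rows.append(row)
            cells_frames.append(res["cells"].assign(condition=name))
        per_cond_cells[name] = pd.concat(cells_frames, ignore_index=True)
    report = pd.DataFrame(rows)
    comparisons = None
    if len(per_cond_cells) == 2:
        (na, ca), (nb, cb) = per_cond_cells.items()
        comp_rows = []
        for col in ("stability", "spatial_info", "out_in_ratio",
                    "dispersion", "width"):
            if col not in ca or col not in cb:
                continue
            a = ca[col].dropna()
            b = cb[col].dropna()
            if len(a) >= 3 and len(b) >= 3:
                st = ranksums(a, b)
                comp_rows.append(dict(metric=col, test="wilcoxon_ranksum",
                                      mean_a=a.mean(), mean_b=b.mean(),
                                      stat=st.statistic, p=st.pvalue,
                                      condition_a=na, condition_b=nb))
        comparisons = pd.DataFrame(comp_rows)
    return {"report": report, "comparisons": comparisons,
            "cells": per_cond_cells}


def object_manipulation_analysis(session_fam: Session, session_new: Session,
                                 template: str = "fam",
                                 n_trials_window: int = 10) -> pd.DataFrame:
    """Map-similarity transition around an object add/remove switch.

    Both sessions must hold the same cells (matched ids).  The template is
    the mean map of the condition with objects (the more stable one);
    similarity of template-condition laps uses a leave-one-out template.
    Returns one row per back-and-forth trial offset (-n..-1, 1..n) with the
    mean similarity across active pyramidal cells.
    """
    ids_a = set(session_fam.cell_ids)
    if ids_a != set(session_new.cell_ids):
        raise ValueError("sessions have unmatched cells")
    grid = BinGrid.from_manifest(session_fam.manifest)
    for s in (session_fam, session_new):
        if s.trajectory.speed is None:
            compute_speed(s.trajectory)
    sims_before, sims_after = [], []
    for cid in sorted(ids_a):
        if ratemaps.classify_pyramidal(session_fam.cell_meta(cid)) \
                != "pyramidal":
            continue
        maps_f = ratemaps.rate_maps_by_direction(
            session_fam.trajectory, session_fam.spike_train(cid), grid)
        maps_n = ratemaps.rate_maps_by_direction(
            session_new.trajectory, session_new.spike_train(cid), grid)
        if ratemaps.classify_active(maps_f) != "active" and \
                ratemaps.classify_active(maps_n) != "active":
            continue
        tmpl_maps = maps_f if template == "fam" else maps_n
        tmpl = {d: m.per_trial_rate for d, m in tmpl_maps.items()}
        tf = {d: m.per_trial_rate for d, m in maps_f.items()}
        tn = {d: m.per_trial_rate for d, m in maps_n.items()}
        sims_before.append(metrics.map_similarity(
            tf, tmpl, grid, template_is_self=(template == "fam")))
        sims_after.append(metrics.map_similarity(
            tn, tmpl, grid, template_is_self=(template == "new")))
    before = np.nanmean(_stack_tail(sims_before, n_trials_window, True),
                        axis=0)
    after = np.nanmean(_stack_tail(sims_after, n_trials_window, False),
                       axis=0)
    offs = list(range(-len(before), 0)) + list(range(1, len(after) + 1))
    return pd.DataFrame({"trial_offset": offs,
                         "map_similarity": np.concatenate([before, after])})


def _stack_tail(series_list, n, tail):
    m = min(len(s) for s in series_list)
    k = min(n, m)
    if tail:
        return np.vstack([s[len(s) - k:] for s in series_list])
    return np.vstack([s[:k] for s in series_list])
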