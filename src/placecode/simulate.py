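"""Synthetic virtual linear-track sessions with known ground truth.

The generator emulates the statistical structure the analysis stages
assume: back-and-forth trials on a 200 cm track with teleportations at the
ends, ~15 cm/s running with stationary pauses, place cells with Gaussian
spatial tuning plus out-of-field baseline firing and trial-to-trial center
jitter, a theta-band (~6.7 Hz) LFP with optional speed modulation of
frequency and amplitude, spikes that precess in phase through their fields,
non-spatial active cells, silent cells, interneurons, and object-responsive
cells anchored to individual object zones.

Spikes are drawn from an inhomogeneous Poisson process on a 1 ms grid with
intensity

    lambda(t) = [b + p * exp(-(x(t) - c_trial)^2 / (2 sigma^2))]
                * [1 + m * cos(phi_lfp(t) - psi(x(t)))]

where ``c_trial`` is the field center jittered per trial and ``psi``
advances linearly across the field with the requested precession slope.
Phase-dependent intensity yields both single-cell phase precession and
theta-timescale compression across cell pairs with one mechanism.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .session import (BACK, DEFAULT_LFP_FS, DEFAULT_OBJECT_ZONES,
                      DEFAULT_TRAJ_DT, FORTH, CellMeta, LfpSignal, Session,
                      SessionManifest, SpikeTrain, Trajectory, compute_speed,
                      save_session)


@dataclass
class PlaceCellSpec:
    """Ground-truth tuning of one simulated place cell.

    ``center_forth`` / ``center_back`` are the field centers (cm) in each
    running direction; ``None`` means no field in that direction.
    ``precession_slope`` is in radians per normalized field unit, the field
    spanning center +/- 2 sigma along the direction of travel.
    """

    center_forth: float | None = 100.0
    center_back: float | None = None
    width_sigma: float = 9.0
    peak_rate: float = 8.0
    baseline_rate: float = 0.5
    center_jitter_sd: float = 0.0
    precession_slope: float = -2.0
    precession_onset_phase: float = np.pi
    theta_mod_depth: float = 0.6

    def __post_init__(self):
        if self.width_sigma <= 0:
            raise ValueError("width_sigma must be > 0")
        if self.peak_rate < 0 or self.baseline_rate < 0:
            raise ValueError("rates must be >= 0")
        if abs(self.precession_slope) > 4 * np.pi:
            raise ValueError("|precession_slope| must be <= 4*pi")


@dataclass
class LfpSpec:
    """Parameters of the simulated theta-band LFP."""

    base_freq: float = 6.7
    freq_speed_gain: float = 0.0   # Hz per cm/s
    amp_speed_gain: float = 0.0    # relative amplitude per cm/s
    asymmetry: float = 0.0         # [0,1) phase-warp factor
    noise_sd: float = 0.3
    fs: float = DEFAULT_LFP_FS

    def __post_init__(self):
        if not (4.0 < self.base_freq < 12.0):
            raise ValueError("base_freq must lie in (4, 12) Hz")


@dataclass
class EnsembleSpec:
    """Composition of a simulated ensemble."""

    n_place: int = 20
    n_active_nonspatial: int = 10
    n_silent: int = 8
    n_interneuron: int = 3
    n_object_responsive: int = 0
    seed: int = 0

    def __post_init__(self):
        for f in ("n_place", "n_active_nonspatial", "n_silent",
                  "n_interneuron", "n_object_responsive"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


#: condition presets: generator parameters that emulate a cue-rich track
#: (low jitter / low baseline, strong precession) and a cue-poor track
#: (high jitter / high baseline, no consistent precession).
PRESETS = {
    "OT-like": dict(width_sigma=9.0, peak_rate=8.0, baseline_rate=0.8,
                    center_jitter_sd=2.0, precession_slope=-2.0,
                    theta_mod_depth=0.6, n_place=22, n_active_nonspatial=8,
                    n_silent=10, n_interneuron=3, freq_speed_gain=0.02),
    "NT-like": dict(width_sigma=12.0, peak_rate=7.0, baseline_rate=3.5,
                    center_jitter_sd=8.0, precession_slope=0.0,
                    theta_mod_depth=0.4, n_place=6, n_active_nonspatial=24,
                    n_silent=10, n_interneuron=3, freq_speed_gain=0.0),
}


def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def simulate_trajectory(n_trials: int, track_length: float = 200.0,
                        mean_speed: float = 15.0, pause_prob: float = 0.05,
                        dt: float = DEFAULT_TRAJ_DT,
                        speed_cv: float = 0.15, pause_mean_s: float = 1.0,
                        seed=None) -> Trajectory:
    """Alternating forth/back trials covering the whole track.

    Running speed fluctuates around ``mean_speed`` (Ornstein-Uhlenbeck
    modulation, clipped so it never drops below ``mean_speed / 2`` while
    running); stationary pauses start at rate ``pause_prob`` per second and
    last ``Exp(pause_mean_s)``.  Trials end when the far end of the track is
    reached; the next trial starts at the same position facing the other way
    (teleportation).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if mean_speed <= 0 or pause_prob < 0:
        raise ValueError("invalid trajectory parameters")
    rng = _rng(seed)
    ou_decay = np.exp(-dt / 1.0)
    ou_sd = np.sqrt(1.0 - ou_decay ** 2)
    t_list, x_list, tr_list, dir_list = [], [], [], []
    t = 0.0
    for trial in range(1, n_trials + 1):
        forth = trial % 2 == 1
        x = 0.0 if forth else track_length
        sgn = 1.0 if forth else -1.0
        z = rng.standard_normal()
        pause_left = 0.0
        while True:
            t_list.append(t)
            x_list.append(x)
            tr_list.append(trial)
            dir_list.append(FORTH if forth else BACK)
            t += dt
            if pause_left > 0.0:
                pause_left -= dt
            else:
                if pause_prob > 0 and rng.random() < pause_prob * dt:
                    pause_left = rng.exponential(pause_mean_s)
                    continue
                z = ou_decay * z + ou_sd * rng.standard_normal()
                v = mean_speed * np.clip(1.0 + speed_cv * z, 0.55, 1.6)
                x += sgn * v * dt
            if (forth and x >= track_length) or (not forth and x <= 0.0):
                x = np.clip(x, 0.0, track_length)
                t_list.append(t)
                x_list.append(x)
                tr_list.append(trial)
                dir_list.append(FORTH if forth else BACK)
                t += dt
                break
    traj = Trajectory(np.array(t_list), np.array(x_list),
                      np.array(tr_list), np.array(dir_list),
                      track_length=track_length)
    return compute_speed(traj)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def simulate_lfp(traj: Trajectory, spec: LfpSpec | None = None,
                 seed=None) -> tuple[LfpSignal, np.ndarray]:
    """Theta LFP with speed-dependent frequency/amplitude.

    Instantaneous frequency is ``base_freq + freq_speed_gain * speed(t)``;
    the returned second element is the ground-truth unwrapped phase on the
    LFP time base.  ``asymmetry`` warps the waveform within each cycle
    (phi + a*sin(phi)) without changing the cycle boundaries.
    """
    spec = spec or LfpSpec()
    rng = _rng(seed)
    if traj.speed is None:
        compute_speed(traj)
    fs = spec.fs
    t = traj.t[0] + np.arange(int(np.floor(
        (traj.t[-1] - traj.t[0]) * fs)) + 1) / fs
    speed = np.interp(t, traj.t, traj.speed)
    freq = spec.base_freq + spec.freq_speed_gain * speed
    phase = 2.0 * np.pi * np.cumsum(freq) / fs
    phase -= phase[0]
    amp = 1.0 + spec.amp_speed_gain * speed
    warped = phase + spec.asymmetry * np.sin(phase)
    v = amp * np.cos(warped) + spec.noise_sd * rng.standard_normal(len(t))
    return LfpSignal(t, v, fs), phase


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def _fine_grid(traj: Trajectory, dt_fine: float):
    t = traj.t[0] + np.arange(int(np.floor(
        (traj.t[-1] - traj.t[0]) / dt_fine))) * dt_fine
    x = np.interp(t, traj.t, traj.x)
    idx = np.clip(np.searchsorted(traj.t, t, side="right") - 1,
                  0, len(traj.t) - 1)
    trial = traj.trial_id[idx]
    forth = traj.direction[idx] == FORTH
    return t, x, trial, forth


def simulate_place_cell(traj: Trajectory, spec: PlaceCellSpec, seed=None,
                        lfp_phase: tuple | None = None,
                        dt_fine: float = 0.001,
                        cell_id: int = 0) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes of one place cell (1 ms intensity grid).

    ``lfp_phase`` is ``(t, unwrapped_phase)`` as returned by
    :func:`simulate_lfp`; required whenever ``theta_mod_depth > 0``.
    """
    rng = _rng(seed)
    if spec.theta_mod_depth > 0 and lfp_phase is None:
        raise ValueError("lfp_phase required when theta_mod_depth > 0")
    t, x, trial, forth = _fine_grid(traj, dt_fine)
    lam = np.full(len(t), spec.baseline_rate)
    psi = np.full(len(t), spec.precession_onset_phase)
    trials = np.unique(trial)
    jit = rng.normal(0.0, spec.center_jitter_sd, len(trials)) \
        if spec.center_jitter_sd > 0 else np.zeros(len(trials))
    jitter = jit[np.searchsorted(trials, trial)]
    for is_forth, center in ((True, spec.center_forth),
                             (False, spec.center_back)):
        if center is None:
            continue
        m = forth if is_forth else ~forth
        c = center + jitter[m]
        dx = x[m] - c
        lam[m] = lam[m] + spec.peak_rate * np.exp(
            -dx ** 2 / (2.0 * spec.width_sigma ** 2))
        # normalized position through the field along the direction of travel
        half = 2.0 * spec.width_sigma
        u = (dx if is_forth else -dx) / (2.0 * half) + 0.5
        psi[m] = spec.precession_onset_phase + \
            spec.precession_slope * np.clip(u, 0.0, 1.0)
    if spec.theta_mod_depth > 0:
        tp, ph = lfp_phase
        phi = np.interp(t, tp, ph)
        lam = lam * (1.0 + spec.theta_mod_depth * np.cos(phi - psi))
    counts = rng.poisson(lam * dt_fine)
    hits = np.repeat(np.flatnonzero(counts), counts[counts > 0])
    times = t[hits] + rng.uniform(0.0, dt_fine, len(hits))
    return SpikeTrain(cell_id, np.sort(times))


def simulate_poisson_cell(traj: Trajectory, rate: float, seed=None,
                          lfp_phase: tuple | None = None,
                          theta_mod_depth: float = 0.0,
                          preferred_phase: float = np.pi,
                          dt_fine: float = 0.001,
                          cell_id: int = 0) -> SpikeTrain:
    """Spatially untuned Poisson cell, optionally theta modulated."""
    spec = PlaceCellSpec(center_forth=None, center_back=None,
                         baseline_rate=rate, peak_rate=0.0,
                         theta_mod_depth=theta_mod_depth,
                         precession_onset_phase=preferred_phase,
                         precession_slope=0.0)
    return simulate_place_cell(traj, spec, seed, lfp_phase, dt_fine, cell_id)


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

def _burst_index_from_spikes(times: np.ndarray, duration: float,
                             isi_thresh: float = 0.006) -> float:
    """log2 of observed vs Poisson-expected fraction of ISIs <= 6 ms."""
    if len(times) < 10 or duration <= 0:
        return 0.0
    rate = len(times) / duration
    isi = np.diff(times)
    obs = np.mean(isi <= isi_thresh)
    exp = 1.0 - np.exp(-rate * isi_thresh)
    if obs <= 0 or exp <= 0:
        return -5.0
    return float(np.log2(obs / exp))


def simulate_session(ensemble: EnsembleSpec | None = None,
                     manifest: SessionManifest | None = None,
                     n_trials: int = 30,
                     place_spec: dict | None = None,
                     lfp_spec: LfpSpec | None = None,
                     mean_speed: float = 15.0, pause_prob: float = 0.05,
                     bidirectional: bool = False,
                     out_dir=None, seed: int = 0) -> Session:
    """Generate a complete session; optionally write it to ``out_dir``.

    ``place_spec`` overrides :class:`PlaceCellSpec` defaults for all place
    cells (e.g. the keys of a condition preset).  Place-cell centers tile
    the analyzed track; each cell is unidirectional (random direction)
    unless ``bidirectional``.  Object-responsive cells are always
    bidirectional with both fields inside the same individual object zone.
    The ground-truth block (class labels, centers, slopes) is embedded in
    the returned manifest.
    """
    ensemble = ensemble or EnsembleSpec(seed=seed)
    manifest = manifest or SessionManifest(condition="custom")
    rng = np.random.default_rng(seed)
    traj = simulate_trajectory(n_trials, manifest.track_length, mean_speed,
                               pause_prob, seed=rng)
    lfp_spec = lfp_spec or LfpSpec()
    lfp, phase = simulate_lfp(traj, lfp_spec, seed=rng)
    lfp_phase = (lfp.t, phase)
    duration = traj.t[-1] - traj.t[0]
    pspec = dict(place_spec or {})
    base = PlaceCellSpec(**{k: v for k, v in pspec.items()
                            if k in PlaceCellSpec.__dataclass_fields__})

    spikes, cells, gt_cells = [], [], {}
    cid = 0

    def add(train, cls, burst, dur, extra=None):
        nonlocal cid
        train.cell_id = cid
        spikes.append(train)
        cells.append(CellMeta(cid, len(train.spike_times) / duration,
                              burst, dur))
        gt_cells[cid] = {"class": cls, **(extra or {})}
        cid += 1

    L = manifest.track_length
    lo, hi = 0.15 * L + 5.0, 0.85 * L - 5.0
    n_pl = ensemble.n_place
    centers = np.linspace(lo, hi, n_pl) if n_pl else np.array([])
    centers = centers + rng.uniform(-2.0, 2.0, n_pl)
    for c in centers:
        kw = dict(pspec)
        if bidirectional or rng.random() < kw.pop("p_bidirectional", 0.0):
            kw.update(center_forth=c, center_back=c)
        elif rng.random() < 0.5:
            kw.update(center_forth=c, center_back=None)
        else:
            kw.update(center_forth=None, center_back=c)
        kw = {k: v for k, v in kw.items()
              if k in PlaceCellSpec.__dataclass_fields__}
        sp = PlaceCellSpec(**kw)
        train = simulate_place_cell(traj, sp, rng, lfp_phase)
        add(train, "place", 0.5, 0.5,
            {"center_forth": sp.center_forth, "center_back": sp.center_back,
             "slope": sp.precession_slope, "sigma": sp.width_sigma})
    iozs = manifest.individual_object_zones
    for _ in range(ensemble.n_object_responsive):
        name, a, b = iozs[rng.integers(len(iozs))]
        c = rng.uniform(a + 2.0, b - 2.0)
        kw = {k: v for k, v in pspec.items()
              if k in PlaceCellSpec.__dataclass_fields__}
        kw.update(center_forth=c, center_back=c)
        sp = PlaceCellSpec(**kw)
        train = simulate_place_cell(traj, sp, rng, lfp_phase)
        add(train, "object_responsive", 0.5, 0.5,
            {"center_forth": c, "center_back": c, "object": name})
    for _ in range(ensemble.n_active_nonspatial):
        rate = rng.uniform(1.5, 5.0)
        train = simulate_poisson_cell(traj, rate, rng, lfp_phase,
                                      theta_mod_depth=0.3,
                                      preferred_phase=rng.uniform(
                                          0.7 * np.pi, 1.3 * np.pi))
        add(train, "active_nonspatial", 0.5, 0.5)
    for _ in range(ensemble.n_silent):
        train = simulate_poisson_cell(traj, 0.05, rng)
        add(train, "silent", 0.5, 0.5)
    for _ in range(ensemble.n_interneuron):
        train = simulate_poisson_cell(traj, 30.0, rng, lfp_phase,
                                      theta_mod_depth=0.2)
        add(train, "interneuron", -0.5, 0.25)

    manifest.ground_truth = {
        "seed": int(seed), "n_trials": int(n_trials),
        "cells": gt_cells,
        "lfp": {"base_freq": lfp_spec.base_freq,
                "freq_speed_gain": lfp_spec.freq_speed_gain},
    }
    session = Session(traj, spikes, cells, lfp, manifest)
    if out_dir is not None:
        save_session(session, out_dir)
    return session


def session_digest(path) -> str:
    """SHA-256 digest over the text files of a saved session directory."""
    h = hashlib.sha256()
    from pathlib import Path
    for f in sorted(Path(path).iterdir()):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()
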