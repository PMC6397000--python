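"""Session data model for head-fixed virtual linear-track recordings.

A session bundles the animal trajectory (uniformly sampled position on a
linear track, split into alternating forth/back trials separated by
teleportations), per-unit spike trains, per-unit waveform metadata, and one
LFP channel.  All downstream analyses (rate maps, place-field detection,
decoding, theta analyses) consume these containers.

Coordinate conventions
----------------------
Positions are in cm, 0 at one end of the track.  Spatial bins are half-open
``[k*s, (k+1)*s)`` and 0-indexed.  Back trials are analysed on the same
0..L axis but as a separate running direction.  The reward zones are the
first and last 10% of the track and are excluded from analysis; the
remaining bins are the *analyzed* bins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

FORTH = "forth"
BACK = "back"
DIRECTIONS = (FORTH, BACK)

DEFAULT_TRACK_LENGTH = 200.0
DEFAULT_TRAJ_DT = 0.02  # s (50 Hz position sampling)
DEFAULT_LFP_FS = 1250.0  # Hz

#: object zones of the standard objects track: two stretches of track
#: containing virtual 3D objects (crane+cube, and tree).
DEFAULT_OBJECT_ZONES = ((30.0, 70.0), (160.0, 180.0))
#: individual object zones, one per object, used for object-responsive cells.
DEFAULT_INDIVIDUAL_OBJECT_ZONES = (
    ("crane", 30.0, 46.0),
    ("cube", 60.0, 70.0),
    ("tree", 164.0, 180.0),
)


class ValidationError(ValueError):
    """Raised when a session component violates a structural invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-stamped position stream for one session.

    Attributes
    ----------
    t : array, seconds, strictly increasing, uniform sampling period.
    x : array, cm in [0, track_length].
    trial_id : int array, >= 1, constant blocks; boundaries are teleports.
    direction : str array, ``"forth"`` or ``"back"``, constant within a trial.
    speed : cm/s, filled by :func:`compute_speed` (NaN until then).
    """

    t: np.ndarray
    x: np.ndarray
    trial_id: np.ndarray
    direction: np.ndarray
    speed: np.ndarray | None = None
    track_length: float = DEFAULT_TRACK_LENGTH

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.trial_id = np.asarray(self.trial_id, dtype=int)
        self.direction = np.asarray(self.direction, dtype="U5")
        if self.speed is not None:
            self.speed = np.asarray(self.speed, dtype=float)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    @property
    def trials(self) -> np.ndarray:
        """Sorted unique trial ids."""
        return np.unique(self.trial_id)

    def trial_direction(self, trial: int) -> str:
        return str(self.direction[self.trial_id == trial][0])

    def validate(self) -> None:
        dts = np.diff(self.t)
        if len(self.t) < 2 or np.any(dts <= 0):
            raise ValidationError("t: must be strictly increasing")
        if np.max(np.abs(dts - np.median(dts))) > 1e-6:
            raise ValidationError("t: sampling period must be uniform")
        if np.any(self.x < -1e-9) or np.any(self.x > self.track_length + 1e-9):
            raise ValidationError("x: positions outside [0, track_length]")
        if np.any(self.trial_id < 1):
            raise ValidationError("trial_id: ids must be >= 1")
        for tr in self.trials:
            d = self.direction[self.trial_id == tr]
            if not np.all(d == d[0]):
                raise ValidationError(
                    f"direction: not constant within trial {tr}")
            if d[0] not in DIRECTIONS:
                raise ValidationError(f"direction: unknown value {d[0]!r}")


@dataclass
class SpikeTrain:
    """Spike times (seconds, sorted) for one unit."""

    cell_id: int
    spike_times: np.ndarray

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    def validate(self, t_start: float | None = None,
                 t_stop: float | None = None) -> None:
        st = self.spike_times
        if np.any(np.diff(st) < 0):
            raise ValidationError(f"spike_times: not sorted (cell {self.cell_id})")
        if t_start is not None and len(st) and (st[0] < t_start - 1e-6 or
                                                st[-1] > t_stop + 1e-6):
            raise ValidationError(
                f"spike_times: outside session bounds (cell {self.cell_id})")


@dataclass
class CellMeta:
    """Waveform/rate metadata for one unit, used for cell-type classification.

    ``burst_index`` follows the convention that values > 0 mean burstier
    than a rate-matched Poisson train; ``spike_duration`` is in ms.
    """

    cell_id: int
    mean_rate: float
    burst_index: float
    spike_duration: float
    region_tag: str = "CA1"

    def validate(self) -> None:
        if self.mean_rate < 0:
            raise ValidationError(f"mean_rate: negative (cell {self.cell_id})")
        if self.spike_duration <= 0:
            raise ValidationError(
                f"spike_duration: must be > 0 (cell {self.cell_id})")


@dataclass
class LfpSignal:
    """Single LFP channel, uniformly sampled at ``fs`` Hz."""

    t: np.ndarray
    v: np.ndarray
    fs: float = DEFAULT_LFP_FS

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)

    def validate(self) -> None:
        dts = np.diff(self.t)
        if len(self.t) >= 2 and np.max(np.abs(dts - 1.0 / self.fs)) > 1e-6:
            raise ValidationError("lfp.t: sampling not uniform at fs")


@dataclass
class SessionManifest:
    """Session-level description: condition, track geometry and zones."""

    condition: str = "custom"
    track_length: float = DEFAULT_TRACK_LENGTH
    reward_fraction: float = 0.10
    object_zones: tuple = DEFAULT_OBJECT_ZONES
    individual_object_zones: tuple = DEFAULT_INDIVIDUAL_OBJECT_ZONES
    lfp_fs: float = DEFAULT_LFP_FS
    ground_truth: dict | None = None

    def __post_init__(self):
        self.object_zones = tuple((float(a), float(b))
                                  for a, b in self.object_zones)
        self.individual_object_zones = tuple(
            (str(n), float(a), float(b))
            for n, a, b in self.individual_object_zones)

    def validate(self) -> None:
        L = self.track_length
        for a, b in self.object_zones:
            if not (0 <= a < b <= L):
                raise ValidationError(f"object_zones: ({a},{b}) outside track")
        for name, a, b in self.individual_object_zones:
            if not any(za <= a and b <= zb for za, zb in self.object_zones):
                raise ValidationError(
                    f"individual_object_zones: {name} not inside an object zone")


class BinGrid:
    """Partition of the track into equal spatial bins with zone index sets.

    Parameters
    ----------
    bin_size : cm (2 for rate maps / decoding, 10 for field-distribution
        statistics).
    """

    def __init__(self, track_length: float = DEFAULT_TRACK_LENGTH,
                 bin_size: float = 2.0, reward_fraction: float = 0.10,
                 object_zones: tuple = DEFAULT_OBJECT_ZONES):
        n = track_length / bin_size
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("bin_size: must divide track_length")
        self.track_length = float(track_length)
        self.bin_size = float(bin_size)
        self.n_bins = int(round(n))
        self.reward_fraction = float(reward_fraction)
        self.object_zones = tuple(object_zones)
        self.edges = np.arange(self.n_bins + 1) * self.bin_size
        self.centers = self.edges[:-1] + self.bin_size / 2.0

    @classmethod
    def from_manifest(cls, manifest: SessionManifest,
                      bin_size: float = 2.0) -> "BinGrid":
        return cls(manifest.track_length, bin_size, manifest.reward_fraction,
                   manifest.object_zones)

    def zone_bins(self, start: float, end: float) -> np.ndarray:
        """Indices of bins fully contained in [start, end]."""
        k = np.arange(self.n_bins)
        return k[(k * self.bin_size >= start - 1e-9) &
                 ((k + 1) * self.bin_size <= end + 1e-9)]

    @property
    def reward_bins(self) -> np.ndarray:
        L, f = self.track_length, self.reward_fraction
        return np.concatenate([self.zone_bins(0.0, L * f),
                               self.zone_bins(L * (1 - f), L)])

    @property
    def analyzed_bins(self) -> np.ndarray:
        """Bins entering all analyses (reward zones excluded), per direction."""
        return np.setdiff1d(np.arange(self.n_bins), self.reward_bins)

    @property
    def oz_bins(self) -> np.ndarray:
        """Object-zone bins (per direction)."""
        if not self.object_zones:
            return np.array([], dtype=int)
        return np.unique(np.concatenate(
            [self.zone_bins(a, b) for a, b in self.object_zones]))

    @property
    def noz_bins(self) -> np.ndarray:
        """No-object-zone bins: analyzed bins outside object zones."""
        return np.setdiff1d(self.analyzed_bins, self.oz_bins)

    def x_to_bin(self, x: np.ndarray) -> np.ndarray:
        b = np.floor(np.asarray(x) / self.bin_size).astype(int)
        return np.clip(b, 0, self.n_bins - 1)


@dataclass
class Session:
    trajectory: Trajectory
    spikes: list
    cells: list
    lfp: LfpSignal | None
    manifest: SessionManifest

    def spike_train(self, cell_id: int) -> SpikeTrain:
        for st in self.spikes:
            if st.cell_id == cell_id:
                return st
        raise KeyError(cell_id)

    def cell_meta(self, cell_id: int) -> CellMeta:
        for cm in self.cells:
            if cm.cell_id == cell_id:
                return cm
        raise KeyError(cell_id)

    @property
    def cell_ids(self) -> list:
        return [st.cell_id for st in self.spikes]

    def validate(self) -> None:
        self.trajectory.validate()
        self.manifest.validate()
        if self.lfp is not None:
            self.lfp.validate()
        meta_ids = {cm.cell_id for cm in self.cells}
        for st in self.spikes:
            st.validate(self.trajectory.t[0], self.trajectory.t[-1])
            if st.cell_id not in meta_ids:
                raise ValidationError(
                    f"cell_id: spike train {st.cell_id} has no metadata")
        for cm in self.cells:
            cm.validate()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_speed(traj: Trajectory) -> Trajectory:
    """Fill ``traj.speed`` with within-trial finite-difference speed (cm/s).

    The last sample of each trial copies the previous sample's speed, so
    teleportations between trials never produce spurious speed spikes.
    """
    speed = np.zeros_like(traj.x)
    dt = traj.dt
    for tr in traj.trials:
        idx = np.flatnonzero(traj.trial_id == tr)
        if len(idx) < 2:
            warnings.warn(f"trial {tr} has a single sample; speed set to 0")
            continue
        d = np.abs(np.diff(traj.x[idx])) / dt
        speed[idx[:-1]] = d
        speed[idx[-1]] = d[-1]
    traj.speed = speed
    return traj


def run_epoch_mask(traj: Trajectory, speed_threshold: float = 2.0,
                   exclude_reward_zones: bool = True,
                   reward_fraction: float = 0.10) -> np.ndarray:
    """Boolean mask of locomotion samples.

    True iff speed > ``speed_threshold`` cm/s and, if requested, the animal
    is outside the reward zones (strictly inside the central 80% of track).
    """
    if traj.speed is None:
        raise ValidationError("speed: call compute_speed first")
    mask = traj.speed > speed_threshold
    if exclude_reward_zones:
        lo = traj.track_length * reward_fraction
        hi = traj.track_length * (1.0 - reward_fraction)
        mask &= (traj.x > lo) & (traj.x < hi)
    return mask


# ---------------------------------------------------------------------------
# file I/O: manifest.json, trajectory.csv, spikes.csv, cells.csv, lfp.csv
# ---------------------------------------------------------------------------

def save_session(session: Session, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    man = asdict(session.manifest)
    with open(path / "manifest.json", "w") as fh:
        json.dump(man, fh, indent=1, default=_json_default)
    traj = session.trajectory
    df = pd.DataFrame({"t": traj.t, "x": traj.x, "trial_id": traj.trial_id,
                       "direction": traj.direction})
    df.to_csv(path / "trajectory.csv", index=False, float_format="%.6f")
    rows = [(st.cell_id, t) for st in session.spikes for t in st.spike_times]
    sp = pd.DataFrame(rows, columns=["cell_id", "t"])
    sp.to_csv(path / "spikes.csv", index=False, float_format="%.4f")
    cm = pd.DataFrame([asdict(c) for c in session.cells])
    cm.to_csv(path / "cells.csv", index=False)
    if session.lfp is not None:
        pd.DataFrame({"v": session.lfp.v}).to_csv(
            path / "lfp.csv", index=False, float_format="%.5f")
    return path


def load_session(path) -> Session:
    path = Path(path)
    mf = path / "manifest.json"
    if not mf.exists():
        raise FileNotFoundError(f"missing manifest: {mf}")
    with open(mf) as fh:
        man = json.load(fh)
    gt = man.pop("ground_truth", None)
    manifest = SessionManifest(
        condition=man.get("condition", "custom"),
        track_length=man.get("track_length", DEFAULT_TRACK_LENGTH),
        reward_fraction=man.get("reward_fraction", 0.10),
        object_zones=tuple(tuple(z) for z in man.get(
            "object_zones", DEFAULT_OBJECT_ZONES)),
        individual_object_zones=tuple(tuple(z) for z in man.get(
            "individual_object_zones", DEFAULT_INDIVIDUAL_OBJECT_ZONES)),
        lfp_fs=man.get("lfp_fs", DEFAULT_LFP_FS),
        ground_truth=gt,
    )
    df = pd.read_csv(path / "trajectory.csv")
    traj = Trajectory(df["t"].to_numpy(), df["x"].to_numpy(),
                      df["trial_id"].to_numpy(),
                      df["direction"].to_numpy(dtype="U5"),
                      track_length=manifest.track_length)
    sp = pd.read_csv(path / "spikes.csv")
    cmdf = pd.read_csv(path / "cells.csv")
    spikes = []
    for cid in cmdf["cell_id"]:
        st = sp.loc[sp["cell_id"] == cid, "t"].to_numpy()
        spikes.append(SpikeTrain(int(cid), np.sort(st)))
    cells = [CellMeta(int(r.cell_id), float(r.mean_rate),
                      float(r.burst_index), float(r.spike_duration),
                      str(getattr(r, "region_tag", "CA1")))
             for r in cmdf.itertuples()]
    lfp = None
    lf = path / "lfp.csv"
    if lf.exists():
        v = pd.read_csv(lf)["v"].to_numpy()
        fs = manifest.lfp_fs
        t = traj.t[0] + np.arange(len(v)) / fs
        lfp = LfpSignal(t, v, fs)
    session = Session(traj, spikes, cells, lfp, manifest)
    session.validate()
    compute_speed(traj)
    return session


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
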