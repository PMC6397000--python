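"""Bootstrap place-field detection and per-field geometry metrics.

Detection compares the observed mean rate vector with surrogate mean rate
vectors built, per trial, from homogeneous Poisson spike trains at that
trial's mean firing rate mapped through the real trajectory.  Because a
homogeneous Poisson train binned through the trajectory yields independent
Poisson counts with mean ``rate * occupancy`` per bin, surrogate count
vectors are drawn directly as Poisson variates and passed through the same
smoothing/division as the data.  The per-bin p-value is one-sided
(surrogate >= observed, add-one corrected): fields are firing increases.

Procedure order (fixed): candidate runs -> merge to fixed point -> edge
extension -> size filter -> trial-stability criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np

from .ratemaps import RateMap, smoothing_matrix
from .session import BinGrid, SessionManifest


@dataclass
class LapField:
    trial_index: int       # row in the rate map, not the session trial id
    start: int
    stop: int              # inclusive
    center_bin: int
    peak_rate: float


@dataclass
class PlaceField:
    cell_id: int
    direction: str
    start: int             # bin indices, inclusive extent
    stop: int
    peak_bin: int
    peak_rate: float
    is_primary: bool = False
    complete: bool = False
    width: float | None = None          # cm, complete fields only
    dispersion: float | None = None     # cm
    out_in_ratio: float | None = None
    track_class: str = "OnTrack"
    lap_fields: list = dfield(default_factory=list)

    @property
    def bins(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 1)

    @property
    def size(self) -> int:
        return self.stop - self.start + 1


def _runs(mask: np.ndarray, offset: int = 0) -> list:
    """Inclusive (start, stop) index pairs of True runs."""
    out = []
    i = 0
    m = np.asarray(mask)
    while i < len(m):
        if m[i]:
            j = i
            while j + 1 < len(m) and m[j + 1]:
                j += 1
            out.append((i + offset, j + offset))
            i = j + 1
        else:
            i += 1
    return out


def _merge(intervals: list, gap: int) -> list:
    """Merge intervals whose closest edges are <= gap bins apart (fixed point)."""
    ivs = sorted(intervals)
    changed = True
    while changed:
        changed = False
        out = []
        for iv in ivs:
            if out and iv[0] - out[-1][1] <= gap:
                out[-1] = (out[-1][0], max(out[-1][1], iv[1]))
                changed = True
            else:
                out.append(list(iv) if isinstance(iv, list) else iv)
        ivs = [tuple(iv) for iv in out]
    return ivs


def bootstrap_pvalues(rate_map: RateMap, n_boot: int = 1000,
                      rng=None, observed: np.ndarray | None = None,
                      trial_rows: np.ndarray | None = None) -> np.ndarray:
    """Per-bin add-one p-values of the (mean) rate vector under the
    trial-wise homogeneous Poisson null."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    rows = np.arange(rate_map.n_trials) if trial_rows is None else trial_rows
    occ = rate_map.per_trial_occupancy[rows]
    occ_s = rate_map.per_trial_occ_smooth[rows]
    lam = rate_map.trial_mean_rate[rows]
    if observed is None:
        observed = rate_map.per_trial_rate[rows].mean(axis=0)
    S = smoothing_matrix(rate_map.grid.n_bins, rate_map.sigma_bins)
    mean_counts = lam[:, None] * occ
    n_bins = rate_map.grid.n_bins
    exceed = np.zeros(n_bins)
    good = occ_s >= 1e-3
    chunk = max(1, int(2.5e6 // (len(rows) * n_bins)))
    for k0 in range(0, n_boot, chunk):
        k = min(chunk, n_boot - k0)
        draws = rng.poisson(mean_counts, size=(k,) + mean_counts.shape)
        sm = draws.astype(float) @ S.T
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(good, sm / occ_s, 0.0)
        exceed += (rate.mean(axis=1) >= observed - 1e-12).sum(axis=0)
    return (1.0 + exceed) / (1.0 + n_boot)


def _candidates_from_pvalues(p: np.ndarray, grid: BinGrid,
                             alpha_bin: float = 0.01, p_extend: float = 0.30,
                             merge_gap: int = 5, min_size: int = 4,
                             max_size: int = 45, max_extend: int = 5) -> list:
    ab = grid.analyzed_bins
    lo, hi = ab[0], ab[-1]
    sig = np.zeros(grid.n_bins, bool)
    sig[ab] = p[ab] < alpha_bin
    cands = [iv for iv in _runs(sig) if iv[1] - iv[0] + 1 >= min_size]
    cands = _merge(cands, merge_gap)
    # extend edges while sub-threshold, staying in the analyzed region and
    # never crossing into a neighboring candidate
    out = []
    for i, (a, b) in enumerate(cands):
        left_lim = max(lo, cands[i - 1][1] + 1 if i > 0 else lo)
        right_lim = min(hi, cands[i + 1][0] - 1 if i + 1 < len(cands) else hi)
        for _ in range(max_extend):
            if a - 1 >= left_lim and p[a - 1] < p_extend:
                a -= 1
            else:
                break
        for _ in range(max_extend):
            if b + 1 <= right_lim and p[b + 1] < p_extend:
                b += 1
            else:
                break
        out.append((a, b))
    return [iv for iv in out if iv[1] - iv[0] + 1 <= max_size]


def detect_place_fields(rate_map: RateMap, n_boot: int = 1000,
                        alpha_bin: float = 0.01, p_extend: float = 0.30,
                        merge_gap: int = 5, min_size: int = 4,
                        max_size: int = 45, stability_r: float = 0.60,
                        stability_frac: float = 0.40,
                        seed=None) -> list:
    """Detect mean place fields of one cell in one direction.

    Returns the validated fields with geometry metrics filled (width,
    out/in ratio, track class) and the primary field flagged.  Lap fields
    and dispersion are added by :func:`detect_lap_fields`.
    """
    if rate_map.per_trial_counts.sum() == 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    grid = rate_map.grid
    p = bootstrap_pvalues(rate_map, n_boot, rng)
    cands = _candidates_from_pvalues(p, grid, alpha_bin, p_extend,
                                     merge_gap, min_size, max_size)
    mean_v = rate_map.mean_rate_vector
    ab = grid.analyzed_bins
    fields = []
    for a, b in cands:
        others = [iv for iv in cands if iv != (a, b)]
        excl = np.zeros(grid.n_bins, bool)
        for oa, ob in others:
            excl[oa:ob + 1] = True
        corr_bins = ab[~excl[ab]]
        n_ok = 0
        mv = mean_v[corr_bins]
        for row in rate_map.per_trial_rate:
            r = _pearson(row[corr_bins], mv)
            if r is not None and r > stability_r:
                n_ok += 1
        if rate_map.n_trials and n_ok / rate_map.n_trials >= stability_frac:
            pk = a + int(np.argmax(mean_v[a:b + 1]))
            fields.append(PlaceField(rate_map.cell_id, rate_map.direction,
                                     a, b, pk, float(mean_v[pk])))
    if fields:
        best = max(fields, key=lambda f: (f.peak_rate, -f.peak_bin))
        best.is_primary = True
        for f in fields:
            f.complete, f.width = field_width(f, mean_v, grid)
            f.out_in_ratio = out_in_ratio(f, mean_v, fields, grid)
            f.track_class = classify_track_position(f, grid)
    return fields


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    """Pearson r, or None when either vector is constant."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return None
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def detect_lap_fields(rate_map: RateMap, mean_fields: list,
                      n_boot: int = 1000, seed=None, **kw) -> list:
    """Per-lap field detection (no stability criterion); fills
    ``lap_fields`` and ``dispersion`` of each mean field in place.

    A lap field is kept iff it overlaps >= 1 bin with the closest mean
    field (closest by center distance).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if not mean_fields:
        return mean_fields
    for f in mean_fields:
        f.lap_fields = []
    grid = rate_map.grid
    for row in range(rate_map.n_trials):
        if rate_map.per_trial_counts[row].sum() == 0:
            continue
        v = rate_map.per_trial_rate[row]
        p = bootstrap_pvalues(rate_map, n_boot, rng, observed=v,
                              trial_rows=np.array([row]))
        for a, b in _candidates_from_pvalues(p, grid, **kw):
            pk = a + int(np.argmax(v[a:b + 1]))
            closest = min(mean_fields,
                          key=lambda f: abs(f.peak_bin - pk))
            if a <= closest.stop and b >= closest.start:  # >=1 bin overlap
                closest.lap_fields.append(
                    LapField(row, a, b, pk, float(v[pk])))
    for f in mean_fields:
        f.dispersion = field_dispersion(f, grid)
    return mean_fields


# ---------------------------------------------------------------------------
# per-field metrics
# ---------------------------------------------------------------------------

def field_width(f: PlaceField, mean_rate_vector: np.ndarray,
                grid: BinGrid) -> tuple[bool, float | None]:
    """(complete?, width in cm).

    A field is complete when the rate rises above ``min + 0.3*(max - min)``
    and later falls back below it within the analyzed region; the width is
    the distance between the two (linearly interpolated) crossings.
    """
    ab = grid.analyzed_bins
    v = mean_rate_vector
    vmax = v[f.peak_bin]
    vmin = float(v[ab].min())
    if vmax <= vmin:
        warnings.warn(f"flat field (cell {f.cell_id}); width undefined")
        return False, None
    thr = vmin + 0.3 * (vmax - vmin)
    lo, hi = ab[0], ab[-1]
    c = grid.centers

    def cross(from_bin, step):
        i = from_bin
        while lo <= i + step <= hi:
            if v[i + step] < thr:
                j = i + step
                frac = (v[i] - thr) / (v[i] - v[j])
                return c[i] + frac * (c[j] - c[i])
            i += step
        return None

    left = cross(f.peak_bin, -1)
    right = cross(f.peak_bin, +1)
    if left is None or right is None:
        return False, None
    return True, float(right - left)


def field_dispersion(f: PlaceField, grid: BinGrid) -> float | None:
    """RMS distance (cm) of lap-field centers around the mean-field center."""
    if not f.lap_fields:
        return None
    ci = np.array([lf.center_bin for lf in f.lap_fields], float)
    return float(grid.bin_size * np.sqrt(np.mean((f.peak_bin - ci) ** 2)))


def out_in_ratio(f: PlaceField, mean_rate_vector: np.ndarray,
                 all_fields: list, grid: BinGrid) -> float | None:
    """Mean rate outside all detected fields / mean rate inside this field."""
    excl = np.zeros(grid.n_bins, bool)
    for g in all_fields:
        excl[g.start:g.stop + 1] = True
    ab = grid.analyzed_bins
    outside = ab[~excl[ab]]
    inside = f.bins
    mi = mean_rate_vector[inside].mean()
    if mi == 0:
        return None
    mo = mean_rate_vector[outside].mean() if len(outside) else 0.0
    return float(mo / mi)


def classify_track_position(f: PlaceField, grid: BinGrid) -> str:
    """End-track iff the peak sits on the first or last analyzed bin."""
    ab = grid.analyzed_bins
    return "EndTrack" if f.peak_bin in (ab[0], ab[-1]) else "OnTrack"


def classify_object_responsive(fields_by_direction: dict,
                               manifest: SessionManifest,
                               grid: BinGrid) -> bool:
    """Object-responsive: bidirectional place cell with a field peaking in
    the same individual object zone in both running directions."""
    if not manifest.individual_object_zones:
        raise ValueError("manifest has no individual object zones")
    ff = fields_by_direction.get("forth", [])
    fb = fields_by_direction.get("back", [])
    if not ff or not fb:
        return False
    for name, a, b in manifest.individual_object_zones:
        zb = set(grid.zone_bins(a, b).tolist())
        if any(f.peak_bin in zb for f in ff) and \
           any(f.peak_bin in zb for f in fb):
            return True
    return False
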