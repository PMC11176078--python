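"""Bout segmentation, tail-cycle extraction and per-bout kinematics.

Works on head trajectories sampled uniformly (nominally 290 Hz).  Bouts are
velocity-threshold episodes with hysteresis; tail half-cycles are read out
against the lateral motion of the subpixel head centroid, which is
synchronized with the tail and gives a cleaner cycle reference at low
magnification; per-bout parameters include the L/R balance

    |sum(right peak angles) - sum(left peak angles)|
    ------------------------------------------------
     sum(right peak angles) + sum(left peak angles)

(0 for symmetric undulation, 1 when every excursion is to one side), and a
multiplicative model ``distance = k * freq^a * n^b * angle^c`` is fitted to
forward swims to validate the tail-parameter extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats
from scipy.ndimage import uniform_filter1d

__all__ = [
    "BoutDetectionParams",
    "DistanceModel",
    "QCResult",
    "detect_bouts",
    "bout_lateral_displacement",
    "extract_tail_cycles",
    "compute_bout_parameters",
    "analyze_session",
    "filter_central",
    "filter_forward_swims",
    "session_qc",
    "fit_distance_model",
]

BOUT_COLUMNS = ["onset_s", "offset_s", "x0_mm", "y0_mm", "x1_mm", "y1_mm",
                "distance_mm", "duration_s", "interval_s",
                "heading_change_deg", "epoch"]


@dataclass
class BoutDetectionParams:
    """Thresholds for velocity-based bout segmentation.

    The onset/offset pair implements hysteresis; all time constants are in
    milliseconds.  Defaults are standard larval-bout scales.
    """

    onset_mm_s: float = 4.0
    offset_mm_s: float = 2.0
    smooth_ms: float = 15.0
    merge_gap_ms: float = 50.0
    min_duration_ms: float = 30.0


def _smoothed_speed(xy: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    step = np.linalg.norm(np.diff(xy, axis=0), axis=1) * fs
    speed = np.concatenate([step[:1], step])      # align to frame index
    win = max(int(round(smooth_ms * fs / 1000.0)), 1)
    return uniform_filter1d(speed, size=win)


def detect_bouts(xy_mm: np.ndarray, fs_hz: float,
                 params: BoutDetectionParams | None = None,
                 config=None, t_s: np.ndarray | None = None) -> pd.DataFrame:
    """Segment swim bouts from a uniformly sampled head trajectory.

    Parameters
    ----------
    xy_mm : (n, 2) array
    fs_hz : float
        Sampling rate.  If ``t_s`` is given it must be uniform at this rate.
    params : BoutDetectionParams
    config : SessionConfig, optional
        When given, each bout is labeled with the task epoch ('spont'/'omr')
        containing its onset; otherwise epoch is ''.

    Returns
    -------
    DataFrame with columns ``onset_s, offset_s, x0_mm, y0_mm, x1_mm, y1_mm,
    distance_mm, duration_s, interval_s, heading_change_deg, epoch``.
    ``interval_s`` is the time since the previous bout's offset (NaN for the
    first bout).  ``distance_mm`` is the path length within the bout.
    """
    params = params or BoutDetectionParams()
    xy = np.asarray(xy_mm, dtype=float)
    if t_s is not None:
        dt = np.diff(np.asarray(t_s, dtype=float))
        if dt.size and (np.abs(dt - 1.0 / fs_hz) > 1e-6 / fs_hz + 1e-9).any():
            raise ValueError("timestamps are not uniform at the stated rate")
    speed = _smoothed_speed(xy, fs_hz, params.smooth_ms)

    runs = _hysteresis_runs(speed, params.onset_mm_s, params.offset_mm_s)
    runs = _merge_runs(runs, int(round(params.merge_gap_ms * fs_hz / 1000.0)))
    min_len = int(round(params.min_duration_ms * fs_hz / 1000.0))
    runs = [(i0, i1) for i0, i1 in runs if i1 - i0 >= min_len]

    rows = []
    prev_off = np.nan
    for i0, i1 in runs:
        seg = xy[i0:i1 + 1]
        onset, offset = i0 / fs_hz, i1 / fs_hz
        rows.append(dict(
            onset_s=onset, offset_s=offset,
            x0_mm=seg[0, 0], y0_mm=seg[0, 1],
            x1_mm=seg[-1, 0], y1_mm=seg[-1, 1],
            distance_mm=float(np.linalg.norm(np.diff(seg, axis=0),
                                             axis=1).sum()),
            duration_s=offset - onset,
            interval_s=onset - prev_off if np.isfinite(prev_off) else np.nan,
            heading_change_deg=_heading_change(seg, fs_hz),
            epoch=config.epoch_at(onset) if config is not None else "",
        ))
        prev_off = offset
    return pd.DataFrame(rows, columns=BOUT_COLUMNS)


def _hysteresis_runs(speed, onset_thr, offset_thr):
    above = speed >= onset_thr
    if not above.any():
        return []
    low = speed < offset_thr
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(np.flatnonzero(np.diff(above.astype(int)) == 1) + 1)
    ends = list(np.flatnonzero(np.diff(above.astype(int)) == -1))
    del edges
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(speed) - 1)
    runs = []
    for s, e in zip(starts, ends):
        while s > 0 and not low[s - 1]:
            s -= 1
        while e < len(speed) - 1 and not low[e + 1]:
            e += 1
        runs.append((s, e))
    # hysteresis extension can make consecutive runs touch or overlap
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return merged


def _merge_runs(runs, gap_frames):
    if not runs:
        return runs
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= gap_frames:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _heading_change(seg, fs):
    # net displacement over each half of the bout; robust to the lateral
    # head oscillation that contaminates frame-scale direction estimates
    mid = len(seg) // 2
    d0 = seg[mid] - seg[0]
    d1 = seg[-1] - seg[mid]
    if np.linalg.norm(d0) == 0 or np.linalg.norm(d1) == 0:
        return 0.0
    h0 = np.degrees(np.arctan2(d0[1], d0[0]))
    h1 = np.degrees(np.arctan2(d1[1], d1[0]))
    return float((h1 - h0 + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# tail cycles
# ---------------------------------------------------------------------------

def bout_lateral_displacement(xy_mm: np.ndarray, i0: int, i1: int
                              ) -> np.ndarray:
    """Head displacement perpendicular to the bout's travel direction.

    Projects positions within [i0, i1] onto the normal of the net start->end
    direction and removes the linear trend, isolating the oscillatory lateral
    component used as the tail-cycle reference.
    """
    seg = np.asarray(xy_mm, dtype=float)[i0:i1 + 1]
    d = seg[-1] - seg[0]
    n = np.linalg.norm(d)
    if n == 0:
        u = seg - seg.mean(axis=0)
        _, _, vt = np.linalg.svd(u, full_matrices=False)
        d = vt[0]
    else:
        d = d / n
    normal = np.array([-d[1], d[0]])
    lat = (seg - seg[0]) @ normal
    x = np.arange(len(lat))
    if len(lat) > 1:
        coef = np.polyfit(x, lat, 1)
        lat = lat - np.polyval(coef, x)
    return lat


def extract_tail_cycles(onset_s: float, offset_s: float, fs_hz: float,
                        lateral_mm: np.ndarray, tail_angle_deg: np.ndarray,
                        min_prominence_mm: float = 0.005) -> pd.DataFrame:
    """One row per tail half-cycle: ``time_s, peak_angle_deg, side``.

    Half-cycles are delimited by alternating signed peaks of the lateral
    head displacement (series aligned to the full session time base); within
    each half-cycle window the maximum |tail angle| and its sign give the
    peak angle and the side.  Raises ValueError when the lateral trace is
    flat over the bout (tracking failure).
    """
    i0 = int(round(onset_s * fs_hz))
    i1 = int(round(offset_s * fs_hz))
    lat = np.asarray(lateral_mm, dtype=float)[i0:i1 + 1]
    tail = np.asarray(tail_angle_deg, dtype=float)[i0:i1 + 1]
    if lat.size == 0 or np.ptp(lat) < 1e-12:
        raise ValueError("lateral displacement is flat over the bout; "
                         "cannot reference tail cycles")

    pk_hi, _ = signal.find_peaks(lat, prominence=min_prominence_mm)
    pk_lo, _ = signal.find_peaks(-lat, prominence=min_prominence_mm)
    peaks = np.sort(np.concatenate([pk_hi, pk_lo]))
    if peaks.size == 0:
        return pd.DataFrame(columns=["time_s", "peak_angle_deg", "side"])

    # enforce alternation: of consecutive same-sign peaks keep the larger
    keep = []
    for p in peaks:
        if keep and np.sign(lat[p]) == np.sign(lat[keep[-1]]):
            if abs(lat[p]) > abs(lat[keep[-1]]):
                keep[-1] = p
        else:
            keep.append(p)
    peaks = np.asarray(keep)

    # one half-cycle window per lateral peak: midpoint to midpoint
    bounds = np.concatenate([[0], (peaks[:-1] + peaks[1:]) // 2 + 1,
                             [len(lat)]])
    rows = []
    for k in range(len(peaks)):
        w0, w1 = bounds[k], bounds[k + 1]
        j = w0 + int(np.argmax(np.abs(tail[w0:w1])))
        rows.append(dict(time_s=(i0 + j) / fs_hz,
                         peak_angle_deg=abs(tail[j]),
                         side="right" if tail[j] >= 0 else "left"))
    return pd.DataFrame(rows)


def compute_bout_parameters(cycles: pd.DataFrame,
                            interval_s: float = np.nan) -> dict:
    """Per-bout kinematic parameters from its tail half-cycles.

    ``n_motions`` counts half-cycles; the reported tail frequency is the
    half-cycle rate divided by two (full tail-beat convention), defined for
    two or more half-cycles and NaN otherwise; ``lr_balance`` follows the
    summed-peak-angle formula and lies in [0, 1].
    """
    if len(cycles) == 0:
        raise ValueError("bout has no tail cycles")
    n = len(cycles)
    ang = cycles["peak_angle_deg"].to_numpy(dtype=float)
    s_r = ang[cycles["side"].to_numpy() == "right"].sum()
    s_l = ang[cycles["side"].to_numpy() == "left"].sum()
    lr = abs(s_r - s_l) / (s_r + s_l) if (s_r + s_l) > 0 else np.nan
    if n >= 2:
        span = cycles["time_s"].iloc[-1] - cycles["time_s"].iloc[0]
        freq = 0.5 * (n - 1) / span if span > 0 else np.nan
    else:
        freq = np.nan
    return dict(tail_freq_hz=freq, n_motions=n,
                mean_peak_angle_deg=float(ang.mean()), lr_balance=float(lr),
                interval_s=float(interval_s))


def analyze_session(pose: pd.DataFrame, config,
                    params: BoutDetectionParams | None = None,
                    use_pose_lateral: bool = True) -> pd.DataFrame:
    """Full kinematic pass over a pose table: bouts + per-bout parameters.

    ``use_pose_lateral`` selects the pose table's ``lateral_disp_mm`` column
    as the cycle reference when present; otherwise the lateral component is
    recomputed from the head trajectory per bout.
    """
    fs = config.frame_rate_hz
    xy = pose[["head_x_mm", "head_y_mm"]].to_numpy()
    tail = pose["tail_angle_deg"].to_numpy()
    bouts = detect_bouts(xy, fs, params, config=config)
    have_lat = use_pose_lateral and "lateral_disp_mm" in pose
    lat_full = pose["lateral_disp_mm"].to_numpy() if have_lat else None

    extras = []
    for _, b in bouts.iterrows():
        i0 = int(round(b.onset_s * fs))
        i1 = int(round(b.offset_s * fs))
        if have_lat:
            lat = lat_full
        else:
            lat = np.zeros(len(xy))
            lat[i0:i1 + 1] = bout_lateral_displacement(xy, i0, i1)
        try:
            cyc = extract_tail_cycles(b.onset_s, b.offset_s, fs, lat, tail)
            p = compute_bout_parameters(cyc, b.interval_s) if len(cyc) else \
                dict(tail_freq_hz=np.nan, n_motions=0,
                     mean_peak_angle_deg=np.nan, lr_balance=np.nan,
                     interval_s=b.interval_s)
        except ValueError:
            p = dict(tail_freq_hz=np.nan, n_motions=0,
                     mean_peak_angle_deg=np.nan, lr_balance=np.nan,
                     interval_s=b.interval_s)
        p.pop("interval_s", None)       # already a bout column
        extras.append(p)
    return pd.concat([bouts.reset_index(drop=True),
                      pd.DataFrame(extras)], axis=1)


# ---------------------------------------------------------------------------
# spatial filters & QC
# ---------------------------------------------------------------------------

def filter_central(bouts: pd.DataFrame, arena_diameter_mm: float,
                   center_mm=(0.0, 0.0),
                   radius_mm: float | None = None) -> pd.DataFrame:
    """Keep bouts whose onset lies in the central region of the arena.

    The central radius is 30 mm for large (> 50 mm) arenas and 10 mm for
    small ones, overridable via ``radius_mm``.
    """
    if radius_mm is None:
        radius_mm = 30.0 if arena_diameter_mm > 50.0 else 10.0
    r = np.hypot(bouts["x0_mm"] - center_mm[0], bouts["y0_mm"] - center_mm[1])
    return bouts[r <= radius_mm].reset_index(drop=True)


def filter_forward_swims(bouts: pd.DataFrame, arena_diameter_mm: float = 90.0,
                         center_mm=(0.0, 0.0),
                         max_heading_change_deg: float = 30.0) -> pd.DataFrame:
    """Central-region bouts with |heading change| below 30 degrees."""
    central = filter_central(bouts, arena_diameter_mm, center_mm)
    keep = central["heading_change_deg"].abs() < max_heading_change_deg
    return central[keep].reset_index(drop=True)


@dataclass
class QCResult:
    passed: bool
    n_omr_bouts: int
    rate_per_min: float


def session_qc(bouts: pd.DataFrame, config, min_omr_bouts: int = 50
               ) -> QCResult:
    """Exclusion rule: fail sessions with fewer than 50 OMR-epoch bouts.

    Also reports the equivalent per-minute rate over the total OMR time
    (e.g. 50 bouts over the 7.5 OMR minutes of a default 15-min session is
    6.7 swims/min).
    """
    n_omr = int((bouts["epoch"] == "omr").sum())
    omr_frac = config.epoch_omr_s / config.cycle_s
    omr_minutes = config.session_duration_s * omr_frac / 60.0
    rate = n_omr / omr_minutes if omr_minutes > 0 else np.nan
    return QCResult(passed=n_omr >= min_omr_bouts, n_omr_bouts=n_omr,
                    rate_per_min=rate)


# ---------------------------------------------------------------------------
# multiplicative distance model
# ---------------------------------------------------------------------------

@dataclass
class DistanceModel:
    """distance = k * freq^a * n_motions^b * angle^c (mm; angle in degrees)."""

    k: float
    exp_freq: float
    exp_count: float
    exp_angle: float
    fit_quality: float       # Pearson r, predicted vs observed

    def predict(self, freq, n_motions, angle):
        return self.k * np.asarray(freq, float) ** self.exp_freq \
            * np.asarray(n_motions, float) ** self.exp_count \
            * np.asarray(angle, float) ** self.exp_angle


def fit_distance_model(bouts: pd.DataFrame, exponent_bounds=(0.0, 3.0),
                       log_domain: bool = False) -> DistanceModel:
    """Fit the multiplicative distance model with bounded L-BFGS-B.

    Requires >= 20 bouts with positive frequency, count, angle and distance;
    any parameter that is constant across bouts makes its exponent
    unidentifiable and raises ValueError.  The objective is the squared
    error on raw distances (``log_domain=True`` switches to log distances).
    The fit is initialized from the log-linear least-squares solution.
    """
    cols = ["tail_freq_hz", "n_motions", "mean_peak_angle_deg", "distance_mm"]
    data = bouts[cols].dropna()
    data = data[(data > 0).all(axis=1)]
    if len(data) < 20:
        raise ValueError(f"need >= 20 usable bouts, got {len(data)}")
    f, m, ang, d = (data[c].to_numpy(dtype=float) for c in cols)
    for name, v in (("frequency", f), ("count", m), ("angle", ang)):
        if np.ptp(v) < 1e-12 * max(abs(v).max(), 1.0):
            raise ValueError(f"{name} is constant across bouts; "
                             "exponent unidentifiable")

    # log-linear initialization, clipped into bounds
    X = np.column_stack([np.ones_like(f), np.log(f), np.log(m), np.log(ang)])
    beta, *_ = np.linalg.lstsq(X, np.log(d), rcond=None)
    lo, hi = exponent_bounds
    x0 = np.array([beta[0], *np.clip(beta[1:], lo, hi)])

    def objective(p):
        logk, a, b, c = p
        pred = np.exp(logk) * f ** a * m ** b * ang ** c
        if log_domain:
            return np.sum((np.log(pred) - np.log(d)) ** 2)
        return np.sum((pred - d) ** 2)

    res = optimize.minimize(objective, x0, method="L-BFGS-B",
                            bounds=[(None, None), (lo, hi), (lo, hi),
                                    (lo, hi)])
    logk, a, b, c = res.x
    model = DistanceModel(k=float(np.exp(logk)), exp_freq=float(a),
                          exp_count=float(b), exp_angle=float(c),
                          fit_quality=np.nan)
    r, _ = stats.pearsonr(model.predict(f, m, ang), d)
    model.fit_quality = float(r)
    return model
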