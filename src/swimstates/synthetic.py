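"""Synthetic session generator for larval-zebrafish swim and raphe-activity data.

Real recordings behind this kind of analysis are single-fish videos (8-bit,
83 μm/px, 290 Hz) of a dark fish on a light arena, plus light-sheet
fluorescence traces from dorsal-raphe neurons sampled at 1 Hz during an
alternating 10-s spontaneous / 10-s optomotor-response (OMR) task.  This
module emulates both with known ground truth so the tracking, kinematics,
state-embedding and neural stages can be tested end to end:

* swim bouts are drawn from latent behavioral states (spontaneous scooting,
  rapid OMR scooting, turning/escape) with state-specific tail-beat
  frequency, peak tail angle, number of tail half-cycles, left/right
  asymmetry, inter-bout interval and bout speed;
* experimental conditions (control, stress, psilocybin-like, ...) reweight
  the state mixture per task epoch and apply multiplicative shifts to
  per-state kinematic parameters;
* raphe traces contain two complementary neuron classes active in opposite
  task epochs, multiplicative slow baseline drift and additive noise.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq

__all__ = [
    "Discretized",
    "Mixture",
    "truncated_normal",
    "LatentStateSpec",
    "SessionConfig",
    "ConditionEffect",
    "NeuralSimConfig",
    "GaussianFishTemplate",
    "default_states",
    "condition",
    "simulate_session",
    "simulate_distance_bouts",
    "render_frames",
    "simulate_drn_activity",
    "POSE_POINT_NAMES",
]


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

def truncated_normal(mean: float, sd: float, low: float = 0.0,
                     high: float = np.inf):
    """Normal(mean, sd) truncated to [low, high] as a frozen scipy dist."""
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


class Discretized:
    """Integer-valued wrapper: rounds draws from ``dist`` and floors at ``low``."""

    def __init__(self, dist, low: int = 1):
        self.dist = dist
        self.low = low

    def rvs(self, size=None, random_state=None):
        x = np.rint(self.dist.rvs(size=size, random_state=random_state))
        return np.maximum(x, self.low).astype(int)

    def mean(self):
        return float(self.dist.mean())


class Mixture:
    """Finite mixture of frozen distributions (used for bimodal turn angles)."""

    def __init__(self, components, weights):
        weights = np.asarray(weights, dtype=float)
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        self.components = list(components)
        self.weights = weights

    def rvs(self, size=None, random_state=None):
        rng = np.random.default_rng(random_state)
        n = int(np.prod(size)) if size is not None else 1
        which = rng.choice(len(self.components), size=n, p=self.weights)
        out = np.empty(n)
        for k, comp in enumerate(self.components):
            m = which == k
            if m.any():
                out[m] = comp.rvs(size=int(m.sum()), random_state=rng)
        if size is None:
            return float(out[0])
        return out.reshape(size)

    def mean(self):
        return float(sum(w * c.mean() for w, c in
                         zip(self.weights, self.components)))


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class LatentStateSpec:
    """One latent behavioral state and its kinematic parameter distributions.

    All distributions must have nonnegative support; ``n_motions`` counts tail
    half-cycles (one lateral excursion each) and is integer-valued ≥ 1;
    ``lr_asymmetry`` is the target left/right balance in [0, 1].
    """

    name: str
    tail_freq_hz: object          # full tail-beat cycles per second
    peak_angle_deg: object        # per-half-cycle peak tail angle
    n_motions: object             # number of half-cycles, integer >= 1
    lr_asymmetry: object          # target L/R balance in [0, 1]
    interbout_interval_s: object  # rest before the bout
    bout_speed_mm_s: object       # mean forward speed over the bout


@dataclass
class SessionConfig:
    """Arena / acquisition geometry and task schedule."""

    arena_diameter_mm: float = 90.0
    pixel_size_um: float = 83.0
    frame_rate_hz: float = 290.0
    epoch_spont_s: float = 10.0
    epoch_omr_s: float = 10.0
    session_duration_s: float = 900.0
    seed: int = 0

    def __post_init__(self):
        if min(self.epoch_spont_s, self.epoch_omr_s,
               self.session_duration_s) <= 0:
            raise ValueError("epoch and session durations must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.session_duration_s * self.frame_rate_hz))

    @property
    def cycle_s(self) -> float:
        return self.epoch_spont_s + self.epoch_omr_s

    def epoch_at(self, t_s):
        """'spont' or 'omr' for time(s) ``t_s`` (spontaneous epoch first)."""
        phase = np.asarray(t_s, dtype=float) % self.cycle_s
        out = np.where(phase < self.epoch_spont_s, "spont", "omr")
        return out if out.ndim else str(out)


@dataclass
class ConditionEffect:
    """Treatment/stress condition: per-epoch state mixtures + parameter shifts.

    ``parameter_shifts`` maps state name -> {'tail_freq_hz'|'peak_angle_deg'|
    'interbout_interval_s': positive multiplier}.
    """

    name: str
    state_mixture_spont: dict
    state_mixture_omr: dict
    parameter_shifts: dict = field(default_factory=dict)

    def __post_init__(self):
        for mix in (self.state_mixture_spont, self.state_mixture_omr):
            if not np.isclose(sum(mix.values()), 1.0):
                raise ValueError(f"{self.name}: state mixture must sum to 1")
        for shifts in self.parameter_shifts.values():
            if any(v <= 0 for v in shifts.values()):
                raise ValueError("parameter shifts must be positive")


@dataclass
class NeuralSimConfig:
    """Raphe population simulator settings (1 Hz sampling)."""

    n_class1: int = 40            # spontaneous-epoch-active neurons
    n_class2: int = 40            # OMR-epoch-active neurons
    n_null: int = 120
    n_trials: int = 20
    response_amplitude: float = 0.5   # ΔF/F units added during preferred epoch
    baseline_drift: float = 0.05      # multiplicative drift amplitude
    drift_timescale_s: float = 60.0
    noise_sd: float = 0.05            # additive noise, ΔF/F units
    seed: int = 0

    def __post_init__(self):
        if min(self.n_class1, self.n_class2, self.n_null) < 0:
            raise ValueError("neuron counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# default states & conditions
# ---------------------------------------------------------------------------

def default_states() -> list[LatentStateSpec]:
    """The three default latent states.

    Parameters are configurable defaults chosen to give the qualitative
    geometry of the known swim-type repertoire (short scoots, rapid long
    scoots, turning/escape with one-sided tails); they are not measured
    constants.  Routine turns and C-turns are merged into a single
    ``turn_escape`` state with a bimodal angle distribution.
    """
    return [
        LatentStateSpec(
            name="spont_scoot",
            tail_freq_hz=truncated_normal(22.0, 3.0, low=5.0),
            peak_angle_deg=truncated_normal(15.0, 4.0, low=2.0),
            n_motions=Discretized(truncated_normal(4.0, 1.0, low=2.0), low=2),
            lr_asymmetry=truncated_normal(0.15, 0.10, low=0.0, high=1.0),
            interbout_interval_s=truncated_normal(1.5, 0.5, low=0.25),
            bout_speed_mm_s=truncated_normal(15.0, 4.0, low=4.0),
        ),
        LatentStateSpec(
            name="omr_scoot",
            tail_freq_hz=truncated_normal(32.0, 3.0, low=5.0),
            peak_angle_deg=truncated_normal(18.0, 4.0, low=2.0),
            n_motions=Discretized(truncated_normal(10.0, 2.0, low=4.0), low=4),
            lr_asymmetry=truncated_normal(0.10, 0.07, low=0.0, high=1.0),
            interbout_interval_s=truncated_normal(0.6, 0.2, low=0.2),
            bout_speed_mm_s=truncated_normal(35.0, 6.0, low=8.0),
        ),
        LatentStateSpec(
            name="turn_escape",
            tail_freq_hz=truncated_normal(28.0, 3.0, low=5.0),
            peak_angle_deg=Mixture(
                [truncated_normal(35.0, 6.0, low=5.0),    # routine turns
                 truncated_normal(60.0, 8.0, low=20.0)],  # C-turn-like
                [0.6, 0.4]),
            n_motions=Discretized(truncated_normal(5.0, 1.5, low=2.0), low=2),
            lr_asymmetry=truncated_normal(0.80, 0.10, low=0.0, high=1.0),
            interbout_interval_s=truncated_normal(1.2, 0.4, low=0.2),
            bout_speed_mm_s=truncated_normal(25.0, 6.0, low=5.0),
        ),
    ]


_CONDITIONS = {
    "control": ConditionEffect(
        "control",
        state_mixture_spont={"spont_scoot": 0.75, "omr_scoot": 0.05,
                             "turn_escape": 0.20},
        state_mixture_omr={"spont_scoot": 0.15, "omr_scoot": 0.70,
                           "turn_escape": 0.15},
    ),
    # acute stress: irregular one-sided swims, longer rests, less distance
    "stress": ConditionEffect(
        "stress",
        state_mixture_spont={"spont_scoot": 0.40, "omr_scoot": 0.05,
                             "turn_escape": 0.55},
        state_mixture_omr={"spont_scoot": 0.10, "omr_scoot": 0.50,
                           "turn_escape": 0.40},
        parameter_shifts={"spont_scoot": {"interbout_interval_s": 1.8},
                          "turn_escape": {"interbout_interval_s": 1.8}},
    ),
    # psilocybin-like stimulatory shift toward rapid scooting when unstimulated
    "drug": ConditionEffect(
        "drug",
        state_mixture_spont={"spont_scoot": 0.45, "omr_scoot": 0.35,
                             "turn_escape": 0.20},
        state_mixture_omr={"spont_scoot": 0.15, "omr_scoot": 0.70,
                           "turn_escape": 0.15},
        parameter_shifts={"spont_scoot": {"tail_freq_hz": 1.10,
                                          "interbout_interval_s": 0.75}},
    ),
    # drug pretreatment prevents most of the stress shift
    "drug_stress": ConditionEffect(
        "drug_stress",
        state_mixture_spont={"spont_scoot": 0.62, "omr_scoot": 0.08,
                             "turn_escape": 0.30},
        state_mixture_omr={"spont_scoot": 0.12, "omr_scoot": 0.65,
                           "turn_escape": 0.23},
        parameter_shifts={"spont_scoot": {"interbout_interval_s": 1.25},
                          "turn_escape": {"interbout_interval_s": 1.25}},
    ),
}


def condition(name: str) -> ConditionEffect:
    """Return a copy of a built-in condition preset."""
    try:
        base = _CONDITIONS[name]
    except KeyError:
        raise KeyError(f"unknown condition {name!r}; "
                       f"choose from {sorted(_CONDITIONS)}") from None
    return replace(base)


# ---------------------------------------------------------------------------
# tail geometry: parabola with a prescribed angle at 1 mm arc length
# ---------------------------------------------------------------------------

POSE_POINT_NAMES = ("eye_l", "eye_r", "nostril", "trunk",
                    "tail1", "tail2", "tail3", "tail4", "tail5", "tail6")
_TAIL_ARC_MM = np.arange(1, 7) * 0.5   # tail1..tail6 arc positions from trunk


def _parabola_arclen(x, q):
    """Arc length of y = q x^2 from 0 to x (q > 0)."""
    u = 2.0 * q * x
    return 0.5 * x * np.sqrt(1.0 + u * u) + np.arcsinh(u) / (4.0 * q)


class _TailCurveTable:
    """Lookup tables mapping tail angle (deg, at 1 mm arc) <-> curvature q.

    Solving the arc-length equation per frame is too slow for 10^5-frame
    sessions, so we tabulate once over a dense q grid and interpolate.
    """

    def __init__(self, q_max=6.0, n_grid=600, eval_dist_mm=1.0):
        qs = np.concatenate([[0.0], np.geomspace(1e-4, q_max, n_grid)])
        x_eval = np.empty_like(qs)
        x_arcs = np.empty((qs.size, _TAIL_ARC_MM.size))
        x_eval[0] = eval_dist_mm
        x_arcs[0] = _TAIL_ARC_MM
        for i, q in enumerate(qs[1:], start=1):
            x_eval[i] = brentq(lambda x: _parabola_arclen(x, q) - eval_dist_mm,
                               0.0, eval_dist_mm)
            for j, L in enumerate(_TAIL_ARC_MM):
                x_arcs[i, j] = brentq(lambda x: _parabola_arclen(x, q) - L,
                                      0.0, L)
        self.qs = qs
        self.theta_deg = np.degrees(np.arctan(2.0 * qs * x_eval))
        self.x_arcs = x_arcs

    def q_from_angle(self, theta_deg):
        """Signed curvature for signed tail angles (degrees)."""
        mag = np.interp(np.abs(theta_deg), self.theta_deg, self.qs)
        return np.sign(theta_deg) * mag

    def tail_points_body(self, theta_deg):
        """Body-frame (x, y) of the six tail points for angle array (n,).

        Body frame: x along nostril->trunk (tailward), y toward the fish's
        right; trunk at the origin.  Returns arrays of shape (n, 6).
        """
        theta_deg = np.asarray(theta_deg, dtype=float)
        q = self.q_from_angle(theta_deg)
        qa = np.abs(q)
        xs = np.empty(theta_deg.shape + (_TAIL_ARC_MM.size,))
        for j in range(_TAIL_ARC_MM.size):
            xs[..., j] = np.interp(qa, self.qs, self.x_arcs[:, j])
        ys = q[..., None] * xs ** 2
        return xs, ys


_tail_table_cache: dict[float, _TailCurveTable] = {}


def _tail_table(eval_dist_mm: float = 1.0) -> _TailCurveTable:
    if eval_dist_mm not in _tail_table_cache:
        _tail_table_cache[eval_dist_mm] = _TailCurveTable(
            eval_dist_mm=eval_dist_mm)
    return _tail_table_cache[eval_dist_mm]


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

# body geometry relative to the head centroid, along the heading (mm)
_NOSTRIL_AHEAD_MM = 0.5
_EYE_AHEAD_MM = 0.2
_EYE_ASIDE_MM = 0.25
_TRUNK_BEHIND_MM = 1.0
# lateral head displacement per degree of tail angle, in antiphase (mm/deg)
_LATERAL_GAIN_MM_PER_DEG = 0.003
# heading change per (asymmetry x mean peak angle), degrees/degree
_TURN_GAIN = 1.2
# displacement per (Hz x half-cycle x deg^0.4): couples bout distance to the
# tail parameters via the multiplicative law the kinematic validation fits
_DISTANCE_GAIN_MM = 0.004
_DISTANCE_ANGLE_POWER = 0.4


def _draw(dist, rng, size=None):
    return dist.rvs(size=size, random_state=rng)


def simulate_session(config: SessionConfig,
                     cond: ConditionEffect,
                     states: list[LatentStateSpec] | None = None,
                     position_noise_mm: float = 0.0,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one free-swimming session.

    Each bout is a damped tail oscillation at its drawn beat frequency with
    per-half-cycle peak angles, an antiphase lateral head oscillation (the
    cycle reference used downstream), and forward displacement consistent
    with the drawn bout speed.  Latent states are drawn per bout from the
    condition's epoch-specific mixture.

    Parameters
    ----------
    config : SessionConfig
    cond : ConditionEffect
    states : list of LatentStateSpec, optional
        Defaults to :func:`default_states`.
    position_noise_mm : float
        Optional white positional jitter added to the head trajectory.

    Returns
    -------
    pose : DataFrame
        One row per frame: ``frame, t_s, head_x_mm, head_y_mm``, the ten
        body points (``<name>_x_mm / _y_mm``), ``tail_angle_deg``,
        ``lateral_disp_mm``, ``heading_deg`` and ``epoch``.  Coordinates are
        mm with the arena center at the origin, x rightward, y downward.
    truth : DataFrame
        One row per bout with the generating state and the true kinematic
        parameters (onset/offset, frequency, half-cycle count, mean peak
        angle, exact L/R balance of the emitted peaks, interval, distance,
        heading change).
    """
    if states is None:
        states = default_states()
    if not states:
        raise ValueError("state list is empty")
    state_by_name = {s.name: s for s in states}
    for mix in (cond.state_mixture_spont, cond.state_mixture_omr):
        missing = set(mix) - set(state_by_name)
        if missing:
            raise ValueError(f"mixture references unknown states: {missing}")

    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    fs = config.frame_rate_hz
    t = np.arange(n) / fs

    tail = np.zeros(n)
    lateral = np.zeros(n)
    heading = np.full(n, np.nan)
    x = np.zeros(n)
    y = np.zeros(n)

    r_max = 0.45 * config.arena_diameter_mm
    pos = rng.uniform(-0.2, 0.2, size=2) * config.arena_diameter_mm / 2
    phi = rng.uniform(0.0, 360.0)

    mixtures = {"spont": cond.state_mixture_spont,
                "omr": cond.state_mixture_omr}
    records = []
    cur = 0.0          # current time (s), end of previous bout
    prev_offset = np.nan
    i_prev = 0

    while True:
        epoch_guess = config.epoch_at(cur)
        mix = mixtures[epoch_guess]
        names = sorted(mix)
        state = state_by_name[rng.choice(names, p=[mix[k] for k in names])]
        shifts = cond.parameter_shifts.get(state.name, {})

        interval = float(_draw(state.interbout_interval_s, rng)) * \
            shifts.get("interbout_interval_s", 1.0)
        onset = cur + interval
        freq = float(_draw(state.tail_freq_hz, rng)) * \
            shifts.get("tail_freq_hz", 1.0)
        angle = float(_draw(state.peak_angle_deg, rng)) * \
            shifts.get("peak_angle_deg", 1.0)
        n_half = int(_draw(state.n_motions, rng))
        asym = float(np.clip(_draw(state.lr_asymmetry, rng), 0.0, 1.0))
        # drawn speed sets the bout's relative vigor; the displacement itself
        # follows the multiplicative tail-parameter law
        vigor = float(_draw(state.bout_speed_mm_s, rng)) / \
            state.bout_speed_mm_s.mean()
        duration = n_half / (2.0 * freq)
        if onset + duration >= config.session_duration_s:
            break

        # containment: steer toward center when near the wall
        if np.hypot(*pos) > 0.75 * r_max:
            phi = np.degrees(np.arctan2(-pos[1], -pos[0])) + rng.normal(0, 15)

        # per-half-cycle peaks: dominant side scaled up to hit the target
        # L/R balance, mild exponential decay, renormalized to mean `angle`
        side0 = rng.choice([1, -1])          # sign of the first half-cycle
        dom = rng.choice([1, -1])            # dominant side
        k = np.arange(n_half)
        sides = side0 * (-1) ** k
        scale = np.where(sides == dom, 1.0 + asym, 1.0 - asym)
        decay = np.exp(-k / max(n_half, 2))
        peaks = angle * scale * decay / np.mean(scale * decay)

        s_r = peaks[sides > 0].sum()
        s_l = peaks[sides < 0].sum()
        lr_true = abs(s_r - s_l) / (s_r + s_l)
        dheading = -dom * _TURN_GAIN * asym * np.mean(peaks)
        target_dist = _DISTANCE_GAIN_MM * freq * n_half * \
            np.mean(peaks) ** _DISTANCE_ANGLE_POWER * vigor
        speed = target_dist / duration          # mean speed over the bout

        i0 = int(np.ceil(onset * fs))
        i1 = min(int(np.ceil((onset + duration) * fs)), n)
        tau = t[i0:i1] - onset
        half_idx = np.minimum((2.0 * freq * tau).astype(int), n_half - 1)
        osc = np.abs(np.sin(2.0 * np.pi * freq * tau))
        tail_seg = peaks[half_idx] * sides[half_idx] * osc
        tail[i0:i1] = tail_seg
        lateral[i0:i1] = -_LATERAL_GAIN_MM_PER_DEG * tail_seg

        # heading rotates linearly across the bout; speed envelope sin^2
        phi_seg = phi + dheading * np.clip(tau / duration, 0, 1)
        v = 2.0 * speed * np.sin(np.pi * np.clip(tau / duration, 0, 1)) ** 2
        fwd = np.cumsum(v) / fs
        fx = np.cos(np.radians(phi_seg))
        fy = np.sin(np.radians(phi_seg))
        x[i_prev:i0] = pos[0]
        y[i_prev:i0] = pos[1]
        heading[i_prev:i0] = phi
        x[i0:i1] = pos[0] + fwd * fx
        y[i0:i1] = pos[1] + fwd * fy
        heading[i0:i1] = phi_seg

        distance = float(fwd[-1]) if len(fwd) else 0.0
        records.append(dict(
            state=state.name, onset_s=onset, offset_s=onset + duration,
            duration_s=duration, tail_freq_hz=freq, n_motions=n_half,
            mean_peak_angle_deg=float(np.mean(peaks)), lr_balance=lr_true,
            interval_s=(onset - prev_offset) if np.isfinite(prev_offset)
            else np.nan,
            bout_speed_mm_s=speed, distance_mm=distance,
            heading_change_deg=dheading, epoch=config.epoch_at(onset),
            x0_mm=pos[0], y0_mm=pos[1],
        ))
        if len(fwd):
            pos = np.array([x[i1 - 1], y[i1 - 1]])
            phi = phi_seg[-1] % 360.0
        cur = onset + duration
        prev_offset = cur
        i_prev = i1

    x[i_prev:] = pos[0]
    y[i_prev:] = pos[1]
    heading[i_prev:] = phi

    if position_noise_mm > 0:
        x = x + rng.normal(0, position_noise_mm, n)
        y = y + rng.normal(0, position_noise_mm, n)

    pose = _pose_table(t, x, y, heading, tail, lateral, config)
    truth = pd.DataFrame.from_records(records)
    return pose, truth


def _pose_table(t, x, y, heading_deg, tail_deg, lateral_mm,
                config: SessionConfig) -> pd.DataFrame:
    """Assemble the per-frame pose table (ten body points from the skeleton)."""
    phi = np.radians(heading_deg)
    fx, fy = np.cos(phi), np.sin(phi)
    nx, ny = -np.sin(phi), np.cos(phi)       # fish's right in image coords

    head_x = x + lateral_mm * nx
    head_y = y + lateral_mm * ny

    cols = {"frame": np.arange(len(t)), "t_s": t,
            "head_x_mm": head_x, "head_y_mm": head_y}

    def put(name, px, py):
        cols[f"{name}_x_mm"] = px
        cols[f"{name}_y_mm"] = py

    put("eye_l", head_x + _EYE_AHEAD_MM * fx - _EYE_ASIDE_MM * nx,
        head_y + _EYE_AHEAD_MM * fy - _EYE_ASIDE_MM * ny)
    put("eye_r", head_x + _EYE_AHEAD_MM * fx + _EYE_ASIDE_MM * nx,
        head_y + _EYE_AHEAD_MM * fy + _EYE_ASIDE_MM * ny)
    put("nostril", head_x + _NOSTRIL_AHEAD_MM * fx,
        head_y + _NOSTRIL_AHEAD_MM * fy)
    trunk_x = head_x - _TRUNK_BEHIND_MM * fx
    trunk_y = head_y - _TRUNK_BEHIND_MM * fy
    put("trunk", trunk_x, trunk_y)

    # tail points on the parabola with the prescribed angle at 1 mm arc;
    # body x-axis (tailward) is -forward, body y-axis is the fish's right
    xs, ys = _tail_table().tail_points_body(tail_deg)
    for j in range(6):
        px = trunk_x + xs[:, j] * (-fx) + ys[:, j] * nx
        py = trunk_y + xs[:, j] * (-fy) + ys[:, j] * ny
        put(f"tail{j + 1}", px, py)

    cols["tail_angle_deg"] = tail_deg
    cols["lateral_disp_mm"] = lateral_mm
    cols["heading_deg"] = heading_deg
    cols["epoch"] = config.epoch_at(t)
    return pd.DataFrame(cols)


def simulate_distance_bouts(n_bouts: int, k: float = 0.005, a: float = 1.0,
                            b: float = 1.0, c: float = 0.4,
                            noise_sigma: float = 0.0, seed: int = 0
                            ) -> pd.DataFrame:
    """Bouts whose distance follows the multiplicative tail-parameter model.

    distance = k * freq^a * n_motions^b * angle^c * lognormal(noise_sigma),
    with frequency, half-cycle count and mean peak angle drawn over realistic
    ranges.  Used to validate distance-model fitting against known exponents.
    """
    rng = np.random.default_rng(seed)
    freq = rng.uniform(15.0, 40.0, n_bouts)
    n_mot = rng.integers(2, 15, n_bouts).astype(float)
    ang = rng.uniform(5.0, 60.0, n_bouts)
    noise = np.exp(rng.normal(0.0, noise_sigma, n_bouts)) \
        if noise_sigma > 0 else 1.0
    dist = k * freq ** a * n_mot ** b * ang ** c * noise
    return pd.DataFrame({"tail_freq_hz": freq, "n_motions": n_mot,
                         "mean_peak_angle_deg": ang, "distance_mm": dist})


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

@dataclass
class GaussianFishTemplate:
    """Isotropic Gaussian dark blob standing in for the fish head."""

    sigma_px: float = 4.0
    depth: float = 150.0        # grayscale units below background at the peak
    background: float = 220.0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("template must be darker than the background")


def render_frames(positions_mm: np.ndarray, config: SessionConfig,
                  template: GaussianFishTemplate | None = None,
                  noise_sd: float = 0.0, seed: int = 0,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Render 8-bit frames with the fish template at known subpixel positions.

    Parameters
    ----------
    positions_mm : (n, 2) array
        Head positions in mm, image convention (origin at the top-left pixel
        corner grid: mm = px * pixel_size).  Must lie inside the frame.
    config : SessionConfig
        Provides pixel size and arena (= frame) extent.
    template : GaussianFishTemplate
    noise_sd : float
        Additive Gaussian noise (grayscale units) before 8-bit quantization.
    seed : int

    Returns
    -------
    stack : (n, h, w) uint8
    truth_px : (n, 2) float
        The same positions in (x, y) pixel units.
    """
    if template is None:
        template = GaussianFishTemplate()
    positions_mm = np.atleast_2d(np.asarray(positions_mm, dtype=float))
    px_size_mm = config.pixel_size_um / 1000.0
    side = int(round(config.arena_diameter_mm / px_size_mm))
    pos_px = positions_mm / px_size_mm
    if (pos_px < 0).any() or (pos_px >= side).any():
        raise ValueError("positions fall outside the frame")

    halfw = int(np.ceil(4.0 * template.sigma_px))
    if 2 * halfw + 1 > side:
        raise ValueError("template larger than the frame")
    rng = np.random.default_rng(seed)
    stack = np.empty((len(pos_px), side, side), dtype=np.uint8)
    for i, (cx, cy) in enumerate(pos_px):
        frame = np.full((side, side), template.background, dtype=float)
        x0 = max(int(np.floor(cx)) - halfw, 0)
        x1 = min(int(np.floor(cx)) + halfw + 1, side)
        y0 = max(int(np.floor(cy)) - halfw, 0)
        y1 = min(int(np.floor(cy)) + halfw + 1, side)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        frame[y0:y1, x0:x1] -= template.depth * np.exp(
            -r2 / (2.0 * template.sigma_px ** 2))
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, frame.shape)
        stack[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
    return stack, pos_px


# ---------------------------------------------------------------------------
# raphe activity simulation
# ---------------------------------------------------------------------------

def simulate_drn_activity(config: NeuralSimConfig,
                          epoch_spont_s: float = 10.0,
                          epoch_omr_s: float = 10.0,
                          ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate raw fluorescence traces for two complementary neuron classes.

    Class-1 neurons are elevated during spontaneous epochs, class-2 during
    OMR epochs, null neurons are flat; all traces carry a multiplicative slow
    baseline drift and additive noise, at 1 Hz sampling.

    Returns
    -------
    traces : (n_neurons, T) float
        Raw (positive) fluorescence, arbitrary units.
    labels : (n_neurons,) str array
        Ground-truth class per neuron ('class1', 'class2', 'null').
    schedule : dict
        ``{'epoch_spont_s', 'epoch_omr_s', 'n_trials'}`` for downstream use.
    """
    if config.n_trials <= 0:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(config.seed)
    period = int(round(epoch_spont_s + epoch_omr_s))
    T = config.n_trials * period
    t = np.arange(T)
    in_spont = (t % period) < epoch_spont_s

    labels = np.array(["class1"] * config.n_class1 +
                      ["class2"] * config.n_class2 +
                      ["null"] * config.n_null)
    n_neurons = labels.size
    f0 = 100.0

    resp = np.zeros((n_neurons, T))
    resp[labels == "class1"] = np.where(in_spont, config.response_amplitude, 0)
    resp[labels == "class2"] = np.where(in_spont, 0, config.response_amplitude)
    # 1-s calcium-like smoothing of the epoch-locked response
    resp = gaussian_filter1d(resp, sigma=1.0, axis=1, mode="nearest")

    drift = gaussian_filter1d(rng.standard_normal((n_neurons, T)),
                              sigma=config.drift_timescale_s, axis=1,
                              mode="nearest")
    sd = drift.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    drift = 1.0 + config.baseline_drift * drift / sd

    noise = rng.normal(0.0, config.noise_sd, (n_neurons, T))
    traces = f0 * drift * (1.0 + resp + noise)
    traces = np.clip(traces, 1.0, None)
    schedule = {"epoch_spont_s": epoch_spont_s, "epoch_omr_s": epoch_omr_s,
                "n_trials": config.n_trials}
    return traces, labels, schedule
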