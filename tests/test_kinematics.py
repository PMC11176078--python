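"""Bout segmentation, cycle extraction, L/R balance, filters, distance model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swimstates import kinematics, synthetic

FS = 290.0


def _trajectory_with_bouts(onsets_s, duration_s=0.12, peak_mm_s=80.0,
                           total_s=10.0, heading_deg=0.0):
    """Piecewise-stationary trajectory with sin^2 speed bursts."""
    n = int(total_s * FS)
    t = np.arange(n) / FS
    speed = np.zeros(n)
    for onset in onsets_s:
        m = (t >= onset) & (t < onset + duration_s)
        speed[m] = peak_mm_s * np.sin(np.pi * (t[m] - onset) / duration_s) ** 2
    d = np.cumsum(speed) / FS
    phi = np.radians(heading_deg)
    return np.column_stack([d * np.cos(phi), d * np.sin(phi)])


class TestDetectBouts:
    def test_stationary_with_subthreshold_drift_gives_no_bouts(self):
        t = np.arange(int(5 * FS)) / FS
        # slow sway peaking at 2 mm/s, half the onset threshold
        x = (2.0 / (2 * np.pi * 0.5)) * np.sin(2 * np.pi * 0.5 * t)
        bouts = kinematics.detect_bouts(np.column_stack([x, 0 * x]), FS)
        assert len(bouts) == 0

    def test_two_bouts_recovered_with_accurate_onsets(self):
        xy = _trajectory_with_bouts([2.0, 3.25])
        bouts = kinematics.detect_bouts(xy, FS)
        assert len(bouts) == 2
        assert np.allclose(bouts.onset_s, [2.0, 3.25], atol=0.010)
        assert bouts.interval_s.iloc[1] == pytest.approx(1.13, abs=0.02)
        assert np.isnan(bouts.interval_s.iloc[0])

    def test_count_invariant_under_half_threshold_noise(self):
        xy = _trajectory_with_bouts([2.0, 3.25, 5.0])
        t = np.arange(len(xy)) / FS
        sway = (2.0 / (2 * np.pi * 0.5)) * np.sin(2 * np.pi * 0.5 * t)
        noisy = xy + np.column_stack([sway, -sway]) / np.sqrt(2)
        assert len(kinematics.detect_bouts(noisy, FS)) == \
            len(kinematics.detect_bouts(xy, FS))

    def test_translation_invariance(self):
        xy = _trajectory_with_bouts([2.0, 3.25])
        a = kinematics.detect_bouts(xy, FS)
        b = kinematics.detect_bouts(xy + [123.4, -56.7], FS)
        assert np.allclose(a.onset_s, b.onset_s)
        assert np.allclose(a.distance_mm, b.distance_mm)

    def test_close_bouts_are_merged(self):
        xy = _trajectory_with_bouts([2.0, 2.15])   # 30 ms gap < 50 ms merge
        assert len(kinematics.detect_bouts(xy, FS)) == 1

    def test_nonuniform_timestamps_rejected(self):
        xy = _trajectory_with_bouts([2.0])
        t = np.arange(len(xy)) / FS
        t[100] += 0.01
        with pytest.raises(ValueError, match="uniform"):
            kinematics.detect_bouts(xy, FS, t_s=t)


def _sinusoid_bout(n_half=8, freq=25.0, amp=20.0, total_s=2.0,
                   onset=0.5, sides=None):
    """Lateral + tail series holding one synthetic bout."""
    n = int(total_s * FS)
    t = np.arange(n) / FS
    duration = n_half / (2 * freq)
    tail = np.zeros(n)
    m = (t >= onset) & (t < onset + duration)
    tau = t[m] - onset
    k = np.minimum((2 * freq * tau).astype(int), n_half - 1)
    sign = (-1.0) ** k if sides is None else np.asarray(sides)[k]
    tail[m] = amp * sign * np.abs(np.sin(2 * np.pi * freq * tau))
    lateral = -0.003 * tail
    return onset, onset + duration, lateral, tail


class TestExtractTailCycles:
    def test_eight_half_cycles_with_alternating_sides(self):
        onset, offset, lat, tail = _sinusoid_bout(n_half=8, amp=20.0)
        cyc = kinematics.extract_tail_cycles(onset, offset, FS, lat, tail)
        assert len(cyc) == 8
        sides = cyc.side.to_numpy()
        assert np.all(sides[1:] != sides[:-1])

    def test_single_sided_bout_all_right(self):
        onset, offset, lat, tail = _sinusoid_bout(
            n_half=6, sides=np.ones(6))
        # lateral reference still oscillates
        lat = -0.06 * np.sin(2 * np.pi * 25.0 *
                             (np.arange(len(tail)) / FS - onset)) * (tail != 0)
        cyc = kinematics.extract_tail_cycles(onset, offset, FS, lat, tail)
        assert len(cyc) >= 5
        assert set(cyc.side) == {"right"}

    def test_pure_sinusoid_peaks_within_one_percent(self):
        # 14.5 Hz at 290 Hz sampling puts every true peak on the sample grid
        amp = 20.0
        onset, offset, lat, tail = _sinusoid_bout(n_half=8, amp=amp,
                                                  freq=14.5, onset=0.5)
        cyc = kinematics.extract_tail_cycles(onset, offset, FS, lat, tail)
        assert np.all(np.abs(cyc.peak_angle_deg - amp) < 0.01 * amp)

    def test_flat_lateral_signals_tracking_failure(self):
        onset, offset, _, tail = _sinusoid_bout()
        with pytest.raises(ValueError, match="flat"):
            kinematics.extract_tail_cycles(onset, offset, FS,
                                           np.zeros_like(tail), tail)


def _cycles(right, left):
    rows = [dict(time_s=i * 0.02, peak_angle_deg=a, side=s)
            for i, (a, s) in enumerate(
                [(a, "right") for a in right] + [(a, "left") for a in left])]
    return pd.DataFrame(rows)


class TestBoutParameters:
    @pytest.mark.parametrize("right,left,expected", [
        ([20.0, 15.0, 10.0], [], 1.0),          # fully one-sided
        ([20.0, 10.0], [15.0, 15.0], 0.0),      # balanced sums
        ([30.0], [10.0], 0.5),                  # hand evaluation
    ])
    def test_lr_balance_worked_cases(self, right, left, expected):
        p = kinematics.compute_bout_parameters(_cycles(right, left))
        assert p["lr_balance"] == pytest.approx(expected)

    def test_tail_frequency_uses_full_cycle_convention(self):
        # 8 half-cycle peaks of a 25 Hz beat span 7/(2*25) s
        cyc = _cycles([1.0] * 4, [1.0] * 4)
        cyc["time_s"] = np.arange(8) / 50.0
        p = kinematics.compute_bout_parameters(cyc)
        assert p["tail_freq_hz"] == pytest.approx(25.0)
        assert p["n_motions"] == 8

    def test_single_cycle_frequency_undefined(self):
        p = kinematics.compute_bout_parameters(_cycles([20.0], []))
        assert np.isnan(p["tail_freq_hz"])

    def test_zero_cycles_rejected(self):
        with pytest.raises(ValueError):
            kinematics.compute_bout_parameters(_cycles([], []))

    @given(st.lists(st.floats(0.1, 90.0), min_size=1, max_size=12),
           st.lists(st.floats(0.1, 90.0), max_size=12),
           st.floats(0.1, 50.0))
    @settings(max_examples=60, deadline=None)
    def test_lr_balance_in_unit_interval_and_scale_free(self, right, left,
                                                        scale):
        p1 = kinematics.compute_bout_parameters(_cycles(right, left))
        p2 = kinematics.compute_bout_parameters(
            _cycles([scale * a for a in right], [scale * a for a in left]))
        assert 0.0 <= p1["lr_balance"] <= 1.0
        assert p1["lr_balance"] == pytest.approx(p2["lr_balance"],
                                                 rel=1e-9)


class TestSpatialFilters:
    def _bouts(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "x0_mm": rng.uniform(-45, 45, n),
            "y0_mm": rng.uniform(-45, 45, n),
            "heading_change_deg": rng.uniform(-90, 90, n),
        })

    def test_center_kept_boundary_removed(self):
        bouts = pd.DataFrame({"x0_mm": [0.0, 30.1], "y0_mm": [0.0, 0.0],
                              "heading_change_deg": [0.0, 0.0]})
        kept = kinematics.filter_central(bouts, arena_diameter_mm=90.0)
        assert len(kept) == 1 and kept.x0_mm.iloc[0] == 0.0

    def test_central_filter_matches_brute_force(self):
        bouts = self._bouts()
        kept = kinematics.filter_central(bouts, arena_diameter_mm=90.0)
        brute = (np.hypot(bouts.x0_mm, bouts.y0_mm) <= 30.0).sum()
        assert len(kept) == brute

    def test_small_arena_uses_ten_mm(self):
        bouts = pd.DataFrame({"x0_mm": [0.0, 15.0], "y0_mm": [0.0, 0.0],
                              "heading_change_deg": [0.0, 0.0]})
        assert len(kinematics.filter_central(bouts, 35.0)) == 1

    def test_forward_swims_match_brute_force(self):
        bouts = self._bouts(seed=1)
        kept = kinematics.filter_forward_swims(bouts)
        central = np.hypot(bouts.x0_mm, bouts.y0_mm) <= 30.0
        brute = (central & (bouts.heading_change_deg.abs() < 30.0)).sum()
        assert len(kept) == brute
        assert np.all(kept.heading_change_deg.abs() < 30.0)

    def test_straight_kept_turn_removed(self):
        bouts = pd.DataFrame({"x0_mm": [0.0, 0.0], "y0_mm": [0.0, 0.0],
                              "heading_change_deg": [0.0, 45.0]})
        kept = kinematics.filter_forward_swims(bouts)
        assert kept.heading_change_deg.tolist() == [0.0]


class TestSessionQC:
    config = synthetic.SessionConfig()   # 15 min, 10 s / 10 s

    def _bouts(self, n_omr):
        return pd.DataFrame({"epoch": ["omr"] * n_omr + ["spont"] * 10})

    def test_fifty_omr_bouts_pass_at_rate_6_7(self):
        qc = kinematics.session_qc(self._bouts(50), self.config)
        assert qc.passed
        assert qc.rate_per_min == pytest.approx(50 / 7.5)
        assert round(qc.rate_per_min, 1) == 6.7

    def test_forty_nine_fails(self):
        assert not kinematics.session_qc(self._bouts(49), self.config).passed

    def test_zero_bouts_fail_with_zero_rate(self):
        qc = kinematics.session_qc(self._bouts(0), self.config)
        assert not qc.passed and qc.rate_per_min == 0.0


class TestDistanceModel:
    def test_noiseless_exponent_recovery_and_perfect_fit(self):
        df = synthetic.simulate_distance_bouts(500, k=0.005, a=1.0, b=1.0,
                                               c=0.4, seed=1)
        m = kinematics.fit_distance_model(df)
        assert m.exp_freq == pytest.approx(1.0, abs=0.05)
        assert m.exp_count == pytest.approx(1.0, abs=0.05)
        assert m.exp_angle == pytest.approx(0.4, abs=0.05)
        assert m.fit_quality > 0.999

    def test_noisy_recovery_within_tenth(self):
        rng = np.random.default_rng(2)
        for i in range(5):
            a, b, c = rng.uniform(0.2, 1.5, 3)
            df = synthetic.simulate_distance_bouts(
                500, k=0.01, a=a, b=b, c=c, noise_sigma=0.05, seed=100 + i)
            m = kinematics.fit_distance_model(df)
            assert abs(m.exp_freq - a) < 0.1
            assert abs(m.exp_count - b) < 0.1
            assert abs(m.exp_angle - c) < 0.1

    def test_fit_quality_monotone_in_noise(self):
        rs = []
        for sigma in (0.0, 0.1, 0.3):
            df = synthetic.simulate_distance_bouts(
                400, k=0.01, a=1.0, b=1.0, c=0.4, noise_sigma=sigma, seed=7)
            rs.append(kinematics.fit_distance_model(df).fit_quality)
        assert rs[0] >= rs[1] >= rs[2]

    def test_constant_parameter_unidentifiable(self):
        df = synthetic.simulate_distance_bouts(100, seed=3)
        df["tail_freq_hz"] = 25.0
        with pytest.raises(ValueError, match="unidentifiable"):
            kinematics.fit_distance_model(df)

    def test_too_few_bouts_rejected(self):
        df = synthetic.simulate_distance_bouts(10, seed=4)
        with pytest.raises(ValueError, match="20"):
            kinematics.fit_distance_model(df)


class TestEndToEndRecovery:
    def test_detected_bouts_match_generator_truth(self, control_bouts):
        _, bouts, truth = control_bouts
        assert np.allclose(bouts.onset_s, truth.onset_s, atol=0.010)
        ok = np.isfinite(bouts.tail_freq_hz)
        ferr = np.abs(bouts.tail_freq_hz[ok] - truth.tail_freq_hz[ok])
        assert ferr.mean() < 1.5
        # decayed edge half-cycles are occasionally missed: most counts are
        # exact and nearly all are within one half-cycle
        count_diff = (bouts.n_motions - truth.n_motions).abs()
        assert (count_diff == 0).mean() > 0.8
        assert (count_diff <= 1).mean() > 0.95
        lr_err = np.abs(bouts.lr_balance - truth.lr_balance)
        assert np.nanmean(lr_err) < 0.05
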