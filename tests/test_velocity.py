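"""Similarity shifts, velocity closed forms, sector rules, record tracking."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ehgprop.preprocess import BANDS, OrientedSignalSet, preprocess_record
from ehgprop.synth import WaveSpec, simulate_record
from ehgprop.velocity import (
    VelocityTrack,
    XCorrParams,
    assign_sector,
    shifts_to_velocity,
    similarity_shift,
    track_record,
    window_normalize,
)

FS = 20.0


def brute_force_shift(x, y, d_ss):
    """Direct evaluation of C(m) = sum_n x(n) y(n - m + off), same tie-break."""
    off = (len(y) - len(x)) // 2
    best_m, best_c = None, -math.inf
    for m in sorted(range(-d_ss, d_ss + 1), key=lambda m: (abs(m), m)):
        c = 0.0
        for n in range(len(x)):
            j = n - m + off
            if 0 <= j < len(y):
                c += x[n] * y[j]
        if c > best_c:
            best_c, best_m = c, m
    return best_m


class TestWindowNormalize:
    def test_three_point_example(self):
        np.testing.assert_array_equal(
            window_normalize(np.array([2.0, 4.0, 6.0])), np.array([0.0, 0.5, 1.0])
        )

    def test_constant_window_is_degenerate(self):
        assert window_normalize(np.array([5.0, 5.0, 5.0])) is None

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_normalize(np.array([]))

    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=30)
        base = window_normalize(x)
        scaled = window_normalize(a * x + b)
        np.testing.assert_allclose(scaled, base, atol=1e-9)


class TestSimilarityShift:
    def test_delayed_copy_yields_negative_lag(self, rng):
        """y = x delayed by k gives shift -k under C(m) = sum x(n) y(n-m)."""
        x = rng.random(100)
        y = np.roll(x, 6)
        y[:6] = 0.0
        assert similarity_shift(x, y, 20) == -6

    def test_identical_windows_peak_at_zero(self, rng):
        x = rng.random(100)
        assert similarity_shift(x, x, 20) == 0

    def test_shift_is_clamped_to_search_range(self, rng):
        x = rng.random(100)
        y = np.roll(x, 30)
        y[:30] = 0.0
        shift = similarity_shift(x, y, 20)
        assert abs(shift) <= 20

    def test_degenerate_window_returns_none(self, rng):
        assert similarity_shift(None, rng.random(100), 20) is None
        assert similarity_shift(rng.random(100), None, 20) is None

    def test_odd_length_margin_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            similarity_shift(rng.random(100), rng.random(101), 20)

    @pytest.mark.parametrize("extended", [False, True])
    def test_matches_brute_force_on_random_pairs(self, rng, extended):
        """Fast correlation equals direct evaluation of the lag sum, exactly."""
        margin = 40 if extended else 0
        for _ in range(100):
            x = rng.random(80)
            y = rng.random(80 + margin)
            assert similarity_shift(x, y, 20) == brute_force_shift(x, y, 20)


class TestShiftsToVelocity:
    def test_no_propagation_when_both_shifts_zero(self):
        assert shifts_to_velocity(0, 0, FS, 7.0, 30.0) == (0.0, 0.0, 0.0, None)

    def test_single_axis_closed_form(self):
        t_v, t_h, cv, phi = shifts_to_velocity(-14, 0, FS, 7.0, 30.0)
        assert (t_v, t_h) == (0.7, 0.0)
        assert cv == pytest.approx(10.0)
        assert phi == 0.0
        assert assign_sector(phi) == ("vertical", "south")

    def test_diagonal_closed_form(self):
        t_v, t_h, cv, phi = shifts_to_velocity(-7, -7, FS, 7.0, 30.0)
        assert (t_v, t_h) == (0.35, 0.35)
        assert cv == pytest.approx(7.0 / (0.35 * math.sqrt(2)))
        assert phi == pytest.approx(45.0)
        assert assign_sector(phi) == ("horizontal", "east")

    def test_outlier_above_ceiling_zeroed(self):
        t_v, t_h, cv, phi = shifts_to_velocity(-1, 0, FS, 7.0, 30.0)
        assert t_v == 0.05
        assert cv == 0.0 and phi is None

    def test_degenerate_pair_contributes_zero_time(self):
        t_v, t_h, cv, phi = shifts_to_velocity(None, -14, FS, 7.0, 30.0)
        assert t_v == 0.0 and t_h == 0.7
        assert cv == pytest.approx(10.0)
        assert phi == pytest.approx(90.0)

    def test_upward_wave_maps_to_north(self):
        # positive vertical shift = upward travel; phi wraps to -180
        _, _, cv, phi = shifts_to_velocity(14, 0, FS, 7.0, 30.0)
        assert cv == pytest.approx(10.0)
        assert phi == -180.0
        assert assign_sector(phi) == ("vertical", "north")

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            shifts_to_velocity(0, 0, 0.0, 7.0, 30.0)


class TestAssignSector:
    @pytest.mark.parametrize(
        "phi,expected",
        [
            (0.0, ("vertical", "south")),
            (44.999, ("vertical", "south")),
            (45.0, ("horizontal", "east")),
            (134.999, ("horizontal", "east")),
            (135.0, ("vertical", "north")),
            (179.999, ("vertical", "north")),
            (-180.0, ("vertical", "north")),
            (-135.001, ("vertical", "north")),
            (-135.0, ("horizontal", "west")),
            (-45.001, ("horizontal", "west")),
            # -45 belongs to the south sector: the west rule is the
            # half-open range -135 <= phi < -45
            (-45.0, ("vertical", "south")),
        ],
    )
    def test_half_open_sector_rules(self, phi, expected):
        assert assign_sector(phi) == expected

    def test_undefined_angle(self):
        assert assign_sector(None) == (None, None)

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(ValueError):
            assign_sector(180.0)


class TestParams:
    def test_window_must_exceed_twice_search_range(self):
        with pytest.raises(ValueError, match="w_c"):
            XCorrParams(w_c=2.0, d_ss=1.0)

    def test_defaults(self):
        p = XCorrParams()
        assert (p.w_c, p.d_ci, p.d_ss, p.d_cm, p.cv_max) == (5.0, 0.5, 1.0, 7.0, 30.0)
        assert p.shift_samples(FS) == 20


def _zero_track(n_samples):
    z = np.zeros(n_samples)
    signals = OrientedSignalSet(z, z, z, z, BANDS["B1"], FS)
    return track_record(signals)


class TestTrackRecord:
    def test_thirty_minute_record_tiling(self):
        """(1800 s - 5 s) / 0.5 s + 1 = 3591 correlation intervals."""
        track = _zero_track(36000)
        assert len(track) == 3591
        centers = [e.center_sample for e in track.estimates]
        assert centers[0] == 50
        assert np.all(np.diff(centers) == 10)

    def test_all_zero_record_gives_no_propagation_everywhere(self):
        track = _zero_track(4000)
        assert all(e.cv == 0.0 and e.phi is None for e in track.estimates)
        assert all(e.direction is None and e.sector is None for e in track.estimates)

    def test_record_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            _zero_track(80)

    def test_shift_bound_holds_on_noise(self, rng):
        x = [rng.normal(size=3000) for _ in range(4)]
        signals = OrientedSignalSet(*x, BANDS["B1"], FS)
        track = track_record(signals)
        for e in track.estimates:
            assert abs(e.s_v or 0) <= 20 and abs(e.s_h or 0) <= 20

    def test_cv_floor_and_ceiling_on_noise(self, rng):
        """Nonzero CV is bounded by d/(sqrt(2) d_SS) below and cv_max above."""
        x = [rng.normal(size=6000) for _ in range(4)]
        signals = OrientedSignalSet(*x, BANDS["B1"], FS)
        track = track_record(signals)
        floor = 7.0 / math.sqrt(2.0)
        nonzero = [e.cv for e in track.estimates if e.cv != 0]
        assert nonzero, "expected some nonzero estimates on noise"
        for cv in nonzero:
            assert floor - 1e-9 <= cv <= 30.0 + 1e-9

    def test_track_csv_round_trip_columns(self, tmp_path, single_wave_record):
        oriented = preprocess_record(single_wave_record.record, "B1")
        track = track_record(oriented, record_id="single")
        path = track.to_csv(tmp_path / "track.csv")
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == [
            "k", "center_s", "s_V", "s_H", "t_V", "t_H",
            "CV_cm_s", "phi_deg", "direction", "sector",
        ]
        assert len(df) == len(track)


def _recover_at_burst(cv_true, phi_true, band="B1", noise_sd=0.0, seed=1):
    waves = [WaveSpec(cv_true=cv_true, phi_true=phi_true, onset_s=30.0)]
    synth = simulate_record(waves, duration_s=60.0, noise_sd=noise_sd, rng_seed=seed)
    oriented = preprocess_record(synth.record, band)
    track = track_record(oriented)
    est = min(track.estimates, key=lambda e: abs(e.center_sample - 600))
    return est, waves[0]


def quantization_bound(phi_true, fs=FS, d=7.0):
    phi = math.radians(phi_true)
    return (abs(math.cos(phi)) + abs(math.sin(phi))) / (fs * d)


SWEEP = [
    (cv, phi)
    for cv in (6.0, 8.0, 10.0, 12.0, 15.0, 20.0)
    for phi in (0.0, 30.0, -30.0, 60.0, -60.0, 90.0, -90.0, 120.0, 150.0, 179.0)
    # keep combinations whose true per-axis lags fit the +/- d_SS search range
    if max(
        abs(7.0 * math.cos(math.radians(phi)) / cv),
        abs(7.0 * math.sin(math.radians(phi)) / cv),
    )
    <= 1.0
]


class TestParameterRecovery:
    @pytest.mark.parametrize("cv_true,phi_true", SWEEP)
    def test_noise_free_wave_recovers_sector_and_cv(self, cv_true, phi_true):
        est, wave = _recover_at_burst(cv_true, phi_true)
        assert est.sector == wave.true_sector
        assert est.cv > 0
        assert abs(1 / est.cv - 1 / cv_true) <= quantization_bound(phi_true)

    def test_rotating_the_wave_by_90_degrees_swaps_the_shifts(self):
        """phi -> phi + 90 maps (s_V, s_H) to (-s_H, s_V)."""
        est_a, _ = _recover_at_burst(10.0, 20.0)
        est_b, _ = _recover_at_burst(10.0, 110.0)
        assert abs(est_b.s_v - (-est_a.s_h)) <= 1
        assert abs(est_b.s_h - est_a.s_v) <= 1
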