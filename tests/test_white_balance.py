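"""Gain model, scaler estimation, update test, and offline color correction."""

import math

import numpy as np
import pytest

from torsomark import color
from torsomark import white_balance as wb
from torsomark.config import GamutTarget, WhiteBalanceConfig

TARGET = GamutTarget()
TC = np.array([TARGET.r, TARGET.g, TARGET.b])


class TestGainModel:
    def test_unit_gain_at_center_temperature(self):
        gr, gb, gk = wb.gain_model(4500.0, 2500.0, 6500.0)
        assert gr == pytest.approx(1.0)
        assert gb == pytest.approx(1.0)
        assert gk == pytest.approx(1.0)

    def test_upper_bound(self):
        _, _, gk = wb.gain_model(6500.0, 2500.0, 6500.0)
        assert gk == pytest.approx(math.sqrt(2.0))

    def test_near_lower_bound(self):
        _, _, gk = wb.gain_model(2501.0, 2500.0, 6500.0)
        assert gk == pytest.approx(math.sqrt(2.0 / 4000.0))

    def test_lower_bound_rejected(self):
        with pytest.raises(ValueError):
            wb.gain_model(2500.0, 2500.0, 6500.0)


class TestScaler:
    def test_neutral_means_unit_scaler(self):
        assert wb.estimate_scaler(tuple(TC), TARGET) == pytest.approx(1.0)

    def test_reddish_cast(self):
        # red doubled, blue unchanged (any common normalizer cancels)
        cast = np.array([2 * TC[0], TC[1], TC[2]])
        cast /= cast.sum()
        assert wb.estimate_scaler(tuple(cast), TARGET) == pytest.approx(
            math.sqrt(0.5)
        )

    def test_bluish_cast(self):
        cast = np.array([TC[0], TC[1], 2 * TC[2]])
        cast /= cast.sum()
        assert wb.estimate_scaler(tuple(cast), TARGET) == pytest.approx(
            math.sqrt(2.0)
        )

    def test_degenerate_channel_gives_no_estimate(self):
        assert wb.estimate_scaler((0.0, 0.5, 0.5), TARGET) is None


class TestGamutErrors:
    def test_zero_at_target(self):
        e, e_star = wb.gamut_errors(tuple(TC), 1.0, TARGET)
        assert e == pytest.approx(0.0)
        assert e_star == pytest.approx(0.0)

    def test_known_offset(self):
        e, _ = wb.gamut_errors((TC[0] + 0.1, TC[1], TC[2] - 0.1), 1.0, TARGET)
        assert e == pytest.approx(0.02)

    def test_scaler_predicts_improvement_on_random_casts(self, rng):
        cfg = WhiteBalanceConfig()
        improved = 0
        for _ in range(100):
            gk = rng.uniform(0.6, 1.6)
            cast = TC * np.array([gk, 1.0, 1.0 / gk])
            cast /= cast.sum()
            scaler = wb.estimate_scaler(tuple(cast), TARGET)
            e, e_star = wb.gamut_errors(tuple(cast), scaler, TARGET)
            if e > cfg.error_threshold:
                assert e_star < e
                improved += 1
        assert improved > 50  # the draw actually produced real casts


class TestAwbStep:
    def test_neutral_image_keeps_setting(self):
        img = np.tile(TC * 1.2, (8, 8, 1))
        state = wb.CameraState(kw=4000.0)
        new, est = wb.awb_step(color.to_chromaticity(img), state)
        assert new.kw == state.kw
        assert est.error <= WhiteBalanceConfig().error_threshold

    def test_marginal_improvement_keeps_setting(self):
        # E slightly above the threshold but E-E* below the margin cannot
        # trigger an update; emulate via a state whose scaler is ~1
        cfg = WhiteBalanceConfig(error_margin=1.0)  # impossible margin
        img = np.tile(TC * np.array([1.02, 1.0, 0.98]) * 1.2, (8, 8, 1))
        state = wb.CameraState(kw=4000.0)
        new, _ = wb.awb_step(color.to_chromaticity(img), state, cfg=cfg)
        assert new.kw == state.kw

    def test_update_stays_in_sensor_range(self, rng):
        for _ in range(20):
            k_ill = rng.uniform(2600.0, 6400.0)
            state = wb.CameraState(kw=4500.0)
            img = wb.apply_cast(
                np.tile(TC * 1.2, (8, 8, 1)), k_ill, state.kw, state.kw_min, state.kw_max
            )
            new, _ = wb.awb_step(color.to_chromaticity(img), state)
            assert state.kw_min <= new.kw <= state.kw_max

    def test_closed_loop_converges_on_simulated_camera(self, gray_scene_image):
        # camera at 4500 K under a 3300 K illuminant: iterate sensing+update
        cfg = WhiteBalanceConfig()
        state = wb.CameraState(kw=4500.0)
        est = None
        for _ in range(50):
            img = wb.apply_cast(
                gray_scene_image, 3300.0, state.kw, state.kw_min, state.kw_max
            )
            new, est = wb.awb_step(color.to_chromaticity(img), state)
            if new.kw == state.kw:
                break
            state = new
        assert est is not None
        assert est.error < cfg.error_threshold
        assert state.kw == pytest.approx(3300.0, abs=50.0)


class TestOfflineCorrection:
    def test_neutral_texture_is_fixed_point(self, gray_scene_image):
        res = wb.color_correct_offline(gray_scene_image, 5500.0)
        assert res.kw == pytest.approx(5500.0, abs=20.0)
        assert np.allclose(res.linear, np.clip(gray_scene_image, 0, 1), atol=0.02)

    @pytest.mark.parametrize("k0", [2800.0, 4000.0, 7000.0, 8500.0])
    def test_roundtrip_recovers_chromaticity(self, gray_scene_image, k0):
        cfg = WhiteBalanceConfig()
        cast = wb.apply_cast(
            gray_scene_image, k0, 5500.0, cfg.virtual_kw_min, cfg.virtual_kw_max
        )
        res = wb.color_correct_offline(cast, 5500.0, cfg)
        before = color.to_chromaticity(np.clip(gray_scene_image, 0, 1))
        after = color.to_chromaticity(res.linear)
        both = before.defined & after.defined
        dev = np.abs(after.chromaticity[both] - before.chromaticity[both])
        assert np.quantile(dev, 0.99) < 0.01

    def test_overflowing_pixel_saturates_all_channels(self, gray_scene_image):
        # bluish cast (8000 K light recorded at 5500 K): the correction
        # raises the red gain, blowing the red-heavy pixel past 1
        cfg = WhiteBalanceConfig()
        img = wb.apply_cast(
            gray_scene_image, 8000.0, 5500.0,
            cfg.virtual_kw_min, cfg.virtual_kw_max,
        )
        img[0, 0] = [1.0, 0.2, 0.9]
        res = wb.color_correct_offline(img, 5500.0, cfg)
        assert res.kw == pytest.approx(8000.0, abs=150.0)
        assert res.linear[0, 0].tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_recording_temperature_rejected(self):
        with pytest.raises(ValueError):
            wb.color_correct_offline(np.zeros((2, 2, 3)), 9500.0)
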