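"""Preprocessing chain: windowing, transfer, crop, flip, resize, pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from orbitvae.phantom import HUVolume, PhantomSpec, make_phantom, muscle_mask
from orbitvae.preprocess import (PipelineStageError, PreprocessConfig,
                                 PreprocessConfigError, TransferFunction,
                                 WindowSettings, default_muscle_transfer,
                                 emphasize_muscle, extract_orbit, flip_lr,
                                 identity_transfer, preprocess_pipeline,
                                 resize_to_cube, window_hu)


def _vol(arr, lat="unknown"):
    return HUVolume(values=np.asarray(arr, dtype=np.float32), laterality=lat)


class TestWindowing:
    @pytest.mark.parametrize("hu,expected", [
        (-160.0, 0.0), (40.0, 0.5), (240.0, 1.0), (700.0, 1.0), (-500.0, 0.0)])
    def test_default_window_mapping(self, hu, expected):
        out = window_hu(np.full((1, 1, 1), hu))
        assert out[0, 0, 0] == pytest.approx(expected)

    def test_invalid_width(self):
        with pytest.raises(PreprocessConfigError):
            WindowSettings(center=40.0, width=0.0)

    @given(st.lists(st.floats(-2000, 3000), min_size=2, max_size=20))
    def test_monotone_and_idempotent(self, values):
        arr = np.array(sorted(values)).reshape(1, 1, -1)
        out = window_hu(arr)
        assert np.all(np.diff(out.ravel()) >= 0)
        # already-clamped values pass through a unit window unchanged
        unit = WindowSettings(center=0.5, width=1.0)
        np.testing.assert_allclose(window_hu(out, unit), out, atol=1e-6)


class TestTransfer:
    def test_identity_transfer(self, rng):
        g = rng.random((4, 5, 6)).astype(np.float32)
        np.testing.assert_array_equal(emphasize_muscle(g, identity_transfer()), g)

    def test_default_suppresses_bone_and_peaks_muscle(self):
        t = default_muscle_transfer()
        assert t(np.array(1.0)) == 0.0           # saturated bone
        assert t(np.array(0.50)) == 1.0          # muscle-band plateau edges
        assert t(np.array(0.60)) == 1.0
        muscle_w = float(window_hu(np.full((1, 1, 1), 55.0))[0, 0, 0])
        assert t(np.array(muscle_w)) == 1.0      # typical muscle HU lands on 1
        globe_w = float(window_hu(np.full((1, 1, 1), 10.0))[0, 0, 0])
        assert t(np.array(globe_w)) == 0.0       # vitreous/globe suppressed

    def test_non_monotone_domain_rejected(self):
        with pytest.raises(PreprocessConfigError):
            TransferFunction(((0, 0), (0.5, 1), (0.5, 0), (1, 0)))
        with pytest.raises(PreprocessConfigError):
            TransferFunction(((0, 0), (0.5, 2.0), (1, 0)))
        with pytest.raises(PreprocessConfigError):
            TransferFunction(((0.1, 0), (1, 1)))

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ValueError):
            emphasize_muscle(np.array([[[1.5]]]))


class TestCropFlip:
    def test_centered_crop_corner(self):
        arr = np.zeros((3, 272, 272), dtype=np.float32)
        arr[:, 68, 68] = 77.0
        out = extract_orbit(_vol(arr), crop_edge=136)
        assert out.shape == (3, 136, 136)
        assert out.values[0, 0, 0] == 77.0  # (68, 68) becomes the corner

    def test_crop_larger_than_image(self):
        with pytest.raises(ValueError, match="exceeds"):
            extract_orbit(_vol(np.zeros((2, 64, 64))), crop_edge=136)

    def test_crop_retains_muscle(self):
        spec = PhantomSpec(grid_shape=(24, 64, 64), muscle_radius_vox=2.0,
                           noise_sd=0.0, jitter=0.0)
        vol = make_phantom(spec, "normal", seed=2)
        mask = muscle_mask(spec, "normal", 2, "inferior")
        big = np.pad(vol.values, ((0, 0), (20, 20), (20, 20)),
                     constant_values=spec.background_hu)
        bigmask = np.pad(mask, ((0, 0), (20, 20), (20, 20)))
        out = extract_orbit(_vol(big), crop_edge=64)
        # the centered crop recovers the original grid, muscle included
        assert np.array_equal(out.values, vol.values)
        assert bigmask[:, 20:84, 20:84].sum() == mask.sum()

    def test_flip_is_involution(self, rng):
        v = _vol(rng.random((3, 5, 7)), lat="left")
        back = flip_lr(flip_lr(v))
        np.testing.assert_array_equal(back.values, v.values)
        assert back.laterality == "left"

    def test_flip_moves_marker_and_updates_laterality(self):
        arr = np.zeros((1, 4, 9), dtype=np.float32)
        arr[0, 2, 1] = 5.0
        out = flip_lr(_vol(arr, lat="left"))
        assert out.values[0, 2, 9 - 1 - 1] == 5.0
        assert out.laterality == "right"

    def test_flip_of_symmetric_volume_is_identity(self):
        arr = np.zeros((2, 3, 5), dtype=np.float32)
        arr[:, :, 2] = 9.0
        np.testing.assert_array_equal(flip_lr(_vol(arr)).values, arr)


class TestResize:
    def test_constant_preserved(self):
        out = resize_to_cube(np.full((10, 20, 30), 0.37), edge=8)
        np.testing.assert_allclose(out, 0.37, atol=1e-6)

    def test_identity_when_already_cubic(self, rng):
        g = rng.random((16, 16, 16))
        np.testing.assert_allclose(resize_to_cube(g, edge=16), g, atol=1e-6)

    def test_range_containment(self, rng):
        g = rng.random((40, 50, 33))
        out = resize_to_cube(g, edge=16)
        assert out.min() >= g.min() - 1e-6
        assert out.max() <= g.max() + 1e-6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resize_to_cube(np.empty((0, 4, 4)))


class TestPipeline:
    def test_phantom_contract_and_determinism(self, small_spec):
        vol = make_phantom(small_spec, "normal", seed=4, laterality="left")
        cfg = PreprocessConfig(crop_edge=48, out_edge=16)
        a = preprocess_pipeline(vol, cfg)
        b = preprocess_pipeline(vol, cfg)
        assert a.shape == (16, 16, 16)
        assert a.min() >= 0.0 and a.max() <= 1.0
        np.testing.assert_array_equal(a, b)

    def test_bone_only_volume_suppressed(self):
        vol = _vol(np.full((8, 20, 20), 700.0))
        cfg = PreprocessConfig(crop_edge=20, out_edge=8)
        out = preprocess_pipeline(vol, cfg)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_bone_dimmer_than_muscle(self, quiet_spec):
        """Emphasis must invert the brightness order of bone and muscle."""
        vol = make_phantom(quiet_spec, "normal", seed=6)
        g = emphasize_muscle(window_hu(vol))
        bone = vol.values == quiet_spec.bone_hu
        muscle = vol.values == quiet_spec.muscle_hu
        assert g[bone].mean() < g[muscle].mean()

    def test_stage_error_names_stage(self):
        vol = _vol(np.zeros((4, 10, 10)))
        with pytest.raises(PipelineStageError, match="crop"):
            preprocess_pipeline(vol, PreprocessConfig(crop_edge=999))

    def test_left_orbit_flipped(self, small_spec):
        cfg = PreprocessConfig(crop_edge=48, out_edge=16)
        right = make_phantom(small_spec, "normal", seed=4, laterality="right")
        left = HUVolume(values=np.ascontiguousarray(right.values[:, :, ::-1]),
                        laterality="left")
        np.testing.assert_allclose(preprocess_pipeline(left, cfg),
                                   preprocess_pipeline(right, cfg), atol=1e-5)
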