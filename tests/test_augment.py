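"""Permutation, rigid rotation, conjugate-axis mirroring, magnitude scaling."""

import numpy as np
import pytest

from strainnet import (AugmentationConfig, RotationAxis, VelocityProfile,
                       augment_dataset, conjugate_axis, mirror_profile,
                       permute_components, peak_resultant, random_rotation,
                       resultant, rotation_axis_at_peak, scale_magnitude)
from strainnet.augment import PERMUTATIONS


class TestPermuteComponents:
    def test_six_outputs_in_fixed_order(self, pulse_profile):
        out = permute_components(pulse_profile)
        assert len(out) == 6
        assert [p.impact_id for p in out] == \
            [f"pulse_{s}" for s in ("xyz", "xzy", "yxz", "yzx", "zxy", "zyx")]
        np.testing.assert_array_equal(out[0].samples, pulse_profile.samples)

    def test_identical_channels_give_identical_arrays(self):
        s = np.tile(np.sin(np.linspace(0, 3, 40)), (3, 1))
        out = permute_components(VelocityProfile("iso", 1.0, s))
        for p in out:
            np.testing.assert_array_equal(p.samples, s)

    def test_distinct_channels_give_pairwise_distinct_arrays(self, pulse_profile):
        out = permute_components(pulse_profile)
        for i in range(6):
            for j in range(i + 1, 6):
                assert not np.array_equal(out[i].samples, out[j].samples)

    def test_orderings_permute_rows(self, pulse_profile):
        out = {p.impact_id.split("_")[-1]: p for p in
               permute_components(pulse_profile)}
        np.testing.assert_array_equal(
            out["zyx"].samples, pulse_profile.samples[[2, 1, 0]])


class TestRandomRotation:
    def test_preserves_resultant(self, random_profiles):
        rng = np.random.default_rng(3)
        for p in random_profiles[:50]:
            q = random_rotation(p, rng)
            np.testing.assert_allclose(resultant(q), resultant(p), rtol=1e-12)

    def test_right_angle_about_z_maps_x_to_y(self):
        s = np.zeros((3, 10))
        s[0] = np.linspace(0, 5, 10)
        p = VelocityProfile("px", 1.0, s)

        class FixedRng:
            def __init__(self):
                self.calls = 0

            def standard_normal(self, n):
                return np.array([0.0, 0.0, 1.0])

            def uniform(self, lo, hi):
                return 90.0

        q = random_rotation(p, FixedRng(), max_angle=90.0)
        np.testing.assert_allclose(q.samples[1], s[0], atol=1e-12)
        np.testing.assert_allclose(q.samples[0], 0, atol=1e-12)

    def test_invalid_max_angle(self, pulse_profile):
        with pytest.raises(ValueError):
            random_rotation(pulse_profile, np.random.default_rng(0), 200.0)


class TestRotationAxisAtPeak:
    def test_pure_x(self):
        s = np.zeros((3, 5))
        s[0, 2] = 3.0
        ax = rotation_axis_at_peak(VelocityProfile("x", 1.0, s))
        assert ax.theta == pytest.approx(0.0) and ax.alpha == pytest.approx(0.0)

    def test_pure_z_is_90_elevation(self):
        s = np.zeros((3, 5))
        s[2, 2] = 3.0
        ax = rotation_axis_at_peak(VelocityProfile("z", 1.0, s))
        assert ax.alpha == pytest.approx(90.0)

    def test_oblique_45_45(self):
        s = np.zeros((3, 5))
        s[:, 2] = [1.0, 1.0, np.sqrt(2.0)]
        ax = rotation_axis_at_peak(VelocityProfile("o", 1.0, s))
        assert ax.theta == pytest.approx(45.0)
        assert ax.alpha == pytest.approx(45.0)

    def test_zero_peak_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            rotation_axis_at_peak(VelocityProfile("0", 1.0, np.zeros((3, 4))))

    def test_unit_vector_roundtrip(self, random_profiles):
        for p in random_profiles[:100]:
            ax = rotation_axis_at_peak(p)
            u = ax.unit_vector()
            assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-12)
            info = peak_resultant(p)
            np.testing.assert_allclose(
                u, p.samples[:, info.peak_index] / info.peak_magnitude,
                atol=1e-10)


class TestConjugateAxis:
    @pytest.mark.parametrize("axis, expected", [
        ((120.0, 30.0), (60.0, -30.0)),
        ((90.0, 0.0), (90.0, 0.0)),
        ((135.0, -20.0), (45.0, 20.0)),
        ((-150.0, 10.0), (-30.0, -10.0)),
    ])
    def test_direct_formula(self, axis, expected):
        out = conjugate_axis(RotationAxis(*axis))
        assert (out.theta, out.alpha) == pytest.approx(expected)

    def test_moves_into_half_space(self):
        for theta in np.linspace(-179.0, 180.0, 73):
            ax = RotationAxis(float(theta), 15.0)
            if not ax.in_sampled_half_space:
                assert conjugate_axis(ax).in_sampled_half_space


class TestMirrorProfile:
    def test_component_rule(self):
        s = np.array([[1.0, 1], [2.0, 2], [3.0, 3]])
        m = mirror_profile(VelocityProfile("m", 1.0, s))
        np.testing.assert_array_equal(m.samples, [[-1, -1], [2, 2], [-3, -3]])

    def test_involution(self, random_profiles):
        for p in random_profiles[:50]:
            np.testing.assert_array_equal(
                mirror_profile(mirror_profile(p)).samples, p.samples)

    def test_axis_maps_to_conjugate(self, random_profiles):
        for p in random_profiles:
            a = conjugate_axis(rotation_axis_at_peak(p))
            b = rotation_axis_at_peak(mirror_profile(p))
            assert b.theta == pytest.approx(a.theta, abs=1e-9)
            assert b.alpha == pytest.approx(a.alpha, abs=1e-9)

    def test_preserves_resultant(self, pulse_profile):
        np.testing.assert_allclose(
            resultant(mirror_profile(pulse_profile)),
            resultant(pulse_profile), rtol=1e-12)


class TestScaleMagnitude:
    def test_scalar_proportionality(self, pulse_profile):
        class FixedRng:
            def uniform(self, lo, hi):
                return 25.0

        q = scale_magnitude(pulse_profile, FixedRng())
        assert peak_resultant(q).peak_magnitude == pytest.approx(25.0)
        np.testing.assert_allclose(q.samples, pulse_profile.samples * 2.5)

    def test_band_respected_over_many_draws(self, pulse_profile):
        rng = np.random.default_rng(11)
        peaks = [peak_resultant(scale_magnitude(pulse_profile, rng)).peak_magnitude
                 for _ in range(1000)]
        assert min(peaks) > 21.9 and max(peaks) < 40.0

    def test_zero_peak_rejected(self):
        with pytest.raises(ValueError, match="zero-peak"):
            scale_magnitude(VelocityProfile("0", 1.0, np.zeros((3, 4))),
                            np.random.default_rng(0))


class TestAugmentDataset:
    @pytest.mark.parametrize("n_base, batches, expected", [
        (110, 2, 1320), (53, 2, 636), (53, 4, 1272),
    ])
    def test_count_identity(self, random_profiles, n_base, batches, expected):
        cfg = AugmentationConfig(n_batches=batches, seed=5)
        out, recs = augment_dataset(random_profiles[:n_base], cfg)
        assert len(out) == expected and len(recs) == expected

    def test_all_axes_in_half_space(self, random_profiles):
        out, _ = augment_dataset(random_profiles[:40],
                                 AugmentationConfig(n_batches=2, seed=1))
        assert all(rotation_axis_at_peak(p).in_sampled_half_space for p in out)

    def test_seed_reproducibility_and_divergence(self, random_profiles):
        base = random_profiles[:10]
        a1, _ = augment_dataset(base, AugmentationConfig(n_batches=1, seed=42))
        a2, _ = augment_dataset(base, AugmentationConfig(n_batches=1, seed=42))
        a3, _ = augment_dataset(base, AugmentationConfig(n_batches=1, seed=43))
        for p, q in zip(a1, a2):
            np.testing.assert_array_equal(p.samples, q.samples)
        assert any(not np.array_equal(p.samples, q.samples)
                   for p, q in zip(a1, a3))

    def test_scaled_peaks_inside_band(self, random_profiles):
        out, _ = augment_dataset(random_profiles[:30],
                                 AugmentationConfig(n_batches=2, seed=2))
        peaks = np.array([peak_resultant(p).peak_magnitude for p in out])
        assert np.all(peaks > 21.9) and np.all(peaks < 40.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            augment_dataset([], AugmentationConfig())
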