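"""Thickness and longitudinal band penalties, temporal weights, warping."""

import numpy as np
import pytest

from longiseg4d.constraints import (
    LongitudinalRange,
    TemporalWeights,
    ThicknessRange,
    longitudinal_penalty,
    temporal_weights,
    thickness_penalty,
    warp_image,
    warp_levelset,
)
from longiseg4d.geometry import LevelSetField, reinitialize

from conftest import circle_sdf


def _isolated_flow(step_fn, n_iter=40, dt=1.0, cap=0.9):
    """Run a gradient flow with re-distancing, no other forces."""
    for _ in range(n_iter):
        step_fn(dt, cap)


class TestThicknessPenalty:
    def test_in_band_zero_energy_and_force(self):
        phi1 = LevelSetField(circle_sdf(64, 12.0), 1.0)
        phi2 = LevelSetField(circle_sdf(64, 15.0), 1.0)  # 3 mm gap, in [1, 6.5]
        e, f1, f2 = thickness_penalty(phi1, phi2, ThicknessRange(), 1.0)
        assert e == 0.0
        assert np.abs(f1).max() == 0.0 and np.abs(f2).max() == 0.0

    def test_thin_gap_flow_opens_band(self):
        """Pure thickness flow pushes a 0.5 mm gap toward >= 1 mm."""
        phi1 = LevelSetField(circle_sdf(64, 12.0), 1.0)
        phi2 = LevelSetField(circle_sdf(64, 12.5), 1.0)
        rng_t = ThicknessRange()
        e0, _, _ = thickness_penalty(phi1, phi2, rng_t, 1.0)
        assert e0 > 0
        for _ in range(50):
            _, f1, f2 = thickness_penalty(phi1, phi2, rng_t, 1.0)
            phi1 = reinitialize(LevelSetField(np.clip(phi1.values - f1, phi1.values - 0.9, phi1.values + 0.9), 1.0))
            phi2 = reinitialize(LevelSetField(np.clip(phi2.values - f2, phi2.values - 0.9, phi2.values + 0.9), 1.0))
        from longiseg4d.phantom import gm_band_widths
        from longiseg4d.geometry import LevelSetTriple

        tri = LevelSetTriple(phi1, phi2, LevelSetField(circle_sdf(64, 20.0), 1.0))
        widths = gm_band_widths(tri)
        assert np.median(widths) >= 0.95
        e1, _, _ = thickness_penalty(phi1, phi2, rng_t, 1.0)
        assert e1 < e0

    def test_too_thick_gap_forces_contract(self):
        """8 mm gap: energy positive, flow reduces the band toward d_max."""
        phi1 = LevelSetField(circle_sdf(96, 10.0), 1.0)
        phi2 = LevelSetField(circle_sdf(96, 18.0), 1.0)
        rng_t = ThicknessRange()
        e0, f1, f2 = thickness_penalty(phi1, phi2, rng_t, 1.0)
        assert e0 > 0
        for _ in range(30):
            _, f1, f2 = thickness_penalty(phi1, phi2, rng_t, 1.0)
            phi1 = reinitialize(LevelSetField(phi1.values - np.clip(f1, -0.9, 0.9), 1.0))
            phi2 = reinitialize(LevelSetField(phi2.values - np.clip(f2, -0.9, 0.9), 1.0))
        e1, _, _ = thickness_penalty(phi1, phi2, rng_t, 1.0)
        assert e1 < 0.2 * e0

    def test_translation_invariance(self):
        e_a = thickness_penalty(
            LevelSetField(circle_sdf(96, 12.0, (40, 40)), 1.0),
            LevelSetField(circle_sdf(96, 12.4, (40, 40)), 1.0),
            ThicknessRange(),
            1.0,
        )[0]
        e_b = thickness_penalty(
            LevelSetField(circle_sdf(96, 12.0, (55, 55)), 1.0),
            LevelSetField(circle_sdf(96, 12.4, (55, 55)), 1.0),
            ThicknessRange(),
            1.0,
        )[0]
        assert e_a == pytest.approx(e_b, rel=0.02)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            ThicknessRange(3.0, 2.0)


class TestTemporalWeights:
    def test_two_timepoints_unit_weight(self):
        tw = temporal_weights([0.0, 12.0], 0)
        assert tw.as_dict() == {1: 1.0}

    def test_last_timepoint_dominates_and_sums_to_one(self):
        ages = [0.0, 3.0, 6.0, 9.0, 12.0]
        for target in range(5):
            tw = temporal_weights(ages, target)
            w = tw.as_dict()
            assert sum(w.values()) == pytest.approx(1.0)
            assert max(w, key=w.get) == 4 if target != 4 else 3

    def test_monotone_non_decreasing_with_source_age(self):
        ages = [0.0, 3.0, 6.0, 9.0, 12.0]
        for target in range(5):
            tw = temporal_weights(ages, target)
            ordered = [tw.as_dict()[i] for i in sorted(tw.indices)]
            assert all(b >= a for a, b in zip(ordered, ordered[1:]))

    def test_single_timepoint_empty(self):
        assert temporal_weights([6.0], 0).indices == ()

    def test_non_increasing_ages_rejected(self):
        with pytest.raises(ValueError):
            temporal_weights([3.0, 3.0], 0)


class TestWarp:
    def test_identity_deformation_equals_reinit(self):
        phi = LevelSetField(circle_sdf(48, 10.0), 1.0)
        u = np.zeros((2, 48, 48))
        out = warp_levelset(phi, u)
        expected = reinitialize(phi)
        assert np.abs(out.values - expected.values).max() < 0.25

    def test_translation_moves_zero_set(self):
        phi = LevelSetField(circle_sdf(48, 10.0), 1.0)
        u = np.zeros((2, 48, 48))
        u[0] = 2.0  # sample source at x+2: zero set shifts -2 along axis 0
        out = warp_levelset(phi, u)
        inside_before = np.argwhere(phi.values > 0).mean(axis=0)
        inside_after = np.argwhere(out.values > 0).mean(axis=0)
        shift = inside_after - inside_before
        assert shift[0] == pytest.approx(-2.0, abs=0.5)
        assert shift[1] == pytest.approx(0.0, abs=0.5)

    def test_phantom_deformation_roundtrip_dice(self):
        from longiseg4d.phantom import PhantomSpec, dice_ratio, generate_phantom

        spec = PhantomSpec(shape=(96, 96), ages=(0.0, 12.0), channels=("t1",),
                           deformation_mm=1.0, noise_sd=0.0, bias_amplitude=0.0, seed=5)
        s0, s1 = generate_phantom(spec)
        warped = warp_image(s0.labels.astype(float), s1.deformation_to_first,
                            (1.0, 1.0), order=0).astype(np.uint8)
        for label in (1, 2, 3):
            assert dice_ratio(warped, s1.labels, label) >= 0.98


class TestLongitudinalPenalty:
    def test_identical_reference_zero(self):
        phi = LevelSetField(circle_sdf(48, 10.0), 1.0)
        tw = TemporalWeights((1,), np.array([1.0]))
        e, f = longitudinal_penalty(phi, [phi.copy()], tw, LongitudinalRange(1.5), 1.0)
        assert e == 0.0 and np.abs(f).max() == 0.0

    def test_empty_references_zero(self):
        phi = LevelSetField(circle_sdf(48, 10.0), 1.0)
        e, f = longitudinal_penalty(phi, [], TemporalWeights((), np.empty(0)),
                                    LongitudinalRange(1.5), 1.0)
        assert e == 0.0 and np.abs(f).max() == 0.0

    def test_displaced_reference_flow_pulls_into_band(self):
        """3 mm displaced reference: flow brings the interface within epsilon."""
        phi = LevelSetField(circle_sdf(64, 10.0), 1.0)
        ref = LevelSetField(circle_sdf(64, 13.0), 1.0)
        tw = TemporalWeights((1,), np.array([1.0]))
        band = LongitudinalRange(1.5)
        e0, _ = longitudinal_penalty(phi, [ref], tw, band, 1.0)
        assert e0 > 0
        for _ in range(40):
            _, f = longitudinal_penalty(phi, [ref], tw, band, 1.0)
            phi = reinitialize(LevelSetField(phi.values - np.clip(f, -0.9, 0.9), 1.0))
        on_interface = np.abs(phi.values) < 0.5
        assert np.abs(ref.values[on_interface]).max() <= band.epsilon + 0.5
        e1, _ = longitudinal_penalty(phi, [ref], tw, band, 1.0)
        assert e1 < 0.05 * e0

    def test_weight_linearity(self):
        phi = LevelSetField(circle_sdf(48, 10.0), 1.0)
        ref = LevelSetField(circle_sdf(48, 13.0), 1.0)
        e1, _ = longitudinal_penalty(phi, [ref], np.array([1.0]), LongitudinalRange(0.5), 1.0)
        e2, _ = longitudinal_penalty(phi, [ref], np.array([2.0]), LongitudinalRange(0.5), 1.0)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_forces_vanish_where_band_satisfied(self):
        """Reference within epsilon everywhere near the interface: zero force voxelwise."""
        phi = LevelSetField(circle_sdf(48, 10.0), 1.0)
        ref = LevelSetField(circle_sdf(48, 10.4), 1.0)  # within the band everywhere
        e, f = longitudinal_penalty(phi, [ref], np.array([1.0]), LongitudinalRange(1.5), 1.0)
        assert e == 0.0
        np.testing.assert_array_equal(f, 0.0)
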