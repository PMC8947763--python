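"""Swing-twist decomposition, domain-motion recovery and flexion angles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tetrapore import (DomainDefinition, domain_motion, flexion_angle,
                       swing_twist_decompose)
from tetrapore.frame import rotation_about_axis
from tetrapore.motions import recompose
from tetrapore.synthetic import (apply_rigid_motion, build_flexion_fixture)

MARKERS = DomainDefinition("markers", ((348, 348), (984, 984)))
FRAME_SEL = DomainDefinition("pore_side", ((4800, 5100),))


def swing_angle_after_detwist(R, axis, twist_deg):
    """Rotation angle left after removing a twist by ``twist_deg``."""
    resid = R @ rotation_about_axis(axis, -twist_deg)
    return np.degrees(np.arccos(np.clip((np.trace(resid) - 1) / 2, -1, 1)))


class TestSwingTwist:
    def test_pure_twist(self):
        a = np.array([0.0, 0.0, 1.0])
        tw, sw, _ = swing_twist_decompose(rotation_about_axis(a, 30.0), a)
        assert tw == pytest.approx(30.0, abs=1e-10)
        assert sw == pytest.approx(0.0, abs=1e-10)

    def test_pure_swing(self):
        a = np.array([0.0, 0.0, 1.0])
        perp = np.array([1.0, 0.0, 0.0])
        tw, sw, _ = swing_twist_decompose(rotation_about_axis(perp, 10.0), a)
        assert tw == pytest.approx(0.0, abs=1e-10)
        assert sw == pytest.approx(10.0, abs=1e-10)

    def test_degenerate_180_about_perpendicular_gives_zero_twist(self):
        a = np.array([0.0, 0.0, 1.0])
        perp = np.array([0.0, 1.0, 0.0])
        tw, sw, _ = swing_twist_decompose(rotation_about_axis(perp, 180.0), a)
        assert tw == pytest.approx(0.0, abs=1e-9)
        assert sw == pytest.approx(180.0, abs=1e-9)

    def test_recomposition_exact_on_1000_random_rotations(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            R = Rotation.random(random_state=rng).as_matrix()
            a = rng.normal(size=3)
            a /= np.linalg.norm(a)
            tw, sw, az = swing_twist_decompose(R, a)
            assert -180.0 < tw <= 180.0
            assert 0.0 <= sw <= 180.0
            worst = max(worst, np.abs(recompose(tw, sw, az, a) - R).max())
        assert worst < 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_twist_minimises_residual_swing(self, seed):
        # grid oracle: no twist value leaves a smaller swing rotation
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=rng).as_matrix()
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        tw, sw, _ = swing_twist_decompose(R, a)
        grid = np.arange(-180.0, 180.0, 0.001)
        near = grid[np.abs((grid - tw + 180) % 360 - 180) < 0.5]
        coarse = grid[::500]
        swings = [swing_angle_after_detwist(R, a, t)
                  for t in np.concatenate([near, coarse])]
        assert sw <= min(swings) + 1e-6

    def test_non_rotation_rejected(self):
        with pytest.raises(ValueError):
            swing_twist_decompose(np.diag([1.0, 1.0, -1.0]),
                                  np.array([0.0, 0.0, 1.0]))


class TestDomainMotion:
    def test_identity_motion(self):
        base = build_flexion_fixture(0.0)
        m = domain_motion(base, base, MARKERS, frame_selection=FRAME_SEL)
        assert m.twist_deg == pytest.approx(0.0, abs=1e-9)
        assert m.swing_deg == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.norm(m.translation) < 1e-9

    @pytest.mark.parametrize("twist", [-30.0, -5.0, -1.0, 1.0, 5.0, 30.0])
    @pytest.mark.parametrize("swing", [0.0, 3.0, 10.0])
    def test_generator_parameters_recovered(self, twist, swing):
        base = build_flexion_fixture(0.0)
        moved = apply_rigid_motion(base, MARKERS, twist_deg=twist,
                                   swing_deg=swing,
                                   swing_axis_azimuth_deg=40.0)
        m = domain_motion(base, moved, MARKERS, frame_selection=FRAME_SEL)
        assert m.twist_deg == pytest.approx(twist, abs=0.01)
        assert m.swing_deg == pytest.approx(swing, abs=0.01)

    def test_same_axis_twists_are_additive(self):
        base = build_flexion_fixture(0.0)
        m1 = apply_rigid_motion(base, MARKERS, twist_deg=2.0)
        m2 = apply_rigid_motion(m1, MARKERS, twist_deg=3.0)
        m = domain_motion(base, m2, MARKERS, frame_selection=FRAME_SEL)
        assert m.twist_deg == pytest.approx(5.0, abs=0.01)

    def test_upward_swing_sign_positive(self):
        base = build_flexion_fixture(0.0)
        moved = base.copy()
        mask = np.isin(moved.res_number, [348, 984])
        moved.xyz[mask] += np.array([0.0, 0.0, 3.0])
        m = domain_motion(base, moved, MARKERS, frame_selection=FRAME_SEL)
        assert m.swing_sign == 1


class TestFlexion:
    @pytest.mark.parametrize("angle", [-5.6, -4.4, -2.2, 0.0, 2.0])
    def test_fixture_round_trip(self, angle):
        res = flexion_angle(build_flexion_fixture(angle))
        assert res.mean == pytest.approx(angle, abs=0.01)

    def test_per_protomer_agreement_on_c4_fixture(self):
        res = flexion_angle(build_flexion_fixture(-4.6))
        assert np.ptp(res.per_protomer) < 1e-6

    def test_invariant_under_global_rigid_motion(self):
        model = build_flexion_fixture(-5.0)
        base = flexion_angle(model).mean
        R = rotation_about_axis(np.array([2.0, -1.0, 3.0]) / np.sqrt(14), 61.0)
        moved = model.transformed(R, np.array([7.0, 1.0, -4.0]))
        moved.protomer[:] = -1
        from tetrapore import assign_protomers
        assert flexion_angle(assign_protomers(moved)).mean == \
            pytest.approx(base, abs=0.01)

    def test_missing_anchor_names_protomer(self):
        model = build_flexion_fixture(0.0)
        reduced = model.subset(~((model.res_number == 984) &
                                 (model.protomer == 1)))
        from tetrapore.errors import TetraporeError
        with pytest.raises(TetraporeError, match="protomer 1"):
            flexion_angle(reduced)
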