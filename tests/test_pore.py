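"""Pore radius profile against a brute-force inscribed-sphere oracle."""

import numpy as np
import pytest

from tetrapore import (AnalysisConfig, DomainDefinition, PoreProfile,
                       compute_channel_frame, compute_pore_profile,
                       gate_diameter_calpha, radius_at_landmark,
                       read_structure, write_dot_surface, write_profile)
from tetrapore.errors import PoreEnclosureError, TetraporeError
from tetrapore.frame import rotation_about_axis
from tetrapore.pore import read_profile
from tetrapore.synthetic import PoreFixtureSpec, build_c4_pore_fixture

RING_SELECTION = DomainDefinition("rings", ((4930, 4945),))


def brute_force_gate_radius(model, config: AnalysisConfig, ring_z: float,
                            half_width: float = 2.0, grid: float = 0.01) -> float:
    """Grid maximisation of min_i(|c - x_i| - vdW_i) on the gate plane."""
    sub = model.subset(~model.is_hetero & (model.res_number >= 4930) &
                       (model.res_number <= 4945))
    radii = np.array([config.vdw(e) for e in sub.element])
    xs = np.arange(-half_width, half_width + grid / 2, grid)
    gx, gy = np.meshgrid(xs, xs)
    centers = np.stack([gx.ravel(), gy.ravel(),
                        np.full(gx.size, ring_z)], axis=1)
    best = -np.inf
    for chunk in np.array_split(centers, 8):
        d = np.linalg.norm(chunk[:, None, :] - sub.xyz[None], axis=2) - radii
        best = max(best, float(d.min(axis=1).max()))
    return best


def _profile(model, selection=RING_SELECTION, config=None):
    frame = compute_channel_frame(model)
    return compute_pore_profile(model, frame, selection=selection,
                                config=config or AnalysisConfig())


class TestOracleEquivalence:
    def test_min_radius_matches_grid_oracle_on_randomized_fixtures(self, config):
        rng = np.random.default_rng(20)
        for _ in range(20):
            spec = PoreFixtureSpec(
                gate_radius=float(rng.uniform(0.6, 1.8)),
                vestibule_radius=float(rng.uniform(3.5, 6.0)),
                ring_atom_count=int(rng.choice([8, 12, 16])),
                ring_z=float(rng.uniform(-0.1, 0.1)),
            )
            model = build_c4_pore_fixture(spec)
            prof = _profile(model)
            oracle = brute_force_gate_radius(model, config, spec.ring_z)
            assert prof.min_radius == pytest.approx(oracle, abs=0.05)
            assert prof.min_radius == pytest.approx(spec.gate_radius, abs=0.05)

    def test_single_ring_of_eight_oxygens(self):
        # ring centers at 4.65 A from axis, O vdW 1.65 -> radius 3.00
        spec = PoreFixtureSpec(gate_radius=3.0, vestibule_radius=6.0,
                               ring_atom_count=8)
        prof = _profile(build_c4_pore_fixture(spec))
        assert radius_at_landmark(prof, 4937) == pytest.approx(3.0, abs=0.05)


class TestProfileProperties:
    def test_monotone_response_to_gate_enlargement(self):
        delta = 0.5
        r1 = _profile(build_c4_pore_fixture(PoreFixtureSpec(gate_radius=1.0))).min_radius
        r2 = _profile(build_c4_pore_fixture(PoreFixtureSpec(gate_radius=1.0 + delta))).min_radius
        assert r2 - r1 == pytest.approx(delta, abs=0.05)

    def test_rotation_invariance(self):
        model = build_c4_pore_fixture(PoreFixtureSpec(gate_radius=1.2))
        prof0 = _profile(model)
        rng = np.random.default_rng(5)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = rotation_about_axis(axis, 37.0)
        rotated = model.transformed(R, np.array([3.0, -2.0, 1.0]))
        rotated.protomer[:] = -1
        from tetrapore import assign_protomers
        prof1 = _profile(assign_protomers(rotated))
        assert abs(prof1.min_radius - prof0.min_radius) <= 0.02

    def test_samples_evenly_spaced_and_continuous(self):
        prof = _profile(build_c4_pore_fixture(PoreFixtureSpec()))
        assert np.allclose(np.diff(prof.z), prof.step, atol=1e-6)
        lateral = np.linalg.norm(np.diff(prof.centers, axis=0), axis=1)
        assert np.all(lateral < 2 * prof.step + prof.step)  # includes z step

    def test_enclosure_failure_raises(self):
        model = build_c4_pore_fixture(PoreFixtureSpec())
        # keep only one side of the channel: axis no longer enclosed
        half = model.subset(model.xyz[:, 0] > -0.5)
        frame = compute_channel_frame(model)
        with pytest.raises(PoreEnclosureError):
            compute_pore_profile(half, frame, selection=RING_SELECTION)


class TestGateDiameter:
    def test_square_of_markers_diameter_equals_twice_circumradius(self):
        model = build_c4_pore_fixture(
            PoreFixtureSpec(gate_radius=7.9, vestibule_radius=12.0),
            marker_radius=7.9)
        frame = compute_channel_frame(model)
        assert gate_diameter_calpha(model, 4937, frame) == pytest.approx(15.8,
                                                                         abs=1e-9)

    def test_diagonals_agree_on_c4_exact_fixture(self):
        model = build_c4_pore_fixture(PoreFixtureSpec(), marker_radius=5.0)
        frame = compute_channel_frame(model)
        cyc = frame.protomer_cycle
        pos = {}
        mask = model.ca_mask & (model.res_number == 4937)
        for i in np.nonzero(mask)[0]:
            pos[int(model.protomer[i])] = model.xyz[i]
        d1 = np.linalg.norm(pos[cyc[0]] - pos[cyc[2]])
        d2 = np.linalg.norm(pos[cyc[1]] - pos[cyc[3]])
        assert abs(d1 - d2) < 1e-6

    def test_missing_protomer_reported(self):
        model = build_c4_pore_fixture(PoreFixtureSpec())
        reduced = model.subset(~((model.res_number == 4937) &
                                 (model.name == "CA") & (model.protomer == 2)))
        with pytest.raises(TetraporeError, match=r"\[2\]"):
            gate_diameter_calpha(reduced, 4937)


class TestLandmarksAndOutput:
    def test_landmark_midway_between_samples_interpolates(self):
        prof = PoreProfile(z=np.array([0.0, 0.25]),
                           centers=np.zeros((2, 3)),
                           radius=np.array([1.0, 2.0]),
                           landmarks={4937: 0.125}, step=0.25)
        assert radius_at_landmark(prof, 4937) == pytest.approx(1.5)

    def test_unknown_or_out_of_range_landmark(self):
        prof = PoreProfile(z=np.array([0.0, 0.25]), centers=np.zeros((2, 3)),
                           radius=np.array([1.0, 2.0]),
                           landmarks={4937: 5.0}, step=0.25)
        with pytest.raises(TetraporeError):
            radius_at_landmark(prof, 1234)
        with pytest.raises(TetraporeError):
            radius_at_landmark(prof, 4937)

    def test_csv_round_trip(self, tmp_path):
        prof = _profile(build_c4_pore_fixture(PoreFixtureSpec()))
        path = tmp_path / "profile.csv"
        write_profile(prof, path)
        df = read_profile(path)
        assert len(df) == prof.n_samples
        assert np.abs(df["radius"].to_numpy() - prof.radius).max() < 1e-3

    def test_dot_surface_is_valid_pdb_hetatm(self, tmp_path):
        prof = _profile(build_c4_pore_fixture(PoreFixtureSpec()))
        path = tmp_path / "dots.pdb"
        write_dot_surface(prof, path, points_per_sphere=8)
        back = read_structure(path)
        assert back.n_atoms == 8 * prof.n_samples
        assert back.is_hetero.all()
        # sphere radius encoded in the B-factor column
        assert np.abs(np.sort(np.unique(back.b_factor.round(2))) -
                      np.sort(np.unique(prof.radius.round(2)))).max() < 0.02
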