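"""Kabsch superposition and the three RMSD regimes."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tetrapore import (DomainDefinition, kabsch_fit, rmsd_cd_aligned,
                       rmsd_heatmap, rmsd_in_frame, rmsd_prealigned)
from tetrapore.errors import DegenerateGeometryError
from tetrapore.frame import rotation_about_axis

from conftest import MINI_RANGES, build_mini_tetramer

CD = DomainDefinition("CD", (MINI_RANGES["CD"],))
CTD = DomainDefinition("CTD", (MINI_RANGES["CTD"],))


def numeric_min_rmsd(X, Y, n_starts=12, seed=0) -> float:
    """Independent oracle: minimise RMSD over rotation vectors numerically."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(((X @ R.T - Y) ** 2).sum() / len(X))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        rv0 = rng.uniform(-np.pi, np.pi, size=3)
        res = minimize(cost, rv0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 4000})
        best = min(best, res.fun)
    return float(best)


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        fit = kabsch_fit(X, X)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.rotation, np.eye(3), atol=1e-12)

    def test_exact_recovery_of_known_rotation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        R = rotation_about_axis(np.array([1.0, 2.0, -1.0]) / np.sqrt(6), 53.0)
        t = np.array([4.0, -2.0, 7.0])
        fit = kabsch_fit(X, X @ R.T + t)
        assert np.abs(fit.rotation - R).max() < 1e-9
        assert fit.rmsd < 1e-9

    def test_rotation_is_proper_and_orthonormal(self):
        rng = np.random.default_rng(2)
        fit = kabsch_fit(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
        assert np.allclose(fit.rotation @ fit.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_numeric_rotation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(5, 3))
        assert kabsch_fit(X, Y).rmsd == pytest.approx(
            numeric_min_rmsd(X, Y, seed=seed), abs=1e-3)

    def test_collinear_points_rejected(self):
        X = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(X, X)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_fit(np.zeros((4, 3)), np.zeros((5, 3)))


def _translated_domain_pair(domain_range=MINI_RANGES["CTD"], shift=(2.0, 0, 0)):
    A = build_mini_tetramer(0)
    B = A.copy()
    mask = (B.res_number >= domain_range[0]) & (B.res_number <= domain_range[1])
    B.xyz[mask] += np.asarray(shift, float)
    return A, B


class TestRegimes:
    def test_identical_models_zero_everywhere(self, registry):
        A = build_mini_tetramer(0)
        assert rmsd_prealigned(A, A, CD) == pytest.approx(0.0, abs=1e-12)
        assert rmsd_in_frame(A, A, CD) == pytest.approx(0.0, abs=1e-12)
        assert rmsd_cd_aligned(A, A, CTD, anchor=CD) == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_prealigned_removes_rigid_displacement(self):
        A, B = _translated_domain_pair()
        assert rmsd_prealigned(A, B, CTD) == pytest.approx(0.0, abs=1e-9)

    def test_unaligned_sees_translation_exactly(self):
        A, B = _translated_domain_pair(shift=(2.0, 0.0, 0.0))
        rest = DomainDefinition("rest", (MINI_RANGES["CD"],
                                         MINI_RANGES["pore_region"],
                                         MINI_RANGES["S2S3_loop"]))
        assert rmsd_in_frame(A, B, CTD, frame_selection=rest) == \
            pytest.approx(2.0, abs=1e-6)

    def test_repositioning_equals_shift(self):
        A, B = _translated_domain_pair()
        rest = DomainDefinition("rest", (MINI_RANGES["CD"],
                                         MINI_RANGES["pore_region"]))
        una = rmsd_in_frame(A, B, CTD, frame_selection=rest)
        pre = rmsd_prealigned(A, B, CTD)
        assert una - pre == pytest.approx(2.0, abs=1e-6)

    def test_cd_aligned_domain_equals_prealigned_for_anchor_itself(self):
        A, B = _translated_domain_pair()
        assert rmsd_cd_aligned(A, B, CD, anchor=CD, protomer=0) == \
            pytest.approx(rmsd_prealigned(A, B, CD, protomer=0), abs=1e-12)

    def test_cd_aligned_detects_rotation_about_anchor(self):
        A = build_mini_tetramer(1)
        B = A.copy()
        cd_mask = (B.res_number >= MINI_RANGES["CD"][0]) & \
                  (B.res_number <= MINI_RANGES["CD"][1]) & (B.protomer == 0)
        pivot = B.xyz[cd_mask].mean(axis=0)
        R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 10.0)
        distal = (B.res_number >= MINI_RANGES["CTD"][0]) & \
                 (B.res_number <= MINI_RANGES["CTD"][1]) & (B.protomer == 0)
        B.xyz[distal] = (B.xyz[distal] - pivot) @ R.T + pivot
        pre = rmsd_prealigned(A, B, CTD, protomer=0)
        cda = rmsd_cd_aligned(A, B, CTD, anchor=CD, protomer=0)
        assert pre == pytest.approx(0.0, abs=1e-9)
        assert cda > 0.5

    def test_symmetry_of_prealigned(self):
        A = build_mini_tetramer(0)
        B = build_mini_tetramer(0)
        rng = np.random.default_rng(9)
        B.xyz += rng.normal(scale=0.3, size=B.xyz.shape)
        assert rmsd_prealigned(A, B, CD) == pytest.approx(
            rmsd_prealigned(B, A, CD), abs=1e-9)

    def test_invariance_under_shared_global_motion(self):
        A = build_mini_tetramer(0)
        B = build_mini_tetramer(0)
        rng = np.random.default_rng(11)
        B.xyz += rng.normal(scale=0.4, size=B.xyz.shape)
        base = (rmsd_prealigned(A, B, CD), rmsd_in_frame(A, B, CD),
                rmsd_cd_aligned(A, B, CTD, anchor=CD))
        R = rotation_about_axis(np.array([1.0, 1.0, 1.0]) / np.sqrt(3), 33.0)
        t = np.array([10.0, -4.0, 2.0])
        A2, B2 = A.transformed(R, t), B.transformed(R, t)
        moved = (rmsd_prealigned(A2, B2, CD), rmsd_in_frame(A2, B2, CD),
                 rmsd_cd_aligned(A2, B2, CTD, anchor=CD))
        assert np.allclose(base, moved, atol=1e-9)

    def test_fit_optimality_ordering_on_random_pairs(self):
        for seed in range(4):
            A = build_mini_tetramer(0)
            B = build_mini_tetramer(0)
            rng = np.random.default_rng(100 + seed)
            B.xyz += rng.normal(scale=0.5, size=B.xyz.shape)
            for dom in (CD, CTD):
                pre = rmsd_prealigned(A, B, dom, protomer=0)
                una = rmsd_in_frame(A, B, dom, protomer=0)
                cda = rmsd_cd_aligned(A, B, dom, anchor=CD, protomer=0)
                assert pre <= una + 1e-9
                assert pre <= cda + 1e-9


class TestHeatmap:
    def test_identical_models_all_zero(self, registry):
        A = build_mini_tetramer(0)
        hm = rmsd_heatmap(A, A, registry, domains=["CD", "CTD", "EF_loops"])
        for d in hm.domains:
            assert hm.prealigned[d] == pytest.approx(0.0, abs=1e-9)
            assert hm.unaligned[d] == pytest.approx(0.0, abs=1e-9)
            assert hm.repositioning[d] == pytest.approx(0.0, abs=1e-9)

    def test_translated_domain_localised(self, registry):
        A, B = _translated_domain_pair()
        rest = DomainDefinition("rest", (MINI_RANGES["CD"],
                                         MINI_RANGES["pore_region"],
                                         MINI_RANGES["S2S3_loop"],
                                         MINI_RANGES["EF_loops"]))
        hm = rmsd_heatmap(A, B, registry, domains=["CD", "CTD", "EF_loops"],
                          frame_selection=rest)
        assert hm.prealigned["CTD"] == pytest.approx(0.0, abs=1e-9)
        assert hm.repositioning["CTD"] == pytest.approx(2.0, abs=1e-6)
        for d in ("CD", "EF_loops"):
            assert hm.repositioning[d] == pytest.approx(0.0, abs=1e-6)

    def test_missing_domain_recorded_not_fatal(self, registry):
        A = build_mini_tetramer(0)
        hm = rmsd_heatmap(A, A, registry, domains=["CD", "luminal_loop"])
        assert "luminal_loop" in hm.missing
        assert "CD" in hm.prealigned
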