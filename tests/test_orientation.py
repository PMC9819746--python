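import numpy as np
import pytest

from ly6orient.orientation import (
    ReferenceVectors, assign_leaflets, com_height, feasible_beta,
    nearest_feasible_beta, orientation_series, reference_vectors,
    rotation_angle, tilt_angle, wrap_angle,
)


def vecs(B, f_z, A=(1.0, 0.0, 0.0)):
    return ReferenceVectors(A=np.array(A, float), B=np.array(B, float),
                            F=np.array([0.0, 0.0, f_z]) if f_z else
                            np.array([1.0, 0.0, 0.0]))


class TestTiltAngle:
    @pytest.mark.parametrize("A, expected", [
        ((0, 0, 1), 90.0),                      # A along the normal
        ((1, 0, 0), 0.0),                       # central loop parallel
        ((1 / np.sqrt(2), 0, -1 / np.sqrt(2)), -45.0),
        ((0, 0, -1), -90.0),
    ])
    def test_examples(self, A, expected):
        v = ReferenceVectors(A=np.array(A, float), B=np.array([0.0, 1.0, 0.0]),
                             F=np.array([0.0, 0.0, 1.0]))
        assert tilt_angle(v) == pytest.approx(expected, abs=1e-9)

    def test_antisymmetry_under_flip(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            A = rng.standard_normal(3)
            v1 = ReferenceVectors(A=A, B=np.zeros(3) + 1, F=np.ones(3))
            v2 = ReferenceVectors(A=-A, B=np.zeros(3) + 1, F=np.ones(3))
            assert tilt_angle(v1) == pytest.approx(-tilt_angle(v2), abs=1e-9)

    def test_zero_length_is_an_error(self):
        with pytest.raises(ValueError):
            tilt_angle(ReferenceVectors(A=np.zeros(3), B=np.ones(3), F=np.ones(3)))


class TestRotationAngle:
    @pytest.mark.parametrize("B, f_z, expected", [
        ((0, 0, 1), +0.5, 90.0),        # branch 1, B up
        ((0, 0, -1), +0.5, -90.0),      # branch 1, B down
        ((1, 0, 0), -0.5, 180.0),       # branch 2 boundary (B_z = 0 tie)
    ])
    def test_branch_examples(self, B, f_z, expected):
        assert rotation_angle(vecs(B, f_z)) == pytest.approx(expected, abs=1e-9)

    def test_branch3_near_boundary(self):
        # just below B_z = 0 with F_z < 0: beta = -270 + angle(B, Z)
        b = rotation_angle(vecs((1, 0, -0.01), -0.5))
        ang = np.degrees(np.arccos(-0.01 / np.linalg.norm([1, 0, -0.01])))
        assert b == pytest.approx(-270.0 + ang, abs=1e-9)
        assert b == pytest.approx(-179.43, abs=0.01)

    def test_continuity_across_bz_zero(self):
        """Crossing B_z = 0 with F_z < 0 is continuous on the circle: the
        jump shrinks in proportion to the step across the boundary."""
        for eps in (1e-4, 1e-6, 1e-8):
            hi = rotation_angle(vecs((1, 0, +eps), -0.5))
            lo = rotation_angle(vecs((1, 0, -eps), -0.5))
            gap = abs(float(wrap_angle(hi - lo)))
            assert gap <= 2.1 * np.degrees(eps) + 1e-9

    def test_covers_the_full_circle(self):
        """A dense sweep of B directions with both F_z signs spans (-180, 180]."""
        t = np.radians(np.arange(0.5, 180.0, 1.0))
        betas = []
        for th in t:
            B = (np.sin(th), 0.0, np.cos(th))
            for f_z in (+0.5, -0.5):
                betas.append(rotation_angle(vecs(B, f_z)))
        betas = np.sort(np.array(betas))
        assert betas.min() > -180.0 and betas.max() <= 180.0
        gaps = np.diff(betas)
        wrap_gap = (betas[0] + 360.0) - betas[-1]
        assert max(gaps.max(), wrap_gap) < 2.5   # 1-deg grid -> ~2-deg spacing

    def test_zero_f_vector_is_an_error(self):
        with pytest.raises(ValueError):
            rotation_angle(ReferenceVectors(A=np.ones(3), B=np.ones(3),
                                            F=np.zeros(3)))


class TestFeasibility:
    def test_wedges_around_pm90(self):
        assert feasible_beta(0.0, -90.0)
        assert not feasible_beta(-45.0, -90.0)
        assert not feasible_beta(30.0, 75.0)
        assert feasible_beta(30.0, 55.0)
        assert feasible_beta(30.0, 125.0)

    def test_projection_lands_feasible(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            a = rng.uniform(-89, 89)
            b = rng.uniform(-180, 180)
            proj = nearest_feasible_beta(a, b)
            assert feasible_beta(a, proj)
            if feasible_beta(a, b, tol=-1e-3):
                assert proj == pytest.approx(b)


class TestLeafletsAndHeight:
    def test_leaflet_split_and_midplane(self, small_traj):
        traj, _ = small_traj
        leaf = assign_leaflets(traj.topology, traj.coords[0])
        assert len(leaf.upper_residues) == 36
        assert len(leaf.lower_residues) == 36
        assert set(leaf.upper_residues) & set(leaf.lower_residues) == set()
        z_up = traj.coords[0][leaf.upper_p_atoms, 2]
        z_lo = traj.coords[0][leaf.lower_p_atoms, 2]
        assert z_up.min() > leaf.midplane_z > z_lo.max()

    def test_no_phosphorus_is_an_error(self, small_traj):
        traj, _ = small_traj
        top = traj.topology
        import copy

        broken = copy.deepcopy(top)
        broken.elements = np.where(broken.elements == "P", "C", broken.elements)
        with pytest.raises(ValueError, match="phosphorus"):
            assign_leaflets(broken, traj.coords[0])

    def test_degenerate_flat_bilayer_is_an_error(self, small_traj):
        traj, _ = small_traj
        coords = traj.coords[0].copy()
        p = (traj.topology.moieties == "lipid") & (traj.topology.elements == "P")
        coords[p, 2] = 4.0
        with pytest.raises(ValueError, match="degenerate"):
            assign_leaflets(traj.topology, coords)

    def test_com_height_sign_convention(self, small_traj):
        traj, _ = small_traj
        top = traj.topology
        leaf = assign_leaflets(top, traj.coords[0])
        sel = np.flatnonzero(top.moieties == "amino-acid")
        coords = traj.coords[0].copy()
        surf = coords[leaf.upper_p_atoms, 2].mean()
        # place the protein COM exactly 1.5 nm above / 0.3 below the surface
        for target in (1.5, -0.3):
            com_now = np.average(coords[sel, 2], weights=top.masses[sel])
            coords[sel, 2] += (surf + target) - com_now
            assert com_height(coords, sel, top.masses, leaf) == \
                pytest.approx(target, abs=1e-12)

    def test_empty_selection_is_an_error(self, small_traj):
        traj, _ = small_traj
        leaf = assign_leaflets(traj.topology, traj.coords[0])
        with pytest.raises(ValueError, match="empty"):
            com_height(traj.coords[0], np.array([], dtype=int),
                       traj.topology.masses, leaf)


class TestReferenceVectors:
    def test_vectors_from_group_coms(self, small_traj, groups):
        traj, _ = small_traj
        v = reference_vectors(traj.coords[0], traj.topology, groups)
        assert np.linalg.norm(v.A) == pytest.approx(1.05, abs=1e-9)
        assert np.linalg.norm(v.B) == pytest.approx(1.10, abs=1e-9)
        assert abs(np.dot(v.A, v.B)) < 1e-9
        assert np.linalg.norm(v.F) == pytest.approx(1.0, abs=1e-12)

    def test_missing_group_is_an_error(self, small_traj, groups):
        import dataclasses

        traj, _ = small_traj
        bad = dataclasses.replace(groups, head=[999])
        with pytest.raises(ValueError, match="head"):
            reference_vectors(traj.coords[0], traj.topology, bad)


class TestOrientationSeries:
    def test_matches_ground_truth(self, small_traj, groups):
        traj, truth = small_traj
        series = orientation_series(traj, groups)
        assert series.n_frames == traj.n_frames
        assert np.abs(series.Z - truth.Z).max() < 1e-9
        assert np.abs(series.alpha - truth.alpha).max() < 1e-9
        assert np.abs(wrap_angle(series.beta - truth.beta)).max() < 1e-9

    def test_rigid_body_invariance(self, small_traj, groups):
        """xy translation and z rotation of the whole system change nothing."""
        traj, _ = small_traj
        base = orientation_series(traj, groups, unwrap=False)
        import copy

        moved = copy.deepcopy(traj)
        th = np.radians(73.0)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        centre = np.array([moved.boxes[0][0] / 2, moved.boxes[0][1] / 2, 0.0])
        moved.coords = (moved.coords - centre) @ R.T + centre + [0.37, -0.21, 0.0]
        out = orientation_series(moved, groups, unwrap=False)
        assert np.abs(out.Z - base.Z).max() < 1e-9
        assert np.abs(out.alpha - base.alpha).max() < 1e-9
        assert np.abs(wrap_angle(out.beta - base.beta)).max() < 1e-9

    def test_summary_reports_extremes(self, small_traj, groups):
        traj, truth = small_traj
        s = orientation_series(traj, groups).summary()
        assert s["n_frames"] == traj.n_frames
        assert s["beta_deg"]["min"] == pytest.approx(truth.beta.min(), abs=1e-9)
        assert s["alpha_deg"]["max"] == pytest.approx(truth.alpha.max(), abs=1e-9)
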