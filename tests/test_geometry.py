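"""Superposition, RMSD, Rg and distance kernels against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleftdyn.errors import FitError
from cleftdyn.geometry import (
    com_distance,
    count_within,
    min_distance,
    per_residue_rmsd,
    radius_of_gyration,
    rmsd_series,
    superpose,
    weighted_rmsd,
)
from cleftdyn.structio import Selection, Trajectory, select

from conftest import make_structure


def _rot(axis, deg):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    a = np.deg2rad(deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def grid_search_rmsd(mobile, reference, weights, step_deg=4.0):
    """Brute-force minimisation over a 3-Euler-angle grid (independent of
    the Kabsch route): centres both sets, scans rotations exhaustively."""
    w = np.asarray(weights, float)
    cm = (w[:, None] * mobile).sum(0) / w.sum()
    cr = (w[:, None] * reference).sum(0) / w.sum()
    x = mobile - cm
    y = reference - cr
    best = np.inf
    angles = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    half = np.deg2rad(np.arange(0.0, 180.0 + step_deg, step_deg))
    for a in angles:
        Ra = _rot([0, 0, 1], np.rad2deg(a))
        for b in half:
            Rb = _rot([0, 1, 0], np.rad2deg(b)) @ Ra
            for c in angles:
                R = _rot([0, 0, 1], np.rad2deg(c)) @ Rb
                d2 = ((x @ R.T - y) ** 2).sum(1)
                r = np.sqrt((w * d2).sum() / w.sum())
                if r < best:
                    best = r
    return best


class TestSuperpose:
    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        fit = superpose(x, x)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered(self, rng):
        x = rng.normal(size=(8, 3))
        y = x @ _rot([0, 0, 1], 90).T + np.array([1.0, 1.0, 1.0])
        fit = superpose(x, y)
        assert fit.rmsd <= 1e-10
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(fit.apply(x), y, atol=1e-9)

    def test_mirror_still_gives_proper_rotation(self, rng):
        x = rng.normal(size=(6, 3))
        y = x.copy()
        y[:, 0] *= -1  # reflected copy
        fit = superpose(x, y)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_search_oracle(self, rng):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 0.7, 0], [0.2, 0.1, 1.3]])
        y = x @ _rot([1, 2, 3], 37).T + 0.5 + rng.normal(scale=0.05, size=x.shape)
        w = np.array([1.0, 2.0, 1.0, 3.0])
        fit = superpose(x, y, w)
        oracle = grid_search_rmsd(x, y, w)
        assert fit.rmsd <= oracle + 1e-12  # optimality
        assert oracle - fit.rmsd <= 0.01  # grid resolution bound

    def test_rmsd_symmetric_for_equal_weights(self, rng):
        x = rng.normal(size=(7, 3))
        y = rng.normal(size=(7, 3))
        assert superpose(x, y).rmsd == pytest.approx(superpose(y, x).rmsd, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(FitError):
            superpose(line, line)

    def test_optimality_vs_random_rigid_placements(self, rng):
        x = rng.normal(size=(12, 3))
        y = rng.normal(size=(12, 3))
        best = superpose(x, y).rmsd
        for _ in range(100):
            axis = rng.normal(size=3)
            R = _rot(axis, rng.uniform(0, 360))
            t = rng.normal(size=3)
            assert weighted_rmsd(x @ R.T + t, y) >= best - 1e-9


def _traj_from_frames(s, frames, dt=10.0):
    return Trajectory(s, dt * np.arange(len(frames)), np.asarray(frames))


class TestRmsdSeries:
    @pytest.fixture()
    def s(self):
        return make_structure(
            [
                ("N", "N", "GLY", 1, "A", (0.0, 0.0, 0.0)),
                ("CA", "C", "GLY", 1, "A", (0.3, 0.0, 0.0)),
                ("C", "C", "GLY", 1, "A", (0.0, 0.4, 0.0)),
                ("O", "O", "GLY", 1, "A", (0.0, 0.0, 0.5)),
                ("CA", "C", "GLY", 2, "A", (1.0, 1.0, 1.0)),
            ]
        )

    def test_identical_frames_give_zero(self, s):
        traj = _traj_from_frames(s, [s.coords, s.coords])
        sel = select(s, "all")
        np.testing.assert_allclose(rmsd_series(traj, s, sel), 0.0, atol=1e-10)

    def test_translation_removed_by_fit(self, s):
        traj = _traj_from_frames(s, [s.coords + np.array([1.0, 1.0, 1.0])])
        sel = select(s, "all")
        assert rmsd_series(traj, s, sel)[0] == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_displacement(self, s):
        # fit on residue 1 (identical), measure the displaced lone CA
        frame = s.coords.copy()
        frame[4] += np.array([0.0, 0.0, 0.12])
        traj = _traj_from_frames(s, [frame])
        fit_sel = select(s, "resid 1")
        calc_sel = select(s, "resid 2")
        out = rmsd_series(traj, s, fit_sel, calc_sel)
        assert out[0] == pytest.approx(0.12, abs=1e-9)

    def test_mean_over_frames_matches_formula(self, s, rng):
        # two frames with different displacements of the calc atom
        f1, f2 = s.coords.copy(), s.coords.copy()
        f1[4] += [0.1, 0, 0]
        f2[4] += [0, 0.2, 0]
        traj = _traj_from_frames(s, [f1, f2])
        out = rmsd_series(traj, s, select(s, "resid 1"), select(s, "resid 2"))
        np.testing.assert_allclose(out, [0.1, 0.2], atol=1e-9)


class TestPerResidueRmsd:
    def test_identical_gives_zeros(self, toy_system):
        traj = toy_system.trajectory
        top = toy_system.structure
        ref_traj = Trajectory(top, np.array([0.0]), top.coords[None])
        out = per_residue_rmsd(ref_traj, top, select(top, "backbone"))
        assert all(v == pytest.approx(0.0, abs=1e-10) for v in out.values())

    def test_planted_displacement_recovered(self):
        records = []
        for r in range(1, 11):
            for name, el, off in (("N", "N", 0.0), ("CA", "C", 0.1), ("C", "C", 0.2),
                                  ("O", "O", 0.3)):
                records.append((name, el, "GLY", r, "A", (0.5 * r + off, 0.1 * ((r + 1) % 3), 0.05 * (r % 4))))
        s = make_structure(records)
        frame = s.coords.copy()
        moved = slice(0, 4)  # residue 1 backbone
        frame[moved] += np.array([0.0, 0.0, 0.2])
        traj = Trajectory(s, np.array([0.0]), frame[None])
        # fit on the (much larger) undisplaced remainder
        out = per_residue_rmsd(traj, s, select(s, "backbone and not resid 1"))
        assert out[("A", 1)] == pytest.approx(0.2, rel=0.05)
        others = [v for k, v in out.items() if k != ("A", 1)]
        assert max(others) < 0.01  # fit leakage stays small


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(np.zeros((1, 3)), np.array([12.0])) == 0.0

    def test_two_unit_masses_give_half_separation(self):
        c = np.array([[0.0, 0, 0], [0.8, 0, 0]])
        assert radius_of_gyration(c, np.ones(2)) == pytest.approx(0.4)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 5.0))
    def test_rigid_invariance_and_scaling(self, seed, alpha):
        rng = np.random.default_rng(seed)
        c = rng.normal(size=(15, 3))
        m = rng.uniform(1, 16, size=15)
        rg = radius_of_gyration(c, m)
        moved = c @ _rot([1, 1, 0], 63.0).T + np.array([2.0, -1.0, 0.5])
        assert radius_of_gyration(moved, m) == pytest.approx(rg, rel=1e-9)
        assert radius_of_gyration(alpha * c, m) == pytest.approx(alpha * rg, rel=1e-9)


class TestDistances:
    def test_two_atoms(self):
        s = make_structure(
            [
                ("CA", "C", "GLY", 1, "A", (0, 0, 0)),
                ("CA", "C", "GLY", 2, "A", (0.3, 0, 0)),
            ]
        )
        a, b = select(s, "resid 1"), select(s, "resid 2")
        assert min_distance(a, b, s.coords) == pytest.approx(0.3)
        assert min_distance(b, a, s.coords) == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 4, size=(100, 3))
        a = Selection(np.arange(50), 100)
        b = Selection(np.arange(50, 100), 100)
        oracle = min(
            np.linalg.norm(coords[i] - coords[j])
            for i in a.indices
            for j in b.indices
        )
        assert min_distance(a, b, coords) == pytest.approx(oracle, abs=1e-12)

    def test_overlapping_selections_rejected(self):
        coords = np.zeros((4, 3))
        with pytest.raises(ValueError, match="overlap"):
            min_distance(Selection([0, 1], 4), Selection([1, 2], 4), coords)

    def test_com_distance_identical_selection_is_zero(self):
        coords = np.arange(12.0).reshape(4, 3)
        m = np.ones(4)
        sel = Selection([0, 1, 2, 3], 4)
        assert com_distance(sel, sel, coords, m) == 0.0

    def test_com_distance_hand_computed(self):
        coords = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [2.0, 0, 0], [3.0, 0, 0], [2.5, 1.0, 0]]
        )
        m = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 1.0])
        a = Selection([0, 1, 2], 6)
        b = Selection([3, 4, 5], 6)
        ca = (m[:3, None] * coords[:3]).sum(0) / 4.0
        cb = (m[3:, None] * coords[3:]).sum(0) / 4.0
        assert com_distance(a, b, coords, m) == pytest.approx(np.linalg.norm(ca - cb))

    def test_min_le_com_plus_extents_on_blobs(self, rng):
        c1 = rng.normal(scale=0.2, size=(20, 3))
        c2 = rng.normal(scale=0.2, size=(20, 3)) + [3.0, 0, 0]
        coords = np.vstack([c1, c2])
        m = np.ones(40)
        a, b = Selection(np.arange(20), 40), Selection(np.arange(20, 40), 40)
        ext = c1.std() * 4 + c2.std() * 4
        assert min_distance(a, b, coords) <= com_distance(a, b, coords, m) + ext


class TestCountWithin:
    def _zn_waters(self, n_in, n_out):
        records = [("ZN", "ZN", "ZN", 1, "Z", (0.0, 0.0, 0.0))]
        rid = 10
        for i in range(n_in):
            ang = 2 * np.pi * i / max(n_in, 1)
            records.append(
                ("O", "O", "HOH", rid, "W", (0.3 * np.cos(ang), 0.3 * np.sin(ang), 0.0))
            )
            rid += 1
        for i in range(n_out):
            records.append(("O", "O", "HOH", rid, "W", (1.0 + 0.2 * i, 0.0, 0.0)))
            rid += 1
        return make_structure(records)

    def test_none_within(self):
        s = self._zn_waters(0, 5)
        zn = select(s, "resname ZN")
        waters = select(s, "water")
        assert count_within(zn, waters, 0.35, s.coords, s) == 0

    def test_planted_count_exact(self):
        s = self._zn_waters(7, 5)
        zn = select(s, "resname ZN")
        waters = select(s, "water")
        assert count_within(zn, waters, 0.35, s.coords, s) == 7

    def test_monotone_in_cutoff(self):
        s = self._zn_waters(7, 5)
        zn = select(s, "resname ZN")
        waters = select(s, "water")
        counts = [
            count_within(zn, waters, c, s.coords, s)
            for c in (0.1, 0.35, 0.9, 1.2, 3.0)
        ]
        assert counts == sorted(counts)
        assert counts[-1] == 12
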