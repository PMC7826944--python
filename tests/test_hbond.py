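"""Donor/acceptor assignment, hydrogen placement, detection and occupancy."""

import numpy as np
import pytest

from cleftdyn.errors import MappingError
from cleftdyn.hbond import (
    GroupingScheme,
    HBondCriteria,
    assign_donors_acceptors,
    detect_hbonds,
    group_cofactor_hbonds,
    occupancy,
    place_polar_hydrogens,
)
from cleftdyn.structio import Trajectory

from conftest import make_structure


def _water(resid, origin, with_h=True, chain="W"):
    o = np.asarray(origin, float)
    rec = [("O", "O", "HOH", resid, chain, o)]
    if with_h:
        rec += [
            ("H1", "H", "HOH", resid, chain, o + [0.095, 0.03, 0]),
            ("H2", "H", "HOH", resid, chain, o + [-0.095, 0.03, 0]),
        ]
    return rec


class TestAssignment:
    def test_water_with_hydrogens_is_donor_and_acceptor(self):
        s = make_structure(_water(1, (0, 0, 0)) + _water(2, (1, 0, 0)))
        da = assign_donors_acceptors(s)
        assert 0 in da.donors and len(da.donors[0]) == 2
        assert 0 in da.acceptors

    def test_backbone_amide_and_carbonyl(self):
        s = make_structure(
            [
                ("N", "N", "GLY", 1, "A", (0.0, 0, 0)),
                ("H", "H", "GLY", 1, "A", (0.0, 0.1, 0)),
                ("CA", "C", "GLY", 1, "A", (0.15, 0, 0)),
                ("C", "C", "GLY", 1, "A", (0.3, 0, 0)),
                ("O", "O", "GLY", 1, "A", (0.3, -0.12, 0)),
            ]
        )
        da = assign_donors_acceptors(s)
        assert list(da.donors) == [0]  # amide N with its H
        assert list(da.acceptors) == [4]  # carbonyl O

    def test_deprotonated_asp_is_acceptor_only(self):
        s = make_structure(
            [
                ("CB", "C", "ASP", 5, "A", (0, 0, 0)),
                ("CG", "C", "ASP", 5, "A", (0.15, 0, 0)),
                ("OD1", "O", "ASP", 5, "A", (0.25, 0.1, 0)),
                ("OD2", "O", "ASP", 5, "A", (0.25, -0.1, 0)),
            ]
        )
        da = assign_donors_acceptors(s)
        assert not da.donors
        assert set(da.acceptors) == {2, 3}

    def test_his_ring_n_without_h_becomes_acceptor(self):
        s = make_structure(
            [
                ("CG", "C", "HIS", 7, "A", (0, 0, 0)),
                ("ND1", "N", "HIS", 7, "A", (0.14, 0.05, 0)),
                ("NE2", "N", "HIS", 7, "A", (0.0, 0.22, 0)),
            ]
        )
        da = assign_donors_acceptors(s)
        assert set(da.acceptors) == {1, 2}


class TestPlacement:
    def test_protonated_structure_unchanged(self):
        s = make_structure(_water(1, (0, 0, 0)))
        out = place_polar_hydrogens(s)
        assert out is s

    def test_lone_amide_gets_anti_hydrogen(self):
        s = make_structure(
            [
                ("N", "N", "GLY", 1, "A", (0.0, 0.0, 0)),
                ("CA", "C", "GLY", 1, "A", (0.15, 0.0, 0)),
                ("C", "C", "GLY", 1, "A", (0.25, 0.12, 0)),
                ("O", "O", "GLY", 1, "A", (0.2, 0.24, 0)),
            ]
        )
        out = place_polar_hydrogens(s)
        assert out.n_atoms == 5
        h = out.coords[np.nonzero(out.elements == "H")[0][0]]
        n = s.coords[0]
        assert np.linalg.norm(h - n) == pytest.approx(0.10, abs=0.001)
        # anti to the carbonyl direction: NH opposes N->O
        no = s.coords[3] - n
        assert (h - n) @ no < 0

    def test_serine_hydroxyl_torsion_minimises_acceptor_distance(self):
        # SER OG next to a carboxylate: the placed H must be the torsion-scan
        # optimum, re-verified here with an independent 1-degree scan
        s = make_structure(
            [
                ("CB", "C", "SER", 1, "A", (0.0, 0.0, 0.0)),
                ("OG", "O", "SER", 1, "A", (0.14, 0.0, 0.0)),
                ("OD1", "O", "ASP", 2, "A", (0.30, 0.2, 0.05)),
            ]
        )
        out = place_polar_hydrogens(s)
        hg = out.coords[np.nonzero(out.elements == "H")[0][0]]
        og, cb, od1 = s.coords[1], s.coords[0], s.coords[2]
        d_placed = np.linalg.norm(hg - od1)

        w = (cb - og) / np.linalg.norm(cb - og)
        e1 = np.array([0.0, 1.0, 0.0]) - w * w[1]
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(w, e1)
        ang = np.deg2rad(109.5)
        best = np.inf
        for phi in np.deg2rad(np.arange(0, 360, 1.0)):
            d = np.cos(ang) * w + np.sin(ang) * (np.cos(phi) * e1 + np.sin(phi) * e2)
            best = min(best, np.linalg.norm(og + 0.1 * d - od1))
        assert d_placed <= best + 0.002

    def test_idempotent_after_placement(self):
        s = make_structure(
            [
                ("N", "N", "GLY", 1, "A", (0.0, 0.0, 0)),
                ("CA", "C", "GLY", 1, "A", (0.15, 0.0, 0)),
                ("C", "C", "GLY", 1, "A", (0.25, 0.12, 0)),
                ("O", "O", "GLY", 1, "A", (0.2, 0.24, 0)),
            ]
        )
        once = place_polar_hydrogens(s)
        twice = place_polar_hydrogens(once)
        assert twice.n_atoms == once.n_atoms


def _donor_acceptor_pair(d_no, angle_deg=0.0):
    """Amide N-H pointing at a water O at distance d_no, with the H tilted
    off the N->O axis by angle_deg."""
    a = np.deg2rad(angle_deg)
    h = np.array([0.1 * np.cos(a), 0.1 * np.sin(a), 0.0])
    return make_structure(
        [
            ("N", "N", "GLY", 1, "A", (0.0, 0.0, 0.0)),
            ("H", "H", "GLY", 1, "A", h),
            ("CA", "C", "GLY", 1, "A", (-0.15, 0.0, 0.0)),
            ("O", "O", "HOH", 2, "W", (d_no, 0.0, 0.0)),
        ]
    )


class TestDetection:
    def test_ideal_linear_bond_detected(self):
        s = _donor_acceptor_pair(0.29, angle_deg=0.0)
        bonds = detect_hbonds(s.coords, s)
        assert len(bonds) == 1
        assert bonds[0].donor_residue == ("A", 1)
        assert bonds[0].acceptor_residue == ("W", 2)

    def test_distance_cutoff_enforced(self):
        s = _donor_acceptor_pair(0.36, angle_deg=0.0)
        assert detect_hbonds(s.coords, s) == []

    @pytest.mark.parametrize("angle,expected", [(20.0, 1), (45.0, 0)])
    def test_angle_cutoff(self, angle, expected):
        s = _donor_acceptor_pair(0.30, angle_deg=angle)
        assert len(detect_hbonds(s.coords, s)) == expected

    def test_dha_convention(self):
        s = _donor_acceptor_pair(0.30, angle_deg=0.0)
        c = HBondCriteria(convention="dha")
        assert len(detect_hbonds(s.coords, s, c)) == 1  # perfectly linear

    def test_monotone_in_criteria(self, rng):
        s, _ = _random_toy(rng)
        tight = {
            (b.donor, b.acceptor)
            for b in detect_hbonds(s.coords, s, HBondCriteria(0.30, 20.0))
        }
        loose = {
            (b.donor, b.acceptor)
            for b in detect_hbonds(s.coords, s, HBondCriteria(0.35, 30.0))
        }
        assert tight <= loose

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        s, da = _random_toy(rng)
        c = HBondCriteria()
        got = {
            (b.donor, b.hydrogen, b.acceptor) for b in detect_hbonds(s.coords, s, c)
        }
        expected = _brute_force_triples(s, da, c)
        assert got == expected


def _random_toy(rng, n_units=10):
    """~40 atoms: amide-like donors and water acceptors at random poses."""
    records = []
    resid = 1
    for _ in range(n_units // 2):
        pos = rng.uniform(0, 1.2, size=3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        records += [
            ("N", "N", "GLY", resid, "A", pos),
            ("H", "H", "GLY", resid, "A", pos + 0.1 * u),
            ("CA", "C", "GLY", resid, "A", pos - 0.15 * u),
        ]
        resid += 1
    for _ in range(n_units // 2):
        records += _water(resid, rng.uniform(0, 1.2, size=3))
        resid += 1
    s = make_structure(records)
    return s, assign_donors_acceptors(s)


def _brute_force_triples(s, da, c):
    """Independent triple-loop re-derivation of the detection rule."""
    out = set()
    rindex = s.residue_index()
    for d, hs in da.donors.items():
        for a in da.acceptors:
            a = int(a)
            if rindex[a] == rindex[d]:
                continue
            v_da = s.coords[a] - s.coords[d]
            if np.linalg.norm(v_da) > c.d_max:
                continue
            for h in hs:
                v_dh = s.coords[h] - s.coords[d]
                cosang = v_dh @ v_da / (
                    np.linalg.norm(v_dh) * np.linalg.norm(v_da)
                )
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < c.angle_max:
                    out.add((d, h, a))
                    break
    return out


class TestOccupancy:
    def _two_state_traj(self, pattern, dt=10.0):
        """Frames alternate bound/unbound according to `pattern`."""
        s = _donor_acceptor_pair(0.29)
        far = s.coords.copy()
        far[3, 0] = 1.5  # acceptor out of range
        frames = [s.coords if on else far for on in pattern]
        return Trajectory(s, dt * np.arange(len(pattern)), np.array(frames))

    def test_always_present_is_one_regardless_of_stride(self):
        traj = self._two_state_traj([1] * 8)
        for stride in (10.0, 20.0, 40.0):
            table = occupancy(traj, stride_ps=stride)
            assert table.table.iloc[0]["fraction"] == 1.0

    def test_alternating_presence_is_half(self):
        traj = self._two_state_traj([1, 0] * 5)
        table = occupancy(traj, stride_ps=10.0)
        assert table.table.iloc[0]["fraction"] == pytest.approx(0.5)

    def test_min_fraction_flags_rare_pairs(self):
        traj = self._two_state_traj([1, 0, 0, 0, 0] * 2)
        table = occupancy(traj, stride_ps=10.0, min_fraction=0.30)
        row = table.table.iloc[0]
        assert row["fraction"] == pytest.approx(0.2)
        assert not row["reported"]
        assert len(table.reported()) == 0

    def test_stride_below_frame_spacing_rejected(self):
        traj = self._two_state_traj([1, 1])
        with pytest.raises(ValueError, match="stride"):
            occupancy(traj, stride_ps=1.0)


class TestCofactorGrouping:
    def _cofactor_toy(self):
        records = []
        # three protein donors, each aimed at one cofactor moiety
        for resid, x in ((1, 0.0), (2, 1.0), (3, 2.0)):
            records += [
                ("N", "N", "GLY", resid, "A", (x, 0.0, 0.0)),
                ("H", "H", "GLY", resid, "A", (x, 0.1, 0.0)),
                ("CA", "C", "GLY", resid, "A", (x, -0.15, 0.0)),
            ]
        records += [
            ("N1A", "N", "NAP", 9, "A", (0.0, 0.30, 0.0)),  # adenine
            ("O7N", "O", "NAP", 9, "A", (1.0, 0.30, 0.0)),  # nicotinamide
            ("O2A", "O", "NAP", 9, "A", (2.0, 0.30, 0.0)),  # pyrophosphate
        ]
        s = make_structure(records)
        return Trajectory(s, np.array([0.0]), s.coords[None])

    def test_one_row_per_moiety(self):
        traj = self._cofactor_toy()
        table = occupancy(traj, stride_ps=10.0)
        assert (table.table["group"] == "cofactor").all()
        out = group_cofactor_hbonds(table, traj.topology)
        assert sorted(out.table["group"]) == [
            "cofactor-adenine",
            "cofactor-dinucleotide/phosphate",
            "cofactor-nicotinamide",
        ]

    def test_unmapped_cofactor_atom_raises(self):
        traj = self._cofactor_toy()
        table = occupancy(traj, stride_ps=10.0)
        with pytest.raises(MappingError):
            group_cofactor_hbonds(table, traj.topology, moiety_map={"N1A": "adenine"})


class TestGroupingTags:
    def test_tag_rules(self):
        s = make_structure(
            [
                ("CA", "C", "GLY", 10, "A", (0, 0, 0)),      # rossmann, chain A
                ("CA", "C", "GLY", 200, "A", (1, 0, 0)),     # helical, chain A
                ("CA", "C", "GLY", 10, "D", (2, 0, 0)),      # rossmann, chain D
                ("CA", "C", "GLY", 20, "A", (3, 0, 0)),      # rossmann, chain A
                ("N1A", "N", "NAP", 500, "A", (4, 0, 0)),
                ("O", "O", "HOH", 600, "W", (5, 0, 0)),
            ]
        )
        g = GroupingScheme(domains=(("rossmann", 1, 181), ("helical", 182, 387)))
        assert g.tag(s, 0, 1) == "interdomain"
        assert g.tag(s, 0, 2) == "inter-monomer"
        assert g.tag(s, 0, 3) == "intra-domain"
        assert g.tag(s, 0, 4) == "cofactor"
        assert g.tag(s, 4, 5) == "water"

    def test_toy_system_inventory_groups(self, toy_system):
        """Bound-pose inventory: cofactor rows present throughout, water
        rows flagged separately (never part of the published inventories)."""
        traj = toy_system.trajectory.strided(20)
        table = occupancy(traj, stride_ps=200.0)
        groups = set(table.table["group"])
        assert "cofactor" in groups
        assert "water" in groups
        assert table.mean_bonds_per_frame["cofactor"] > 0
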