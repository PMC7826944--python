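"""Geometric hydrogen-bond detection and occupancy accounting.

A hydrogen bond is called when the donor–acceptor heavy-atom distance is
at most ``d_max`` (default 0.35 nm) and the angle between the D→H and D→A
vectors is below ``angle_max`` (default 30°) — the donor-centred convention
used by the GROMACS analysis tools.  The alternative D–H···A linearity
convention (angle ≥ 150°) is available via ``HBondCriteria.convention``.
Bonds are inventoried at the residue-pair level: all atom-level contacts
between two residues collapse to one occupancy row.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import MappingError
from .structio import Structure, Trajectory
from .templates import NADP_MOIETY_MAP, SP2, SP3, WATER, residue_template

H_BOND_MAX = 0.125  # nm, hydrogen considered bonded to its heavy atom
HEAVY_BOND_MAX = 0.18  # nm, heavy-heavy covalent bond for neighbour frames
NH_LENGTH = 0.10  # nm, idealised polar X-H bond length


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric cutoff set; ``convention`` is 'donor-centred' or 'dha'."""

    d_max: float = 0.35
    angle_max: float = 30.0
    convention: str = "donor-centred"
    dha_min: float = 150.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0 < self.angle_max < 90):
            raise ValueError("angle_max must be in (0, 90) degrees")
        if self.convention not in ("donor-centred", "dha"):
            raise ValueError(f"unknown convention {self.convention!r}")


@dataclass(frozen=True)
class HBond:
    """One detected bond; indices refer to the structure's atom order."""

    donor: int
    hydrogen: int | None
    acceptor: int
    donor_residue: tuple[str, int]
    acceptor_residue: tuple[str, int]


@dataclass
class DonorAcceptorSet:
    """Donor heavy atoms with their bonded hydrogens, plus acceptor atoms."""

    donors: dict[int, list[int]]
    acceptors: np.ndarray


@dataclass
class OccupancyTable:
    """Residue-pair occupancy rows plus per-frame simultaneous-bond counts.

    ``table`` columns: donor_res, acceptor_res, donor_atom, acceptor_atom,
    group, fraction, mean_per_frame, reported.  ``mean_bonds_per_frame``
    holds the average number of simultaneously present residue-pair bonds,
    overall and per grouping tag.
    """

    table: pd.DataFrame
    n_frames_analyzed: int
    min_fraction: float
    mean_bonds_per_frame: dict[str, float] = field(default_factory=dict)

    def reported(self) -> pd.DataFrame:
        return self.table[self.table["reported"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _bonded_hydrogens(s: Structure) -> dict[int, list[int]]:
    """heavy index -> bonded hydrogen indices (distance < 0.125 nm)."""
    elements = np.char.upper(s.elements.astype(str))
    h_idx = np.nonzero(elements == "H")[0]
    heavy_idx = np.nonzero(elements != "H")[0]
    out: dict[int, list[int]] = defaultdict(list)
    if len(h_idx) == 0 or len(heavy_idx) == 0:
        return out
    tree = cKDTree(s.coords[heavy_idx])
    d, j = tree.query(s.coords[h_idx])
    for h, dist, jj in zip(h_idx, d, j):
        if dist < H_BOND_MAX:
            out[int(heavy_idx[jj])].append(int(h))
    return out


def assign_donors_acceptors(s: Structure) -> DonorAcceptorSet:
    """Identify donor and acceptor atoms from elements, bonded hydrogens and
    residue templates.

    Donors are N/O atoms with at least one bonded hydrogen.  Acceptors come
    from the residue template; for residues without a template the generic
    rule (any O; any N without bonded hydrogen) applies with a warning,
    and a template-less residue with no hydrogens at all is skipped.
    """
    elements = np.char.upper(s.elements.astype(str))
    h_by_heavy = _bonded_hydrogens(s)
    rindex = s.residue_index()

    donors: dict[int, list[int]] = {}
    acceptors: list[int] = []
    warned: set[str] = set()
    for i in range(s.n_atoms):
        el = elements[i]
        if el not in ("N", "O"):
            continue
        resname = str(s.resnames[i]).upper()
        name = str(s.names[i]).upper()
        tmpl = residue_template(resname)
        hs = h_by_heavy.get(i, [])
        if hs:
            donors[i] = hs
        if tmpl is None:
            if resname not in warned:
                warned.add(resname)
                res_has_h = any(
                    elements[j] == "H"
                    for j in np.nonzero(rindex == rindex[i])[0]
                )
                if not res_has_h:
                    warnings.warn(
                        f"residue {resname} has no template and no hydrogens; skipped"
                    )
                    continue
                warnings.warn(
                    f"residue {resname} has no template; using generic N/O rules"
                )
            if el == "O" or (el == "N" and not hs):
                acceptors.append(i)
        else:
            if name in tmpl["acceptors"]:
                acceptors.append(i)
            elif el == "N" and not hs and name in tmpl["donors"]:
                # ring N modelled as donor in the template but carrying no
                # proton in this structure: lone pair available
                acceptors.append(i)
    return DonorAcceptorSet(donors=donors, acceptors=np.asarray(acceptors, dtype=int))


# ---------------------------------------------------------------------------
# hydrogen placement
# ---------------------------------------------------------------------------


def _heavy_neighbors(s: Structure, elements: np.ndarray) -> dict[int, list[int]]:
    heavy_idx = np.nonzero(elements != "H")[0]
    tree = cKDTree(s.coords[heavy_idx])
    pairs = tree.query_pairs(HEAVY_BOND_MAX)
    out: dict[int, list[int]] = defaultdict(list)
    for a, b in pairs:
        ia, ib = int(heavy_idx[a]), int(heavy_idx[b])
        out[ia].append(ib)
        out[ib].append(ia)
    return out


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _sp2_directions(x: np.ndarray, neighbors: list[np.ndarray], n_h: int) -> list[np.ndarray]:
    """In-plane directions completing a trigonal centre."""
    if len(neighbors) >= 2:
        u = sum((x - nb) / np.linalg.norm(x - nb) for nb in neighbors)
        norm = np.linalg.norm(u)
        d = u / norm if norm > 1e-8 else _perp(x - neighbors[0])
        return [d][:n_h]
    nb = neighbors[0]
    u = (x - nb) / np.linalg.norm(x - nb)
    p = _perp(u)
    out = []
    for sign in (1.0, -1.0):
        out.append(np.cos(np.pi / 3) * u + sign * np.sin(np.pi / 3) * p)
    return out[:n_h]


def _sp3_direction(
    x: np.ndarray,
    neighbor: np.ndarray,
    acceptor_coords: np.ndarray | None,
) -> np.ndarray:
    """Rotatable X-H: scan the torsion circle at 109.5° from the X-B bond and
    point at the nearest acceptor (falls back to an arbitrary torsion)."""
    w = (neighbor - x) / np.linalg.norm(neighbor - x)
    e1 = _perp(w)
    e2 = np.cross(w, e1)
    ang = np.deg2rad(109.5)
    best_d, best = np.inf, None
    phis = np.deg2rad(np.arange(0, 360, 5.0))
    for phi in phis:
        d = np.cos(ang) * w + np.sin(ang) * (np.cos(phi) * e1 + np.sin(phi) * e2)
        h = x + NH_LENGTH * d
        if acceptor_coords is None or len(acceptor_coords) == 0:
            return d
        dist = np.linalg.norm(acceptor_coords - h, axis=1).min()
        if dist < best_d:
            best_d, best = dist, d
    return best


def place_polar_hydrogens(s: Structure) -> Structure:
    """Add missing hydrogens on template donor N/O atoms (idealised 0.10 nm
    geometry); a fully protonated structure is returned unchanged."""
    from .structio import Atom

    elements = np.char.upper(s.elements.astype(str))
    h_by_heavy = _bonded_hydrogens(s)
    neighbors = _heavy_neighbors(s, elements)
    rindex = s.residue_index()

    # acceptor positions guide rotatable hydroxyls (excluding, per donor,
    # acceptors of the donor's own residue)
    da = assign_donors_acceptors(s)
    acc_idx = np.asarray(da.acceptors, dtype=int)
    acc_coords = s.coords[acc_idx] if len(acc_idx) else np.empty((0, 3))
    acc_res = rindex[acc_idx] if len(acc_idx) else np.empty(0, dtype=int)

    new_atoms: list[Atom] = []
    next_serial = int(s.serials.max()) + 1
    res_names_cache: dict[int, set[str]] = {}
    for i in range(s.n_atoms):
        resname = str(s.resnames[i]).upper()
        tmpl = residue_template(resname)
        if tmpl is None:
            continue
        name = str(s.names[i]).upper()
        if name not in tmpl["donors"]:
            continue
        n_expected, geom = tmpl["donors"][name]
        have = len(h_by_heavy.get(i, []))
        missing = n_expected - have
        if missing <= 0:
            continue
        nbrs = [s.coords[j] for j in neighbors.get(i, [])]
        if not nbrs:
            warnings.warn(f"cannot place H on isolated atom {name} of {resname}")
            continue
        x = s.coords[i]
        if geom == SP2:
            dirs = _sp2_directions(x, nbrs, missing)
        elif geom in (SP3, WATER):
            near = None
            if len(acc_coords):
                mask = (np.linalg.norm(acc_coords - x, axis=1) <= 0.35) & (
                    acc_res != rindex[i]
                )
                near = acc_coords[mask]
            d1 = _sp3_direction(x, nbrs[0], near)
            dirs = [d1]
            if missing > 1:
                p = _perp(d1)
                ang = np.deg2rad(104.5)
                dirs.append(np.cos(ang) * d1 + np.sin(ang) * p)
            if missing > 2:
                dirs.append(np.cos(ang) * d1 - np.sin(ang) * p)
        else:  # pragma: no cover
            continue
        res_atoms = res_names_cache.setdefault(
            int(rindex[i]),
            {str(s.names[j]).upper() for j in np.nonzero(rindex == rindex[i])[0]},
        )
        for k, d in enumerate(dirs[:missing]):
            suffix = name[1:] if len(name) > 1 else ""
            hname = f"H{suffix}"
            n = k + have + 1
            while hname in res_atoms:
                hname = f"H{suffix}{n}"
                n += 1
            res_atoms.add(hname)
            new_atoms.append(
                Atom(
                    next_serial, hname, "H", 1.008, str(s.resnames[i]),
                    int(s.resids[i]), str(s.chains[i]), x + NH_LENGTH * d,
                )
            )
            next_serial += 1
    if not new_atoms:
        return s

    # insert hydrogens directly after their residue so residues stay contiguous
    by_res: dict[tuple[str, int], list[Atom]] = defaultdict(list)
    for a in new_atoms:
        by_res[(a.chain, a.resid)].append(a)
    atoms: list[Atom] = []
    all_atoms = s.atoms
    for idx, a in enumerate(all_atoms):
        atoms.append(a)
        last_of_res = (
            idx + 1 == len(all_atoms)
            or (all_atoms[idx + 1].chain, all_atoms[idx + 1].resid) != (a.chain, a.resid)
        )
        if last_of_res:
            atoms.extend(by_res.pop((a.chain, a.resid), []))
    return Structure.from_atoms(atoms, title=s.title)


# ---------------------------------------------------------------------------
# detection and occupancy
# ---------------------------------------------------------------------------


def detect_hbonds(
    frame: np.ndarray,
    s: Structure,
    c: HBondCriteria = HBondCriteria(),
    assignment: DonorAcceptorSet | None = None,
) -> list[HBond]:
    """All hydrogen bonds in one frame (different residues only)."""
    if assignment is None:
        assignment = assign_donors_acceptors(s)
    frame = np.asarray(frame, dtype=float)
    donors = list(assignment.donors)
    acceptors = assignment.acceptors
    if not donors or len(acceptors) == 0:
        return []
    rindex = s.residue_index()
    dtree = cKDTree(frame[donors])
    atree = cKDTree(frame[acceptors])
    pairs = dtree.query_ball_tree(atree, r=c.d_max)
    out: list[HBond] = []
    for di, acc_list in enumerate(pairs):
        d = donors[di]
        for aj in acc_list:
            a = int(acceptors[aj])
            if a == d or rindex[a] == rindex[d]:
                continue
            v_da = frame[a] - frame[d]
            n_da = np.linalg.norm(v_da)
            if n_da > c.d_max:
                continue
            for h in assignment.donors[d]:
                if c.convention == "donor-centred":
                    v_dh = frame[h] - frame[d]
                    cosang = v_dh @ v_da / (np.linalg.norm(v_dh) * n_da)
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    ok = ang < c.angle_max
                else:  # D-H...A linearity
                    v_hd = frame[d] - frame[h]
                    v_ha = frame[a] - frame[h]
                    cosang = v_hd @ v_ha / (
                        np.linalg.norm(v_hd) * np.linalg.norm(v_ha)
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    ok = ang >= c.dha_min
                if ok:
                    out.append(
                        HBond(
                            donor=d, hydrogen=int(h), acceptor=a,
                            donor_residue=(str(s.chains[d]), int(s.resids[d])),
                            acceptor_residue=(str(s.chains[a]), int(s.resids[a])),
                        )
                    )
                    break
    return out


def residue_label(s: Structure, atom_index: int) -> str:
    return (
        f"{s.resnames[atom_index]}{int(s.resids[atom_index])}"
        f":{s.chains[atom_index]}"
    )


@dataclass(frozen=True)
class GroupingScheme:
    """Rules that tag each residue pair for the occupancy inventory."""

    cofactor_resnames: frozenset = frozenset({"NAP", "NDP"})
    domains: tuple = (("rossmann", 1, 181), ("helical", 182, 387))

    def domain_of(self, resid: int) -> str | None:
        for name, lo, hi in self.domains:
            if lo <= resid <= hi:
                return name
        return None

    def tag(self, s: Structure, i: int, j: int) -> str:
        from .structio import WATER_RESNAMES

        rn_i = str(s.resnames[i]).upper()
        rn_j = str(s.resnames[j]).upper()
        if rn_i in WATER_RESNAMES or rn_j in WATER_RESNAMES:
            return "water"
        if rn_i in self.cofactor_resnames or rn_j in self.cofactor_resnames:
            return "cofactor"
        if str(s.chains[i]) != str(s.chains[j]):
            return "inter-monomer"
        di, dj = self.domain_of(int(s.resids[i])), self.domain_of(int(s.resids[j]))
        if di is not None and dj is not None and di != dj:
            return "interdomain"
        return "intra-domain"


def occupancy(
    traj: Trajectory,
    c: HBondCriteria = HBondCriteria(),
    stride_ps: float = 10.0,
    min_fraction: float = 0.30,
    grouping: GroupingScheme = GroupingScheme(),
    assignment: DonorAcceptorSet | None = None,
) -> OccupancyTable:
    """Residue-pair hydrogen-bond occupancy over a trajectory.

    Frames are analysed every ``stride_ps``.  A pair is present in a frame
    if at least one atom-level bond links the two residues (either
    direction).  Rows below ``min_fraction`` are retained but flagged
    ``reported=False``, matching the convention of listing only pairs
    present >30% of time points.
    """
    s = traj.topology
    if assignment is None:
        assignment = assign_donors_acceptors(s)
    if traj.n_frames > 1:
        spacing = float(traj.times[1] - traj.times[0])
        if stride_ps < spacing:
            raise ValueError("stride_ps must be >= frame spacing")
        step = max(1, int(round(stride_ps / spacing)))
    else:
        step = 1
    frames = range(0, traj.n_frames, step)
    n_analyzed = 0
    presence: Counter = Counter()
    atom_pair: dict[tuple, Counter] = defaultdict(Counter)
    multiplicity: Counter = Counter()
    per_frame_counts: dict[str, list[int]] = defaultdict(list)
    pair_tag: dict[tuple, str] = {}
    for k in frames:
        n_analyzed += 1
        bonds = detect_hbonds(traj.coords[k], s, c, assignment)
        frame_pairs: dict[tuple, int] = Counter()
        for b in bonds:
            key = tuple(sorted((b.donor_residue, b.acceptor_residue)))
            frame_pairs[key] += 1
            atom_pair[key][(str(s.names[b.donor]), str(s.names[b.acceptor]),
                            b.donor_residue)] += 1
            if key not in pair_tag:
                pair_tag[key] = grouping.tag(s, b.donor, b.acceptor)
        for key, cnt in frame_pairs.items():
            presence[key] += 1
            multiplicity[key] += cnt
        tags_this_frame: Counter = Counter()
        for key in frame_pairs:
            tags_this_frame[pair_tag[key]] += 1
        for tag in set(pair_tag.values()):
            per_frame_counts[tag].append(tags_this_frame.get(tag, 0))
        per_frame_counts["all"].append(sum(frame_pairs.values()))

    rows = []
    for key, n_present in sorted(presence.items(), key=lambda kv: -kv[1]):
        fraction = n_present / n_analyzed
        # orient the row along the modal atom-level bond's direction
        res_a, res_b = key
        (d_atom, a_atom, d_res), _ = max(
            atom_pair[key].items(), key=lambda kv: kv[1]
        )
        donor_res = d_res
        acceptor_res = res_b if d_res == res_a else res_a
        rows.append(
            {
                "donor_res": _label(s, donor_res),
                "acceptor_res": _label(s, acceptor_res),
                "donor_atom": d_atom,
                "acceptor_atom": a_atom,
                "group": pair_tag[key],
                "fraction": fraction,
                "mean_per_frame": multiplicity[key] / n_analyzed,
                "reported": fraction >= min_fraction,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "donor_res", "acceptor_res", "donor_atom", "acceptor_atom",
            "group", "fraction", "mean_per_frame", "reported",
        ],
    )
    mean_counts = {
        tag: float(np.mean(v)) if v else 0.0 for tag, v in per_frame_counts.items()
    }
    return OccupancyTable(
        table=table,
        n_frames_analyzed=n_analyzed,
        min_fraction=min_fraction,
        mean_bonds_per_frame=mean_counts,
    )


def _label(s: Structure, residue: tuple[str, int]) -> str:
    chain, resid = residue
    idx = np.nonzero((s.chains.astype(str) == chain) & (s.resids == resid))[0][0]
    return f"{s.resnames[idx]}{resid}:{chain}"


def group_cofactor_hbonds(
    table: OccupancyTable,
    s: Structure,
    moiety_map: dict[str, str] | None = None,
    cofactor_resnames: frozenset = frozenset({"NAP", "NDP"}),
) -> OccupancyTable:
    """Refine 'cofactor' rows into per-moiety tags (adenine, nicotinamide,
    dinucleotide/phosphate) using the cofactor-side atom name."""
    if moiety_map is None:
        moiety_map = NADP_MOIETY_MAP
    df = table.table.copy()
    cof_res = {
        _label(s, (str(s.chains[i]), int(s.resids[i])))
        for i in range(s.n_atoms)
        if str(s.resnames[i]).upper() in cofactor_resnames
    }
    new_groups = []
    for _, row in df.iterrows():
        if row["group"] != "cofactor":
            new_groups.append(row["group"])
            continue
        if row["donor_res"] in cof_res:
            atom = row["donor_atom"]
        else:
            atom = row["acceptor_atom"]
        key = atom.upper()
        if key not in moiety_map:
            raise MappingError(f"cofactor atom {atom!r} not in moiety map")
        new_groups.append(f"cofactor-{moiety_map[key]}")
    df["group"] = new_groups
    return OccupancyTable(
        table=df,
        n_frames_analyzed=table.n_frames_analyzed,
        min_fraction=table.min_fraction,
        mean_bonds_per_frame=table.mean_bonds_per_frame,
    )
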