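"""Superposition, RMSD, radius of gyration and distance kernels.

All fits are mass-weighted by default (the GROMACS convention, which is
what produced every reference number this package reproduces).  The
optimal rotation comes from scipy's Kabsch implementation with proper
reflection correction, so ``det(R) = +1`` always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import FitError, MappingError
from .structio import Selection, Structure, Trajectory


@dataclass(frozen=True)
class FitResult:
    """Optimal rigid superposition of a mobile point set onto a reference."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,), applied after rotation
    rmsd: float  # weighted RMSD after the fit, nm

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Weighted least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimising
    sum_i w_i |R x_i + t - y_i|^2, plus the post-fit weighted RMSD.
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise FitError("mobile and reference must both have shape (n, 3)")
    n = len(x)
    if n < 3:
        raise FitError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or not np.any(w > 0):
            raise FitError("weights must be >= 0 and not all zero")
    wsum = w.sum()
    cx = (w[:, None] * x).sum(axis=0) / wsum
    cy = (w[:, None] * y).sum(axis=0) / wsum
    xc = x - cx
    yc = y - cy
    # degenerate: all effective points collinear -> rotation about the line
    # is undetermined
    if np.linalg.matrix_rank(xc[w > 0] * np.sqrt(w[w > 0])[:, None], tol=1e-10) < 2:
        raise FitError("degenerate point set (collinear or zero spread)")
    rot, _ = Rotation.align_vectors(yc, xc, weights=w)
    R = rot.as_matrix()
    t = cy - R @ cx
    # recompute the residual directly: scipy's rssd loses half the digits
    # to cancellation, which matters for near-exact rigid motions
    d2 = ((x @ R.T + t - y) ** 2).sum(axis=1)
    rmsd = float(np.sqrt((w * d2).sum() / wsum))
    return FitResult(rotation=R, translation=t, rmsd=rmsd)


def weighted_rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Plain (no fitting) weighted RMSD between matched coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    w = np.ones(len(a)) if weights is None else np.asarray(weights, float)
    d2 = ((a - b) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def _map_to_reference(top: Structure, ref: Structure, sel: Selection) -> np.ndarray:
    """Indices in ``ref`` matching ``sel`` atoms of ``top`` by (chain,resid,name)."""
    if top is ref or (
        top.n_atoms == ref.n_atoms
        and np.array_equal(top.names, ref.names)
        and np.array_equal(top.resids, ref.resids)
        and np.array_equal(top.chains, ref.chains)
    ):
        return sel.indices
    lookup = {ref.atom_key(i): i for i in range(ref.n_atoms)}
    out = []
    for i in sel.indices:
        key = top.atom_key(int(i))
        if key not in lookup:
            raise MappingError(f"atom {key} absent from reference structure")
        out.append(lookup[key])
    return np.asarray(out, dtype=int)


def rmsd_series(
    traj: Trajectory,
    ref: Structure,
    fit_sel: Selection,
    calc_sel: Selection | None = None,
    *,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame RMSD to a reference after a least-squares fit.

    Each frame is fitted on ``fit_sel`` (mass-weighted) and the RMSD is then
    evaluated over ``calc_sel`` (defaults to ``fit_sel``), which allows e.g.
    per-domain deviations after a whole-monomer alignment.
    """
    if calc_sel is None:
        calc_sel = fit_sel
    if len(fit_sel) == 0 or len(calc_sel) == 0:
        raise MappingError("fit and calc selections must be non-empty")
    top = traj.topology
    fit_ref_idx = _map_to_reference(top, ref, fit_sel)
    calc_ref_idx = _map_to_reference(top, ref, calc_sel)
    w_fit = top.masses[fit_sel.indices] if mass_weighted else None
    w_calc = top.masses[calc_sel.indices] if mass_weighted else None
    ref_fit = ref.coords[fit_ref_idx]
    ref_calc = ref.coords[calc_ref_idx]
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        frame = traj.coords[k]
        fit = superpose(frame[fit_sel.indices], ref_fit, w_fit)
        moved = fit.apply(frame[calc_sel.indices])
        out[k] = weighted_rmsd(moved, ref_calc, w_calc)
    return out


def per_residue_rmsd(
    traj: Trajectory,
    ref: Structure,
    fit_sel: Selection,
) -> dict[tuple[str, int], float]:
    """Backbone RMSD per residue, averaged over frames, after a global fit.

    Each frame is mass-weight fitted on ``fit_sel``; the per-residue value is
    the time-averaged backbone RMSD of that residue.  Residues lacking
    backbone atoms are omitted with a warning.
    """
    import warnings

    from .structio import BACKBONE_NAMES, AMINO_ACIDS

    top = traj.topology
    fit_ref_idx = _map_to_reference(top, ref, fit_sel)
    w_fit = top.masses[fit_sel.indices]
    ref_fit = ref.coords[fit_ref_idx]

    # group backbone atoms by residue
    groups: dict[tuple[str, int], list[int]] = {}
    for i in range(top.n_atoms):
        if (
            str(top.names[i]).upper() in BACKBONE_NAMES
            and str(top.resnames[i]).upper() in AMINO_ACIDS
        ):
            groups.setdefault((str(top.chains[i]), int(top.resids[i])), []).append(i)
    for key in top.residue_keys():
        if str(top.resnames[np.nonzero((top.chains == key[0]) & (top.resids == key[1]))[0][0]]).upper() in AMINO_ACIDS and key not in groups:
            warnings.warn(f"residue {key} has no backbone atoms; omitted")

    sq_sums = {key: 0.0 for key in groups}
    ref_groups = {
        key: _map_to_reference(top, ref, Selection(np.array(idx), top.n_atoms))
        for key, idx in groups.items()
    }
    for k in range(traj.n_frames):
        frame = traj.coords[k]
        fit = superpose(frame[fit_sel.indices], ref_fit, w_fit)
        moved = fit.apply(frame)
        for key, idx in groups.items():
            d2 = ((moved[idx] - ref.coords[ref_groups[key]]) ** 2).sum(axis=1)
            sq_sums[key] += float(d2.mean())
    return {key: float(np.sqrt(v / traj.n_frames)) for key, v in sq_sums.items()}


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration, sqrt(sum m |r - r_com|^2 / sum m)."""
    r = np.asarray(coords, dtype=float).reshape(-1, 3)
    m = np.ones(len(r)) if masses is None else np.asarray(masses, dtype=float)
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    com = (m[:, None] * r).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((r - com) ** 2).sum(axis=1)).sum() / m.sum()))


def min_distance(
    a: Selection,
    b: Selection,
    frame: np.ndarray,
    *,
    structure: Structure | None = None,
    heavy_only: bool = False,
) -> float:
    """Minimum pairwise atom distance between two disjoint selections (exact).

    ``heavy_only`` drops hydrogens (requires ``structure`` for elements).
    """
    ia, ib = a.indices, b.indices
    if heavy_only:
        if structure is None:
            raise ValueError("heavy_only requires the structure for elements")
        heavy = np.char.upper(structure.elements.astype(str)) != "H"
        ia = ia[heavy[ia]]
        ib = ib[heavy[ib]]
    if len(ia) == 0 or len(ib) == 0:
        raise MappingError("min_distance selections must be non-empty")
    if len(np.intersect1d(ia, ib)):
        raise ValueError("min_distance selections overlap (ambiguous contact)")
    frame = np.asarray(frame, dtype=float)
    return float(cdist(frame[ia], frame[ib]).min())


def com_distance(
    a: Selection,
    b: Selection,
    frame: np.ndarray,
    masses: np.ndarray,
) -> float:
    """Distance between the mass-weighted centroids of two selections."""
    frame = np.asarray(frame, dtype=float)
    m = np.asarray(masses, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise MappingError("com_distance selections must be non-empty")
    ca = (m[a.indices, None] * frame[a.indices]).sum(axis=0) / m[a.indices].sum()
    cb = (m[b.indices, None] * frame[b.indices]).sum(axis=0) / m[b.indices].sum()
    return float(np.linalg.norm(ca - cb))


def count_within(
    center: Selection,
    candidates: Selection,
    cutoff: float,
    frame: np.ndarray,
    structure: Structure,
) -> int:
    """Number of candidate *residues* with any atom within ``cutoff`` of any
    center atom (one water molecule counts once)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frame = np.asarray(frame, dtype=float)
    if len(center) == 0 or len(candidates) == 0:
        return 0
    d = cdist(frame[candidates.indices], frame[center.indices]).min(axis=1)
    rindex = structure.residue_index()
    hit = np.unique(rindex[candidates.indices[d <= cutoff]])
    return int(len(hit))
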