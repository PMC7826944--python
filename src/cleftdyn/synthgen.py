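"""Synthetic hinged-domain trajectories with known gating kinetics.

The generator replaces the MD engine for testing: a two-state
continuous-time Markov chain (CLOSED ⇄ OPEN with exponential dwells)
drives the cleft distance, which is embedded geometrically as a rigid
rotation of one pseudo-domain about a hinge so the marker-residue pair
reproduces the latent distance to within 0.005 nm per frame.  The system
carries a bound pseudo-cofactor (real NADP atom names, three moieties)
that can depart on schedule, a Zn ion with a fixed water shell, and
backbone N–H / C=O hydrogen-bond geometry, so every downstream analysis
has exact ground truth.

The CTMC is simulated in continuous time and then discretised, so dwell
statistics are exact and independent of the frame spacing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from .cleftkin import CleftState
from .errors import LayoutError
from .structio import Atom, Structure, Trajectory, write_pdb, write_traj

NS_TO_PS = 1000.0


@dataclass(frozen=True)
class GatingSpec:
    """Parameters of the latent gating process and its distance observable.

    Rates are per ns; the distance observable is Gaussian about the state
    mean (0.25 nm closed / 1.30 nm open by default) with a hard floor at
    0.14 nm, and transitions ramp linearly through the partial band over
    ``transit_ps``.
    """

    lambda_open: float = 2.0  # CLOSED -> OPEN rate, 1/ns
    lambda_close: float = 2.0  # OPEN -> CLOSED rate, 1/ns
    dt_ps: float = 10.0
    duration_ns: float = 100.0
    seed: int = 0
    closed_mu: float = 0.25
    closed_sigma: float = 0.08
    open_mu: float = 1.30
    open_sigma: float = 0.10
    transit_ps: float = 20.0
    distance_floor: float = 0.14

    def __post_init__(self) -> None:
        if self.lambda_open <= 0 or self.lambda_close <= 0:
            raise ValueError("rates must be positive")
        if not (self.closed_mu < 0.55 < 1.0 < self.open_mu):
            raise ValueError("state means must straddle the 0.55/1.0 thresholds")
        if self.closed_sigma < 0 or self.open_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.dt_ps <= 0 or self.duration_ns <= 0:
            raise ValueError("dt and duration must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic twin of a gating run, used as the recovery oracle."""

    stationary_closed: float
    stationary_open: float
    mean_dwell_closed_ns: float  # 1 / lambda_open
    mean_dwell_open_ns: float  # 1 / lambda_close
    expected_events: float
    release_time_ns: float | None = None


def ground_truth_of(spec: GatingSpec, release_time_ns: float | None = None) -> GroundTruth:
    lo, lc = spec.lambda_open, spec.lambda_close
    cycle = 1.0 / lo + 1.0 / lc
    return GroundTruth(
        stationary_closed=lc / (lo + lc),
        stationary_open=lo / (lo + lc),
        mean_dwell_closed_ns=1.0 / lo,
        mean_dwell_open_ns=1.0 / lc,
        expected_events=2.0 * spec.duration_ns / cycle,
        release_time_ns=release_time_ns,
    )


@dataclass
class GatingPath:
    """Discretised realisation of the gating CTMC."""

    times_ps: np.ndarray
    distances: np.ndarray
    latent_states: np.ndarray  # CleftState per frame (terminal states only)
    transit_mask: np.ndarray  # True while the distance is ramping
    switch_times_ps: np.ndarray  # exact CTMC switch times
    spec: GatingSpec

    @property
    def n_frames(self) -> int:
        return len(self.times_ps)

    @property
    def latent_numeric(self) -> np.ndarray:
        return np.array([s.value for s in self.latent_states])


def _sample_dwells(rng: np.random.Generator, spec: GatingSpec) -> np.ndarray:
    """Exact exponential dwell sequence (ns), alternating from CLOSED."""
    total = 0.0
    dwells: list[float] = []
    state_closed = True
    while total <= spec.duration_ns:
        rate = spec.lambda_open if state_closed else spec.lambda_close
        d = rng.exponential(1.0 / rate)
        dwells.append(d)
        total += d
        state_closed = not state_closed
    return np.asarray(dwells)


def simulate_gating(
    spec: GatingSpec, rng: np.random.Generator | None = None
) -> tuple[GatingPath, GroundTruth]:
    """Simulate the latent CTMC and its noisy distance observable.

    The chain starts CLOSED (the equilibrated holo structure is closed).
    Same spec and seed give bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    dwells = _sample_dwells(rng, spec)
    switch_ns = np.cumsum(dwells)
    times_ps = np.arange(0.0, spec.duration_ns * NS_TO_PS + 0.5 * spec.dt_ps, spec.dt_ps)
    times_ps = times_ps[times_ps <= spec.duration_ns * NS_TO_PS]
    switch_ps = switch_ns * NS_TO_PS
    # state index: number of switches before t; even -> CLOSED (start state)
    k = np.searchsorted(switch_ps, times_ps, side="right")
    closed = (k % 2) == 0
    latent = np.empty(len(times_ps), dtype=object)
    latent[closed] = CleftState.CLOSED
    latent[~closed] = CleftState.OPEN

    mu = np.where(closed, spec.closed_mu, spec.open_mu)
    sigma = np.where(closed, spec.closed_sigma, spec.open_sigma)
    transit = np.zeros(len(times_ps), dtype=bool)
    if spec.transit_ps > 0:
        # ramp the mean linearly over transit_ps after each switch
        relevant = switch_ps[switch_ps <= times_ps[-1] + spec.transit_ps]
        for i, s in enumerate(relevant):
            in_ramp = (times_ps >= s) & (times_ps < s + spec.transit_ps)
            if not in_ramp.any():
                continue
            frac = (times_ps[in_ramp] - s) / spec.transit_ps
            new_closed = ((i + 1) % 2) == 0
            mu_old = spec.open_mu if new_closed else spec.closed_mu
            mu_new = spec.closed_mu if new_closed else spec.open_mu
            sg_old = spec.open_sigma if new_closed else spec.closed_sigma
            sg_new = spec.closed_sigma if new_closed else spec.open_sigma
            mu[in_ramp] = mu_old + frac * (mu_new - mu_old)
            sigma[in_ramp] = sg_old + frac * (sg_new - sg_old)
            transit[in_ramp] = True
    d = mu + sigma * rng.standard_normal(len(times_ps))
    d = np.maximum(d, spec.distance_floor)
    path = GatingPath(
        times_ps=times_ps,
        distances=d,
        latent_states=latent,
        transit_mask=transit,
        switch_times_ps=switch_ps[switch_ps <= times_ps[-1]],
        spec=spec,
    )
    return path, ground_truth_of(spec)


# =============================================================================
# geometric embedding
# =============================================================================


@dataclass(frozen=True)
class ToyLayout:
    """Geometry of the two-rod hinged pseudo-enzyme.

    Two rigid 20-residue pseudo-domains radiate from a hinge at the
    origin; domain 2 rotates about z.  The marker residues (ASP 159 /
    HIS 363, echoing the cleft pair of the real enzyme) sit at the rod
    tips, whose separation tracks the latent cleft distance.
    """

    n_res_per_domain: int = 20
    inner_radius: float = 0.62  # nm, first residue distance from hinge
    spacing: float = 0.125  # nm between residue anchors along the rod
    tip_radius: float = 3.05  # nm, marker tip atoms
    domain2_z: float = 0.45  # nm, out-of-plane offset keeping rods apart
    domain1_resids: tuple[int, int] = (140, 159)
    domain2_resids: tuple[int, int] = (344, 363)
    with_cofactor: bool = True
    release_time_ns: float | None = None
    release_step_nm: float = 1.2  # cofactor displacement per frame after release
    release_n_steps: int = 4
    n_waters_shell: int = 12  # within 0.35 nm of Zn
    n_waters_outer: int = 8
    zn_shell_radius: float = 0.28
    theta_bounds: tuple[float, float] = (1e-4, 1.2)  # rad


def _backbone_atoms(base: np.ndarray, along: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """(name, element, position) for an N(H)-CA-C=O unit anchored at base."""
    u = along / np.linalg.norm(along)
    perp = np.array([-u[1], u[0], 0.0])
    return [
        ("N", "N", base - 0.055 * u + 0.045 * perp),
        ("H", "H", base - 0.055 * u + 0.145 * perp),
        ("CA", "C", base),
        ("C", "C", base + 0.055 * u - 0.045 * perp),
        ("O", "O", base + 0.055 * u - 0.165 * perp),
    ]


def _domain_atoms(
    layout: ToyLayout,
    resid_range: tuple[int, int],
    marker: tuple[str, str] | None,
    z: float,
) -> list[tuple[str, str, int, str, np.ndarray]]:
    """(resname, name, resid, element, position) for one rod in body frame
    (rod along +x); the marker residue is last, at the tip."""
    lo, hi = resid_range
    n = hi - lo + 1
    out = []
    for i in range(n):
        resid = lo + i
        is_marker = marker is not None and resid == hi
        if is_marker:
            base = np.array([layout.tip_radius - 0.05, 0.0, z / 3.0])
        else:
            base = np.array([layout.inner_radius + i * layout.spacing, 0.0, z])
        resname = marker[0] if is_marker else "GLY"
        for name, el, pos in _backbone_atoms(base, np.array([1.0, 0.0, 0.0])):
            out.append((resname, name, resid, el, pos))
        if is_marker:
            tipname, tipel = marker[1], marker[1][0]
            out.append(
                (resname, tipname, resid, tipel,
                 np.array([layout.tip_radius, 0.0, 0.0]))
            )
    return out


def _rotz(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_COFACTOR_ATOMS = (
    # nicotinamide moiety (near the Zn end)
    "N1N", "C2N", "C3N", "C7N", "O7N", "N7N", "C4N", "C5N", "C6N",
    # dinucleotide / pyrophosphate bridge
    "O5D", "PN", "O1N", "O2N", "O3", "PA", "O1A", "O2A", "O5B",
    # adenine moiety (near the cleft mouth)
    "N9A", "C8A", "N7A", "C5A", "C6A", "N6A", "N1A", "C2A", "N3A", "C4A",
)


def _cofactor_atoms(x_lo: float, x_hi: float, y: float) -> list[tuple[str, str, np.ndarray]]:
    """Bound pose: atoms strung along x at height y, slight zig-zag."""
    n = len(_COFACTOR_ATOMS)
    xs = np.linspace(x_lo, x_hi, n)
    out = []
    for i, name in enumerate(_COFACTOR_ATOMS):
        el = "P" if name.startswith("P") else name[0]
        pos = np.array([xs[i], y + 0.02 * (-1) ** i, 0.0])
        out.append((name, el, pos))
    return out


@dataclass
class ToySystem:
    """A generated topology + trajectory with its exact ground truth."""

    structure: Structure
    trajectory: Trajectory
    path: GatingPath
    truth: GroundTruth
    layout: ToyLayout

    def write(self, prefix: str | Path, traj_format: str = "dcd") -> dict[str, Path]:
        """Write PDB topology, coordinate trajectory and ground-truth JSON."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "topology": prefix.with_suffix(".pdb"),
            "trajectory": prefix.with_suffix("." + traj_format),
            "truth": prefix.with_suffix(".truth.json"),
        }
        write_pdb(self.structure, paths["topology"])
        write_traj(self.trajectory, paths["trajectory"])
        truth = asdict(self.truth)
        truth["spec"] = asdict(self.path.spec)
        truth["dt_ps"] = self.path.spec.dt_ps
        paths["truth"].write_text(json.dumps(truth, indent=2))
        return paths


def build_toy_system(
    spec: GatingSpec,
    layout: ToyLayout = ToyLayout(),
    rng: np.random.Generator | None = None,
) -> ToySystem:
    """Embed a gating realisation as a hinged-rod trajectory.

    Domain 2 rotates about the z-axis hinge so that the ASP159–HIS363
    minimum distance equals the latent distance to within 0.005 nm in
    every frame.  If ``layout.release_time_ns`` is set, the cofactor moves
    straight out of the cleft starting at the first OPEN frame at or after
    that time (release proceeds from an open cleft, as in the proposed
    mechanism); the realised time is recorded in the ground truth.
    """
    path, truth = simulate_gating(spec, rng)

    dom1 = _domain_atoms(layout, layout.domain1_resids, ("ASP", "OD1"), 0.0)
    dom2 = _domain_atoms(layout, layout.domain2_resids, ("HIS", "NE2"), layout.domain2_z)

    atoms: list[Atom] = []
    serial = 1
    for resname, name, resid, el, pos in dom1 + dom2:
        mass = {"N": 14.007, "C": 12.011, "O": 15.999, "H": 1.008}[el]
        atoms.append(Atom(serial, name, el, mass, resname, resid, "A", pos))
        serial += 1
    n_dom1_atoms = len(dom1)
    dom2_slice = slice(n_dom1_atoms, n_dom1_atoms + len(dom2))

    cof_slice = None
    if layout.with_cofactor:
        start = len(atoms)
        for name, el, pos in _cofactor_atoms(1.45, 3.1, 0.34):
            mass = {"N": 14.007, "C": 12.011, "O": 15.999, "P": 30.974}[el]
            atoms.append(Atom(serial, name, el, mass, "NAP", 500, "A", pos))
            serial += 1
        cof_slice = slice(start, len(atoms))

    zn_pos = np.array([1.42, -0.08, 0.0])  # ~0.45 nm below the nicotinamide end
    atoms.append(Atom(serial, "ZN", "ZN", 65.38, "ZN", 501, "A", zn_pos))
    serial += 1

    # water shell: exact count inside 0.35 nm of Zn, placed on the -y
    # hemisphere away from the cofactor; outer waters well outside
    golden = np.pi * (3.0 - np.sqrt(5.0))
    wat_resid = 1
    for i in range(layout.n_waters_shell):
        zf = -(i + 0.5) / layout.n_waters_shell  # z in (-1, 0): hemisphere
        r = np.sqrt(1.0 - zf * zf)
        ang = golden * i
        d = np.array([r * np.cos(ang), zf, r * np.sin(ang)])  # y < 0 side
        o = zn_pos + layout.zn_shell_radius * d
        for name, el, off in (
            ("O", "O", np.zeros(3)),
            ("H1", "H", np.array([0.095, 0.03, 0.0])),
            ("H2", "H", np.array([-0.095, 0.03, 0.0])),
        ):
            mass = 15.999 if el == "O" else 1.008
            atoms.append(Atom(serial, name, el, mass, "HOH", wat_resid, "W", o + off))
            serial += 1
        wat_resid += 1
    for i in range(layout.n_waters_outer):
        ang = golden * (i + 1)
        o = zn_pos + np.array(
            [0.8 * np.cos(ang), -0.6 - 0.12 * i, 0.8 * np.sin(ang)]
        )
        for name, el, off in (
            ("O", "O", np.zeros(3)),
            ("H1", "H", np.array([0.095, 0.03, 0.0])),
            ("H2", "H", np.array([-0.095, 0.03, 0.0])),
        ):
            mass = 15.999 if el == "O" else 1.008
            atoms.append(Atom(serial, name, el, mass, "HOH", wat_resid, "W", o + off))
            serial += 1
        wat_resid += 1

    structure = Structure.from_atoms(atoms, title="synthetic hinged two-domain system")
    base = structure.coords.copy()

    # marker atoms for the exact distance solve
    marker1 = np.array(
        [i for i in range(len(atoms))
         if atoms[i].resid == layout.domain1_resids[1] and atoms[i].chain == "A"]
    )
    marker2 = np.array(
        [i for i in range(len(atoms))
         if atoms[i].resid == layout.domain2_resids[1] and atoms[i].chain == "A"]
    )
    m1 = base[marker1]
    m2_body = base[marker2]

    def marker_distance(theta: float) -> float:
        return float(cdist(m1, m2_body @ _rotz(theta).T).min())

    th_lo, th_hi = layout.theta_bounds
    d_lo, d_hi = marker_distance(th_lo), marker_distance(th_hi)
    if path.distances.min() < d_lo - 1e-9 or path.distances.max() > d_hi + 1e-9:
        raise LayoutError(
            f"latent distances [{path.distances.min():.3f}, "
            f"{path.distances.max():.3f}] nm outside the hinge's reachable "
            f"range [{d_lo:.3f}, {d_hi:.3f}] nm"
        )

    # realised release schedule: first OPEN frame at/after the request
    release_frame = None
    if layout.with_cofactor and layout.release_time_ns is not None:
        req_ps = layout.release_time_ns * NS_TO_PS
        candidates = np.nonzero(
            (path.times_ps >= req_ps)
            & (path.latent_states == CleftState.OPEN)
            & ~path.transit_mask
        )[0]
        if len(candidates) == 0:
            raise LayoutError("no OPEN frame at or after the requested release time")
        release_frame = int(candidates[0])
        truth = ground_truth_of(spec, release_time_ns=path.times_ps[release_frame] / NS_TO_PS)

    n_frames = path.n_frames
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    # exit along -z: perpendicular both to the static rod plane and to the
    # arc swept by the rotating domain, so one step clears the threshold
    exit_dir = np.array([0.0, 0.0, -1.0])
    for k in range(n_frames):
        target = float(path.distances[k])
        theta = brentq(
            lambda th: marker_distance(th) - target, th_lo, th_hi, xtol=1e-9
        )
        coords[k, dom2_slice] = base[dom2_slice] @ _rotz(theta).T
        if release_frame is not None and k >= release_frame:
            steps = min(k - release_frame + 1, layout.release_n_steps)
            coords[k, cof_slice] = (
                base[cof_slice] + steps * layout.release_step_nm * exit_dir
            )

    traj = Trajectory(structure, path.times_ps.copy(), coords)
    return ToySystem(structure=structure, trajectory=traj, path=path,
                     truth=truth, layout=layout)


# =============================================================================
# regime pair demo
# =============================================================================

#: open-biased, fast-switching regime (oxidized-cofactor-like)
REGIME_OPEN_BIASED = {"lambda_open": 2.4, "lambda_close": 0.7}
#: closed-biased, slow-switching regime (reduced-cofactor-like)
REGIME_CLOSED_BIASED = {"lambda_open": 0.4, "lambda_close": 0.8}


@dataclass
class RegimePair:
    """Two sets of gating realisations contrasting cofactor oxidation states."""

    open_biased: list[GatingPath]
    closed_biased: list[GatingPath]
    truth_open_biased: GroundTruth
    truth_closed_biased: GroundTruth


def make_regime_pair(
    seed: int,
    duration_ns: float = 200.0,
    n_replicas: int = 5,
    dt_ps: float = 10.0,
) -> RegimePair:
    """Simulate the qualitative contrast between an open-biased fast
    regime and a closed-biased slow regime (n_replicas independent runs of
    duration_ns each, mirroring the five independent simulations per
    cofactor state)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_replicas)
    out: dict[str, list[GatingPath]] = {"A": [], "B": []}
    truths = {}
    for r, (tag, rates) in enumerate(
        (("A", REGIME_OPEN_BIASED), ("B", REGIME_CLOSED_BIASED))
    ):
        spec = GatingSpec(
            lambda_open=rates["lambda_open"],
            lambda_close=rates["lambda_close"],
            duration_ns=duration_ns,
            dt_ps=dt_ps,
            seed=seed,
        )
        truths[tag] = ground_truth_of(spec)
        for i in range(n_replicas):
            rng = np.random.default_rng(children[r * n_replicas + i])
            p, _ = simulate_gating(spec, rng)
            out[tag].append(p)
    return RegimePair(
        open_biased=out["A"],
        closed_biased=out["B"],
        truth_open_biased=truths["A"],
        truth_closed_biased=truths["B"],
    )
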