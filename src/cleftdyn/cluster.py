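"""GROMOS neighbour-count conformational clustering.

Frames are compared by mass-weighted RMSD after optimal superposition
(typically on backbone atoms).  The greedy neighbour-count algorithm then
repeatedly takes the frame with the most neighbours within the cutoff
(0.13 nm by default) as the next cluster centre, removes it and its
neighbours, and repeats until every frame is assigned.  Neighbour counts
include the frame itself; ties break to the lowest frame index.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MappingError
from .geometry import superpose
from .structio import Selection, Trajectory

DEFAULT_CUTOFF_NM = 0.13
DEFAULT_STRIDE_PS = 100.0


@dataclass
class ClusterResult:
    """A partition of frames into neighbour-count clusters.

    ``assignments`` maps frame index -> cluster id; cluster ids are ordered
    by decreasing size (0 is the largest); ``centers`` maps cluster id ->
    central frame index.  ``frame_indices`` records which original
    trajectory frames the matrix rows correspond to (after striding).
    """

    assignments: np.ndarray
    centers: dict[int, int]
    sizes: dict[int, int]
    cutoff: float
    frame_indices: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    @property
    def n_frames(self) -> int:
        return len(self.assignments)


def pairwise_rmsd(
    traj: Trajectory,
    sel: Selection,
    stride_ps: float = DEFAULT_STRIDE_PS,
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric matrix of mass-weighted fitted RMSDs between strided frames.

    Returns ``(matrix, frame_indices)``.  Entry (i, j) is the RMSD of frame
    j superposed onto frame i over ``sel``; the matrix is symmetric with a
    zero diagonal.  Memory grows as the square of the frame count, so use
    the stride (100 ps by default) for long trajectories.
    """
    if len(sel) == 0:
        raise MappingError("cluster selection is empty")
    if traj.n_frames > 1:
        spacing = float(traj.times[1] - traj.times[0])
        step = max(1, int(round(stride_ps / spacing)))
    else:
        step = 1
    idx = np.arange(0, traj.n_frames, step)
    if len(idx) < 2:
        raise ValueError("need at least 2 frames after striding")
    weights = traj.topology.masses[sel.indices]
    coords = traj.coords[np.ix_(idx, sel.indices)]
    n = len(idx)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = superpose(coords[j], coords[i], weights).rmsd
            m[i, j] = m[j, i] = r
    return m, idx


def gromos_cluster(m: np.ndarray, cutoff: float) -> ClusterResult:
    """Greedy neighbour-count clustering of a symmetric distance matrix."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    if np.any(m < 0):
        raise ValueError("matrix must be non-negative")
    n = m.shape[0]
    neighbors = m <= cutoff
    unassigned = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    raw_clusters: list[tuple[int, np.ndarray]] = []
    while unassigned.any():
        # neighbour counts among unassigned frames only (self included)
        counts = (neighbors & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(neighbors[center] & unassigned)[0]
        raw_clusters.append((center, members))
        unassigned[members] = False
    # order clusters by decreasing size, ties by first-extracted
    order = sorted(
        range(len(raw_clusters)),
        key=lambda k: (-len(raw_clusters[k][1]), k),
    )
    centers: dict[int, int] = {}
    sizes: dict[int, int] = {}
    for new_id, k in enumerate(order):
        center, members = raw_clusters[k]
        centers[new_id] = center
        sizes[new_id] = len(members)
        assignments[members] = new_id
    return ClusterResult(
        assignments=assignments, centers=centers, sizes=sizes, cutoff=cutoff
    )


def cluster_report(r: ClusterResult, n_top: int = 3) -> pd.DataFrame:
    """Top-cluster populations as percentages of all frames."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    total = r.n_frames
    rows = []
    cum = 0.0
    for cid in range(min(n_top, r.n_clusters)):
        pct = 100.0 * r.sizes[cid] / total
        cum += pct
        rows.append(
            {
                "cluster": cid,
                "size": r.sizes[cid],
                "percent": pct,
                "cumulative_percent": cum,
                "center_frame": r.centers[cid],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# matrix cache: int32 dimension header followed by the row-major lower
# triangle (excluding the diagonal) as little-endian float32
# ---------------------------------------------------------------------------


def save_matrix(m: np.ndarray, path: str | Path) -> None:
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    tri = m[np.tril_indices(n, k=-1)].astype("<f4")
    with open(path, "wb") as fh:
        fh.write(struct.pack("<i", n))
        fh.write(tri.tobytes())


def load_matrix(path: str | Path) -> np.ndarray:
    with open(path, "rb") as fh:
        (n,) = struct.unpack("<i", fh.read(4))
        tri = np.frombuffer(fh.read(), dtype="<f4")
    if len(tri) != n * (n - 1) // 2:
        raise ValueError(f"matrix cache {path} is truncated")
    m = np.zeros((n, n))
    m[np.tril_indices(n, k=-1)] = tri
    return m + m.T
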