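"""Cleft-distance state classification and opening/closing kinetics.

The interdomain cleft is measured as the all-atom minimum distance between
a residue pair at the mouth of the cofactor-binding site (Asp159–His363 in
YqhD).  Frames are classified CLOSED (< 0.55 nm), OPEN (> 1.0 nm) or
PARTIAL (the transitional band in between; boundary values are PARTIAL
because the terminal-state inequalities are strict).  Switching events are
transitions between the two terminal states; the waiting time of an event
is measured from the moment the departing terminal state was entered, so
transit through the partial band counts toward the dwell, matching the
notion of "time to remain in a conformation before switching".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import SelectionError
from .geometry import min_distance
from .structio import Selection, Trajectory, select


class CleftState(Enum):
    """Terminal and transitional cleft states with the 1/0.5/0 encoding."""

    CLOSED = 1.0
    PARTIAL = 0.5
    OPEN = 0.0


@dataclass(frozen=True)
class StateThresholds:
    """closed iff d < closed_max; open iff d > open_min (strict)."""

    closed_max: float = 0.55
    open_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.closed_max < self.open_min):
            raise ValueError("need 0 < closed_max < open_min")

    def classify(self, distances: np.ndarray) -> np.ndarray:
        d = np.asarray(distances, dtype=float)
        out = np.full(d.shape, CleftState.PARTIAL, dtype=object)
        out[d < self.closed_max] = CleftState.CLOSED
        out[d > self.open_min] = CleftState.OPEN
        return out


@dataclass
class CleftStateSeries:
    """Per-frame cleft distance and state."""

    times: np.ndarray  # ps
    distances: np.ndarray  # nm
    states: np.ndarray  # CleftState objects
    thresholds: StateThresholds = field(default_factory=StateThresholds)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        self.states = np.asarray(self.states, dtype=object)
        if not (len(self.times) == len(self.distances) == len(self.states)):
            raise ValueError("times, distances, states must align")

    @property
    def numeric_states(self) -> np.ndarray:
        return np.array([s.value for s in self.states], dtype=float)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SwitchEvent:
    """One terminal-state transition with its waiting time."""

    from_state: CleftState
    to_state: CleftState
    event_time: float  # ps, first frame in the new terminal state
    waiting_time: float  # ps, since the departing terminal state was entered


@dataclass
class KineticsSummary:
    """State populations, event counts and waiting-time statistics."""

    fractions: dict  # CleftState -> fraction of time points
    n_events: int
    counts: dict  # (from, to) -> int
    mean_waiting: dict  # (from, to) -> ps (nan if no events)
    max_waiting: dict  # (from, to) -> ps (nan if no events)
    n_frames: int
    total_time: float  # ps
    censored_state: CleftState | None = None
    censored_dwell: float = 0.0  # ps spent in the final terminal state

    def validate(self) -> None:
        assert abs(sum(self.fractions.values()) - 1.0) < 1e-9
        co = self.counts.get((CleftState.CLOSED, CleftState.OPEN), 0)
        oc = self.counts.get((CleftState.OPEN, CleftState.CLOSED), 0)
        assert self.n_events == co + oc
        assert abs(co - oc) <= 1


def cleft_series(
    traj: Trajectory,
    resA: str | Selection,
    resB: str | Selection,
    th: StateThresholds = StateThresholds(),
) -> CleftStateSeries:
    """Cleft minimum-distance series and state labels for a trajectory.

    ``resA``/``resB`` are selection expressions (e.g. ``"resid 159"``) or
    pre-built Selections; the distance is the all-atom minimum between the
    two residues, hydrogens included when present.
    """
    top = traj.topology
    sel_a = select(top, resA) if isinstance(resA, str) else resA
    sel_b = select(top, resB) if isinstance(resB, str) else resB
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise SelectionError("cleft residue selection matched no atoms")
    d = np.array(
        [min_distance(sel_a, sel_b, traj.coords[k]) for k in range(traj.n_frames)]
    )
    return CleftStateSeries(traj.times.copy(), d, th.classify(d), th)


def series_from_distances(
    times: np.ndarray,
    distances: np.ndarray,
    th: StateThresholds = StateThresholds(),
) -> CleftStateSeries:
    """Build a state series directly from a distance trace (no structure)."""
    distances = np.asarray(distances, dtype=float)
    return CleftStateSeries(np.asarray(times, float), distances,
                            th.classify(distances), th)


TERMINAL = (CleftState.CLOSED, CleftState.OPEN)


def switch_events(
    series: CleftStateSeries,
    *,
    min_dwell_ps: float = 0.0,
    exclude_transit: bool = False,
) -> tuple[list[SwitchEvent], KineticsSummary]:
    """Scan a state series for terminal-state switches.

    PARTIAL frames never emit events.  The waiting time of a switch at time
    t is t − entry, where entry is when the departing terminal state was
    entered (series start / previous event); with ``exclude_transit`` the
    clock instead stops at the last frame still in the departing state.
    ``min_dwell_ps`` > 0 debounces: terminal visits shorter than this are
    ignored (off by default; raw fluctuations are part of the signal).
    """
    if len(series) == 0:
        raise ValueError("empty series")
    states = series.states
    times = series.times

    # optional debounce: relabel terminal visits shorter than min_dwell_ps
    # as PARTIAL
    if min_dwell_ps > 0:
        states = states.copy()
        i = 0
        n = len(states)
        while i < n:
            if states[i] in TERMINAL:
                j = i
                while j + 1 < n and states[j + 1] == states[i]:
                    j += 1
                if times[j] - times[i] < min_dwell_ps and not (i == 0 or j == n - 1):
                    states[i : j + 1] = CleftState.PARTIAL
                i = j + 1
            else:
                i += 1

    events: list[SwitchEvent] = []
    current: CleftState | None = None
    entry_time = 0.0
    last_in_current = 0.0
    for t, st in zip(times, states):
        if st not in TERMINAL:
            continue
        if current is None:
            current, entry_time, last_in_current = st, float(t), float(t)
        elif st == current:
            last_in_current = float(t)
        else:
            start = last_in_current if exclude_transit else entry_time
            events.append(
                SwitchEvent(
                    from_state=current, to_state=st,
                    event_time=float(t), waiting_time=float(t) - start,
                )
            )
            current, entry_time, last_in_current = st, float(t), float(t)

    n = len(series)
    fractions = {
        s: float(np.sum(states == s)) / n
        for s in (CleftState.CLOSED, CleftState.PARTIAL, CleftState.OPEN)
    }
    counts = {
        (CleftState.CLOSED, CleftState.OPEN): 0,
        (CleftState.OPEN, CleftState.CLOSED): 0,
    }
    waits: dict = {k: [] for k in counts}
    for e in events:
        counts[(e.from_state, e.to_state)] += 1
        waits[(e.from_state, e.to_state)].append(e.waiting_time)
    summary = KineticsSummary(
        fractions=fractions,
        n_events=len(events),
        counts=counts,
        mean_waiting={k: float(np.mean(v)) if v else float("nan") for k, v in waits.items()},
        max_waiting={k: float(np.max(v)) if v else float("nan") for k, v in waits.items()},
        n_frames=n,
        total_time=float(times[-1] - times[0]) if n > 1 else 0.0,
        censored_state=current,
        censored_dwell=float(times[-1]) - entry_time if current is not None else 0.0,
    )
    summary.validate()
    return events, summary


def aggregate_kinetics(summaries: list[KineticsSummary]) -> KineticsSummary:
    """Pool replica summaries: fractions weighted by time points, events and
    waiting-time statistics pooled across replicas (replicas are never
    concatenated, so no spurious cross-replica events arise)."""
    if not summaries:
        raise ValueError("need at least one summary")
    n_total = sum(s.n_frames for s in summaries)
    fractions = {
        st: sum(s.fractions[st] * s.n_frames for s in summaries) / n_total
        for st in (CleftState.CLOSED, CleftState.PARTIAL, CleftState.OPEN)
    }
    keys = [
        (CleftState.CLOSED, CleftState.OPEN),
        (CleftState.OPEN, CleftState.CLOSED),
    ]
    counts = {k: sum(s.counts.get(k, 0) for s in summaries) for k in keys}
    mean_waiting = {}
    max_waiting = {}
    for k in keys:
        n_k = counts[k]
        if n_k == 0:
            mean_waiting[k] = float("nan")
            max_waiting[k] = float("nan")
        else:
            mean_waiting[k] = (
                sum(
                    s.mean_waiting[k] * s.counts.get(k, 0)
                    for s in summaries
                    if s.counts.get(k, 0)
                )
                / n_k
            )
            max_waiting[k] = max(
                s.max_waiting[k] for s in summaries if s.counts.get(k, 0)
            )
    out = KineticsSummary(
        fractions=fractions,
        n_events=sum(s.n_events for s in summaries),
        counts=counts,
        mean_waiting=mean_waiting,
        max_waiting=max_waiting,
        n_frames=n_total,
        total_time=sum(s.total_time for s in summaries),
    )
    # per-direction counts may differ by more than 1 when pooling replicas;
    # validate only the per-replica invariants that survive pooling
    assert abs(sum(out.fractions.values()) - 1.0) < 1e-9
    return out


@dataclass
class DistanceHistogram:
    """Density-normalised histogram of cleft distances with observed range."""

    edges: np.ndarray
    density: np.ndarray
    range: tuple[float, float]

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def modes(self, min_separation_bins: int = 2) -> list[float]:
        """Local maxima of the density, strongest first."""
        d = self.density
        peaks = [
            i
            for i in range(len(d))
            if d[i] > 0
            and all(
                d[i] >= d[j]
                for j in range(max(0, i - min_separation_bins),
                               min(len(d), i + min_separation_bins + 1))
            )
        ]
        peaks.sort(key=lambda i: -d[i])
        return [float(self.centers[i]) for i in peaks]


def distance_histogram(
    series: CleftStateSeries | np.ndarray,
    bin_width: float = 0.02,
) -> DistanceHistogram:
    """Histogram of cleft distances (density integrates to 1)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = series.distances if isinstance(series, CleftStateSeries) else np.asarray(series, float)
    lo, hi = float(d.min()), float(d.max())
    span_lo = np.floor(lo / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((hi - span_lo) / bin_width)))
    edges = span_lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] <= hi:
        edges = np.append(edges, edges[-1] + bin_width)
    density, edges = np.histogram(d, bins=edges, density=True)
    return DistanceHistogram(edges=edges, density=density, range=(lo, hi))
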