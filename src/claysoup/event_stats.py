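"""Persistent-contact ("effective clash") and cation-contact statistics.

Two statistics are computed from a trajectory:

* **Effective clashes** — heavy-atom pairs of class C–C, C–N or C–O, not
  bonded in the initial frame, that stay below their pair cutoff for a run
  of consecutive frames *longer than* the persistence window.  Each maximal
  below-cutoff run that qualifies is one event; a pair that unbinds and
  rebinds can generate several.
* **Cation contacts** — pair-frame occurrences of a cation (Ca²⁺ here)
  within a fixed cutoff (default 2.5 Å) of C, H, N or O atoms, normalised
  per picosecond of trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bondgraph_species import ThresholdTable, build_bond_graph, min_image_displacement
from .trajectory_io import Trajectory

__all__ = [
    "CLASH_CLASSES",
    "ClashEvent",
    "ClashReport",
    "ContactStats",
    "detect_clashes",
    "count_cation_contacts",
    "clash_count_convergence",
]

# Unordered heavy-atom pair classes monitored for reactive contacts.
CLASH_CLASSES = ("C-C", "C-N", "C-O")
CONTACT_PARTNERS = ("C", "H", "N", "O")
DEFAULT_PERSISTENCE_FRAMES = 100
DEFAULT_CATION_CUTOFF = 2.5  # Å


@dataclass(frozen=True)
class ClashEvent:
    """One persistent new contact episode between a heavy-atom pair."""

    atoms: tuple[int, int]
    elements: tuple[str, str]
    pair_class: str  # "C-C", "C-N", or "C-O"
    start_frame: int
    length_frames: int
    length_fs: float


@dataclass
class ClashReport:
    events: list[ClashEvent]
    counts: dict[str, int]
    persistence_frames: int

    def count(self, pair_class: str) -> int:
        return self.counts.get(pair_class, 0)


@dataclass
class ContactStats:
    """Per-partner-element cation contact tallies and per-ps rates."""

    cation: str
    cutoff: float
    tallies: dict[str, int]
    rates: dict[str, float]
    duration_ps: float


def _pair_class(a: str, b: str) -> str | None:
    pair = frozenset((a, b))
    if pair == {"C"}:
        return "C-C"
    if pair == {"C", "N"}:
        return "C-N"
    if pair == {"C", "O"}:
        return "C-O"
    return None


def _candidate_pairs(
    traj: Trajectory, thresholds: ThresholdTable
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Heavy-atom pairs of a clash class, minus pairs bonded in frame 0."""
    elements = traj.elements
    frame0_bonds = build_bond_graph(traj.frames[0], elements, traj.cell, thresholds).edges
    ii, jj, classes, cutoffs = [], [], [], []
    heavy = [i for i, e in enumerate(elements) if e in ("C", "N", "O")]
    for a_pos, i in enumerate(heavy):
        for j in heavy[a_pos + 1 :]:
            cls = _pair_class(elements[i], elements[j])
            if cls is None or (i, j) in frame0_bonds:
                continue
            ii.append(i)
            jj.append(j)
            classes.append(cls)
            cutoffs.append(thresholds.cutoff(elements[i], elements[j]))
    return np.array(ii, dtype=int), np.array(jj, dtype=int), classes, np.array(cutoffs)


def _below_cutoff_series(
    traj: Trajectory, ii: np.ndarray, jj: np.ndarray, cutoffs: np.ndarray
) -> np.ndarray:
    """(n_frames, n_pairs) boolean: min-image distance below the pair cutoff."""
    pos = traj.positions_array()
    delta = pos[:, ii, :] - pos[:, jj, :]
    delta = min_image_displacement(delta, traj.cell)
    dist = np.sqrt((delta**2).sum(axis=2))
    return dist < cutoffs[None, :]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length) pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def detect_clashes(
    traj: Trajectory,
    thresholds: ThresholdTable | None = None,
    persistence: int = DEFAULT_PERSISTENCE_FRAMES,
) -> ClashReport:
    """Find effective clashes: persistent new C–C / C–N / C–O contacts.

    A maximal run of consecutive frames with the pair below its cutoff
    counts only if strictly longer than ``persistence`` frames.  Pairs
    bonded in frame 0 are never candidates (only *newly formed* contacts
    count).
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1 frame")
    if traj.n_frames <= persistence:
        raise ValueError(
            f"trajectory of {traj.n_frames} frames cannot exceed a "
            f"{persistence}-frame persistence window"
        )
    thresholds = thresholds or ThresholdTable()
    spacing = traj.frame_spacing_fs
    ii, jj, classes, cutoffs = _candidate_pairs(traj, thresholds)
    events: list[ClashEvent] = []
    if len(ii):
        below = _below_cutoff_series(traj, ii, jj, cutoffs)
        for p in range(len(ii)):
            for start, length in _runs(below[:, p]):
                if length > persistence:
                    events.append(
                        ClashEvent(
                            atoms=(int(ii[p]), int(jj[p])),
                            elements=(traj.elements[ii[p]], traj.elements[jj[p]]),
                            pair_class=classes[p],
                            start_frame=start,
                            length_frames=length,
                            length_fs=length * spacing,
                        )
                    )
    events.sort(key=lambda e: (e.start_frame, e.atoms))
    counts = {cls: 0 for cls in CLASH_CLASSES}
    for ev in events:
        counts[ev.pair_class] += 1
    return ClashReport(events=events, counts=counts, persistence_frames=persistence)


def count_cation_contacts(
    traj: Trajectory,
    cation: str = "Ca",
    cutoff: float = DEFAULT_CATION_CUTOFF,
) -> ContactStats:
    """Count cation–X short contacts (X ∈ C, H, N, O) per picosecond.

    Every (cation, X) pair within ``cutoff`` in a frame adds one to the X
    tally; rates divide the tallies by the trajectory duration in ps.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    duration = traj.duration_ps
    cation_idx = [i for i, e in enumerate(traj.elements) if e == cation]
    tallies = {x: 0 for x in CONTACT_PARTNERS}
    if not cation_idx:
        warnings.warn(f"no {cation} atoms in trajectory; contact stats are empty")
        return ContactStats(cation, cutoff, tallies, dict(tallies), duration)
    pos = traj.positions_array()
    for x in CONTACT_PARTNERS:
        x_idx = [i for i, e in enumerate(traj.elements) if e == x]
        if not x_idx:
            continue
        delta = pos[:, cation_idx, None, :] - pos[:, None, x_idx, :]
        delta = min_image_displacement(delta, traj.cell)
        dist = np.sqrt((delta**2).sum(axis=3))
        tallies[x] = int((dist < cutoff).sum())
    rates = {x: tallies[x] / duration for x in tallies}
    return ContactStats(cation, cutoff, tallies, rates, duration)


def clash_count_convergence(
    traj: Trajectory,
    thresholds: ThresholdTable | None = None,
    persistence: int = DEFAULT_PERSISTENCE_FRAMES,
    window_ps: float = 1.0,
) -> dict[str, np.ndarray]:
    """Cumulative per-class clash counts at successive window boundaries.

    Returns ``{"time_ps": boundaries, "C-C": counts, ...}`` where the count
    at boundary *t* is the number of qualifying episodes when the
    trajectory is truncated to its first *t* picoseconds — the convergence
    diagnostic behind checking that the event count flattens with time.
    """
    thresholds = thresholds or ThresholdTable()
    spacing = traj.frame_spacing_fs
    frames_per_window = max(1, int(round(window_ps * 1000.0 / spacing)))
    boundaries = list(range(frames_per_window, traj.n_frames + 1, frames_per_window))
    if not boundaries or boundaries[-1] != traj.n_frames:
        boundaries.append(traj.n_frames)
    ii, jj, classes, cutoffs = _candidate_pairs(traj, thresholds)
    series = {cls: np.zeros(len(boundaries), dtype=int) for cls in CLASH_CLASSES}
    if len(ii):
        below = _below_cutoff_series(traj, ii, jj, cutoffs)
        for p in range(len(ii)):
            for start, length in _runs(below[:, p]):
                for b, boundary in enumerate(boundaries):
                    if min(start + length, boundary) - start > persistence:
                        series[classes[p]][b] += 1
    out: dict[str, np.ndarray] = {
        "time_ps": np.array(boundaries) * spacing / 1000.0
    }
    out.update(series)
    return out
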