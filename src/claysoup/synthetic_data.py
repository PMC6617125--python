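"""Synthetic trajectories with known chemical ground truth.

Stands in for ab initio MD output so every analysis stage can be verified
exactly.  Dynamics are kinematic, not physical: molecules undergo rigid
Gaussian positional jitter around a packed starting configuration, and a
script steers chosen atom pairs below (merge) or above (split) their
bonding cutoff for exactly prescribed frame windows.  Each generator
returns its ground truth so detector output can be asserted against it.

Three generators are provided:

* :func:`generate_trajectory` — jittered molecules + scripted
  bond-formation/breaking events;
* :func:`generate_ideal_gas` — independent uniform positions per frame,
  the null model for which g(r) ≡ 1;
* :func:`generate_cation_fixture_trajectory` — static cation + partner
  atoms at exact separations, giving closed-form contact rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bondgraph_species import (
    ThresholdTable,
    build_bond_graph,
    hill_formula,
    min_image_displacement,
)
from .chem_systems import CompositionSpec, composition_elements
from .trajectory_io import Frame, SimulationCell, Trajectory, TrajectoryMetadata

__all__ = [
    "ScriptedEvent",
    "EventScript",
    "GroundTruthEvent",
    "GenerationError",
    "generate_trajectory",
    "generate_ideal_gas",
    "generate_cation_fixture_trajectory",
    "scripted_event_benchmark",
]


class GenerationError(RuntimeError):
    """The realised trajectory deviates from its script."""

    def __init__(self, message: str, frame: int | None = None):
        if frame is not None:
            message = f"frame {frame}: {message}"
        super().__init__(message)
        self.frame = frame


@dataclass(frozen=True)
class ScriptedEvent:
    """One scripted reactive encounter.

    ``atoms`` is a global atom-index pair (i, j).  For a merge, i and j sit
    in different molecules and the molecule containing j is steered so the
    pair distance equals ``approach`` (below the bonding cutoff) during
    [onset, onset+duration).  For a split, (i, j) is a bonded pair and the
    fragment containing j is pushed out to ``approach`` (above the cutoff)
    for the window.
    """

    kind: str  # "merge" | "split"
    atoms: tuple[int, int]
    onset: int
    duration: int
    approach: float  # Å

    def __post_init__(self):
        if self.kind not in ("merge", "split"):
            raise ValueError(f"kind must be 'merge' or 'split', got {self.kind!r}")
        if self.duration < 1:
            raise ValueError("duration must be >= 1 frame")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.approach <= 0:
            raise ValueError("approach distance must be positive")


@dataclass
class EventScript:
    """A set of scripted events plus the thermal-noise amplitudes."""

    events: list[ScriptedEvent] = field(default_factory=list)
    jitter: float = 0.05  # rigid per-molecule Gaussian jitter σ, Å
    atom_jitter: float = 0.0  # optional extra per-atom jitter σ, Å
    ramp_frames: int = 10  # cosine approach/retreat length


@dataclass(frozen=True)
class GroundTruthEvent:
    """What a perfect detector must report for one scripted event."""

    kind: str
    atoms: tuple[int, int]
    pair_class: str | None  # clash class if C-C/C-N/C-O, else None
    start_frame: int
    length_frames: int
    species_formula: str  # merged species (merge) / moved fragment (split)


def _pair_class_of(a: str, b: str) -> str | None:
    pair = sorted((a, b))
    if pair == ["C", "C"]:
        return "C-C"
    if pair == ["C", "N"]:
        return "C-N"
    if pair == ["C", "O"]:
        return "C-O"
    return None


def _cosine_ramp(d_from: float, d_to: float, t: float) -> float:
    """Smooth interpolation, t ∈ [0, 1]."""
    return d_to + (d_from - d_to) * 0.5 * (1.0 + math.cos(math.pi * t))


def _unit_min_image(p_from: np.ndarray, p_to: np.ndarray, cell: SimulationCell) -> np.ndarray:
    d = min_image_displacement(p_to - p_from, cell)
    n = np.linalg.norm(d)
    if n == 0.0:
        return np.array([1.0, 0.0, 0.0])
    return d / n


def _align_rotation(v: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v onto unit vector u."""
    c = float(np.dot(v, u))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any axis perpendicular to v
        axis = np.cross(v, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(v, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2.0 * k @ k
    axis = np.cross(v, u)
    s = np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + k + k @ k * ((1.0 - c) / (s**2))


def generate_trajectory(
    initial: Frame,
    spec: CompositionSpec | list[str],
    script: EventScript,
    n_frames: int,
    frame_spacing: float = 4.0,
    seed: int = 0,
    cell: SimulationCell | None = None,
    thresholds: ThresholdTable | None = None,
    validate: bool = True,
) -> tuple[Trajectory, list[GroundTruthEvent]]:
    """Jittered rigid-body trajectory with scripted bond events.

    Molecule membership comes from the initial frame's bond graph.  During
    a merge window the scripted pair distance is held *exactly* at the
    approach value (below cutoff); the cosine ramps before and after stay
    above the cutoff, so the below-cutoff window is exactly
    [onset, onset+duration).  Splits mirror this above the cutoff.  With
    ``validate=True`` every frame's bond graph is checked against the
    scripted expectation and any unscripted bond raises
    :class:`GenerationError` naming the frame.
    """
    if cell is None:
        raise ValueError("a SimulationCell is required")
    thresholds = thresholds or ThresholdTable()
    elements = (
        composition_elements(spec) if isinstance(spec, CompositionSpec) else list(spec)
    )
    if len(elements) != initial.n_atoms:
        raise ValueError("composition and initial frame disagree on atom count")
    base = np.asarray(initial.positions, dtype=float)
    n = len(elements)
    bg0 = build_bond_graph(initial, elements, cell, thresholds)
    molecules = [sorted(c) for c in nx.connected_components(bg0.graph)]
    mol_of = np.empty(n, dtype=int)
    for m, atoms in enumerate(molecules):
        mol_of[atoms] = m

    # resolve each event: moving atom group, schedule, cutoff
    resolved = []
    truth: list[GroundTruthEvent] = []
    ramp = script.ramp_frames
    busy: dict[int, list[tuple[int, int]]] = {}
    for ev in script.events:
        i, j = ev.atoms
        cutoff = thresholds.cutoff(elements[i], elements[j])
        if cutoff <= 0:
            raise ValueError(f"pair {ev.atoms} has no bonding cutoff; cannot script it")
        d0 = float(np.linalg.norm(min_image_displacement(base[j] - base[i], cell)))
        if ev.kind == "merge":
            if mol_of[i] == mol_of[j]:
                raise ValueError(f"merge atoms {ev.atoms} are in the same molecule")
            if ev.approach >= cutoff:
                raise ValueError(
                    f"merge approach {ev.approach} must lie below the cutoff {cutoff}"
                )
            if d0 <= cutoff + 0.2:
                raise ValueError(
                    f"merge pair {ev.atoms} starts at {d0:.2f} Å, too close to script"
                )
            moving = list(molecules[mol_of[j]])
            formula = hill_formula(
                elements[a] for a in molecules[mol_of[i]] + molecules[mol_of[j]]
            )
        else:
            if (min(i, j), max(i, j)) not in bg0.edges:
                raise ValueError(f"split atoms {ev.atoms} are not bonded in frame 0")
            if ev.approach <= cutoff:
                raise ValueError(
                    f"split approach {ev.approach} must lie above the cutoff {cutoff}"
                )
            sub = bg0.graph.subgraph(molecules[mol_of[i]]).copy()
            sub.remove_edge(i, j)
            frag = sorted(nx.node_connected_component(sub, j))
            if i in frag:
                raise ValueError(f"removing bond {ev.atoms} does not split its molecule")
            moving = frag
            formula = hill_formula(elements[a] for a in frag)
        span = (ev.onset - ramp, ev.onset + ev.duration + ramp)
        for m in {int(mol_of[a]) for a in moving} | {int(mol_of[i])}:
            for s0, s1 in busy.get(m, []):
                if span[0] < s1 and s0 < span[1]:
                    raise ValueError(
                        f"events overlap on molecule {m} in frames {span} vs ({s0},{s1})"
                    )
            busy.setdefault(m, []).append(span)
        resolved.append((ev, np.array(moving), cutoff, d0))
        truth.append(
            GroundTruthEvent(
                kind=ev.kind,
                atoms=(min(i, j), max(i, j)),
                pair_class=_pair_class_of(elements[i], elements[j]),
                start_frame=ev.onset,
                length_frames=ev.duration,
                species_formula=formula,
            )
        )

    margin = 0.1
    rng = np.random.default_rng(seed)
    frames: list[Frame] = []
    for f in range(n_frames):
        pos = base.copy()
        for atoms in molecules:
            pos[atoms] += rng.normal(0.0, script.jitter, 3)
        if script.atom_jitter > 0.0:
            pos += rng.normal(0.0, script.atom_jitter, (n, 3))
        for ev, moving, cutoff, d0 in resolved:
            i, j = ev.atoms
            hold0, hold1 = ev.onset, ev.onset + ev.duration
            if f < hold0 - ramp or f >= hold1 + ramp:
                continue
            if ev.kind == "merge":
                edge_val = cutoff + margin
                inside_val = ev.approach
            else:
                edge_val = max(cutoff - 0.03, 0.5 * cutoff)
                inside_val = ev.approach
            if f < hold0:  # approach ramp, stays on the unreactive side
                t = (f - (hold0 - ramp) + 1) / (ramp + 1)
                d_t = _cosine_ramp(d0, edge_val, t)
            elif f < hold1:
                d_t = inside_val
            else:  # retreat ramp
                t = (f - hold1 + 1) / (ramp + 1)
                d_t = _cosine_ramp(edge_val, d0, 1.0 - t)
            u = _unit_min_image(pos[i], pos[j], cell)
            if ev.kind == "merge":
                rel = pos[moving] - pos[j]
                centroid = rel.mean(axis=0)
                cn = np.linalg.norm(centroid)
                if cn > 1e-9:
                    rot = _align_rotation(centroid / cn, u)
                    rel = rel @ rot.T
                pos[moving] = pos[i] + u * d_t + rel
            else:
                d_cur = float(
                    np.linalg.norm(min_image_displacement(pos[j] - pos[i], cell))
                )
                pos[moving] += u * (d_t - d_cur)
        frames.append(Frame(index=f, time=f * frame_spacing, positions=pos))

    traj = Trajectory(
        elements=elements,
        frames=frames,
        cell=cell,
        metadata=TrajectoryMetadata(),
    )
    if validate:
        _validate_against_script(traj, thresholds, bg0.edges, resolved)
    return traj, truth


def _validate_against_script(traj, thresholds, edges0, resolved) -> None:
    for f, frame in enumerate(traj.frames):
        expected = set(edges0)
        for ev, _, _, _ in resolved:
            i, j = sorted(ev.atoms)
            if ev.onset <= f < ev.onset + ev.duration:
                if ev.kind == "merge":
                    expected.add((i, j))
                else:
                    expected.discard((i, j))
        got = build_bond_graph(frame, traj.elements, traj.cell, thresholds).edges
        if got != expected:
            extra = got - expected
            missing = expected - got
            raise GenerationError(
                f"bond graph deviates from script (unscripted: {sorted(extra)}, "
                f"missing: {sorted(missing)})",
                frame=f,
            )


def generate_ideal_gas(
    n_atoms: int,
    element: str,
    cell: SimulationCell,
    n_frames: int,
    seed: int = 0,
    frame_spacing: float = 4.0,
) -> Trajectory:
    """Uncorrelated uniform positions each frame — the g(r) ≡ 1 null model."""
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    frames = [
        Frame(
            index=f,
            time=f * frame_spacing,
            positions=rng.uniform(0.0, cell.lengths, (n_atoms, 3)),
        )
        for f in range(n_frames)
    ]
    return Trajectory(elements=[element] * n_atoms, frames=frames, cell=cell)


def _sphere_directions(k: int) -> np.ndarray:
    """k well-spread unit vectors (golden-spiral construction)."""
    idx = np.arange(k) + 0.5
    phi = np.arccos(1.0 - 2.0 * idx / k)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * idx
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def generate_cation_fixture_trajectory(
    n_ca: int,
    partner_distances: list[float],
    n_frames: int = 1000,
    frame_spacing: float = 4.0,
    partner_element: str = "O",
    cell: SimulationCell | None = None,
) -> Trajectory:
    """Static cations with partner atoms at exact separations.

    All partners surround the first Ca at the given distances along
    well-spread directions; further Ca ions sit 12 Å apart.  Contact rates
    are then known in closed form: a partner at d < cutoff contributes
    n_frames tallies, i.e. a rate of 1000/frame_spacing_fs per ps.
    """
    if n_ca < 1:
        raise ValueError("need at least one cation")
    if any(d <= 0 for d in partner_distances):
        raise ValueError("partner distances must be positive")
    size = max(40.0, 12.0 * n_ca + 20.0)
    cell = cell or SimulationCell(size, size, size)
    coords = [np.array([8.0 + 12.0 * k, 8.0, 8.0]) for k in range(n_ca)]
    elements = ["Ca"] * n_ca
    dirs = _sphere_directions(max(len(partner_distances), 1))
    for d, u in zip(partner_distances, dirs):
        coords.append(coords[0] + d * u)
        elements.append(partner_element)
    pos = np.array(coords)
    frames = [
        Frame(index=f, time=f * frame_spacing, positions=pos.copy())
        for f in range(n_frames)
    ]
    return Trajectory(elements=elements, frames=frames, cell=cell)


def _oriented(template: np.ndarray, flip: bool, origin_atom: int, at: np.ndarray) -> np.ndarray:
    """Template coordinates, optionally mirrored in x, with one atom at ``at``."""
    c = template.copy()
    if flip:
        c[:, 0] = -c[:, 0]
    return c - c[origin_atom] + at


def scripted_event_benchmark(
    n_merge: int = 3,
    n_split: int = 1,
    n_frames: int = 600,
    durations: list[int] | None = None,
    seed: int = 0,
    frame_spacing: float = 4.0,
    thresholds: ThresholdTable | None = None,
):
    """A sparse box of facing molecule pairs with one scripted event each.

    Every event gets its own cluster on a grid (12 Å × 9 Å × 9 Å spacing),
    so events are independent and their ground truth is exact.  Merge
    clusters cycle through the three monitored pair classes — CO···CO
    (C–C), HCN···CO (C–N) and H2O···CO (C–O) — with the reactive atoms
    facing each other 4.5 Å apart; split clusters are single water
    molecules losing one O–H bond.  Returns the generated trajectory and
    its ground truth.
    """
    from .chem_systems import MOLECULES

    thresholds = thresholds or ThresholdTable()
    rng = np.random.default_rng(seed)
    n_events = n_merge + n_split
    if durations is None:
        durations = [150] * n_events
    if len(durations) != n_events:
        raise ValueError("need one duration per event")
    nx_ = max(1, math.ceil(n_events ** (1.0 / 3.0)))
    ny_ = max(1, math.ceil(math.sqrt(n_events / nx_)))
    nz_ = max(1, math.ceil(n_events / (nx_ * ny_)))
    sx, sy, sz = 12.0, 9.0, 9.0
    cell = SimulationCell(nx_ * sx, ny_ * sy, nz_ * sz)

    co = MOLECULES["CO"].coords  # C at origin, O at +x
    hcn = MOLECULES["HCN"].coords
    h2o = MOLECULES["H2O"].coords
    # water rotated so the H-H bisector points -x: O faces the partner
    h2o_facing = h2o[:, [1, 0, 2]] * np.array([-1.0, 1.0, 1.0])
    d0 = 4.5
    merge_kinds = [
        # (left template, elements, flip, left reactive atom, right reactive atom, approach)
        (co, MOLECULES["CO"].elements, True, 0, 0, 1.55),  # C-C
        (hcn, MOLECULES["HCN"].elements, False, 2, 0, 1.45),  # N(HCN)···C(CO)
        (h2o_facing, MOLECULES["H2O"].elements, False, 0, 0, 1.43),  # O(H2O)···C(CO)
    ]
    elements: list[str] = []
    coords: list[np.ndarray] = []
    events: list[ScriptedEvent] = []
    ramp = 10
    for k in range(n_events):
        ix, iy, iz = k % nx_, (k // nx_) % ny_, k // (nx_ * ny_)
        origin = np.array([ix * sx + 2.5, iy * sy + 4.5, iz * sz + 4.5])
        duration = durations[k]
        lo = ramp + 1
        hi = n_frames - duration - ramp - 1
        onset = int(rng.integers(lo, max(lo + 1, hi)))
        if k < n_merge:
            left, left_els, flip, i_local, j_local, approach = merge_kinds[k % 3]
            # left molecule with its reactive atom at origin, body pointing -x
            lcoords = _oriented(left, flip=flip, origin_atom=i_local, at=origin)
            i_global = len(elements) + i_local
            elements.extend(left_els)
            coords.append(lcoords)
            # facing CO with its C toward the left molecule, O pointing +x
            rcoords = _oriented(co, flip=False, origin_atom=0, at=origin + [d0, 0, 0])
            j_global = len(elements) + j_local
            elements.extend(MOLECULES["CO"].elements)
            coords.append(rcoords)
            events.append(
                ScriptedEvent("merge", (i_global, j_global), onset, duration, approach)
            )
        else:
            wcoords = _oriented(h2o, flip=False, origin_atom=0, at=origin)
            i_global = len(elements)  # O
            j_global = len(elements) + 1  # first H
            elements.extend(MOLECULES["H2O"].elements)
            coords.append(wcoords)
            events.append(
                ScriptedEvent("split", (i_global, j_global), onset, duration, 1.6)
            )
    initial = Frame(index=0, time=0.0, positions=np.vstack(coords))
    script = EventScript(events=events, ramp_frames=ramp)
    return generate_trajectory(
        initial,
        elements,
        script,
        n_frames=n_frames,
        frame_spacing=frame_spacing,
        seed=seed,
        cell=cell,
        thresholds=thresholds,
    )
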