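"""Per-frame bond graphs, molecular species, and lifetimes.

A frame becomes an undirected graph over atoms: an edge joins two atoms
whose minimum-image distance falls below the pair-specific bonding cutoff.
Connected components are molecular species; each gets a Hill-order formula
and a canonical key (Weisfeiler–Lehman graph hash over element labels) so
isomeric connectivities are told apart while atom numbering is irrelevant.
Species are tracked through time by their exact atom-index set: a species
record is a maximal contiguous run of frames over which the same atom set
keeps the same connectivity, and a species is *new* if its (atom set, key)
pair is absent from the first frame's partition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .trajectory_io import Frame, SimulationCell, Trajectory

__all__ = [
    "COVALENT_RADII",
    "NONBONDING_ELEMENTS",
    "ThresholdTable",
    "BondGraph",
    "SpeciesRecord",
    "min_image_distance",
    "min_image_displacement",
    "build_bond_graph",
    "partition_species",
    "track_species",
    "hill_formula",
]

# Single-bond covalent radii (Å), Cordero et al. consensus values.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Na": 1.66,
    "Mg": 1.41,
    "Al": 1.21,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "K": 2.03,
    "Ca": 1.76,
}

# Ionic species excluded from covalent bond graphs; their contacts are
# counted separately by event_stats.
NONBONDING_ELEMENTS = frozenset({"Ca", "Na", "K", "Mg"})

# Heavy-pair cutoffs: standard single-bond lengths + 0.1 Å vibrational margin.
# H-H needs an explicit entry: the covalent-radius sum (0.72 Å) undershoots
# the actual H2 bond (0.74 Å); bond length + 0.1 gives 0.84.
_DEFAULT_OVERRIDES = {
    ("C", "C"): 1.64,
    ("C", "N"): 1.57,
    ("C", "O"): 1.53,
    ("H", "H"): 0.84,
}

VIBRATIONAL_MARGIN = 0.1  # Å added to covalent-radius sums


class ThresholdTable:
    """Symmetric (element, element) → bonding-cutoff map in Å.

    Pairs without an explicit entry fall back to the sum of single-bond
    covalent radii plus 0.1 Å.  Elements in ``nonbonding`` never bond.
    """

    def __init__(
        self,
        overrides: dict[tuple[str, str], float] | None = None,
        nonbonding: frozenset[str] = NONBONDING_ELEMENTS,
    ):
        self._table: dict[frozenset, float] = {}
        self.nonbonding = nonbonding
        merged = dict(_DEFAULT_OVERRIDES)
        if overrides:
            merged.update(overrides)
        for (a, b), r in merged.items():
            if r <= 0:
                raise ValueError(f"cutoff for ({a},{b}) must be > 0, got {r}")
            self._table[frozenset((a, b))] = r

    def cutoff(self, a: str, b: str) -> float:
        """Bonding cutoff for an element pair; 0.0 if either never bonds."""
        if a in self.nonbonding or b in self.nonbonding:
            return 0.0
        key = frozenset((a, b))
        if key in self._table:
            return self._table[key]
        try:
            r = COVALENT_RADII[a] + COVALENT_RADII[b] + VIBRATIONAL_MARGIN
        except KeyError as exc:
            raise KeyError(
                f"no bonding cutoff or covalent radius for element {exc.args[0]!r}"
            ) from None
        self._table[key] = r
        return r

    def max_cutoff(self, elements: set[str]) -> float:
        vals = [
            self.cutoff(a, b)
            for a in elements
            for b in elements
        ]
        return max(vals) if vals else 0.0


def min_image_distance(p, q, cell: SimulationCell) -> float:
    """Minimum-image distance between two points in an orthorhombic cell."""
    delta = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    lengths = cell.lengths
    delta -= lengths * np.round(delta / lengths)
    return float(np.linalg.norm(delta))


def min_image_displacement(delta: np.ndarray, cell: SimulationCell) -> np.ndarray:
    """Apply the minimum-image convention to an array of displacement vectors."""
    delta = np.asarray(delta, dtype=float)
    lengths = cell.lengths
    return delta - lengths * np.round(delta / lengths)


@dataclass
class BondGraph:
    """Undirected bond adjacency over atom indices for one frame."""

    frame_index: int
    graph: nx.Graph  # nodes carry an 'element' attribute

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}

    @property
    def n_atoms(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class SpeciesRecord:
    """One molecular species over a contiguous run of frames."""

    atoms: frozenset[int]
    key: str  # canonical connectivity key
    formula: str  # Hill-order formula
    first_frame: int
    last_frame: int
    is_new: bool = False
    frame_spacing_fs: float = 4.0

    @property
    def lifetime_frames(self) -> int:
        return self.last_frame - self.first_frame + 1

    @property
    def lifetime_ps(self) -> float:
        return self.lifetime_frames * self.frame_spacing_fs / 1000.0

    @property
    def identity(self) -> tuple[frozenset[int], str]:
        return (self.atoms, self.key)


def hill_formula(elements) -> str:
    """Hill-convention formula: C first, H second, the rest alphabetical.

    Without carbon, all elements (hydrogen included) sort alphabetically.
    """
    counts = Counter(elements)
    order: list[str] = []
    if "C" in counts:
        order.append("C")
        if "H" in counts:
            order.append("H")
        order.extend(sorted(e for e in counts if e not in ("C", "H")))
    else:
        order.extend(sorted(counts))
    return "".join(f"{e}{counts[e]}" if counts[e] > 1 else e for e in order)


def build_bond_graph(
    frame: Frame,
    elements: list[str],
    cell: SimulationCell,
    thresholds: ThresholdTable | None = None,
) -> BondGraph:
    """Bond graph of one frame: edge iff min-image distance < pair cutoff."""
    thresholds = thresholds or ThresholdTable()
    n = len(elements)
    g = nx.Graph()
    for i, el in enumerate(elements):
        g.add_node(i, element=el)
    if n >= 2:
        pos = frame.positions
        delta = pos[:, None, :] - pos[None, :, :]
        delta = min_image_displacement(delta, cell)
        dist = np.sqrt((delta**2).sum(axis=2))
        cut = np.zeros((n, n))
        uniq = sorted(set(elements))
        el_idx = {e: np.array([i for i, x in enumerate(elements) if x == e]) for e in uniq}
        for a in uniq:
            for b in uniq:
                cut[np.ix_(el_idx[a], el_idx[b])] = thresholds.cutoff(a, b)
        ii, jj = np.where(np.triu(dist < cut, k=1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return BondGraph(frame_index=frame.index, graph=g)


def _canonical_key(graph: nx.Graph, atoms: list[int]) -> str:
    sub = graph.subgraph(atoms)
    return nx.weisfeiler_lehman_graph_hash(sub, node_attr="element", iterations=3)


def partition_species(
    bond_graph: BondGraph,
    elements: list[str],
    frame_spacing_fs: float = 4.0,
    _key_cache: dict | None = None,
) -> list[SpeciesRecord]:
    """Split one frame's bond graph into molecular species.

    Components are returned sorted by lowest atom index; atom sets are
    pairwise disjoint and cover every atom.
    """
    records = []
    for comp in nx.connected_components(bond_graph.graph):
        atoms = sorted(comp)
        if _key_cache is not None:
            edges = frozenset(
                (min(u, v), max(u, v)) for u, v in bond_graph.graph.subgraph(atoms).edges
            )
            cache_id = (tuple(atoms), edges)
            key = _key_cache.get(cache_id)
            if key is None:
                key = _canonical_key(bond_graph.graph, atoms)
                _key_cache[cache_id] = key
        else:
            key = _canonical_key(bond_graph.graph, atoms)
        records.append(
            SpeciesRecord(
                atoms=frozenset(atoms),
                key=key,
                formula=hill_formula(elements[i] for i in atoms),
                first_frame=bond_graph.frame_index,
                last_frame=bond_graph.frame_index,
                frame_spacing_fs=frame_spacing_fs,
            )
        )
    return sorted(records, key=lambda r: min(r.atoms))


def track_species(
    traj: Trajectory,
    thresholds: ThresholdTable | None = None,
    min_lifetime_frames: int = 1,
) -> list[SpeciesRecord]:
    """Track species through a trajectory and report lifetimes.

    A record spans the maximal contiguous run of frames over which the same
    atom set keeps the same canonical key; any change of membership or
    connectivity closes the record.  ``is_new`` marks identities absent
    from frame 0.
    """
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    thresholds = thresholds or ThresholdTable()
    spacing = traj.frame_spacing_fs
    key_cache: dict = {}
    active: dict[tuple[frozenset[int], str], SpeciesRecord] = {}
    closed: list[SpeciesRecord] = []
    initial_identities: set[tuple[frozenset[int], str]] = set()
    for f, frame in enumerate(traj.frames):
        bg = build_bond_graph(frame, traj.elements, traj.cell, thresholds)
        bg.frame_index = f
        current = partition_species(bg, traj.elements, spacing, _key_cache=key_cache)
        if f == 0:
            initial_identities = {r.identity for r in current}
        seen: set[tuple[frozenset[int], str]] = set()
        for rec in current:
            ident = rec.identity
            seen.add(ident)
            if ident in active and active[ident].last_frame == f - 1:
                active[ident].last_frame = f
            else:
                if ident in active:
                    closed.append(active.pop(ident))
                rec.is_new = ident not in initial_identities
                active[ident] = rec
        for ident in [i for i in active if i not in seen]:
            closed.append(active.pop(ident))
    closed.extend(active.values())
    closed.sort(key=lambda r: (r.first_frame, min(r.atoms)))
    return [r for r in closed if r.lifetime_frames >= min_lifetime_frames]
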