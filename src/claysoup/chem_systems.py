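"""Simulation-box builder for the prebiotic-mixture study systems.

Defines the nine small-molecule templates (H2O, NH3, CH4, H2, N2, CO,
formaldehyde, HCN, glycine), the eight named box compositions (g0–g3 pure
condensed phase, m0–m3 with a montmorillonite slab), density-consistent
cell heights, random rigid-body packing with a minimum-separation
constraint, and a layered-slab + 8 Ca²⁺ fixture.

The g/m naming follows the Miller–Strecker staging of the mixtures:
0 = Miller–Urey substrates, 1 = reactants, 2 = intermediates (formaldehyde
+ HCN), 3 = products (glycine + ammonia).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory_io import Frame, SimulationCell

__all__ = [
    "ATOMIC_MASSES",
    "AVOGADRO",
    "MoleculeTemplate",
    "CompositionSpec",
    "SlabFixture",
    "PackingError",
    "MOLECULES",
    "BOX_MIXTURES",
    "BOX_IDS",
    "composition_for_box",
    "atom_count",
    "molar_mass",
    "cell_height_for_density",
    "composition_elements",
    "pack_box",
    "build_slab_fixture",
    "box_cell",
]

AVOGADRO = 6.02214076e23  # mol⁻¹

# Standard atomic weights, g/mol (CIAAW conventional values, 5 sig figs).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "Ca": 40.078,
}


class PackingError(RuntimeError):
    """Packing could not satisfy the minimum-separation constraint."""

    def __init__(self, message: str, best_min_sep: float):
        super().__init__(f"{message} (best achieved min separation {best_min_sep:.3f} Å)")
        self.best_min_sep = best_min_sep


@dataclass(frozen=True)
class MoleculeTemplate:
    """Rigid internal geometry of one molecule (Cartesian Å, arbitrary frame)."""

    name: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (n, 3)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def molar_mass(self) -> float:
        return sum(ATOMIC_MASSES[e] for e in self.elements)

    def centered(self) -> np.ndarray:
        c = np.asarray(self.coords, dtype=float)
        return c - c.mean(axis=0)


def _mol(name: str, atoms: list[tuple[str, float, float, float]]) -> MoleculeTemplate:
    els = tuple(a[0] for a in atoms)
    xyz = np.array([[a[1], a[2], a[3]] for a in atoms], dtype=float)
    return MoleculeTemplate(name=name, elements=els, coords=xyz)


# Gas-phase experimental geometries (bond lengths within the bonding cutoffs
# used by bondgraph_species; glycine is the neutral NH2-CH2-COOH conformer).
MOLECULES: dict[str, MoleculeTemplate] = {
    m.name: m
    for m in [
        _mol("H2O", [("O", 0.0, 0.0, 0.0), ("H", 0.7571, 0.5861, 0.0), ("H", -0.7571, 0.5861, 0.0)]),
        _mol(
            "NH3",
            [
                ("N", 0.0, 0.0, 0.0),
                ("H", 0.9377, 0.0, -0.3816),
                ("H", -0.4689, 0.8121, -0.3816),
                ("H", -0.4689, -0.8121, -0.3816),
            ],
        ),
        _mol(
            "CH4",
            [
                ("C", 0.0, 0.0, 0.0),
                ("H", 0.6276, 0.6276, 0.6276),
                ("H", 0.6276, -0.6276, -0.6276),
                ("H", -0.6276, 0.6276, -0.6276),
                ("H", -0.6276, -0.6276, 0.6276),
            ],
        ),
        _mol("H2", [("H", 0.0, 0.0, 0.0), ("H", 0.741, 0.0, 0.0)]),
        _mol("N2", [("N", 0.0, 0.0, 0.0), ("N", 1.098, 0.0, 0.0)]),
        _mol("CO", [("C", 0.0, 0.0, 0.0), ("O", 1.128, 0.0, 0.0)]),
        _mol(
            "H2CO",
            [
                ("C", 0.0, 0.0, 0.0),
                ("O", 1.205, 0.0, 0.0),
                ("H", -0.582, 0.935, 0.0),
                ("H", -0.582, -0.935, 0.0),
            ],
        ),
        _mol("HCN", [("H", -1.064, 0.0, 0.0), ("C", 0.0, 0.0, 0.0), ("N", 1.156, 0.0, 0.0)]),
        _mol(
            "Glycine",
            [
                ("N", -1.931, 0.316, -0.265),
                ("H", -2.507, -0.485, -0.059),
                ("H", -2.437, 1.143, -0.005),
                ("C", -0.563, 0.246, 0.244),
                ("H", -0.592, 0.308, 1.337),
                ("H", -0.091, 1.149, -0.147),
                ("C", 0.259, -0.965, -0.121),
                ("O", 0.0, -2.061, 0.327),
                ("O", 1.364, -0.738, -0.868),
                ("H", 1.807, -1.590, -0.952),
            ],
        ),
    ]
}


@dataclass
class CompositionSpec:
    """Molecular inventory of one simulation box."""

    entries: list[tuple[MoleculeTemplate, int]]
    slab: bool = False
    temperature: float = 300.0
    box_id: str | None = None

    def __post_init__(self):
        for mol, count in self.entries:
            if count <= 0:
                raise ValueError(f"copy count for {mol.name} must be > 0, got {count}")


@dataclass
class SlabFixture:
    """Layered aluminosilicate slab + 8 interlayer Ca²⁺, 152 atoms total.

    Synthetic stand-in for a montmorillonite fragment: two parallel
    Si/Al/O/H sheets normal to the c axis enclosing an open gallery.  The
    framework is a pyrophyllite-like grid satisfying the study's box
    constraints (144 framework atoms, 8 Ca, gallery ≈ 8 Å), not a
    crystallographic unit cell.
    """

    elements: list[str]
    coords: np.ndarray
    sheet_thickness: float
    cell: SimulationCell

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_ca(self) -> int:
        return sum(1 for e in self.elements if e == "Ca")

    @property
    def gallery_height(self) -> float:
        """Open interlayer space along c, Å."""
        return self.cell.c - 2.0 * self.sheet_thickness

    def gallery_z_range(self) -> tuple[float, float]:
        return self.sheet_thickness, self.cell.c - self.sheet_thickness


# Table-style mixture definitions for the eight named boxes.
BOX_MIXTURES: dict[str, list[tuple[str, int]]] = {
    "g0": [("H2O", 32), ("NH3", 8), ("CH4", 8), ("H2", 4)],
    "g1": [("H2O", 8), ("NH3", 8), ("CH4", 8), ("N2", 5), ("CO", 10)],
    "g2": [("H2O", 9), ("NH3", 9), ("H2CO", 9), ("HCN", 9)],
    "g3": [("NH3", 9), ("Glycine", 9)],
}
BOX_MIXTURES.update({f"m{i}": BOX_MIXTURES[f"g{i}"] for i in range(4)})
BOX_IDS = tuple(f"{env}{stage}" for env in "gm" for stage in range(4))

# Printed cell heights (c, Å) of the named boxes; a and b are common.
BOX_A, BOX_B = 10.30, 17.96
BOX_C: dict[str, float] = {
    "g0": 10.43,
    "g1": 7.41,
    "g2": 7.41,
    "g3": 7.41,
    "m0": 18.07,
    "m1": 17.90,
    "m2": 17.90,
    "m3": 17.90,
}
TEMPERATURES = (300.0, 400.0, 600.0)


def _parse_box_id(box_id: str) -> tuple[str, float]:
    base = box_id[:2]
    if base not in BOX_MIXTURES:
        raise ValueError(f"unknown box id {box_id!r}; expected g0–g3 / m0–m3")
    temp = 300.0
    if len(box_id) > 2:
        temp = float(box_id[2:])
        if temp not in TEMPERATURES:
            raise ValueError(f"temperature {temp:g} K not one of {TEMPERATURES}")
    return base, temp


def composition_for_box(box_id: str) -> CompositionSpec:
    """CompositionSpec for a named box id like ``'g1'`` or ``'m2400'``."""
    base, temp = _parse_box_id(box_id)
    entries = [(MOLECULES[name], n) for name, n in BOX_MIXTURES[base]]
    return CompositionSpec(
        entries=entries, slab=base.startswith("m"), temperature=temp, box_id=box_id
    )


def box_cell(box_id: str) -> SimulationCell:
    """The printed cell of a named box."""
    base, _ = _parse_box_id(box_id)
    return SimulationCell(BOX_A, BOX_B, BOX_C[base])


def atom_count(spec: CompositionSpec) -> int:
    """Total number of atoms in the box, slab fixture included if flagged."""
    n = sum(mol.n_atoms * count for mol, count in spec.entries)
    if spec.slab:
        n += build_slab_fixture().n_atoms
    return n


def molar_mass(spec: CompositionSpec) -> float:
    """Summed molar mass of the molecular inventory (slab excluded), g/mol."""
    return sum(mol.molar_mass * count for mol, count in spec.entries)


def cell_height_for_density(
    spec: CompositionSpec, a: float, b: float, density: float
) -> float:
    """Cell height c (Å) that puts the mixture at the given density (g/mL).

    c = M_total / (N_A · ρ · a · b), with the 10⁻²⁴ cm³/Å³ conversion folded
    in.  Only meaningful for the slab-free, gas-like boxes.
    """
    if spec.slab:
        raise ValueError("cell_height_for_density applies to slab-free boxes only")
    if density <= 0:
        raise ValueError("density must be positive")
    m_total = molar_mass(spec)  # g/mol
    volume = m_total / (AVOGADRO * density * 1e-24)  # Å³
    return volume / (a * b)


def composition_elements(spec: CompositionSpec) -> list[str]:
    """Element symbols of the box in packing order (slab first if present)."""
    elements: list[str] = []
    if spec.slab:
        elements.extend(build_slab_fixture().elements)
    for mol, count in spec.entries:
        elements.extend(list(mol.elements) * count)
    return elements


def _grid(nx: int, ny: int, a: float, b: float, ox: float, oy: float) -> np.ndarray:
    xs = (np.arange(nx) + ox) * (a / nx)
    ys = (np.arange(ny) + oy) * (b / ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def _sheet_atoms(a: float, spacing: float = 1.7) -> list[tuple[str, float, float, float]]:
    """One 72-atom connected sheet in local coordinates (z relative to base).

    A serpentine cation–oxygen network: 8 rows of 6 atoms alternating
    Si/Al and O in both directions, so every in-plane and inter-row
    neighbour is a bonded metal–oxygen pair and the sheet is a single
    connected component.  Sixteen surface oxygens cap the Si atoms from
    the gallery side and eight hydroxyl protons hang below the central
    chain oxygens.  Per sheet: 16 Si, 8 Al, 40 O, 8 H.
    """
    atoms: list[tuple[str, float, float, float]] = []
    x0, y0 = 1.0, 2.0
    z_chain, z_surf, z_h = 2.80, 4.30, 1.85
    for row in range(8):
        y = y0 + row * spacing
        cation_cols = (0, 2, 4) if row % 2 == 0 else (1, 3, 5)
        for col in range(6):
            x = x0 + col * spacing
            if col in cation_cols:
                el = "Al" if col == cation_cols[1] else "Si"
                atoms.append((el, x, y, z_chain))
                if el == "Si":
                    atoms.append(("O", x, y, z_surf))  # gallery-facing cap
            else:
                atoms.append(("O", x, y, z_chain))
                if col == (3 if row % 2 == 0 else 2):
                    atoms.append(("H", x, y, z_h))  # hydroxyl proton
    return atoms


def build_slab_fixture(cell: SimulationCell | None = None) -> SlabFixture:
    """Construct the 152-atom slab + Ca²⁺ fixture.

    Two connected 72-atom Si/Al/O/H sheets hug the c-axis boundaries of
    the cell (the slab is contiguous across the periodic boundary), so the
    open ≈8 Å gallery sits in the middle of the box.  Eight Ca ions
    decorate the gallery-facing surfaces, four per sheet.  Each sheet is a
    single connected component of the bond graph, with no inter-sheet or
    sheet–cation bonds.
    """
    if cell is None:
        cell = SimulationCell(BOX_A, BOX_B, 17.90)
    a, b, c = cell.a, cell.b, cell.c
    thickness = 4.95
    sheet = _sheet_atoms(a)
    elements: list[str] = []
    coords: list[np.ndarray] = []
    for side in (0, 1):
        off = 0.85 * side  # stagger the top sheet in-plane
        for el, x, y, z in sheet:
            zz = z if side == 0 else c - z
            elements.append(el)
            coords.append(np.array([(x + off) % a, (y + off) % b, zz]))
    # 8 Ca ions ~1 Å off the gallery-facing surface-oxygen layers.
    for side, zca in ((0, 5.30), (1, c - 5.30)):
        xy = _grid(2, 2, a, b, 0.5 + 0.27 * side, 0.5 + 0.27 * side)
        for x, y in xy:
            elements.append("Ca")
            coords.append(np.array([x, y, zca]))
    return SlabFixture(
        elements=elements,
        coords=np.array(coords),
        sheet_thickness=thickness,
        cell=cell,
    )


def _min_image_sep(points: np.ndarray, others: np.ndarray, lengths: np.ndarray) -> float:
    delta = points[:, None, :] - others[None, :, :]
    delta -= lengths * np.round(delta / lengths)
    return float(np.sqrt((delta**2).sum(axis=2)).min())


def _batch_min_sep(cands: np.ndarray, others: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Min-image nearest-obstacle distance for each candidate placement.

    ``cands`` is (batch, n_atoms, 3); returns (batch,) minima.
    """
    delta = cands[:, :, None, :] - others[None, None, :, :]
    delta -= lengths * np.round(delta / lengths)
    return np.sqrt((delta**2).sum(axis=3)).min(axis=(1, 2))


def _relax_packing(
    mols_coords: list[np.ndarray],
    fixed: np.ndarray,
    lengths: np.ndarray,
    min_sep: float,
    rng: np.random.Generator,
    max_iters: int = 3000,
    fixed_sep: float | None = None,
) -> list[np.ndarray] | None:
    """Rigidly push overlapping molecules apart until ``min_sep`` holds.

    Translations only (orientations are kept); fixed obstacle atoms never
    move.  Returns the relaxed coordinates, or None if the constraint is
    still violated after ``max_iters`` sweeps.
    """
    sizes = [len(c) for c in mols_coords]
    mol_id = np.concatenate(
        [np.full(s, m) for m, s in enumerate(sizes)] + [np.full(len(fixed), -1)]
    )
    coords = np.vstack(mols_coords + [fixed]) if len(fixed) else np.vstack(mols_coords)
    n_mobile = sum(sizes)
    fixed_sep = min_sep if fixed_sep is None else fixed_sep
    # small margin so the result clears the requirement strictly
    required = np.where(mol_id[None, :] == -1, fixed_sep, min_sep)
    target = required * 1.02
    for it in range(max_iters):
        delta = coords[:n_mobile, None, :] - coords[None, :, :]
        delta -= lengths * np.round(delta / lengths)
        dist = np.sqrt((delta**2).sum(axis=2))
        same = mol_id[:n_mobile, None] == mol_id[None, :]
        dist[same] = np.inf
        if not (dist < required).any():
            out, k = [], 0
            for s in sizes:
                out.append(coords[k : k + s])
                k += s
            return out
        ii, jj = np.where(dist < target)
        shifts = np.zeros((len(sizes), 3))
        counts = np.zeros(len(sizes))
        overlap = target[0, jj] - dist[ii, jj]
        u = delta[ii, jj] / dist[ii, jj][:, None]
        for k in range(len(ii)):
            a = int(mol_id[ii[k]])
            b = int(mol_id[jj[k]])
            step = u[k] * overlap[k]
            if b == -1:  # against a fixed obstacle: mobile side takes the whole step
                shifts[a] += step
                counts[a] += 1
            else:
                shifts[a] += 0.5 * step
                shifts[b] -= 0.5 * step
                counts[a] += 1
                counts[b] += 1
        active = counts > 0
        shifts[active] /= counts[active, None]
        if it and it % 200 == 0:  # shake loose from jammed oscillations
            shifts[active] += rng.normal(0.0, 0.05, (int(active.sum()), 3))
        k = 0
        for m, s in enumerate(sizes):
            coords[k : k + s] += shifts[m]
            k += s
    return None


def pack_box(
    spec: CompositionSpec,
    cell: SimulationCell,
    min_sep: float = 2.0,
    seed: int = 0,
    retry_budget: int = 10_000,
    max_restarts: int = 30,
    slab_clearance: float | None = None,
) -> Frame:
    """Place every molecule with a random rigid rotation + translation.

    Two stages, both deterministic for a fixed seed.  First, sequential
    rejection sampling: molecules (largest first) get uniform random
    orientations (quaternion method via scipy rotations) and uniform
    translations, re-drawn until all minimum-image inter-molecular atom
    pairs clear ``min_sep``.  If a molecule cannot be inserted it is placed
    at its best-found position and a rigid push-apart relaxation resolves
    the remaining overlaps.  With a slab flagged, the framework + Ca atoms
    are fixed obstacles and the mixture goes into the gallery only.
    """
    lengths = cell.lengths
    slab = build_slab_fixture(cell) if spec.slab else None
    slab_sep = min_sep if slab_clearance is None else slab_clearance
    mols: list[MoleculeTemplate] = []
    for mol, count in spec.entries:
        mols.extend([mol] * count)
    order = sorted(range(len(mols)), key=lambda i: -mols[i].n_atoms)

    best_overall = 0.0
    for restart in range(max_restarts):
        rng = np.random.default_rng([seed, restart])
        placed: list[np.ndarray] = []  # coordinates per placed molecule, packing order
        if slab is not None:
            fixed = slab.coords
            z_lo, z_hi = slab.gallery_z_range()
            z_lo, z_hi = z_lo + 0.5, z_hi - 0.5
        else:
            fixed = np.empty((0, 3))
            z_lo, z_hi = 0.0, cell.c
        coords_by_slot: dict[int, np.ndarray] = {}
        needs_relax = False
        for slot in order:
            mol = mols[slot]
            template = mol.centered()
            placed_atoms = (
                np.vstack([coords_by_slot[s] for s in coords_by_slot])
                if coords_by_slot
                else np.empty((0, 3))
            )
            has_obstacle = len(placed_atoms) or len(fixed)
            placed_mol = None
            best_cand = None
            best_here = -np.inf
            batch = 64
            # once one molecule has jammed, relaxation will run anyway:
            # a single batch of draws per remaining molecule is enough
            n_batches = 1 if needs_relax else max(1, retry_budget // batch)
            for _ in range(n_batches):
                rots = Rotation.random(batch, rng=rng).as_matrix()  # (B, 3, 3)
                shifts = np.column_stack(
                    [
                        rng.uniform(0.0, cell.a, batch),
                        rng.uniform(0.0, cell.b, batch),
                        rng.uniform(z_lo, z_hi, batch),
                    ]
                )
                cands = np.einsum("bij,nj->bni", rots, template) + shifts[:, None, :]
                if not has_obstacle:
                    placed_mol = cands[0]
                    break
                # margin to the binding requirement, slab and molecules separately
                margins = np.full(batch, np.inf)
                if len(fixed):
                    margins = _batch_min_sep(cands, fixed, lengths) - slab_sep
                if len(placed_atoms):
                    margins = np.minimum(
                        margins, _batch_min_sep(cands, placed_atoms, lengths) - min_sep
                    )
                b = int(np.argmax(margins))
                if margins[b] > best_here:
                    best_here = float(margins[b])
                    best_cand = cands[b]
                if best_here >= 0.0:
                    placed_mol = best_cand
                    break
            if placed_mol is None:  # jammed: keep the least-bad spot, relax later
                best_overall = max(best_overall, min_sep + best_here)
                placed_mol = best_cand
                needs_relax = True
            coords_by_slot[slot] = placed_mol
        mol_coords = [coords_by_slot[i] for i in range(len(mols))]
        if needs_relax:
            relaxed = _relax_packing(
                mol_coords, fixed, lengths, min_sep, rng, fixed_sep=slab_sep
            )
            if relaxed is None:
                continue
            mol_coords = relaxed
        all_coords = ([slab.coords] if slab is not None else []) + mol_coords
        return Frame(index=0, time=0.0, positions=np.vstack(all_coords))
    raise PackingError(
        f"could not pack {len(mols)} molecules at min_sep={min_sep} Å "
        f"after {max_restarts} restarts",
        best_overall,
    )
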