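"""Radial distribution functions and per-element-class RMSD summaries.

The RDF follows the standard pair-distance normalisation

    g_AB(r) = ΔN_AB / (4π ρ_B r² Δr)

with ΔN_AB the average number of B atoms in the shell (r, r+Δr] around an
A atom per frame, ρ_B the B number density, and r the bin midpoint.  For
A = B, self-pairs are excluded and ρ_B uses (N_B − 1)/V — the per-A
expectation for a finite system.  All distances obey the minimum-image
convention, which restricts r_max to half the shortest cell edge.

RMSD is computed per frame against a reference configuration with no
rotational or translational superposition: the slab is anchored in the
simulation, so drift is part of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bondgraph_species import min_image_displacement
from .trajectory_io import Frame, Trajectory

__all__ = [
    "RDFResult",
    "RMSDSummary",
    "compute_rdf",
    "compute_rmsd",
    "rmsd_by_class",
]


@dataclass
class RDFResult:
    """Binned g_AB(r) with its normalisation metadata."""

    pair: tuple[str, str]
    bin_edges: np.ndarray  # len n_bins + 1, Å
    g: np.ndarray  # dimensionless
    rho_B: float  # Å⁻³ (finite-N corrected when A = B)
    dr: float  # Å
    n_frames: int
    counts: np.ndarray  # raw pair tallies per bin, summed over frames

    @property
    def r(self) -> np.ndarray:
        """Bin midpoints, Å."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def neighbor_integral(self) -> float:
        """Σ g·4πρ_B r²Δr — average B neighbours within r_max of an A atom."""
        return float(np.sum(self.g * 4.0 * np.pi * self.rho_B * self.r**2 * self.dr))

    def to_table(self) -> np.ndarray:
        return np.column_stack([self.r, self.g])


@dataclass
class RMSDSummary:
    """Average / minimum / maximum of per-frame RMSD for one atom class."""

    selection: str
    average: float
    minimum: float
    maximum: float
    series: np.ndarray  # per-frame RMSD, Å
    atomwise_min: float | None = None  # extrema of per-atom time-mean RMSD
    atomwise_max: float | None = None


def compute_rdf(
    traj: Trajectory,
    element_a: str,
    element_b: str,
    dr: float = 0.05,
    r_max: float | None = None,
) -> RDFResult:
    """Atom–atom radial distribution function g_AB(r)."""
    if dr <= 0:
        raise ValueError("dr must be positive")
    half_min_edge = traj.cell.min_edge() / 2.0
    if r_max is None:
        r_max = half_min_edge
    if r_max > half_min_edge + 1e-9:
        raise ValueError(
            f"r_max={r_max} exceeds half the shortest cell edge "
            f"({half_min_edge:.3f} Å); minimum image is invalid beyond that"
        )
    idx_a = np.array([i for i, e in enumerate(traj.elements) if e == element_a])
    idx_b = np.array([i for i, e in enumerate(traj.elements) if e == element_b])
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"elements {element_a}/{element_b} not both present")
    same = element_a == element_b
    if same and len(idx_b) < 2:
        raise ValueError("A = B needs at least two atoms")
    n_bins = int(np.ceil(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    counts = np.zeros(n_bins)
    for frame in traj.frames:
        delta = frame.positions[idx_a, None, :] - frame.positions[None, idx_b, :]
        delta = min_image_displacement(delta, traj.cell)
        dist = np.sqrt((delta**2).sum(axis=2))
        if same:
            np.fill_diagonal(dist, np.inf)
        h, _ = np.histogram(dist.ravel(), bins=edges)
        counts += h
    volume = traj.cell.volume
    n_b_eff = len(idx_b) - 1 if same else len(idx_b)
    rho_b = n_b_eff / volume
    # average B count per A atom per frame, per bin
    dn = counts / (len(idx_a) * traj.n_frames)
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    g = dn / (4.0 * np.pi * rho_b * r_mid**2 * dr)
    return RDFResult(
        pair=(element_a, element_b),
        bin_edges=edges,
        g=g,
        rho_B=rho_b,
        dr=dr,
        n_frames=traj.n_frames,
        counts=counts,
    )


def _selection_indices(traj: Trajectory, selection) -> tuple[np.ndarray, str]:
    if isinstance(selection, str):
        idx = np.array([i for i, e in enumerate(traj.elements) if e == selection])
        label = selection
    else:
        idx = np.asarray(list(selection), dtype=int)
        label = "custom"
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    return idx, label


def compute_rmsd(
    traj: Trajectory,
    reference: Frame,
    selection,
    atomwise: bool = False,
) -> RMSDSummary:
    """Per-frame RMSD of a selection against a reference frame.

    ``selection`` is an element symbol or an iterable of atom indices.
    Displacements are minimum-image; no superposition is applied.  With
    ``atomwise=True`` the extrema of per-atom time-averaged RMSD are also
    reported.
    """
    if reference.n_atoms != traj.n_atoms:
        raise ValueError("reference atom count does not match trajectory")
    idx, label = _selection_indices(traj, selection)
    pos = traj.positions_array()[:, idx, :]
    delta = pos - reference.positions[idx][None, :, :]
    delta = min_image_displacement(delta, traj.cell)
    sq = (delta**2).sum(axis=2)  # (n_frames, n_sel)
    series = np.sqrt(sq.mean(axis=1))
    summary = RMSDSummary(
        selection=label,
        average=float(series.mean()),
        minimum=float(series.min()),
        maximum=float(series.max()),
        series=series,
    )
    if atomwise:
        per_atom = np.sqrt(sq.mean(axis=0))
        summary.atomwise_min = float(per_atom.min())
        summary.atomwise_max = float(per_atom.max())
    return summary


def rmsd_by_class(
    traj: Trajectory,
    reference: Frame | None = None,
    classes: tuple[str, ...] = ("Al", "Si", "Ca"),
) -> dict[str, RMSDSummary]:
    """RMSD summaries for several element classes (slab-report layout)."""
    if reference is None:
        reference = traj.frames[0]
    present = set(traj.elements)
    return {
        cls: compute_rmsd(traj, reference, cls) for cls in classes if cls in present
    }
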