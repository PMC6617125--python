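"""Minimum image, bond graphs, Hill formulas, canonical keys, tracking."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claysoup import chem_systems as cs
from claysoup.bondgraph_species import (
    ThresholdTable,
    build_bond_graph,
    hill_formula,
    min_image_distance,
    partition_species,
    track_species,
)
from claysoup.trajectory_io import Frame, SimulationCell

from conftest import make_trajectory


class TestMinImage:
    def test_identical_points(self, cell):
        assert min_image_distance((1, 2, 3), (1, 2, 3), cell) == 0.0

    def test_wraps_across_boundary(self):
        cell = SimulationCell(10.30, 17.96, 7.41)
        assert min_image_distance((0, 0, 0), (9.8, 0, 0), cell) == pytest.approx(0.50)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_27_image_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cell = SimulationCell(*rng.uniform(4, 20, 3))
        lengths = np.array([cell.a, cell.b, cell.c])
        # 27 explicit images are exhaustive once both points lie in the cell
        p, q = rng.uniform(-10, 30, (2, 3)) % lengths
        best = math.inf
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    shift = np.array([dx * cell.a, dy * cell.b, dz * cell.c])
                    best = min(best, float(np.linalg.norm(p - (q + shift))))
        assert min_image_distance(p, q, cell) == pytest.approx(best, abs=1e-9)


class TestThresholds:
    def test_published_heavy_pair_cutoffs(self, thresholds):
        assert thresholds.cutoff("C", "C") == 1.64
        assert thresholds.cutoff("C", "N") == 1.57
        assert thresholds.cutoff("N", "C") == 1.57  # symmetric
        assert thresholds.cutoff("C", "O") == 1.53

    def test_fallback_is_covalent_radius_sum_plus_margin(self, thresholds):
        assert thresholds.cutoff("O", "H") == pytest.approx(0.66 + 0.31 + 0.1)

    def test_cation_never_bonds(self, thresholds):
        assert thresholds.cutoff("Ca", "O") == 0.0


class TestBondGraph:
    def _two_atoms(self, d, elements, cell):
        pos = np.array([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]])
        return build_bond_graph(Frame(0, 0.0, pos), elements, cell)

    def test_carbon_pair_below_cutoff_bonds(self, cube_cell):
        bg = self._two_atoms(1.60, ["C", "C"], cube_cell)
        assert bg.edges == {(0, 1)}

    def test_carbon_pair_above_cutoff_does_not(self, cube_cell):
        bg = self._two_atoms(1.70, ["C", "C"], cube_cell)
        assert bg.edges == set()

    def test_unknown_element_raises(self, cube_cell):
        with pytest.raises(KeyError):
            self._two_atoms(1.0, ["C", "U"], cube_cell)

    def test_zero_thresholds_give_singletons(self, cube_cell):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 20, (6, 3))
        tiny = ThresholdTable(
            {("C", "C"): 1e-12, ("C", "H"): 1e-12, ("H", "H"): 1e-12}
        )
        bg = build_bond_graph(Frame(0, 0.0, pos), ["C", "H"] * 3, cube_cell, tiny)
        assert len(list(nx.connected_components(bg.graph))) == 6

    def test_huge_thresholds_give_one_species(self, cube_cell):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 20, (6, 3))
        huge = ThresholdTable(
            {("C", "C"): 1e6, ("C", "H"): 1e6, ("H", "H"): 1e6}
        )
        bg = build_bond_graph(Frame(0, 0.0, pos), ["C", "H"] * 3, cube_cell, huge)
        assert len(list(nx.connected_components(bg.graph))) == 1


class TestHillFormula:
    @pytest.mark.parametrize(
        "elements,expected",
        [
            (["C", "H", "H", "H", "O", "H"], "CH4O"),
            (["O", "H", "H"], "H2O"),
            (["N", "N"], "N2"),
            (["C"], "C"),
            (["H", "O", "C", "C", "N", "H"], "C2H2NO"),
        ],
    )
    def test_hill_order(self, elements, expected):
        assert hill_formula(elements) == expected


class TestPartition:
    def test_methanol_like_graph(self, cube_cell):
        # C bonded to 3 H and O; O bonded to its own H
        pos = np.array(
            [
                [5.0, 5.0, 5.0],  # C
                [6.0, 5.0, 5.0],  # H
                [5.0, 6.0, 5.0],  # H
                [5.0, 5.0, 6.0],  # H
                [3.6, 5.0, 5.0],  # O (1.4 from C)
                [2.7, 5.0, 5.0],  # H (0.9 from O)
            ]
        )
        elements = ["C", "H", "H", "H", "O", "H"]
        bg = build_bond_graph(Frame(0, 0.0, pos), elements, cube_cell)
        species = partition_species(bg, elements)
        assert len(species) == 1
        assert species[0].formula == "CH4O"

    def test_edgeless_frame_gives_single_atom_species(self, cube_cell):
        pos = np.array([[1.0, 1, 1], [8.0, 8, 8], [15.0, 15, 15]])
        elements = ["O", "N", "C"]
        bg = build_bond_graph(Frame(0, 0.0, pos), elements, cube_cell)
        species = partition_species(bg, elements)
        assert [s.formula for s in species] == ["O", "N", "C"]

    def test_partition_covers_all_atoms_disjointly(self, cube_cell):
        rng = np.random.default_rng(7)
        elements = list(rng.choice(["C", "N", "O", "H"], 30))
        pos = rng.uniform(0, 20, (30, 3))
        bg = build_bond_graph(Frame(0, 0.0, pos), elements, cube_cell)
        species = partition_species(bg, elements)
        union = set()
        total = 0
        for s in species:
            assert not (union & s.atoms)
            union |= s.atoms
            total += len(s.atoms)
        assert union == set(range(30))
        assert total == 30

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_canonical_key_invariant_under_relabeling(self, seed):
        """Permuting atom numbering never changes the canonical key."""
        rng = np.random.default_rng(seed)
        cell = SimulationCell(30, 30, 30)
        mol = cs.MOLECULES["Glycine"]
        pos = mol.coords + 10.0
        elements = list(mol.elements)
        perm = rng.permutation(len(elements))
        bg1 = build_bond_graph(Frame(0, 0.0, pos), elements, cell)
        bg2 = build_bond_graph(
            Frame(0, 0.0, pos[perm]), [elements[i] for i in perm], cell
        )
        (s1,) = partition_species(bg1, elements)
        (s2,) = partition_species(bg2, [elements[i] for i in perm])
        assert s1.key == s2.key
        assert s1.formula == s2.formula


class TestTracking:
    def test_packed_box_has_expected_molecule_count(self, thresholds):
        """A freshly packed 9 NH3 + 9 glycine box partitions into 18 species."""
        spec = cs.composition_for_box("g3")
        cell = cs.box_cell("g3")
        frame = cs.pack_box(spec, cell, min_sep=2.0, seed=4)
        bg = build_bond_graph(frame, cs.composition_elements(spec), cell, thresholds)
        assert nx.number_connected_components(bg.graph) == 18

    def test_static_trajectory_species_live_forever_and_are_not_new(
        self, cube_cell, thresholds
    ):
        mol = cs.MOLECULES["H2CO"]
        pos = mol.coords + 10.0
        traj = make_trajectory(list(mol.elements), [pos] * 25, cube_cell)
        records = track_species(traj, thresholds)
        assert len(records) == 1
        rec = records[0]
        assert not rec.is_new
        assert rec.lifetime_frames == 25
        assert rec.formula == "CH2O"
        assert rec.lifetime_ps == pytest.approx(25 * 4.0 / 1000.0)

    def test_scripted_merge_produces_new_species_with_exact_lifetime(self, thresholds):
        """H2CO + CO held together for 200 frames appear as one C2H2O2."""
        from claysoup.synthetic_data import EventScript, ScriptedEvent, generate_trajectory

        cell = SimulationCell(24, 12, 12)
        h2co = cs.MOLECULES["H2CO"].coords * np.array([-1.0, 1.0, 1.0]) + np.array(
            [4.0, 6.0, 6.0]
        )
        co = cs.MOLECULES["CO"].coords + np.array([9.0, 6.0, 6.0])
        initial = Frame(0, 0.0, np.vstack([h2co, co]))
        elements = list(cs.MOLECULES["H2CO"].elements) + list(cs.MOLECULES["CO"].elements)
        script = EventScript(
            events=[ScriptedEvent("merge", (0, 4), onset=100, duration=200, approach=1.55)]
        )
        traj, truth = generate_trajectory(
            initial, elements, script, n_frames=400, cell=cell, seed=9
        )
        new = [r for r in track_species(traj, thresholds) if r.is_new]
        assert [r.formula for r in new] == ["C2H2O2"]
        assert new[0].first_frame == 100
        assert new[0].lifetime_frames == 200

    def test_single_frame_trajectory_has_no_new_species(self, cube_cell, thresholds):
        mol = cs.MOLECULES["HCN"]
        traj = make_trajectory(list(mol.elements), [mol.coords + 5.0], cube_cell)
        records = track_species(traj, thresholds)
        assert all(not r.is_new for r in records)

    def test_element_inventory_conserved_every_frame(self, random_trajectory, thresholds):
        from collections import Counter

        traj = random_trajectory(n_atoms=20, n_frames=10, seed=12)
        inventory = Counter(traj.elements)
        for f, frame in enumerate(traj.frames):
            bg = build_bond_graph(frame, traj.elements, traj.cell, thresholds)
            species = partition_species(bg, traj.elements)
            counted = Counter()
            for s in species:
                for i in s.atoms:
                    counted[traj.elements[i]] += 1
            assert counted == inventory
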