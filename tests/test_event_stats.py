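"""Effective-clash detection, cation contacts, and convergence series."""

import warnings

import numpy as np
import pytest

from claysoup import chem_systems as cs
from claysoup.bondgraph_species import ThresholdTable, min_image_displacement
from claysoup.event_stats import (
    clash_count_convergence,
    count_cation_contacts,
    detect_clashes,
)
from claysoup.trajectory_io import SimulationCell

from conftest import make_trajectory


def _pair_trajectory(distances, cell, elements=("C", "C")):
    """Two atoms on the x axis with a scripted distance per frame."""
    frames = [
        np.array([[2.0, 2.0, 2.0], [2.0 + d, 2.0, 2.0]]) for d in distances
    ]
    return make_trajectory(list(elements), frames, cell)


class TestClashBoundary:
    def _episode(self, below_frames, total=300):
        # pair starts apart, dips below cutoff for exactly `below_frames`
        d = [3.0] * 50 + [1.5] * below_frames + [3.0] * (total - 50 - below_frames)
        return d

    def test_episode_equal_to_persistence_is_no_clash(self, cube_cell):
        traj = _pair_trajectory(self._episode(100), cube_cell)
        report = detect_clashes(traj, persistence=100)
        assert report.counts["C-C"] == 0

    def test_episode_one_frame_longer_is_one_clash(self, cube_cell):
        traj = _pair_trajectory(self._episode(101), cube_cell)
        report = detect_clashes(traj, persistence=100)
        assert report.counts["C-C"] == 1
        (event,) = report.events
        assert event.start_frame == 50
        assert event.length_frames == 101
        assert event.length_fs == pytest.approx(101 * 4.0)

    def test_unbind_rebind_counts_two_episodes(self, cube_cell):
        d = [3.0] * 5 + [1.5] * 20 + [3.0] * 5 + [1.5] * 30 + [3.0] * 5
        traj = _pair_trajectory(d, cube_cell)
        report = detect_clashes(traj, persistence=10)
        assert report.counts["C-C"] == 2

    def test_initially_bonded_pair_is_never_a_clash(self, cube_cell):
        """A pair bonded in frame 0 (like glycine's backbone C-C) is excluded."""
        traj = _pair_trajectory([1.5] * 300, cube_cell)
        report = detect_clashes(traj, persistence=100)
        assert report.counts["C-C"] == 0
        assert report.events == []

    def test_persistence_longer_than_trajectory_is_usage_error(self, cube_cell):
        traj = _pair_trajectory([3.0] * 50, cube_cell)
        with pytest.raises(ValueError):
            detect_clashes(traj, persistence=50)


def brute_force_clashes(traj, thresholds, persistence):
    """Independent oracle: explicit distance matrices + python run scan."""
    elements = traj.elements
    n = traj.n_atoms
    heavy_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            pair = frozenset((elements[i], elements[j]))
            if pair in ({"C"}, {"C", "N"}, {"C", "O"}):
                heavy_pairs.append((i, j))
    events = []
    for i, j in heavy_pairs:
        cutoff = thresholds.cutoff(elements[i], elements[j])
        below = []
        for frame in traj.frames:
            delta = min_image_displacement(
                frame.positions[i] - frame.positions[j], traj.cell
            )
            below.append(float(np.linalg.norm(delta)) < cutoff)
        if below[0]:
            continue  # bonded at start
        run = 0
        for f, flag in enumerate(below + [False]):
            if flag:
                run += 1
            else:
                if run > persistence:
                    events.append((i, j, f - run, run))
                run = 0
    return sorted(events)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_on_random_walks(self, random_trajectory, seed):
        thresholds = ThresholdTable()
        traj = random_trajectory(
            n_atoms=30,
            n_frames=400,
            seed=seed,
            elements=["C"] * 10 + ["N"] * 5 + ["O"] * 5 + ["H"] * 10,
            step=0.35,
        )
        report = detect_clashes(traj, thresholds, persistence=5)
        got = sorted(
            (e.atoms[0], e.atoms[1], e.start_frame, e.length_frames)
            for e in report.events
        )
        assert got == brute_force_clashes(traj, thresholds, 5)

    def test_monotone_in_persistence_and_cutoff(self, random_trajectory):
        thresholds = ThresholdTable()
        traj = random_trajectory(
            n_atoms=20, n_frames=300, seed=9, elements=["C"] * 20, step=0.4
        )
        counts = [
            sum(detect_clashes(traj, thresholds, persistence=p).counts.values())
            for p in (2, 5, 10, 20)
        ]
        assert counts == sorted(counts, reverse=True)
        loose = sum(detect_clashes(traj, ThresholdTable({("C", "C"): 2.2}), 5).counts.values())
        tight = sum(detect_clashes(traj, ThresholdTable({("C", "C"): 1.2}), 5).counts.values())
        assert tight <= loose

    def test_invariant_under_rigid_translation(self, random_trajectory):
        thresholds = ThresholdTable()
        traj = random_trajectory(n_atoms=12, n_frames=200, seed=4, elements=["C"] * 12, step=0.4)
        shifted = make_trajectory(
            traj.elements,
            [f.positions + np.array([13.7, -4.2, 55.0]) for f in traj.frames],
            traj.cell,
        )
        a = detect_clashes(traj, thresholds, persistence=5)
        b = detect_clashes(shifted, thresholds, persistence=5)
        assert [(e.atoms, e.start_frame, e.length_frames) for e in a.events] == [
            (e.atoms, e.start_frame, e.length_frames) for e in b.events
        ]


class TestCationContacts:
    def test_closed_form_rate(self):
        from claysoup.synthetic_data import generate_cation_fixture_trajectory

        traj = generate_cation_fixture_trajectory(1, [2.4], n_frames=1000, frame_spacing=4.0)
        stats = count_cation_contacts(traj, "Ca", 2.5)
        assert stats.tallies["O"] == 1000
        assert stats.rates["O"] == pytest.approx(250.0)

    def test_contact_outside_cutoff_counts_zero(self):
        from claysoup.synthetic_data import generate_cation_fixture_trajectory

        traj = generate_cation_fixture_trajectory(1, [2.6], n_frames=100)
        stats = count_cation_contacts(traj, "Ca", 2.5)
        assert stats.tallies["O"] == 0

    def test_two_partners_double_the_rate(self):
        from claysoup.synthetic_data import generate_cation_fixture_trajectory

        one = generate_cation_fixture_trajectory(1, [2.4], n_frames=500)
        two = generate_cation_fixture_trajectory(1, [2.4, 2.4], n_frames=500)
        r1 = count_cation_contacts(one).rates["O"]
        r2 = count_cation_contacts(two).rates["O"]
        assert r2 == pytest.approx(2 * r1)

    def test_missing_cation_warns_and_returns_empty(self, cube_cell):
        traj = _pair_trajectory([3.0] * 10, cube_cell, elements=("C", "O"))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            stats = count_cation_contacts(traj, "Ca", 2.5)
        assert caught
        assert all(v == 0 for v in stats.tallies.values())


class TestConvergence:
    def test_static_trajectory_gives_zero_series(self, cube_cell):
        traj = _pair_trajectory([3.0] * 500, cube_cell)
        series = clash_count_convergence(traj, persistence=10, window_ps=0.5)
        assert all(series["C-C"] == 0)

    def test_series_flat_after_events_cease(self, cube_cell):
        # one 50-frame episode entirely within the first half
        d = [3.0] * 20 + [1.5] * 50 + [3.0] * 430
        traj = _pair_trajectory(d, cube_cell)
        series = clash_count_convergence(traj, persistence=10, window_ps=0.2)
        counts = series["C-C"]
        assert counts[-1] == 1
        half = len(counts) // 2
        assert all(c == counts[-1] for c in counts[half:])

    def test_series_is_nondecreasing(self, random_trajectory):
        traj = random_trajectory(n_atoms=16, n_frames=400, seed=2, elements=["C"] * 16, step=0.4)
        series = clash_count_convergence(traj, persistence=5, window_ps=0.2)
        for cls in ("C-C", "C-N", "C-O"):
            assert all(np.diff(series[cls]) >= 0)
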