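# claysoup

Trajectory analysis for reactive events in molecular-dynamics simulations of
prebiotic small-molecule mixtures — optionally nanoconfined in a
montmorillonite (MMT)-like clay slab with interlayer Ca²⁺ ions.

Ab initio MD studies of "primordial soup" mixtures (H₂O, NH₃, CH₄, H₂, N₂,
CO, H₂CO, HCN, glycine) ask whether clay nanoconfinement and the strong
local fields of surface cations promote the formation of new molecules.
Answering that from a trajectory requires a specific post-processing stack,
which this package implements as a tested, reusable library:

* **Effective clashes** — a heavy-atom pair of class C–C, C–N or C–O, not
  bonded initially, counts as a reactive contact only if it stays below a
  pair-specific threshold *R*(A–B) for strictly more than a persistence
  window of consecutive frames (default 100).  Default thresholds are
  standard single-bond lengths + 0.1 Å for vibrational motion:
  *R*(C–C) = 1.64 Å, *R*(C–N) = 1.57 Å, *R*(C–O) = 1.53 Å.
* **Species identification and lifetimes** — each frame becomes a bond
  graph (edge ⇔ minimum-image distance < threshold); connected components
  are molecular species labelled with a Hill formula and a
  Weisfeiler–Lehman canonical key; species are tracked over contiguous
  frame runs, and a species is *new* if absent from the first frame.
* **Cation contacts** — Ca–X pair-frames (X ∈ C, H, N, O) within 2.5 Å,
  normalised per picosecond.
* **Radial distribution functions** —
  g_AB(r) = ΔN_AB / (4π ρ_B r² Δr) under the minimum-image convention.
* **Per-ion-class RMSD** — per-frame RMSD against a reference, summarised
  as average/min/max per element class (Al, Si, Ca).
* **System building** — the eight named study boxes (g0–g3 condensed
  phase, m0–m3 clay-confined; a = 10.30 Å, b = 17.96 Å), density-derived
  cell heights, PACKMOL-style random packing with a minimum-separation
  constraint, and a 152-atom two-sheet slab + 8 Ca²⁺ fixture.
* **Synthetic trajectories** — kinematic stand-ins for the (undeposited)
  ab initio runs: rigid thermal jitter plus scripted bond
  formation/breaking events with exactly known ground truth, an ideal-gas
  RDF null model, and closed-form cation-contact fixtures.

## Worked example

Generate a synthetic trajectory with two scripted encounters — a CO + CO
merge held for 150 frames and one for only 60 frames — then run the
detectors:

```python
from claysoup import detect_clashes, track_species, scripted_event_benchmark

traj, truth = scripted_event_benchmark(
    n_merge=2, n_split=0, n_frames=500, durations=[150, 60], seed=11
)
report = detect_clashes(traj, persistence=100)
print(report.counts)
for e in report.events:
    print(e.pair_class, e.atoms, e.start_frame, e.length_frames, e.length_fs)
for r in track_species(traj):
    if r.is_new:
        print(r.formula, r.first_frame, r.last_frame, r.lifetime_ps)
```

Output:

```
{'C-C': 1, 'C-N': 0, 'C-O': 0}
C-C (0, 2) 54 150 600.0
C2O2 54 203 0.6
C2HNO 64 123 0.24
```

Only the 150-frame episode exceeds the 100-frame persistence window, so
exactly one C–C clash is reported, starting at its scripted onset (frame
54) with its scripted length (150 frames = 600 fs at 4 fs/frame).  The
species tracker sees both encounters: the persistent one as a transient
C₂O₂ (ethanedione-like) species living exactly 0.6 ps, and the
sub-persistence one as a short-lived C₂HNO species — a *transient
collision*, not an effective clash.

Cation-contact rates come out in closed form on the static fixture: one Ca
with two O atoms at 2.4 Å and one at 2.6 Å over 4 ps gives

```python
from claysoup import count_cation_contacts, generate_cation_fixture_trajectory
traj = generate_cation_fixture_trajectory(1, [2.4, 2.4, 2.6], n_frames=1000)
count_cation_contacts(traj, "Ca", 2.5).rates["O"]   # -> 500.0 per ps
```

## Command line

```bash
claysoup build-box m2300 --seed 1 -o m2300.xyz      # pack a named box
claysoup make-synthetic g1300 -o g1.xyz             # jittered trajectory
claysoup analyze g1.xyz --persistence-frames 100 -o report/
claysoup run-matrix --seed 1 -o matrix/             # all 24 boxes
claysoup report matrix/
```

Trajectories are concatenated extended-XYZ (a `Lattice="…"` record per
frame, lengths in Å, times in fs); reports are TSV plus a JSON manifest,
and identical seeds give byte-identical outputs.

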