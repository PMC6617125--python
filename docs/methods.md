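# Methods

This note records the models and conventions behind each analysis stage,
the choices made where the design was genuinely open, and what the
synthetic trajectories do and do not establish about real data.

## Geometry and units

All coordinates are Cartesian Å, times fs, temperatures K.  Cells are
orthorhombic and periodic in all three axes.  Coordinates are never
wrapped into the primary cell on input; every distance downstream applies
the minimum-image convention (`Δx → Δx − L·round(Δx/L)` per axis), which
keeps displacement series continuous for RMSD.  Frame spacing is explicit
caller-supplied metadata with a default of 4.0 fs (20 ps sampled as 5000
frames); persistence windows are therefore specified in *frames*, the
primitive unit, with fs equivalents derived from the spacing.

## Bond graphs and species

An edge joins atoms *i*, *j* when their minimum-image distance is strictly
below the pair threshold.  Thresholds are single-bond lengths + 0.1 Å for
the pairs that matter most to the reactive statistics — C–C 1.64 Å,
C–N 1.57 Å, C–O 1.53 Å — and fall back to the sum of Cordero covalent
radii + 0.1 Å for all other pairs.  Two special cases:

* H–H carries an explicit 0.84 Å entry (0.74 Å bond + 0.1), because the
  covalent-radius sum (0.62 Å) famously undershoots the H₂ bond length.
* Ca (and Na, K, Mg) never enter the covalent graph: interlayer cations
  are ionic, and their coordination is measured separately as contact
  rates.

Species are connected components.  Identity is the pair (atom-index set,
canonical key), where the key is a Weisfeiler–Lehman graph hash (3
iterations) over element-labelled nodes — cheap, stable under atom
renumbering, and sufficient to distinguish the constitutional isomers that
arise among ≤ 30-atom products.  Stereochemistry and bond orders are out
of scope.

Tracking is strict: a record spans the maximal contiguous frame run over
which the same atom set keeps the same key.  Any membership or
connectivity change closes the record, which makes lifetimes well-defined
and exactly testable.  `is_new` marks identities absent from frame 0.  A
minimum-lifetime filter (default 1 frame, i.e. no filtering) lets callers
separate products from single-frame vibrational excursions; the pipeline's
matrix runs use 10 frames (40 fs) for their product lists.

## Effective clashes

Candidates are all heavy-atom pairs of class C–C/C–N/C–O *not bonded in
frame 0* (only newly formed contacts count; a glycine backbone C–C can
never be an event).  For each candidate the below-threshold boolean series
is scanned for maximal runs; a run qualifies only if strictly longer than
the persistence window (default 100 frames — a 100-frame episode is not an
event, a 101-frame episode is).  Episodes are counted, not pairs: a pair
that unbinds for more than one frame and rebinds long enough yields two
events.  A convergence series (cumulative counts at window boundaries,
computed on truncated prefixes) supports checking that counts flatten in
the second half of a run.

## Cation contacts

Every (cation, X) pair within the cutoff (default 2.5 Å) in a frame adds
one tally for X ∈ {C, H, N, O}; rates divide by the sampled duration
(n_frames × spacing).  Pair-frame counting — as opposed to per-cation
deduplication — is the convention adopted, since it is the only reading
that yields rates of order 10²–10³ per ps for eight cations.

## Radial distribution functions

g_AB(r) = ΔN_AB / (4π ρ_B r² Δr) with ΔN_AB the per-A, per-frame mean
count of B atoms in (r, r+Δr], r the bin midpoint, and Δr defaulting to
0.05 Å.  r_max defaults to (and may not exceed) half the shortest cell
edge, the validity limit of the minimum image.  For A = B, self-pairs are
excluded and ρ_B = (N_B − 1)/V, the correct finite-N per-A expectation —
this makes the ideal-gas g(r) unbiased at 1 and the normalisation integral
Σ g·4πρ_B r²Δr reproduce the directly counted mean neighbour number
identically (the first bin uses its midpoint r = Δr/2, so no division by
zero arises).  g is dimensionless and is reported as such.

## RMSD

Per frame, RMSD = √(mean over selected atoms of the squared minimum-image
displacement from the reference), with *no* rotational/translational
superposition: the slab is anchored in the simulation frame and drift is
part of the signal.  The reference defaults to the first analysed frame.
Summaries report the average, minimum and maximum of the per-frame series
(the per-atom time-averaged extrema are available behind an `atomwise`
flag).

## System building

Box inventories follow the published composition table: four mixtures at
the Miller–Strecker stages (0 substrates, 1 reactants, 2 intermediates,
3 products) in condensed-phase (g) and clay-confined (m) variants at
300/400/600 K, a = 10.30 Å and b = 17.96 Å throughout.  Molecule templates
use gas-phase experimental geometries; glycine is the neutral
NH₂-CH₂-COOH form (10 atoms), which is what makes 9 NH₃ + 9 glycine come
to 126 atoms.  Atomic masses come from a bundled standard-weights table.
The cell height for a gas box is c = M_total/(N_A·ρ·a·b); at ρ = 1 g/mL
the 828 g/mol mixtures give c ≈ 7.44 Å (the published 7.41 Å to within
0.5%).  The g0 box's printed height implies ρ ≈ 0.73 g/mL instead, so
density is an explicit parameter rather than a hard-coded constant.

Packing is a PACKMOL-style stand-in: molecules (largest first) receive
uniform random orientations (quaternion method) and translations, redrawn
until all inter-molecular minimum-image atom pairs clear `min_sep`
(default 2.0 Å, the standard packing tolerance).  At gallery densities
where sequential rejection jams, remaining molecules take their
best-found positions and a rigid push-apart relaxation (translations
only, fixed slab, deterministic) resolves residual overlaps; the
constraint is asserted on the result.  Everything is deterministic under
the seed.

The clay slab is a *synthetic* stand-in, not a crystallographic cell: the
mineral's formula unit is not fixed by the constraints available, so the
fixture is defined by them — 152 atoms total (144 Si/Al/O/H framework +
8 Ca), two parallel sheets normal to c hugging the periodic boundary, and
an ≈ 8 Å open gallery consistent with ~1.0 × 1.8 × 0.8 nm nanocage
confinement.  Each 72-atom sheet (16 Si, 8 Al, 40 O, 8 H) is a serpentine
cation–oxygen network built to be a single connected bond-graph component
with comfortable margins to every cross-component distance, so the slab
contributes exactly two static species plus eight free Ca ions and can
never shed spurious fragments under thermal jitter.

## Synthetic trajectories

Dynamics are kinematic, not physical — the package tests analysis code,
not forces.  Molecules (bond-graph components of the initial frame) move
as rigid bodies with per-frame Gaussian translation jitter
(σ = 0.05 Å default); internal geometry is exactly preserved, so no
intramolecular bond can flicker.  Scripted events steer a chosen atom
pair: a cosine ramp (10 frames) brings the pair from its rest distance to
just outside the threshold, the pair distance is then held *exactly* at
the scripted approach value for the scripted window, and a mirror ramp
restores it.  Because the ramps never cross the threshold, the
below-cutoff window is exactly [onset, onset + duration) — ground truth
is exact by construction, which is what makes recall/precision = 1
a meaningful requirement rather than a statistical outcome.  The steered
molecule is re-oriented so its body points away from the partner,
preventing incidental contacts.  Generation validates every frame's bond
graph against the scripted expectation and fails loudly (with the
offending frame) on any unscripted bond.

What this does *not* show: real reactive trajectories have vibrating
bonds, charge transfer, concerted mechanisms and genuinely ambiguous
transient geometries.  Passing on scripted ground truth demonstrates that
the detectors implement their definitions exactly; it cannot validate the
chemical appropriateness of the thresholds themselves on ab initio data.

The ideal-gas generator (independent uniform positions per frame) is the
null model for which g(r) ≡ 1; the cation fixture holds Ca and partner
atoms at exact separations so contact rates have closed forms
(e.g. one partner at 2.4 Å over 1000 frames at 4 fs/frame → 250 per ps).

## Pipeline scales

The orchestrated matrix (4 mixtures × 2 environments × 3 temperatures =
24 runs) packs each box, generates a 200-frame synthetic trajectory
(0.8 ps at 4 fs/frame) and runs every stage, completing on a laptop-class
core in about a minute; the analysis code is identical at the 5000-frame
scale of production trajectories, and problem sizes in the test suite and
acceptance script (500-frame oracle comparisons, 500-atom/200-frame RDF
checks, five-seed event benchmarks) were chosen as the smallest sizes at
which each property is sharply testable.

## Known limitations

* The slab fixture's site geometry is schematic; RDFs and RMSDs computed
  on it exercise the code paths but are not mineralogically meaningful.
* Species identity requires the identical atom-index set; proton exchange
  between two molecules terminates both records rather than tracking a
  "same molecule, one atom swapped" lineage.
* Charge states and bond orders are not assigned; an ionic and a neutral
  species with the same connectivity share a canonical key.
* Packing satisfies a uniform minimum-separation constraint; it does not
  equilibrate the configuration, and densely packed boxes start with
  contacts at exactly `min_sep`, so jittered trajectories can show
  sub-persistence contact blips (filtered by the lifetime filter, and
  never qualifying as clashes).
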