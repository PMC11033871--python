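# Methods

## The cascade procedure

A trial is a sequence of cycles. Cycle 0 propagates a single replica from
the initial structure (an option allows several independent cycle-0
replicas). For every later cycle, the engine

1. runs `n_replica` short replicas from the exported seed structures,
   each with velocities freshly drawn from the Maxwell–Boltzmann
   distribution at the run temperature;
2. computes the selection feature for **every saved frame of every
   replica of the current cycle** (the seed frame itself, frame 0, is
   included in the candidate pool — harmless under the tie-break and
   consistent with treating every generated snapshot as a candidate);
3. writes the full ranking as `summary.csv` (cycle, replica, frame,
   value, rank);
4. stops if the threshold condition or `max_cycle` is reached, else
   exports the top `n_replica` snapshots as next-cycle seeds and appends
   one lineage record (parent cycle/replica/frame plus the feature value
   at selection) per new replica.

Ranking sorts by value — ascending for minimise-type features, descending
for maximise — with ties broken by (cycle, replica, frame) ascending, so
selection is a deterministic function of the value set. When the pool
holds fewer candidates than `n_replica`, seeds are recycled cyclically;
duplicated seeds still receive distinct velocity seeds, so the replicas
diverge. The stop threshold is inclusive (`best <= threshold` for
minimise, `>=` for maximise); the edge-expansion and
association/dissociation variants ignore the threshold and stop only at
`max_cycle`.

Reproducibility: each trial has one root seed; the RNG seed of replica
*r* in cycle *c* is derived with `numpy.random.SeedSequence(root,
spawn_key=(trial, c, r))`, so replicas are statistically independent,
trials with different roots share no stream, and a rerun (or a resumed
run, or a run with a different process-pool width) is bit-identical.
Completed cycles are detected from their ranking CSVs and never re-run.

### Variant details that the keyword set does not fix

* **a/d switching.** In the dissociation phase the pair is driven apart
  until the cycle-best d_com reaches `d_threshold`. In the association
  phase the cycle best is the minimum d_com over the first `frame_sel`
  frames of each replica; a cycle "stacks" when this best fails to
  decrease relative to the previous association cycle, and after
  `bound_threshold` consecutive stacked cycles the walk flips back to
  dissociation. The stacking comparison itself (no decrease of the
  cycle best) is this package's operationalisation; only the knob names
  are standard.
* **Edge expansion.** The descriptor of a snapshot is the flattened
  coordinate vector of `selection1`; all snapshots sampled so far are
  projected onto the top principal components (2 by default) and the
  convex-hull vertices of the projection, ranked by descending distance
  from the projected centroid, become the seeds. If the hull has fewer
  vertices than `n_replica`, the non-vertex points closest to the hull
  boundary fill the remaining slots. Edge seeds may come from any
  earlier cycle, so for this variant the lineage parent is not
  necessarily in the immediately preceding cycle.
* **Representative pathways.** `genrepresent` picks the snapshot
  optimising the feature in the final cycle (option: over all cycles),
  walks the lineage to cycle 0 and emits each ancestor replica's frames
  up to and including its selected frame — the part of each branch that
  is actually on the path — ending with the terminal replica's frames up
  to the optimising frame.

## Units and constants

Lengths nm, time ps, temperature K, energy kJ/mol, mass g/mol (so
g/mol·nm²/ps² = kJ/mol); k_B = 0.0083144621 kJ/(mol·K). Reported binding
free energies are converted to kcal/mol (4.184 kJ/kcal);
R = 1.98720425864×10⁻³ kcal/(mol·K); standard-state volume
V° = 1.661 nm³ per molecule (1 M). PDB files keep ångströms on disk.

## Langevin toy backend

The built-in integrator is underdamped Langevin dynamics with the BAOAB
splitting (accurate configurational sampling at large Δt; with zero
friction it reduces to velocity Verlet and conserves energy). Noise is
pre-drawn from a per-replica seeded generator; non-finite coordinates
raise an integration error naming the step. Default friction 1 ps⁻¹.

The toy systems stand in for solvated biomolecular systems:

* `double_well_1d` — quartic double well, V = h(x²−a²)²/a⁴. Defaults
  h = 20 kJ/mol (≈ 8 k_BT at 300 K), a = 1 nm, m = 40 g/mol. The mass
  and friction were fixed by a design study so that a 200-step replica
  essentially never crosses the barrier unassisted (the rare-event
  regime the cascade is for) while thermal fluctuations inside a well
  remain large enough for the selection ratchet to advance a measurable
  amount per cycle.
* `double_well_2d` — the same well along x plus a harmonic channel along
  y (k_y = 100 kJ/mol/nm²); its y marginal has the exact variance
  k_BT/k_y, used as an equipartition oracle.
* `lj_dimer` — two beads bound by a Lennard-Jones well (default depth
  25 kJ/mol ≈ 10 k_BT, σ = 0.3 nm) and confined by a half-harmonic
  spherical wall on their separation, mimicking a finite simulation box.
  Dissociation at the default depth is a rare event; the binding
  pipeline tests use a shallower 3 k_BT well so that the 1-D MSM along
  the pair distance converges with desk-scale statistics.
* `bead_chain` — six beads, stiff harmonic bonds, four native 12-10 Go
  contacts; its hairpin native structure is the reference for targeted
  folding tests.

What the toys deliberately lack: explicit solvent, periodic boundaries,
long-range electrostatics, force-field detail, and any timescale overlap
with real proteins. Passing tests therefore demonstrate the correctness
of the cascade/selection/MSM machinery and its statistical properties on
systems with known answers — not force-field accuracy on real systems.

## Geometry

Superposition is Kabsch via SVD with the standard reflection correction
(the smallest singular direction is flipped when the optimal orthogonal
matrix would be improper), weighted uniformly by default. RMSD is
unweighted over the selected atoms unless mass weighting is requested.
Fit groups need at least three non-collinear atoms; the RMSD features
fall back to plain (no-fit) RMSD for smaller systems, which makes the
1-D/2-D toys well-defined. `selection3`/`selection4` remap reference
numbering and default to `selection1`/`selection2`. PCA centres (never
whitens) and uses the unbiased covariance; axis signs are fixed by making
the largest loading positive. Convex hulls use Quickhull
(`scipy.spatial.ConvexHull`); degenerate clouds raise instead of
returning a zero volume.

Group-selection strings use one internal dialect — `all`, `resid a-b,c`,
`name X,Y`, `index i-j` joined with `and`; the `analyzer` keyword is
recorded but does not change parsing.

## Markov state models and free energies

Feature trajectories are discretised with k-means (k-means++
initialisation, Lloyd iterations, deterministic for a given seed).
Transition counts use sliding windows at lag τ and never cross segment
boundaries (cascade segments are disconnected in phase space). The
transition matrix is estimated on the largest strongly connected state
set; states outside it are dropped with an index map, with no
pseudocounts. The default estimator is the simple maximum-likelihood row
normalisation; a symmetrised estimator ((C+Cᵀ)/2, detailed balance by
construction) is available. The reversible maximum-likelihood estimator
used by some MSM packages is intentionally not implemented; on the toy
problems the difference is below the statistical noise, and the
symmetrised option covers the detailed-balance use case.

The stationary distribution is the unit left eigenvector; implied
timescales are −τ/ln λᵢ with the unit eigenvalue excluded, +∞ for
eigenvalues ≥ 1, NaN for non-positive ones, and moduli (with a warning)
for complex pairs. The 1-D profile is Fᵢ = −k_BT ln πᵢ over the k-means
bins, min-shifted, with zero-probability bins excluded; bin populations
are **not** divided by bin width, so a profile over uneven bins carries
bin-size structure of order k_BT·ln(wᵢ/wⱼ) — relevant when judging
plateau flatness (below).

### Standard binding free energy

`standard_binding_dG` takes a d_com profile and the unbound-shell ligand
COM positions. The unbound plateau is the last 20 % of the d_com range;
it must be flat within `plateau_tol` (default 0.5 kJ/mol, appropriate
for profiles with near-uniform bins; the toy-dimer analyses use 1 k_BT
because the r² Jacobian plus uneven k-means bins make that the intrinsic
flatness scale). ΔW is the plateau mean minus the bound minimum; V_sim
is the Quickhull hull volume of the unbound points (by convention the
points with d_com in the top 10 % of the sampled range); and
ΔG° = −ΔW − RT ln(V_sim/V°) in kcal/mol. Two exact properties pin the
convention: V_sim = V° makes the correction vanish, and doubling V_sim
shifts ΔG° by −RT ln 2.

Order-of-magnitude reporting uses 10^⌊log₁₀ x⌋ — an event time of 375 s
is "order 10² s" — and the acceleration ratio is the event time (1/k_off)
divided by the simulation time.

## Problem sizes used in the tests and the acceptance script

Chosen to give stable statistics at interactive runtimes: 20 cascade
trials vs 20 equal-budget plain runs for the enhanced-sampling
comparison (each trial ≤ 1 + 30×10 replicas × 200 steps); 64 independent
walkers × 50 000 steps for equilibrium double-well sampling (PMF within
0.3 k_BT of the analytic profile); a 10⁵-step synthetic chain for
3-state recovery; 10 dissociation trials of the shallow dimer for the
binding pipeline (ΔG° within 1 k_BT of the exact pair integral). The
whole suite runs in about a minute on one CPU.

## Known limitations

* External engines (GROMACS/AMBER/NAMD) are supported only through the
  backend contract; no invocation code ships here.
* No periodic-boundary handling in RMSD/COM features; adapters must
  pre-wrap.
* The d_com PMF of a freely rotating pair contains the −2k_BT ln r shell
  entropy; the plateau/volume-correction convention absorbs it only
  approximately, which is the main error source in the toy binding
  pipeline (≲ 1 k_BT).
* The a/d stacking criterion and the ee vertex ranking are this
  package's precise definitions of loosely specified ideas; both are
  pure functions of the sampled values and are property-tested, but
  other toolkits may differ in detail.
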