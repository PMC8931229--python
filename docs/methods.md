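# Methods

## Backbone model

Structures are backbone-only: N, CA, C, O per residue, one-letter
sequence, 1-based PDB-style numbering (insertion codes rejected).
Chains are built and rebuilt by sequential internal-coordinate (NeRF)
placement with idealized covalent geometry: N–CA 1.458 Å, CA–C 1.523 Å,
C–N 1.329 Å, C=O 1.231 Å; angles N–CA–C 111.2°, CA–C–N 116.2°,
C–N–CA 121.7°, CA–C–O 120.8°. ω defaults to 180° (trans) wherever it is
not explicitly sampled; fragments and loophash entries carry their own ω.
Chain breaks are detected on the C(i)–N(i+1) distance (1.33 ± 0.25 Å),
recorded, and never silently bridged. When a segment rebuild breaks its
downstream junction, the pre-break junction torsions (ω of the last
segment residue and φ of the following residue) are retained as structure
metadata so the closure target geometry can be reconstructed exactly;
this mirrors the fact that idealized benchmark starts keep the anchor
residues' own torsions.

## Analytic kinematic closure

A closure problem fixes the anchors (C of the residue before the first
pivot, N/CA of the first pivot; N of the residue after the last pivot,
with the last pivot's CA/C derived from the downstream anchor), the
covalent geometry, and all nonpivot torsions. The solver exploits the
rigid-triangle structure of the problem:

1. The three pivot CA atoms form a triangle with fixed side lengths
   (nonpivot torsions freeze the two spans; the outer two CAs are pinned),
   so the middle pivot CA lies on a circle parameterized by one angle σ.
2. For each σ, each flanking subproblem ("reach the middle CA with this
   span") reduces to a linear trigonometric equation in one torsion —
   at most two branches, each fixing both free torsions of that span in
   closed form.
3. One scalar constraint remains: the N–CA–C bond angle at the middle
   pivot. Its residual is scanned over σ (720 points) for all four branch
   combinations, sign-change brackets are narrowed by vectorized 16-fold
   subdivision (five rounds, one batched evaluation per round), and
   shallow tangential minima are polished separately.
4. Branch-existence boundaries are handled by clamping the arccos in the
   subproblem solve, which keeps the scanned residual continuous across
   the boundary; clamped pseudo-roots are removed by a feasibility gate
   plus verification. Without this, genuine solutions within one grid
   step of a boundary are missed.
5. At each root the pivot φ/ψ are read off the assembled coordinates.
   All other constraints hold exactly by construction, so the
   reconnection residual is bounded by the remaining angle error times a
   conservative lever arm; solutions above 1e-4 Å are discarded.

Solution sets are deduplicated (1e-4°) and deterministically ordered.
Completeness is certified empirically against an independent brute-force
oracle (tests/oracle_kic.py): a 2° grid over the six pivot torsions,
searched hierarchically with provable rigid-distance pruning bands, every
surviving grid basin followed to its own local minimum by batched damped
Gauss–Newton on the direct forward-kinematics residual. Polished minima
below 1e-6 Å are closures; minima that stall around 1e-5 Å are
near-tangent configurations, not solutions. On randomized 6-residue
problems the analytic and brute-force sets agree exactly in both
directions.

Pivot selection fixes the first and last segment residues as pivots (the
anchors must bound the problem) and draws the middle pivot uniformly among
interior residues. Pivot solutions are screened against the packaged
Ramachandran tables with a density floor (default 1e-4 of the per-class
maximum). Among surviving solutions the sampler by default rebuilds each
and keeps the best-scoring one (`solution_selection="energy"`); the
uniform random choice of the original stochastic protocol is available as
an option. The greedy choice suits the smooth three-term surrogate energy
and measurably improves native recovery at fixed move counts.

CCD closure is provided as a baseline: every segment φ/ψ is swept in
order, each update applying the closed-form rotation that minimizes the
summed squared deviation of the three downstream anchor images, so the
RMS break distance is non-increasing.

## Ramachandran tables

`data/rama_tables.tsv` holds synthetic residue-class (general / glycine /
proline / pre-proline) φ/ψ density grids at 10° resolution, generated by
`loopforge.rama.generate_tables`: mixtures of truncated anisotropic
Gaussians on the canonical α, β, polyproline-II and left-handed-α basins,
truncated at 3.8σ and max-normalized per class. Widths are deliberately
generous (the general-class support covers ≈ 57% of the map) so the
screen rejects only genuinely disallowed torsions; the quadrant around
(φ, ψ) = (150°, −150°) is exactly zero for non-glycine classes. Sampling
draws bins proportional to density (optionally sharpened, p ∝ density^k)
with uniform in-bin jitter. These tables are a documented stand-in for
statistically derived propensity maps; nothing in the package depends on
their precise shape beyond the support/zero structure described here.

## Simplified backbone energy

Three terms, all non-negative: Ramachandran −log density (floor 1e-6),
soft-sphere clash Σ((r₀−d)/r₀)² over backbone pairs with sequence
separation ≥ 2 (r₀ = 3.4 Å CA–CA, 3.0 Å otherwise), and harmonic
coordinate restraints Σ k·d² (default k = 1 energy/Å²). Default weights
1 / 10 / 1. This surrogate ranks closed, clash-free, torsionally plausible
backbones; it makes no claim of comparability to all-atom energies, and
results that depend on fine energetic discrimination (e.g. which of two
plausible loop basins a sequence prefers) inherit its limitations.

## Sampling protocol

Each model is an independent Metropolis trajectory: idealized-extended
(or Ramachandran-randomized) segment initialization, then
`outer_cycles × inner_cycles` moves under a geometric temperature ramp
(defaults 10 × 10 cycles, T 2.0 → 0.6). A failed move (no closure
solutions, empty loophash query, CCD non-closure) is a rejected step.
The recorded model is the lowest-energy closed structure proposed during
the trajectory; coordinates outside the segment are never modified.
Trajectory i is seeded with `seed + i`; reruns are bit-identical.
`n_models` defaults to 500, matching large-scale practice, but every test
and example uses the reduced ensemble and cycle counts stated in its
configuration — the package's reduced benchmark protocol is 25–50 moves
per model, which suffices for the 4–8-residue fixture loops studied here.

## Fragments and loophash

Fragment libraries rank every source window against each alignment frame
by a BLOSUM62 similarity sum to the query window, keeping the top
`max_per_frame` (default 200, the production frame size; at fixture scale,
where a handful of source structures exist, the tests use top-1…5 frames
so the frame population is the desk-scale analogue of "best matches from
a large database"). Homologs are withheld by source id, optionally by a
window-identity cutoff. Picking is uniform at each level (size class,
overlapping frame, fragment), insertion applies φ/ψ/ω exactly on the
overlapped positions, and libraries serialize to a documented TSV.

The loophash database indexes every interior window of the requested
lengths by the rigid transform between the backbone frames (origin CA,
axes from N/CA/C) of the residues bounding it. Keys bucket the
translation at 1.0 Å per axis and intrinsic z-y-x Euler angles at 15° per
axis (wrap-aware); queries return all entries within a Chebyshev bucket
radius (default 1). Application replaces the torsions strictly between
the pivots, optionally mutating the span to the entry's amino acids.

## Synthetic fixtures

Fixtures are helix- (or strand-) flanked loops of length 4–16 built by
forward kinematics: flanks at (−57°, −47°) or (−120°, 130°), loop torsions
from named presets or sharpened Ramachandran draws (p ∝ density⁴, matching
the basin-mode concentration of curated loops). A random loop is accepted
only if the fixture is clash-free (< 0.1) and well bent (anchor CA span
below 55% of maximal extension — real loops bend; near-extended loops
leave closure no geometric room). Random-recipe loops are then refined
into a local optimum of the simplified energy by greedy Ramachandran-KIC
descent, the synthetic analogue of natives being minima of the scoring
model used to rank predictions. Sequences follow a fixed aperiodic
pattern over an 8-letter alphabet (no glycine/proline unless requested)
so window alignment is unambiguous. Two-segment cases place a second,
independently drawn chain with its loop facing the first (first contact
at ≈ 4 Å, at least one inter-loop CA pair < 8 Å).

What passing tests on these fixtures shows — and does not show: the
machinery (closure exactness and completeness, move contracts, metric
definitions, selection operators) is validated unconditionally; the
*performance* results (native recovery, FKIC > KIC ordering, the
fragment-quality anti-correlation) are directional demonstrations under a
surrogate energy and synthetic conformational distributions, not
predictions of real-protein benchmark magnitudes, which require an
all-atom energy function and curated experimental datasets.

## Design loop

Stage 1 runs restrained LHKIC per segment-length variant (only
shortening deltas; candidates are never compared across lengths).
Stage 2 adopts the loophash-accumulated sequences (the stand-in for
rotamer-based sequence design, which needs side chains) and selects by
restraint satisfaction and exact Pareto fronts over
{total energy, restraint satisfaction, clash, Ramachandran, fragment ⟨D⟩}
subsets, with NSGA-II-style crowding-distance subsampling when a front
exceeds the requested size. Stage 3 re-predicts each candidate with
unrestrained FKIC using a library built from the candidate's own
sequence; the restraints are used only to classify models (< 1 Å
satisfied, > 2 Å unsatisfied, the band between excluded) and the score
gap is min unsatisfied energy − min satisfied energy. Candidates whose
every model is satisfied rank highest; candidates with no satisfied model
are flagged failures.

## Numerical choices and limitations

* Closure tolerance 1e-4 Å; solver scan 720 σ-points; duplicate-solution
  radius 1e-4°; solution count is empirically ≤ 16 but not enforced.
* Kabsch superposition delegates to scipy's rotational alignment;
  degenerate (collinear) point sets still return a proper rotation.
* Benchmark RMSD uses all four backbone atoms (N, CA, C, O) after
  superposing on the non-segment backbone; a flag selects other atom
  subsets. Multi-segment cases are scored jointly after one alignment.
* ω stays at its sampled/trans value at pivots; pivot ω is never a
  closure degree of freedom.
* The package does not model side chains, hydrogens, solvation or
  electrostatics, and no claim is made that its energies are comparable
  to any force field's magnitudes.
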