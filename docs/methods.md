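# Methods

This note records the model, its assumptions, the defaults, and the design
choices made where the procedure was genuinely open.  Empirical statements
below are limited to what the test suite and `scripts/acceptance.py`
themselves compute.

## Data model

A morphology is a forest of sections (polylines with radii) attached to a
soma centre; coordinates are absolute micrometres in atlas space and are
never re-centred on read.  SWC I/O accepts the common 7-column dialect with
one- or three-row somata (collapsed to their centroid).  On write,
coordinates are emitted with six decimals; reading canonicalizes
sectioning by merging unbranched chains *within one structure type*, so a
write→read→write cycle is byte-stable and trunk/tuft labels survive
(structure types 2 and 7 respectively).  A morphology built in memory with
redundant section splits will re-read with fewer sections but identical
nodes, topology and labels.

## Tuft clustering

Terminals are clustered pairwise: same tuft iff Euclidean distance
≤ `d_euclidean_max` (default 100 µm) AND tree path distance
≤ `d_path_max` (default 3× the Euclidean threshold), with transitive
merging.  The pairwise path distance is measured terminal-to-terminal along
the tree.  The common ancestor of a multi-terminal tuft is the deepest tree
node shared by all of its terminals' root paths; for a singleton tuft it is
the terminal section's first point.  Tuft membership is defined as the
sections on the root paths from the common ancestor to the tuft's own
terminals: this coincides with "everything distal to the common ancestor"
whenever clusters are subtree-consistent, and keeps trunk/tuft labels a
disjoint partition even when two tufts share an ancestor node.  An axon
whose only common ancestor is the soma is rejected (`degenerate tuft at
soma`) — there would be no trunk at all.

## Barcodes

The barcode of a rooted subtree is the persistence of its path-distance
filtration under the elder rule: at each merge the branch with the smaller
maximal descendant distance dies.  Bars are stored (birth, death) with
birth ≤ death, birth being the merge distance (0 for the root bar).  With
this orientation the bar count equals the terminal count and the summed
persistences equal the subtree cable length exactly, which the suite
asserts to 1e-9 relative error on 1000 random trees.

## Atlas fields

The atlas is an isotropic voxel grid (region ids, depth y(r), per-voxel
orientation toward the pia).  Derived fields:

* **Attraction γ(r)** — a sum of unit-amplitude isotropic Gaussian kernels
  at the attractor points.  The kernel form is a package choice (the
  mechanism only requires a smooth, local, non-negative field); the kernel
  scale defaults to the attractor thinning distance, except in the
  spacing-ladder experiment where it is fixed (50 µm) so that sparser
  attractors genuinely leave gaps.
* **Boundary field b(r)** — per-voxel vector with ‖b‖ = distance to the
  nearest brain boundary.  For inside voxels the stored vector points *away*
  from the boundary (into the brain); outside voxels point back toward the
  brain with fixed norm 1e-3 µm.  The attenuation vector
  a = b̂·exp(−α_b·‖b‖) (with a within-voxel linear refinement of ‖b‖ by
  projecting the point-to-voxel-centre offset onto b̂) is *added* to each
  growth step direction.  The inward orientation for inside voxels is
  deliberate: it is the only sign convention under which adding a repels
  growth from the surface and makes the exterior repulsive, which is the
  stated purpose of the construction.  Since ‖a‖ ≤ 1 cannot dominate a unit
  step direction arbitrarily close to a wall, growth additionally applies a
  hard containment guard: a step that would exit the brain is retried along
  the purely inward direction (scaled down twice if needed).  The guard is a
  numerical safety net; the suite verifies zero escaping points over 50
  surface-hugging tufts, and that far from any wall the boundary machinery
  leaves section-length distributions unchanged.

The edge-weight attraction amplitude λ_γ is restricted to (−1, 0]: with a
positive amplitude, high-affinity regions would *raise* edge weights,
contradicting the intended preference for projection tracts, and values
≤ −1 would allow non-positive weights.

## Trunk synthesis

Graph construction order: terminals → `n_intermediate` evenly spaced points
per source–target segment (default 10) → `n_random` Poisson-disk points in
the bounding box honouring `r_random` (defaults 50 points / 50 µm; rejection
sampling, seeded) → one round of Voronoï vertices (Delaunay circumcentres,
discarded beyond the bounding box + `bbox_margin`) → merge of points closer
than `merge_radius` (default `r_random`/2; the survivor is the point closest
to the cluster centroid, terminals never merge away) → discard of
points outside the brain (never terminals).  Degenerate point sets
(coplanar/collinear) fall back to a complete graph with a logged warning.

The Steiner solver is the classical metric-closure 2-approximation
(terminal-pair Dijkstra → MST of the closure → path expansion → subgraph
MST → leaf pruning), with lexicographic tie-breaks for determinism.  A
Dreyfus–Wagner dynamic program (|terminals| ≤ 10, |nodes| ≤ 16, enforced)
serves as the exact oracle; the suite checks approx/OPT ∈ [1, 2] on 500
random instances and cross-checks the oracle against exhaustive
Steiner-node subset enumeration and networkx's independent implementation.

The walk between consecutive immovable points (source, bifurcations,
targets) uses direction weights β_ep, β_nit, β_hist, β_rand (defaults 1, 2,
1, 1.5; the randomness weight must stay below the sum of the other three,
enforced at construction).  u_hist is the exponentially weighted mean
(decay 0.5) of the last 5 step directions — the history definition is a
package choice.  Step lengths are truncated-normal with the trunk
segment-length statistics; the distribution family is a package choice as
well.  Intermediate-target reassessment: a target is reached when its
distance increased since the previous step or fell below
`step_length_mean × reach_coefficient` (coefficient 1).  The walk snaps
exactly onto the endpoint once within one step of it (after all
intermediates are consumed), so immovable coordinates are preserved
bit-exactly — asserted, not just intended.  β schedules are constant per
walk; a per-step callable can be swapped in.

## Tuft synthesis

Template selection follows the two-factor normal-density affinity on
(total path length, path distance to soma) with bandwidths σ_l, σ_d
(defaults 1000 µm each) and probabilities A_j/ΣA_k.  Whether the densities
are normalized is immaterial: both σ are fixed per query, so normalization
constants cancel in the ratio.

The grower inverts the elder rule: bars sorted by persistence; the most
persistent bar seeds the root tip; each remaining bar attaches to the
already-placed bar whose interval contains its birth (ties to the longest
remaining life).  Step lengths are clamped so bifurcation and termination
land exactly on bar births/deaths; consequently terminal count equals bar
count exactly and synthesized cable equals the summed persistences (up to
1-nm separator segments inserted when two births coincide).  This is a
deliberately simplified, fully documented grower — not a re-implementation
of any external growth package; step directions blend the previous
direction (weight 0.7), the template orientation, and a `randomness`-scaled
uniform sphere sample, plus the boundary attenuation term.  Radii are
constant (0.5 µm); trunk/tuft taper is out of scope.

In the mimic workflow each target grows from its own clustered tuft record
("matched" selection) by default, mirroring the one-axon look-alike
experiment; population synthesis uses the probabilistic Eq-style selection
with the query length set to the dataset mean.

## Validation

* Projection grids accumulate per-voxel clipped cable length (a boolean
  occupancy mode exists); grid bounds default to the joint bounding box
  padded by one voxel so L1 curves are reproducible.
* L1 = Σ|r_i − s_i|/(Σr_i + Σs_i) per voxel size; symmetric and
  scale-invariant by construction.
* MVS = |median_a − median_b| / visible spread, with the visible spread
  defined as the envelope from the smaller 5th to the larger 95th
  percentile of the two samples.  The spread definition is isolated in one
  function so alternatives can be swapped; under this envelope the spread
  always dominates the median difference, so the score lies in [0, ~1] and
  a zero spread implies equal medians.

## Synthetic fixtures and what they do (not) show

The slab atlas is a 1 mm cube of 25 µm voxels: four layers stacked along Y
(depth = world Y, orientation +Y), a 3×3-voxel projection-tract tube along
X, and a 2-voxel outside margin.  Its flat geometry makes boundary-field
and depth-field answers analytic.  Toy axons are trunks visiting anchor
waypoints with a terminal bush per anchor, built so bushes are separable at
the intended clustering distance.  Random trees drive the property tests.

These fixtures exercise every contract of the pipeline, but they are not
statistically realistic mouse axons: they do not reproduce MouseLight
branch statistics, curved cortical depth fields, or region-specific tuft
shapes.  Passing tests therefore certify algorithmic correctness and
mechanism behaviour (tract following, containment, scale-resolved
accuracy), not biological fidelity on real data, which requires real
reconstructions and a real atlas supplied through the same interfaces.

## Experiment sizes and numerical choices

Acceptance experiments run at: 500 Steiner instances (≤16 nodes, ≤5
terminals), 1000 barcode trees, 500 tuft grows, 10⁴ template draws, 200
clustering round-trips, 20 axons per tract-preference arm, 12 graph
realisations per attractor spacing (100/300/500/750 µm), 50 + 2×200
boundary tufts, and 5 mimic runs — sizes chosen to make the stochastic
assertions stable across seeds on a single CPU.  Ties in MSTs break
lexicographically; Dijkstra requires the (guaranteed) positive edge
weights; coincident bar births are separated by 1-nm segments; degenerate
Delaunay inputs fall back to complete graphs; walks failing to converge
raise rather than truncate.  Per-axon RNG substreams are spawned from the
global seed so serial and parallel execution agree.

## Known limitations

* Trunk radii are constant; no diameter model.
* No axon–axon collision avoidance or forbidden-region modelling (parallel
  duplicated trunks collapse to one, as expected from pure cost
  minimisation).
* Isotropic voxels only; single-pass Voronoï enrichment; fixed random-point
  count (a per-volume helper would be a natural extension).
* The inter-segment-angle metric's anchor points are not standardized;
  implemented as the angle between consecutive segments within a section
  and flagged experimental.
* The Bernoulli model for "how many target populations per axon" is a
  package choice; an exact-k mode is provided.
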