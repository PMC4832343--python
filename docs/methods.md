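# Methods

## The fluctuation-correlation network model

The analysis views an equilibrated protein (or protein–peptide complex)
trajectory as a weighted graph of residues.  Three conventions define it:

* **Nodes.** One node per amino acid.  The node's representative point is
  the α-carbon by default (`node_rule="alpha_carbon"`), configurable to the
  residue heavy-atom mass center; the choice is recorded in every output
  because the correlation estimates differ slightly between the two.
* **Edges.** A pair of residues is connected iff it is not covalently
  linked and its minimum heavy-atom distance is below 4.5 Å in strictly
  more than 75% of frames.  "Covalently linked" is interpreted at residue
  level as chain-adjacent (|i−j| ≤ 1 within a chain); inter-chain pairs are
  never excluded.  Both the 4.5 Å cutoff and the 0.75 occupancy threshold
  use strict inequalities, so the boundary cases are well defined and
  tested.
* **Weights.** Each edge carries the normalized covariance of 3-D
  displacement vectors
  `C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩)` estimated with uniform
  weights over the configured frame window, and the derived path length
  `w_ij = −log|C_ij|`.  The logarithm makes path lengths additive in
  correlation magnitude: a chain of strongly correlated contacts is a
  short, efficient information route.  Anticorrelated motion transfers
  information as well as correlated motion, hence the magnitude.  Undefined
  correlations (zero-variance nodes) propagate as missing and the affected
  edges are dropped with a warning, never silently zeroed.

Shortest paths are computed with Floyd–Warshall; path reconstruction uses a
next-hop matrix.  Only strict improvements replace a tentative path and
intermediates are scanned in ascending canonical node order (labels sorted
lexicographically), which makes ties deterministic and results invariant to
node insertion order.  Edge betweenness counts, for every unordered node
pair, the shortest path(s) crossing each edge.  Two policies exist: the
default counts the one deterministically reconstructed path per pair
(integer counts); the `fractional` policy splits credit over all tied
shortest paths (Brandes accumulation, equal-distance tolerance 1e-9
relative).

## Communities and partition selection

Girvan–Newman decomposition repeatedly removes the highest-betweenness edge
(recomputing betweenness after every removal) until no edge remains,
recording each component split and the betweenness of every edge at its
removal.  During removal the same −log|C| lengths are used as everywhere
else, with the fractional betweenness policy — communities should reflect
correlated information flow, not hop counts.  Ties are broken
lexicographically on edge labels, so runs are bit-reproducible.

Inspecting a dendrogram by eye is not an algorithm, so partition selection
is explicit: the default maximizes Newman–Girvan modularity
`Q = Σ_c (e_cc − a_c²)` (evaluated on the original unweighted edge set)
over the recorded component structures; `fixed_k` returns the first
structure reaching k components.  Two caveats are documented deliberately:

* The dendrogram contains only *nested* partitions.  On clearly modular
  graphs (cliques or blocks joined by sparse bridges) the max-Q cut
  coincides with the global modularity optimum over all partitions, and the
  tests verify this against exhaustive search; on arbitrary dense random
  graphs no edge-removal hierarchy can reach the global optimum, and the
  tests instead verify agreement with an independent reference
  implementation of the same hierarchy.
* Community *counts* of real systems depend on this selection rule;
  absolute counts are therefore reported but not treated as recoverable
  constants of the method.

## Perturbations

A modification site's role is probed without new simulation by multiplying
|C| on all of its incident edges by a factor in [0, 1) and recomputing path
lengths; factor 0 removes the edges.  Weakening can only lengthen shortest
paths (monotonicity is tested against an enumeration oracle), is local
(pairs whose every shortest path avoids the site are unaffected), and
removal is idempotent.  The perturbation report re-runs communities and
pathway mining and quantifies the repartition with the adjusted Rand index.
Factor 1 is rejected rather than silently doing nothing.  The report's
"information flow blocked" flag means the inter-site path existed in the
baseline and no longer exists after perturbation.

## Site-to-partner-chain path statistics

"The number of betweenness between a site and the partner chain" admits
several operational readings; three are implemented and labeled, none
asserted as canonical: `site_paths` (default) counts distinct inter-chain
edges traversed by at least one shortest path from the site to any
partner-chain node; `incident` counts inter-chain edges adjacent to the
site's contact neighborhood that lie on at least one global shortest path;
`betweenness_sum` sums the global betweenness of the `site_paths` edge set.

## Fluctuation analytics

Trajectories are superposed by proper-rotation Kabsch fitting to the
time-averaged structure, iterated twice so the reference is
self-consistent.  RMSF is `sqrt(⟨|r_i − ⟨r_i⟩|²⟩)` per node.  Whole-profile
comparisons between two conditions use the paired Wilcoxon signed-rank test
across residues; per-residue comparisons across replicate sets use the
unpaired rank-sum (a handful of replicates cannot support a paired
per-residue design).  For n ≤ 25 the signed-rank null distribution is
computed exactly by a generating-function convolution over midranks, which
remains exact under tied magnitudes; beyond that the normal approximation
with tie correction is used.  Significant regions are maximal runs of
consecutive residues with p < α (default 0.05); both the α and the
merge rule are parameters, not claims.

The energy landscape is the joint 8×8 equal-width histogram of (Rg, RMSD)
over their observed ranges, normalized to total probability 1; the
lowest-energy bin is the argmax and its member frames are retrievable for
ensemble averaging.  Constant series cannot be binned and raise an error.

Interaction assignment uses strict distance rules per frame: hydrophobic
side-chain mass centers < 6.5 Å (class ALA VAL LEU ILE PRO PHE MET TRP,
extensible — acetyl-lysine is commonly added because the acetyl group packs
hydrophobically), positive/negative charged-moiety mass centers < 11 Å
(acetylation removes lysine from the positive set), and donor–acceptor
(N/O) heavy atoms < 3.5 Å with no angle criterion by default.  Populations
are frame fractions; records with population strictly above 40% are
reported.  Mass centers use atomic masses of the side-chain heavy atoms
(hydrophobic) or the charged moiety (guanidinium/ammonium vs carboxylate);
when a topology lacks the canonical moiety atoms (pseudo-residue models)
the side-chain heavy atoms stand in.

## The synthetic-trajectory generator

The generator emulates the statistical structure the network analysis
assumes — equilibrated Cartesian fluctuations with block-correlated
residues — not molecular physics.

* **Displacement model.** Per axis, the n-residue displacement vector is
  multivariate normal with a planted correlation matrix; the three axes are
  independent and isotropic, and a residue's pseudo-atoms move rigidly
  together.  This makes the estimand of the normalized-covariance estimator
  exactly the planted scalar correlation, so convergence can be tested
  quantitatively (error ∝ 1/√n_frames).
* **Planted correlation matrix.** Unit diagonal, `intra_corr` within
  blocks, `inter_corr` across, and `pathway_corr` on consecutive pairs of
  the designated pathway.  Block-plus-boost constructions can be slightly
  indefinite; negative eigenvalues are clipped at 1e-10, the diagonal is
  renormalized, and the repair magnitude (minimum eigenvalue, Frobenius and
  max-entry change) is recorded in the system's `repair_report`.
* **Geometry.** Each residue carries three pseudo heavy atoms: a CA node
  point and two side-chain points offset 0.4 Å (one carbon, one typed
  nitrogen/oxygen tip so the charge and hydrogen-bond rules are
  exercised).  Designed contact graphs are embedded by a hinge-loss
  distance-geometry optimization (classical-MDS initialization, L-BFGS
  refinement, seeded restarts) targeting CA separations of ≤ 4.0 Å for
  contacts and ≥ 7.0 Å for non-contacts, then verified against the actual
  4.5 / 6.0 Å heavy-atom rules; unrealizable graphs raise an error naming
  an offending pair.  The contact (< 4.5 Å) and separation (> 6 Å) rules
  leave a forbidden annulus, so not every graph is embeddable — e.g. a
  4-cycle with all sides in contact cannot have both diagonals separated
  (parallelogram law), which rules out dense clique blocks with selective
  external bridges.  The designed systems therefore use closed
  triangle-strip rings (spatially interleaved so consecutive-in-space
  residues are never chain-adjacent, since covalent neighbors do not form
  network edges), thinned at "anchor" residues where external bridges
  attach.
* **Fluctuation scales.** Default displacement SD is 0.3 Å per axis
  (0.45 Å for peptide residues in the demo complex), the magnitude of an
  equilibrated folded core.  The scale trades off against contact
  occupancy: persistent planted contacts must stay under the 4.5 Å cutoff
  in > 75% of frames, which holds comfortably at these scales while still
  giving non-trivial occupancies.  An optional per-atom thermal jitter
  (`contact_jitter`, default off) decouples occupancy tuning from the
  correlation structure when intermediate occupancies are wanted.
* **Designed systems.** `make_two_block_system` (20 residues, two
  ring-blocks, one bridge contact, marked sites at the far ends),
  `make_ring_pathway_system` (16 residues on a single spatial cycle
  crossing two chains twice, so exactly two routes join the sites and the
  boosted arc is the unique shortest pathway), and `make_demo_complex`
  (a 22-residue receptor with two domains and a flexible linker plus a
  9-residue peptide docking a lysine site K4 and an acetyl-lysine site
  K8ac, with a planted K4 → domain 1 → bridge → domain 2 → K8ac pathway,
  a planted hydrogen bond, and hydrophobic/electrostatic interface
  partners).

What passing tests on these systems do **not** show: real trajectories have
anharmonic, time-correlated dynamics, conformational substates, solvent
effects and rotameric side-chain motion, none of which the i.i.d. Gaussian
model contains.  The synthetic results validate the *estimators and graph
algorithms*, not the biological conclusions one would draw from real MD.

## Numerical conventions

* All distances Å, times ps; correlations unitless in [−1, 1].
* Node order is canonicalized by sorting labels; all tie-breaks
  (Floyd–Warshall intermediates, Girvan–Newman edge removal) are
  deterministic, making runs bit-reproducible for fixed seeds.
* Equal-distance tolerance in fractional betweenness: 1e-9 relative.
* PCA eigenvalues come from SVD of the centered coordinate matrix
  (population normalization, matching the correlation estimator).
* Degenerate inputs fail loudly: single-frame RMSF, constant landscape
  series, collinear superposition selections, empty frame sets, k > n
  community requests, same-sign electrostatic pairs.

## Problem sizes

The shipped analyses run at desk scale by design: synthetic systems of
16–31 residues, 2 000–10 000 frames, networks of ≤ 40 edges.  These sizes
make every oracle (exhaustive path enumeration, brute-force modularity over
all partitions, naive double-loop correlation) affordable while exercising
every code path; the algorithms themselves are polynomial and run on
hundreds of residues without modification.

## Known limitations

* Girvan–Newman recomputes full betweenness after each removal (O(V·E²)
  per decomposition); fine for hundreds of edges, slow beyond.
* The hydrogen-bond rule is distance-only by default, as is conventional
  when donor hydrogens are not resolved; an optional angle criterion is
  deliberately out of scope.
* PCA operates on node representative points, not all heavy atoms.
* The plain-table trajectory format stores 3 decimals (≤ 1e-3 Å round-trip
  error); binary formats (DCD/XTC) are read via mdtraj.
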