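# Methods

## Contact network model

A structure is reduced to one node per residue at its Cα position. The
network at cutoff `r_c` has an edge between residues i ≠ j exactly when
their Cα–Cα distance satisfies `D_ij < r_c` (strict inequality). The
default cutoff is 7.0 Å (0.7 nm), the widely used first-interaction-shell
radius for Cα networks; 6.5 Å and 8.0 Å are the conventional sensitivity
bounds, and contact sets are guaranteed (and tested) to nest monotonically
across cutoffs. Sequence neighbours are not excluded, so the backbone
contributes edges; all distances are handled internally in Å, with the CLI
accepting explicit `A`/`nm` suffixes to avoid unit mistakes.

Assumptions: single chain, one Cα per residue, X-ray-style static
coordinates. Edges are purely geometric — no hydrogen-bond, salt-bridge or
energy typing, and no side-chain or all-atom variants.

## Structure input and annotation

PDB parsing is delegated to gemmi; this package reduces the parsed model to
the Cα trace of one protein chain (the first, unless configured), first
MODEL only, ignoring HETATM and waters, and resolving alternate locations
to the highest-occupancy conformer (ties toward altLoc "A" — the standard
crystallographic convention). An atom named CA is accepted only when its
element is carbon, so calcium ions never become nodes.

Secondary structure comes from the PDB HELIX/SHEET header records by
default; an external two-column file (residue number, H/E/C) can override
it, and everything unannotated is loop. Residue roles are configuration:
a catalytic set (for Lipase A, the triad S77/D133/H156), an active-site
set (the triad plus the pocket residues 12, 14, 15, 18, 106, 108, 131, 134,
135, 136, 153 — this membership is not canonical and is fully
configurable), mutated positions parsed from strings such as "N166Y", and
a terminal window (default 4 positions from either chain end). Every
configured residue number must resolve in the structure or the
configuration is rejected outright.

Residue correspondence between structures is by author residue number
only; length-mismatched homologs requiring sequence alignment are out of
scope. Contacts touching residues outside the matched intersection are
excluded from differential sets and reported separately, so missing
density cannot masquerade as a contact change.

## Contact classification

Each contact (i, j), identified across structures by its author-number
pair, carries flags:

* `range_class`: long when `j − i >` the long-range threshold, default 12.
  The threshold is a genuine convention choice: helical short-range
  contacts span separations up to 4, and typical tertiary bridges sit well
  above 12, but any value in between is defensible, so it is exposed as
  configuration rather than hard-coded.
* `involves_loop` / `involves_terminus`: either endpoint is a loop or
  terminal-window residue.
* `near_active_site`: either endpoint is in the active-site set or within
  the active-site radius (default equal to the contact cutoff, 7 Å) of a
  catalytic Cα.
* `connects_regular_ss`: both endpoints lie in regular secondary structure
  and in *different* maximal helix/strand runs.

For a mutant's made contacts the flags are evaluated on the mutant
structure (where the contact exists); for lost contacts, on the reference.

## Network metrics

Degree, Watts–Strogatz clustering, Brandes betweenness, per-component
closeness and BFS all-pairs shortest paths are implemented directly (the
residue-wise differences of these quantities are the analysis surface, so
the implementation is first-party); networkx, scipy's Floyd–Warshall and
exhaustive path enumeration serve as independent oracles in the tests
only. Betweenness is reported unnormalised by default (normalised variant
divides by (n−1)(n−2)/2). Closeness is `n_reachable / Σ d` within a node's
component and 0 for isolated nodes — crystal-structure networks at 7 Å are
connected, but synthetic fixtures need the disconnected case defined.
Z-score selection standardises within one structure's residue population
using the population (ddof = 0) standard deviation and selects strictly
above the threshold; a constant series yields an empty selection with a
warning rather than an error.

## Communities

Clauset–Newman–Moore greedy agglomeration: start from singletons,
repeatedly merge the connected community pair with the largest modularity
gain ΔQ = 2(e_ij − a_i a_j), and return the partition with the highest Q
seen along the merge sequence. Ties in ΔQ are broken toward the
lexicographically smallest (min id, max id) pair, which makes runs
bit-reproducible — reference implementations leave this order unspecified,
so community *labels* may differ between tools even when Q agrees. Only
connected pairs merge, so no community ever spans two components; an
edgeless graph yields singletons with Q defined as 0.

Partition comparison pairs residues by author number, builds the
contingency table, matches communities greedily by descending overlap, and
reports reassigned residues plus split/merge events. An event requires at
least `min_overlap` residues (default 3) in each involved counterpart,
which filters single-residue flicker; greedy matching is adequate for the
≤ 7 communities these networks produce (a Hungarian assignment would
change nothing at that size).

## Superposition

Rigid-body alignment is the Kabsch solution: SVD of the covariance of the
centred point sets with the determinant guard (flip the smallest singular
vector when the product determinant is negative) so reflections are never
returned. Inputs need n ≥ 3 non-collinear points (rank of the centred
coordinates ≥ 2, tolerance 1e-8). All matched Cα carry unit weight. The
cross-structure RMSD matrix applies this to every pair's matched residues;
the residue-wise profile superposes every ensemble member onto the
reference over the residues common to all structures and reports, per
residue, the RMS deviation of its Cα around the ensemble-mean position.
Note that fragment-based or sequence-order-independent structural aligners
weight and select residues differently, so their pairwise RMSDs can differ
from the all-Cα least-squares value by a few hundredths of an Å.

## Synthetic data

The generator emulates single-chain Cα backbones: ideal α-helices (rise
1.5 Å, twist 100°, radius 2.3 Å — chosen so that every (i, i+1)…(i, i+4)
pair is a 7 Å contact and no separation > 5 pair is, the canonical helical
contact pattern), extended strands (3.3 Å rise, ±0.5 Å zig-zag), and a
gentle wide spiral standing in for coil. Segments stack along z with a
3.8 Å junction step; seeded Gaussian jitter (default study value 0.15 Å)
roughens the geometry. The standard study system is a 40-residue
helix–coil–strand–coil–helix chain with six mutants of three contact
edits each.

A "mutant" is produced by contact edits: to inject (i, j), one endpoint is
moved just inside the cutoff toward the other (candidates: direct pulls
past the cutoff at several margins, jittered pulls, then a full sphere
sweep at 0.9·r_c); to remove, it is pushed just outside (≥ 1.02·r_c, a
margin that keeps the pair robustly beyond the boundary under coordinate
round-tripping). A candidate placement is accepted only if every *other*
pair's cutoff status is preserved, and after all edits the full
brute-force distance matrices of reference and mutant are compared: the
symmetric difference must equal the requested edit set exactly, otherwise
an infeasibility error is raised — never a silent partial application.
Single-residue moves were chosen over multi-residue excursions because
side-effect-free placement is then a tractable search and the post-hoc
verification makes the ground truth unconditional; the cost is that edits
between residues farther apart than the slack in the moved residue's own
neighbourhood (for example bridging helices 30 Å apart) are infeasible,
which the random-edit sampler simply resamples around.

What passing on this generator does and does not show: it validates the
bookkeeping — contact sets, set differences, classifications, metric
deltas, community comparison — exactly, because the ground truth is exact.
It does not exercise real crystallographic artifacts (alternate
conformations beyond the synthetic writer's vocabulary, missing density,
multi-chain packing) beyond the specific parser tests, and toy geometries
have far fewer long-range contacts than a real globular fold, so
category *proportions* on synthetic runs are not comparable to real
proteins.

## Reproduction scope and problem sizes

The package reproduces, given the seven deposited Lipase A structures
(wild type 1I6W; mutants 1T4M, 1T2N, 3D2A, 3D2B, 3D2C, 3QMM), the
wild-type network size (181 residues), the per-mutant and union made/lost
contact counts with their loop/long-range tallies, the degree-change
statistics, the wild-type community count, and the cross-structure RMSD
band. Those coordinate files are not bundled with the package; the
corresponding checks in `tests/test_acceptance.py` look for them under
`data/pdb/` and fail with an explicit message when absent. Loop-dependent
counts depend on the secondary-structure source (PDB header vs DSSP-style
file) and range-dependent counts on the long-range threshold; both are
exposed as configuration for exactly that reason.

The default test and acceptance runs use the synthetic study at n = 40
residues with 6-mutant series, 100-mutant recovery batches, and metric
oracle sweeps over random graphs with n ∈ [5, 50] — sizes chosen so the
full suite exercises every code path in about two minutes on one core
while the brute-force oracles (exhaustive path enumeration, Bell-number
partition enumeration) stay exact.

## Known limitations

* No weighted or all-atom networks; no eigenvector centrality; no
  Louvain/Leiden alternatives.
* Correspondence by author numbering only — renumbered depositions must be
  renumbered before comparison.
* The greedy partition matcher can mis-pair communities of equal overlap;
  with ≤ 7 communities and min_overlap filtering this has not been
  observed on any fixture.
* mmCIF input is not supported (PDB format only).
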