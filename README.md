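# pcnkit

Protein contact network (PCN) comparison of a wild-type protein against a
series of mutants: build Cα contact networks from PDB coordinate files,
compute residue-level network metrics and modularity communities, superpose
structures, and quantify exactly which contacts a mutant makes and loses
relative to the reference — and what those changes do to each residue's
place in the network.

The motivating use case is point-mutant series such as the *Bacillus
subtilis* Lipase A thermostable variants, where mutants are nearly
identical to the wild type in overall conformation (cross-structure RMSD
well under 1 Å) yet differ sharply in stability. At that scale, global
descriptors are uninformative; the signal lives in a handful of gained and
lost residue–residue contacts and in the resulting shifts of centrality and
community membership.

## The model

A structure with *N* residues is reduced to its Cα trace and represented as
a graph with adjacency

    A_ij = 1  if D_ij < r_c and i ≠ j,   else 0

where `D_ij` is the Cα–Cα distance and the cutoff `r_c` defaults to 7.0 Å
(0.7 nm), the standard first-interaction-shell radius; sequence neighbours
are kept. On this graph pcnkit computes, from first principles:

* **degree** `k_i = Σ_j A_ij`;
* **clustering coefficient** `C_i = 2 e_i / (k_i (k_i − 1))` with `e_i` the
  number of edges among i's neighbours;
* **betweenness centrality** `BC_i = Σ_{s≠i≠t} σ_st(i)/σ_st` over unordered
  pairs (Brandes' algorithm), optionally normalised by `(n−1)(n−2)/2`;
* **closeness** (per connected component), BFS **shortest paths**,
  characteristic path length and diameter;
* **z-score outlier selection** within one structure's residue population
  (population SD), e.g. BC at z > 2.5 and clustering at z > 2.0;
* **communities** by Clauset–Newman–Moore greedy modularity maximisation,
  `Q = Σ_c (e_cc − a_c²)`, with deterministic tie-breaking;
* **Kabsch superposition** (SVD with reflection guard), cross-structure
  RMSD matrices and residue-wise RMSD profiles of aligned ensembles.

For a mutant vs the reference, `diff_contacts` reports the contacts made
(only in the mutant) and lost (only in the reference) on the residues
matched by author number, classifies each one (long-range vs short-range by
sequence separation, loop involvement, chain-termini involvement,
active-site proximity, bridging of distinct secondary-structure elements),
and attaches per-residue metric deltas. `union_contacts` deduplicates made
and lost sets across a whole mutant series.

A synthetic-data module generates toy backbones (ideal α-helices, extended
strands, coil spirals) and "mutants" whose contact changes are known
exactly, so the entire pipeline is testable without structure downloads.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study:

```sh
python analysis/01_build_fixtures.py     # reference + 6 edited mutants
python analysis/02_run_pipeline.py       # networks, metrics, diffs, bundle
python analysis/03_community_reorganization.py
python analysis/04_ensemble_rmsd.py
```

`02_run_pipeline.py` prints:

```
reference network: {'n_nodes': 40, 'n_edges': 104, 'n_communities': 4, 'modularity': 0.6564349112426036}
  mutant_101: made=1 lost=2 ground-truth match: yes
  mutant_102: made=1 lost=2 ground-truth match: yes
  mutant_103: made=2 lost=1 ground-truth match: yes
  mutant_104: made=0 lost=3 ground-truth match: yes
  mutant_105: made=0 lost=3 ground-truth match: yes
  mutant_106: made=2 lost=1 ground-truth match: yes
6/6 mutants recovered exactly
union: 6 made / 12 lost (0 long-range made)
degree changes: avg fraction 0.125, max |delta| 1
cross-structure RMSD range: 0.436-1.644 A -> .../results/bundle
```

Each mutant was built by applying three geometrically feasible contact
edits to the 40-residue reference; the pipeline recovers every injected and
removed contact exactly, and the per-mutant made/lost counts, the
deduplicated union, and the degree-change statistics all agree with the
recorded ground truth. The report bundle under `results/bundle/` holds
per-structure metric tables, community memberships, ring-graph layouts,
per-mutant diff reports (JSON + made/lost TSV edge lists), the union
report, and the RMSD matrices; re-running with identical inputs reproduces
it byte for byte.

The same pipeline runs from the shell on any PDB inputs:

```sh
pcnkit run reference.pdb mutant1.pdb mutant2.pdb \
    --cutoff 0.7nm --catalytic 77,133,156 -o results/bundle
```

plus `build`, `metrics`, `communities`, `diff`, `superpose` and `synth`
subcommands for the individual stages.

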