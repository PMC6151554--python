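# Methods

This document records the models implemented in `critres`, their
assumptions, the defaults and the reasoning behind them, and the known
limitations.

## Residue contact graph (`contact_graph`)

Nodes are the residues of one chain of one model, indexed 0..n−1 in
sequence order. An undirected edge joins residues *i* and *j* when the
minimum distance between any selected atom of *i* and any selected atom
of *j* is ≤ `cutoff`.

Parameters:

- `cutoff = 5.0` Å — a standard heavy-atom contact threshold that
  captures first-shell van der Waals and hydrogen-bond interactions
  without bridging across intervening residues.
- `atom_mode = "heavy"` — all non-hydrogen atoms. `"CA"` and `"CB"`
  modes are coarser alternatives (`"CB"` falls back to Cα for glycine,
  then to the first atom present).
- `min_seq_sep = 1` — excludes self-contacts only; raise it to suppress
  trivially contacting sequence neighbors.

Contacts are found with a k-d tree (`scipy.spatial.cKDTree.query_pairs`)
over all selected atoms, so construction is O(A log A) in the atom count
rather than O(A²).

Structure parsing (`structure_io`) uses Biopython's `PDBParser`:
hydrogens/deuteriums are dropped, water and other non-amino-acid
hetero groups are skipped, selenomethionine and similar modified
residues map to their parent amino acid, and alternate locations are
resolved by highest occupancy (ties: altloc identifier order).

## Centrality descriptors (`centrality`)

All eleven measures use hop distances (unit edge weights):

- **excentricity** — the longest shortest distance from the residue, and
  its reciprocal;
- **degree** — contact count;
- **sphere degree** — sum of the neighbors' degrees; the accumulated
  variant adds the residue's own degree;
- **mean distance** — Σd over reachable residues divided by their count;
- **closeness** — 1 / Σd (so closeness · Σd = 1 and
  mean distance · #reachable = Σd are exact identities used as oracles);
- **clustering coefficient** — o / (n(n−1)) with o the number of
  *ordered* adjacent pairs among the n neighbors, and its reciprocal;
- **traversity** — for every residue pair at distance ≥ 2, exactly one
  shortest path is selected and each strictly interior residue on it is
  credited once. Variant A selects the lexicographically smallest
  shortest path by residue index, variant B the lexicographically
  largest. The deterministic tie-break makes the measure reproducible
  and testable against exhaustive path enumeration; it intentionally
  differs from betweenness, which averages over all shortest paths.

Disconnected graphs: distance measures are per-component; isolated
residues score 0 everywhere, and reciprocals of 0 are defined as 0 so
descriptor tables stay finite.

## Correlated mutations (`conservation`)

From a multiple sequence alignment containing the structure's chain, the
substitution frequency of column *c* is

S_c = (#non-gap homolog rows differing from the reference at *c*) /
(#non-gap homolog rows).

Columns where the reference is gapped have no corresponding residue and
are skipped. The correlated-mutation index of residue *j* is
CM_j = Σ S_i over all *i* in contact with *j*, hence 0 ≤ CM_j ≤ deg(j).
The reference row is located by identifier or by ≤ 5% mismatch against
the chain sequence.

## Criticality index (`criticality`, `aa_factors`)

Each amino acid is a point in the five-dimensional physicochemical
factor space of Atchley et al. (PNAS 2005). All 380 ordered
substitutions (400 ordered pairs minus 20 identities) are ranked 1..380
ascending by Euclidean distance, ties broken lexicographically by
(from, to) so the ranking is a deterministic permutation.

For a position with *m* reported mutations:

- all mutant (loss-of-function) phenotype:
  CI = Σ R_i / (sum of the m largest ranks, 381−m .. 380), which lies in
  (0, 1] and attains 1 exactly when the reported mutations are the m
  most drastic possible;
- all wild-type (tolerated) phenotype: CI = 1 − Σ R_i / (same
  denominator) — drastic tolerated substitutions argue against
  criticality;
- both phenotypes: CI = ½ [(1 − Σ RW_i / D_w) + Σ RM_i / D_m] with D_w,
  D_m the top-m_w / top-m_m rank sums.

`strict_paper=True` switches the denominator to the literal (m+1)-term
bounds 380−m .. 380, under which CI = 1 is unattainable; the default
m-term denominator is used because it makes the index attain its stated
range. A residue is labeled **critical** iff CI > 0.5 strictly.

Mutagenesis tables are validated: binary phenotype vocabulary (with
common aliases), standard amino-acid codes, no identity substitutions, a
single wild-type residue per position; exact duplicate records collapse,
and conflicting duplicate reports of the same substitution route the
position to the mixed formula.

## Descriptor filtering (`features`, `_mdlp`)

Three sklearn-style selectors, applied in order by `filter_pipeline`:

1. `ConstantFeatureFilter` — drops zero-variance descriptors.
2. `SpearmanRedundancyFilter(threshold=0.95)` — greedy keep-first pass
   in column order: a descriptor is dropped when its |Spearman ρ| with
   an already-kept descriptor is ≥ the threshold. ρ is computed as the
   Pearson correlation of standardized ranks, so monotone transforms of
   kept columns are recognized exactly.
3. `InfoGainFilter` — drops descriptors with zero information gain under
   Fayyad–Irani MDLP discretization (implemented in `_mdlp`: boundary
   midpoint candidates, recursive MDL acceptance criterion). IG = 0 is
   equivalent to "no accepted cut", matching entropy-based discretizing
   filters in standard ML toolkits.

The IG filter requires a nominal target; for numeric targets the
pipeline skips it and records that in the report.

## GA wrapper selection (`selection_ga`)

`GeneticSubsetSelector` searches descriptor subsets maximizing the mean
Matthews correlation coefficient over stratified 10-fold cross-validation
of a class-weighted linear SVM (`LinearSVC(dual=False)`).

Defaults: population 50; initial subset sizes uniform on [1, m/10];
binary tournament selection (tie → smaller subset → first drawn);
subset-size-oriented common features crossover (children inherit the
parents' intersection, the symmetric difference is partitioned so each
child keeps its parent's size) with probability 0.7; single-index toggle
mutation with probability 0.1 and an emptiness guard; elitism 1;
`max_generations = 100` with stagnation stop after 20 generations
without improvement. Class-weight presets: `set1` = {critical: 9,
non-critical: 3}, `set3` = {critical: 5, non-critical: 1.22}.

Chromosomes are frozensets, fitness is cached per subset, and the CV
folds are built once per fit, so reruns with the same `random_state` are
bit-identical. Fitted attributes follow sklearn conventions
(`support_`, `best_subset_`, `best_score_`, `selected_names_`,
`history_`).

## Evaluation (`evaluation`)

Classification reports contain per-class and support-weighted TP rate,
FP rate, precision, recall and ROC area, plus the MCC (defined as 0 when
a marginal is degenerate). Numeric targets get Pearson correlation and
relative absolute error (%). Protocols: leave-one-out with a pooled
confusion matrix, and swapped-dataset testing that automatically
restricts both tables to their shared descriptors (warning) and rejects
disjoint ones. The overlap between two models' predictions is the
asymmetric quantity 100 · |crit(a) ∩ crit(b)| / |crit(a)| (NaN when
model *a* predicts no critical residues).

## Synthetic generators (`synthetic`)

Pure functions of their seed, emitting machine-readable ground truth so
every stage is testable without external downloads:

- **structures** — Cα-only chains: collinear lattice (contact graph =
  path graph), helix-like spiral, self-avoiding random coil;
- **alignments** — homologs mutated i.i.d. from a reference, returning
  the realized per-column S;
- **mutagenesis tables** — per position, a wild type and 1–3
  mutant-phenotype substitutions whose CI is within 0.02 of a requested
  target (exact where attainable), found by exhaustive search over rank
  combinations;
- **feature tables** — N(0,1) descriptors with the critical class
  shifted by `effect_size` standard deviations in a planted informative
  subset; optional monotone-transformed twins (for the redundancy
  filter) and constant columns. Defaults: 300 instances, 5 informative,
  95 noise, 20% critical, `effect_size = 1.5` — chosen a priori so that
  no single descriptor separates the classes but the planted subset
  does, making subset *recovery* (not single-feature ranking) the test.

These generators model idealized data: real descriptor distributions
are neither Gaussian nor class-conditionally mean-shifted, and real
contact graphs are not random geometric spirals. They validate the
machinery, not biological performance.

## Numerical choices

- Hop distances are exact integers (BFS); no floating-point shortest
  paths.
- Spearman ρ uses average ranks and standardized dot products, agreeing
  with `scipy.stats.spearmanr` to machine precision.
- Reciprocal measures define 1/0 = 0 rather than propagating infinities.
- MCC returns 0 (not NaN) for degenerate confusion matrices.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds are drawn below 2³¹.

## Limitations

- Single chain, single model; no mmCIF input; no HSSP alignment
  parsing (FASTA/Stockholm only).
- Physicochemical descriptor suites (e.g. ProtDCal-style thermodynamic
  descriptors) are out of scope; externally computed tables can be
  merged at the `assemble` stage.
- Traversity is a deterministic single-path variant, not all-paths
  betweenness.
- The GA's fitness is an in-sample CV estimate; reported MCC of the
  selected subset is optimistically biased and should be confirmed on
  held-out data (e.g. the swapped-dataset protocol).
- No automated hyperparameter search over classifiers; the classifier
  family is fixed to class-weighted linear SVM / logistic regression.
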