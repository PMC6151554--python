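# critres

Classification of critical residues for protein function from protein
structure.

## The scientific problem

A small fraction of the residues in a protein are *critical*: mutating
them destroys function even though the fold is preserved. Identifying
them experimentally requires saturating site-directed mutagenesis, which
is expensive; the goal here is to predict them from structure alone.

`critres` implements a descriptor-based pipeline:

1. **Contact graph.** Residues are nodes; two residues are in contact
   when any pair of their heavy atoms lies within a distance cutoff
   (default 5 Å; Cα-only and Cβ modes are available).
2. **Centrality descriptors.** Eleven per-residue centrality measures of
   the contact graph (excentricity, degree, sphere degree, simple-node
   nexus, mean distance, closeness, clustering coefficient, traversity,
   and reciprocals) quantify how topologically central each residue is.
3. **Correlated mutations.** Given a multiple sequence alignment, each
   column's substitution frequency S is the fraction of non-gap homologs
   differing from the reference. The correlated-mutation index of
   residue *j* is CM_j = Σ S_i over all residues *i* in contact with *j*.
4. **Criticality labels.** All 380 ordered amino-acid substitutions are
   ranked 1..380 by the Euclidean distance between the residues'
   five-dimensional physicochemical factor vectors. A position with *m*
   reported loss-of-function mutations of ranks R_i gets a criticality
   index CI = Σ R_i / (sum of the m largest ranks) ∈ (0, 1]; tolerated
   (wild-type-phenotype) substitutions contribute a complementary
   tolerance term. Residues with CI > 0.5 are labeled critical.
5. **Descriptor selection.** A constant/Spearman-redundancy/
   information-gain filter cascade followed by a genetic-algorithm
   wrapper (subset-size-oriented common features crossover, binary
   tournament, elitism) that maximizes the 10-fold cross-validated
   Matthews correlation coefficient of a class-weighted linear SVM.
6. **Evaluation.** Per-class and support-weighted TP/FP rate, precision,
   recall, ROC area, MCC; leave-one-out and swapped-dataset protocols;
   asymmetric overlap between the critical sets predicted by two models.

## Worked example

Generate a synthetic 20-residue chain, compute its descriptors, and
label positions from a mutagenesis table:

```bash
critres fixtures make-structure --n-residues 20 --geometry spiral --seed 7 --out chain.pdb
critres descriptors --pdb chain.pdb --atom-mode CA --out descriptors.csv
head -3 descriptors.csv
```

```
residue,pdb_resseq,excentricity,excentricity_inverted,degree,sphere_degree,sphere_degree_accumulated,mean_distance,closeness,clustering_coefficient,clustering_coefficient_inverted,traversity_A,traversity_B
0,1,19.0,0.05263157894736842,1.0,2.0,3.0,10.0,0.005263157894736842,0.0,0.0,0.0,0.0
1,2,18.0,0.05555555555555555,2.0,3.0,5.0,9.052631578947368,0.005813953488372093,0.0,0.0,18.0,18.0
```

```bash
critres fixtures make-mutagenesis --n-positions 6 --seed 7 --out muts.csv
critres label --mutagenesis muts.csv --out labels.csv
cat labels.csv
```

```
position,m,ci,label
1,3,0.6437994722955145,critical
2,3,0.9023746701846965,critical
3,1,0.7868421052631579,critical
4,3,0.2638522427440633,non-critical
5,3,0.33509234828496043,non-critical
6,2,0.8801054018445322,critical
```

The same machinery is available as a Python API:

```python
>>> from critres.criticality import build_substitution_ranking, ci_from_ranks
>>> ranking = build_substitution_ranking()
>>> ranking.rank("A", "V")       # conservative substitution, low rank
13
>>> ranking.rank("A", "W")       # drastic substitution, high rank
217
>>> ci_from_ranks([13, 217])     # CI of a position with these two mutants
0.30303030303030304
```

Downstream, `critres assemble` merges descriptor tables with labels,
`critres filter` applies the three-stage descriptor filter,
`critres select` runs the GA wrapper, and `critres evaluate` produces
the full metric report (leave-one-out, or swapped-dataset with
`--test-table`).

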