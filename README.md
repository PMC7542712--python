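# copolphase

Phylogenetics of allopolyploids is blocked by a missing datum: sequencing a
tetraploid recovers up to four alleles per locus, but not which two belong
to which diploid-derived subgenome.  `copolphase` infers that assignment
from multi-locus gene trees.  It partitions the alleles of one polyploid
taxon — over all sampled individuals and loci — into at most *n*/2
subgenomes such that, treating each subgenome as a taxon P1…Pk, the implied
species tree minimizes the number of **deep coalescences** (extra gene
lineages), the MDC parsimony criterion of species-tree inference.  The
package is aimed at plant systematists and anyone reconstructing reticulate
phylogenies from multi-locus allele data.

## The method in brief

For a candidate partition of the focal alleles, every gene tree is scored
against the best species tree over the diploid taxa plus the pseudo-taxa
P1…Pk.  The cost of a species tree *S* is

    XL(S) = Σ_trees Σ_branches max(0, k_B − 1),

where k_B is the number of maximal gene-tree clades whose leaves map into
the taxon cluster *B* below a branch; the inner optimum is found exactly by
a dynamic program over taxon subsets.  The partition itself is optimized by
**tabu search**: shift/swap moves respecting the at-most-two-alleles-per-
locus-per-subgenome constraint, a tabu list with configurable tenure,
aspiration on best-ever improvement, and optional restarts.  Replicate
runs are summarized by aligning their arbitrary subgenome labels
(minimizing the mean Shannon entropy −Σ c·ln c of the averaged membership
coefficients), relabeling the replicate trees, and building a greedy
consensus with clade frequencies.  A coalescent simulator (Yule species
trees, multispecies-coalescent gene trees, constructed allopolyploids with
known truth) validates the whole loop.  See `docs/methods.md` for the full
account.

## Worked example

Two loci; diploids A, B, C with two alleles each, and a tetraploid X whose
alleles x1–x8 are to be phased.  `trees.nwk` (one rooted Newick per line):

```
((((a1,a2),(x1,x2)),((b1,b2),(x3,x4))),(c1,c2));
((((a3,a4),(x5,x6)),((b3,b4),(x7,x8))),(c3,c4));
```

`table.tsv` (accession, taxon, ploidy, locus, alleles):

```
accA	A	2	L1	a1,a2
accA	A	2	L2	a3,a4
accB	B	2	L1	b1,b2
accB	B	2	L2	b3,b4
accC	C	2	L1	c1,c2
accC	C	2	L2	c3,c4
accX	X	4	L1	x1,x2,x3,x4
accX	X	4	L2	x5,x6,x7,x8
```

```sh
copolphase run --trees trees.nwk --table table.tsv \
    --focal-taxon X --iterations 20 --seed 1 --out-prefix demo
```

prints

```
best MDC score: 0
best species tree: (((A,P1),(B,P2)),C);
```

A score of 0 means the gene trees embed in the species tree with no extra
lineages: the partition is perfectly consistent with the trees.  Subgenome
P1 (x1, x2, x5, x6 in `demo.partition.tsv`) is sister to diploid A and P2
(x3, x4, x7, x8) sister to B — the allotetraploid's two parental lineages,
recovered from tree topology alone.  The run also writes a score trace CSV
and a JSON manifest (parameters, seed, input checksums) for reproducibility.

Replicate runs are combined with the other subcommands:

```sh
copolphase create-indfile --partitions rep1.partition.tsv \
    --partitions rep2.partition.tsv --out-prefix cons
copolphase align-clusters --indfile cons.indfile --out-prefix cons
copolphase relabel-trees --trees replicate_trees.nwk \
    --permutations cons.permutations.tsv --out-prefix cons
copolphase consensus --trees cons.relabeled.nwk --min-frequency 0.5 \
    --out-prefix cons
```

The averaged membership coefficients written by `align-clusters` read as
per-allele assignment support: values near 0 or 1 mean replicates agree.

`copolphase simulate --out-prefix sim` runs the validation study
(configurable via `--config sim.yaml`): it simulates 8-taxon Yule species
trees of depth 10^6 generations, coalescent gene trees with Ne = 10^5 and
two alleles per taxon, merges two diploids into an artificial tetraploid,
re-infers the partition from sampled loci, and reports allele-assignment
accuracy plus normalized Robinson–Foulds distances against the known truth,
next to a diploid-only baseline.

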