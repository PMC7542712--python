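# Methods

## The problem

An allopolyploid of ploidy *n* carries *n*/2 diploid-derived chromosome
sets (subgenomes), each tracing to a different parental lineage.  Multi-locus
sequencing recovers up to *n* alleles per locus per individual, but not which
allele belongs to which subgenome — and without that assignment, the
polyploid cannot be placed in a species phylogeny except as a single,
internally heterogeneous tip.  `copolphase` infers the assignment from
rooted gene trees alone: it partitions the polyploid's alleles (over all
sampled individuals and loci) into at most *n*/2 subsets so that, when each
subset is treated as an ordinary taxon ("P1" … "Pk"), the implied species
tree requires as little gene-tree/species-tree discordance as possible.

## Objective: minimizing deep coalescences (MDC)

For a rooted gene tree *G* embedded in a rooted species tree *S* under a
leaf-to-taxon mapping, each species-tree branch must carry at least one gene
lineage exiting towards the root; every additional lineage is an *extra
lineage*, i.e. one deep coalescence forced by the embedding.  By Maddison's
parsimony formulation, the minimal number of lineages exiting the branch
with taxon cluster *B* equals the number of **maximal** clades of *G* whose
leaves all map into *B*.  The cost of a candidate species tree is

  XL(S, G) = Σ_branches max(0, k_B − 1),

summed over all non-root branches (pendant branches matter when a taxon
contributes several alleles: two uncoalesced alleles of one taxon already
cost one extra lineage).  Scores of multiple gene trees — including several
trees per locus, e.g. posterior samples — are **summed**, never averaged.
`tests/` verifies this formula against an independent brute-force enumerator
of explicit coalescent embeddings on all 3-taxon instances and large random
samples of 4- and 5-taxon instances.

### Exact species-tree inference by subset dynamic programming

Because the cost of a branch depends only on its cluster *B*, the
MDC-optimal rooted binary species tree is a minimum-weight clade tree.  We
precompute w(B) = Σ_trees (k_B − 1) for every taxon subset *B* (vectorized
over subsets with bitmasks) and solve

  g({x}) = 0,  g(S) = min over splits S = T ∪ U of g(T) + g(U) + w(T) + w(U)

by dynamic programming over subsets (3^n split enumeration).  This returns
the same optimum as literal enumeration of all rooted binary topologies —
the test suite checks this against an explicit topology enumerator — at
polynomial cost in 2^n; the engine accepts up to 16 taxa, comfortably above
the 8-taxon validation design.  `clusters` mode restricts usable clusters to
those induced by the gene trees (plus singletons), the classic search-space
reduction from the MDC literature, and falls back to the exact program if no
tree can be assembled.  Ties are broken deterministically towards the
lexicographically smallest sorted-Newick string; this choice is arbitrary
but reproducible.

Polytomies in gene trees are treated as soft: maximal-clade counting on the
multifurcating tree is exactly the optimistic resolution, so unresolved
consensus or posterior trees are never penalized for lack of resolution.

## The search: tabu search over constrained partitions

The optimization variable assigns every focal-polyploid allele (per locus)
to a subgenome index 1..k.  Under the single-copy-locus assumption, at most
**two** alleles of one accession and locus may share a subgenome; this
constraint is what separates subgenome assignment from free clustering and
prevents biologically impossible solutions.

- **Moves.**  SHIFT (reassign one allele to a subgenome with free capacity)
  and SWAP (exchange two same-accession, same-locus alleles across
  subgenomes).  Swaps are necessary for connectivity: a tetraploid locus
  with four alleles and k = 2 is saturated and admits no valid shift.
- **Tabu attribute.**  Applying a move forbids, for `tabu_tenure`
  iterations, re-placing the moved allele into the subgenome it just left
  (a swap records both pairs).  A tabu candidate is still admissible if it
  improves the best score found so far (aspiration).
- **Sampling.**  Per iteration, at most `neighborhood_sample_size` moves
  are drawn uniformly without replacement and scored; the best admissible
  one is applied even if it worsens the current score.  Larger samples cost
  more evaluations per iteration but pick better steps; because scores are
  cached by a label-symmetry-invariant canonical form of the partition,
  revisited partitions are free.
- **Restarts** rerun the loop from fresh uniform random partitions; the
  best solution over all restarts is reported with its species tree, the
  full score trace, and the parameters (seed included) for reproducibility.

Initial partitions are sampled uniformly over all capacity-valid
assignments (rejection sampling per accession-locus group; worst-case
acceptance ≈ 1/8 for a saturated hexaploid locus).  Defaults
(`tenure=5, iterations=100, sample_size=30, restarts=1`) are starting
points, not recommendations: tenure in particular has no universally
sensible value and should be explored per dataset.  One polyploid is
analysed at a time; other polyploids' alleles must be pruned from the gene
trees first (`prune_nonfocal_polyploids`), since without a subgenome
assignment of their own they carry no interpretable signal.

## Consensus across replicates

Repeated runs differ through plateaus, local optima, and sampling noise,
and their subgenome labels are arbitrary (any column permutation of a
partition is the same biological answer).  Each replicate is encoded as a
binary membership matrix (rows = alleles, columns = subgenomes, one 1 per
row).  If per-replicate column permutations are chosen well, the
element-wise average of the permuted matrices is sharp; sharpness is
measured by the mean Shannon entropy over rows,

  H_i = − Σ_j c_ij ln c_ij,  with 0 ln 0 := 0,

of the averaged coefficients c_ij.  `align_clusters` minimizes mean H_i:
exactly (enumerating all (C!)^(K−1) alignments, replicate 1 gauge-fixed to
the identity) for small problems, or by cyclic coordinate descent over
replicates with random restarts (default).  The natural logarithm is used;
the base only rescales the objective and cannot change the argmin.  Ties
break towards the lexicographically smallest permutation tuple.  Aligned
permutations then relabel the pseudo-taxon leaves of the replicate species
trees, and a greedy consensus (clades ranked by frequency, added while
compatible, annotated with their frequencies, optionally thresholded)
summarizes them.

## Validation by simulation

The simulator reproduces a classic coalescent validation design with a
known truth:

| parameter | default | meaning |
| --- | --- | --- |
| `n_taxa` | 8 | leaves of the Yule species tree |
| `tree_depth` | 10^6 generations | root-to-tip depth after rescaling |
| `ne` | 10^5 | effective population size, **diploid individuals** |
| `alleles_per_taxon` | 2 | sampled gene copies per taxon |
| `merged_taxa_count` | 2 | taxa fused into the artificial polyploid |
| `loci_subset_sizes` | (20,) | loci sampled per reconstruction |
| `n_species_trees` × `replicates` | 3 × 3 | desk-scale grid |

Species trees are pure-birth (uniform speciation), simulated with
dendropy's general sampling approach so pendant edges are not truncated at
the n-th birth, then rescaled to the exact target depth.  Gene trees follow
the multispecies coalescent within the species tree; dendropy's `pop_size`
is the mean pairwise coalescent time, so `2·ne` is passed (rate 1/(2Ne) per
lineage pair per generation).  With depth 10 coalescent units of 2Ne, this
produces substantial but not saturating incomplete lineage sorting.

An allopolyploid with strictly disomic inheritance is then *constructed*,
not simulated: two (or three) taxa's alleles are relabeled as one accession
of ploidy 4 (or 6).  Gene trees are untouched, so the truth — which allele
came from which parent — is known exactly and retained on the accession
table.  Allele identifiers are locus-unique (`taxon_locus_index`): the
cross-locus phase of alleles is precisely what the search must infer, so
identifiers must not couple loci by construction.

Accuracy is measured two ways: (a) fraction of alleles assigned to their
true source taxon under the best subgenome relabeling; (b) normalized
Robinson–Foulds distance (unrooted splits over 2(n−3)) between the inferred
species tree and the truth, minimized over the k! subgenome-to-parent
mappings (2 for tetraploids, 6 for hexaploids).  RF is computed on
*unrooted* topologies: for fully resolved 8-leaf trees it then takes
exactly the six values {0, 0.2, 0.4, 0.6, 0.8, 1}, which the acceptance
suite verifies exhaustively.  A diploid-only baseline (MDC tree from the
same loci under the true taxon mapping) calibrates how much error is due to
the unknown subgenome memberships rather than to coalescent noise itself.

### What the simulations do and do not show

The generator emulates topological discordance from incomplete lineage
sorting only.  It does not model gene-tree estimation error (trees are
known, not inferred from sequences), recombination between subgenomes,
polysomic or mixed inheritance, gene flow after polyploidization, or
missing data.  Passing the validation therefore shows that the
search-plus-criterion machinery recovers subgenome memberships when its
model assumptions hold; it does not certify performance on real data where
those assumptions are violated.  On the desk-scale grid (9 replicates, one
random tetraploid merge per species tree), the residual assignment error is
dominated by constellations that merge closely related diploids, for which
the inferred partitions often score *better* (fewer extra lineages) than
the truth — an ambiguity of the parsimony criterion at high ILS, not an
optimization failure.

## Numerical and degenerate-input choices

- Branch lengths of input gene trees are parsed but ignored by scoring
  (the criterion is topology-only); leaf labels must be Newick-safe tokens.
- Trees whose root has degree ≥ 3 are rejected as unrooted rather than
  silently rooted; internal polytomies below the root are accepted.
- Taxon sets of size < 3 yield the trivial species tree with a logged
  warning; > 16 taxa exceed the subset-DP engine and raise an error.
- All randomness flows from explicit seeds (`random.Random`); results are
  bitwise reproducible across runs given identical inputs and seeds.
- Problem sizes in the test and acceptance runs (200-tree pools, 20-locus
  subsets, 3 × 3 validation grids, 10^4 RF pairs) are the package's
  desk-scale defaults; the full-scale study grid is reachable through
  `SimulationConfig`/YAML without code changes.
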