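"""Coalescent validation harness: known truth, synthetic allopolyploids.

The study design: simulate Yule (pure-birth) species trees scaled to a
fixed depth in generations; within each, simulate multispecies-coalescent
gene trees with two alleles per taxon; then *construct* an allopolyploid by
merging two or three diploid taxa into one artificial polyploid accession
(their alleles become the polyploid's alleles, which models strictly
disomic inheritance with no recombination between subgenomes).  The tabu
search must then rediscover, from the gene trees alone, which alleles came
from which ancestral diploid, and the inferred species tree is compared to
the true one by the normalized Robinson-Foulds distance with the best
subgenome-to-diploid mapping.

Population-size convention: ``ne`` is the number of diploid individuals;
two lineages coalesce at rate 1/(2 Ne) per generation, i.e. mean pairwise
coalescent time 2 Ne generations.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from dendropy.calculate import treecompare
from dendropy.simulate import treesim

from . import mdc
from .search import TabuParams, tabu_search, true_partition_of
from .treeio import AccessionRecord, AccessionTable, GeneTreeSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "simulate_gene_trees",
    "diploid_accession_table",
    "make_polyploid",
    "normalized_rf",
    "candidate_mappings",
    "best_mapping_rf",
    "partition_accuracy",
    "run_validation",
]


@dataclass
class SimulationConfig:
    """Study-design parameters (defaults: the validation conditions, with a
    desk-scale grid; the full design is reachable by widening the lists)."""

    n_taxa: int = 8
    tree_depth: float = 1e6  # generations, root to tip
    ne: float = 1e5  # effective population size (diploid individuals)
    alleles_per_taxon: int = 2
    n_gene_trees: int = 200  # simulated pool per species tree
    n_species_trees: int = 3
    merged_taxa_count: int = 2  # 2 = tetraploid, 3 = hexaploid
    loci_subset_sizes: tuple[int, ...] = (20,)
    replicates: int = 3
    rng_seed: int = 0
    polyploid_label: str = "POLY"
    tabu: TabuParams = field(default_factory=lambda: TabuParams(
        tabu_tenure=5, max_iterations=60, neighborhood_sample_size=30, restarts=1
    ))

    def validate(self) -> "SimulationConfig":
        if self.n_taxa < 3:
            raise ValidationError("need at least 3 taxa")
        if self.merged_taxa_count not in (2, 3):
            raise ValidationError("merged_taxa_count must be 2 or 3")
        for name in ("tree_depth", "ne", "alleles_per_taxon", "n_gene_trees",
                     "n_species_trees", "replicates"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        return self


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------


def simulate_yule_tree(n_taxa: int, depth: float, seed: int | random.Random) -> dendropy.Tree:
    """Ultrametric pure-birth tree rescaled to exactly ``depth`` root-to-tip.

    Uses the general sampling approach so pendant edges are not truncated
    at the n-th birth event.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        gsa_ntax=max(2 * n_taxa, n_taxa + 4),
        rng=rng,
    )
    cur = max(tree.calc_node_root_distances(return_leaf_distances_only=True))
    factor = depth / cur
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    tree.is_rooted = True
    return tree


def simulate_gene_trees(
    species_tree: dendropy.Tree,
    ne: float,
    n_trees: int,
    alleles_per_taxon: int = 2,
    seed: int | random.Random = 0,
) -> GeneTreeSet:
    """Multispecies-coalescent gene trees, one locus per tree.

    Leaf labels are ``{taxon}_{locus}_{i}``: allele identifiers are unique
    per locus because the phase of alleles across loci is exactly what the
    downstream search infers.  Branch lengths are in generations;
    coalescence within a species branch uses pop_size = 2*ne (mean pairwise
    coalescent time 2 Ne generations).
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    gene_to_species = dendropy.TaxonNamespaceMapping.create_contained_taxon_mapping(
        species_tree.taxon_namespace,
        alleles_per_taxon,
        contained_taxon_label_fn=lambda taxon, i: f"{taxon.label}__{i}",
    )
    loci = []
    trees_by_locus: dict[str, list[dendropy.Tree]] = {}
    for t in range(n_trees):
        locus = f"L{t + 1}"
        gtree = treesim.contained_coalescent_tree(
            containing_tree=species_tree,
            gene_to_containing_taxon_map=gene_to_species,
            default_pop_size=2 * ne,
            rng=rng,
        )
        # detach from the shared namespace and make allele ids locus-unique
        tns = dendropy.TaxonNamespace()
        for leaf in gtree.leaf_node_iter():
            taxon_label, idx = leaf.taxon.label.rsplit("__", 1)
            leaf.taxon = tns.require_taxon(label=f"{taxon_label}_{locus}_{idx}")
        gtree.taxon_namespace = tns
        gtree.is_rooted = True
        loci.append(locus)
        trees_by_locus[locus] = [gtree]
    return GeneTreeSet(loci=loci, trees_by_locus=trees_by_locus).validate()


def diploid_accession_table(
    species_tree: dendropy.Tree, gts: GeneTreeSet
) -> AccessionTable:
    """One diploid accession per taxon, alleles parsed from gene-tree labels."""
    taxa = sorted(t.label for t in species_tree.taxon_namespace)
    records = {t: AccessionRecord(f"{t}_acc", t, 2) for t in taxa}
    for locus in gts.loci:
        for label in sorted(gts.leaf_labels(locus)):
            taxon = _source_taxon(label)
            if taxon not in records:
                raise ValidationError(f"allele {label!r} names unknown taxon {taxon!r}")
            records[taxon].alleles.setdefault(locus, []).append(label)
    return AccessionTable(records=[records[t] for t in taxa]).validate()


def _source_taxon(allele_label: str) -> str:
    return allele_label.split("_", 1)[0]


def make_polyploid(
    gts: GeneTreeSet,
    tab: AccessionTable,
    merged_taxa: list[str],
    polyploid_label: str = "POLY",
) -> tuple[GeneTreeSet, AccessionTable]:
    """Merge diploid taxa into one artificial polyploid accession.

    Gene trees are untouched; only the accession table changes.  The true
    allele -> source-taxon assignment is kept on the returned table
    (``tab.truth``) as simulation ground truth.
    """
    if len(set(merged_taxa)) != len(merged_taxa):
        raise ValidationError("merged taxa must be distinct")
    for t in merged_taxa:
        if t not in tab.taxa:
            raise ValidationError(f"merged taxon {t!r} not in table")
        if t == polyploid_label:
            raise ValidationError("polyploid label collides with a merged taxon")
    merged = set(merged_taxa)
    poly = AccessionRecord(f"{polyploid_label}_acc", polyploid_label, 2 * len(merged_taxa))
    truth: dict[str, str] = {}
    records = []
    for rec in tab.records:
        if rec.taxon_id in merged:
            for locus, alleles in rec.alleles.items():
                poly.alleles.setdefault(locus, []).extend(alleles)
                for a in alleles:
                    truth[a] = rec.taxon_id
        else:
            records.append(rec)
    records.append(poly)
    return gts, AccessionTable(records=records, truth=truth).validate()


# ---------------------------------------------------------------------------
# Robinson-Foulds evaluation
# ---------------------------------------------------------------------------


def _as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def normalized_rf(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> float:
    """Unrooted RF split distance divided by its maximum 2(n-3)."""
    la = {(l.taxon.label if l.taxon else l.label) for l in tree_a.leaf_node_iter()}
    lb = {(l.taxon.label if l.taxon else l.label) for l in tree_b.leaf_node_iter()}
    if la != lb:
        raise ValidationError("trees have different leaf sets")
    n = len(la)
    if n < 4:
        raise ValidationError("normalized RF needs at least 4 leaves")
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=_as_newick(tree_a) + "\n", schema="newick",
                           taxon_namespace=tns, rooting="force-unrooted",
                           preserve_underscores=True)
    tb = dendropy.Tree.get(data=_as_newick(tree_b) + "\n", schema="newick",
                           taxon_namespace=tns, rooting="force-unrooted",
                           preserve_underscores=True)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return treecompare.symmetric_difference(ta, tb) / (2 * (n - 3))


def candidate_mappings(k: int, merged_taxa: list[str]) -> list[dict[str, str]]:
    """All k! bijections pseudo-taxon Pj -> merged diploid taxon."""
    if len(merged_taxa) != k:
        raise ValidationError("number of merged taxa must equal k")
    return [
        {f"P{j + 1}": taxon for j, taxon in enumerate(perm)}
        for perm in itertools.permutations(merged_taxa)
    ]


def best_mapping_rf(
    inferred_tree: dendropy.Tree,
    true_tree: dendropy.Tree,
    merged_taxa: list[str],
) -> float:
    """Minimum normalized RF over all subgenome-to-diploid label mappings."""
    labels = {(l.taxon.label if l.taxon else l.label)
              for l in inferred_tree.leaf_node_iter()}
    pseudo = sorted(
        (l for l in labels if l.startswith("P") and l[1:].isdigit()),
        key=lambda l: int(l[1:]),
    )
    k = len(merged_taxa)
    if len(pseudo) != k:
        raise ValidationError(
            f"inferred tree has {len(pseudo)} pseudo-taxa, expected {k}"
        )
    best = float("inf")
    newick = _as_newick(inferred_tree)
    for mapping in candidate_mappings(k, merged_taxa):
        tns = dendropy.TaxonNamespace()
        relabeled = dendropy.Tree.get(data=newick + "\n", schema="newick",
                                      taxon_namespace=tns, rooting="force-rooted",
                                      preserve_underscores=True)
        for leaf in relabeled.leaf_node_iter():
            lbl = leaf.taxon.label
            if lbl in mapping:
                leaf.taxon.label = mapping[lbl]
        best = min(best, normalized_rf(relabeled, true_tree))
    return best


def partition_accuracy(partition, truth: dict[str, str]) -> float:
    """Fraction of alleles assigned to their true source, best subgenome relabel."""
    sources = sorted(set(truth.values()))
    alleles = list(partition.assignment)
    best = 0
    for perm in itertools.permutations(sources):
        sg_to_src = {j + 1: src for j, src in enumerate(perm)}
        hits = sum(
            1 for a in alleles if sg_to_src.get(partition.assignment[a]) == truth[a]
        )
        best = max(best, hits)
    return best / len(alleles)


# ---------------------------------------------------------------------------
# Full validation loop
# ---------------------------------------------------------------------------


def run_validation(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, phase, and evaluate; returns (records, summary) frames.

    Per species tree: one random merged-taxon combination; per replicate and
    loci-subset size: an independent sample of loci, a tabu-search
    reconstruction evaluated by best-mapping RF and allele assignment
    accuracy, and the diploid-only MDC baseline on the same loci.
    """
    config.validate()
    master = random.Random(config.rng_seed)
    rows = []
    failures = 0
    for st_id in range(config.n_species_trees):
        sp_seed = master.randrange(2**31)
        sp_tree = simulate_yule_tree(config.n_taxa, config.tree_depth, sp_seed)
        gts_all = simulate_gene_trees(
            sp_tree, config.ne, config.n_gene_trees,
            config.alleles_per_taxon, master.randrange(2**31),
        )
        taxa = sorted(t.label for t in sp_tree.taxon_namespace)
        merged = master.sample(taxa, config.merged_taxa_count)
        tab_dip = diploid_accession_table(sp_tree, gts_all)
        _, tab_poly = make_polyploid(gts_all, tab_dip, merged, config.polyploid_label)

        for n_loci in config.loci_subset_sizes:
            for rep in range(config.replicates):
                rep_seed = master.randrange(2**31)
                rng = random.Random(rep_seed)
                loci = rng.sample(gts_all.loci, min(n_loci, len(gts_all.loci)))
                sub = GeneTreeSet(
                    loci=sorted(loci, key=gts_all.loci.index),
                    trees_by_locus={l: gts_all.trees_by_locus[l] for l in loci},
                )
                tab_dip_sub = _restrict_table(tab_dip, set(loci))
                tab_poly_sub = _restrict_table(tab_poly, set(loci))
                try:
                    row = _one_replicate(
                        sp_tree, sub, tab_dip_sub, tab_poly_sub, merged,
                        config, rep_seed,
                    )
                except Exception:
                    logger.exception(
                        "replicate failed (tree %d, %d loci, rep %d); skipping",
                        st_id, n_loci, rep,
                    )
                    failures += 1
                    continue
                row.update(
                    species_tree=st_id, merged="+".join(sorted(merged)),
                    n_loci=len(loci), replicate=rep, seed=rep_seed,
                )
                rows.append(row)
    if failures:
        logger.warning("%d replicate(s) failed and were skipped", failures)
    records = pd.DataFrame(rows)
    summary = (
        records.groupby(["merged_count", "n_loci"])[
            ["rf_polyploid", "rf_diploid", "accuracy"]
        ].mean().reset_index()
        if len(records)
        else pd.DataFrame()
    )
    return records, summary


def _restrict_table(tab: AccessionTable, loci: set[str]) -> AccessionTable:
    """Accession table restricted to a locus subset (truth filtered too)."""
    records = [
        AccessionRecord(
            r.accession_id, r.taxon_id, r.ploidy,
            {l: list(a) for l, a in r.alleles.items() if l in loci},
        )
        for r in tab.records
    ]
    kept = {a for r in records for al in r.alleles.values() for a in al}
    truth = (
        {a: s for a, s in tab.truth.items() if a in kept}
        if tab.truth is not None else None
    )
    return AccessionTable(records=records, truth=truth).validate()


def _one_replicate(sp_tree, sub, tab_dip, tab_poly, merged, config, rep_seed):
    # diploid-only baseline: MDC species tree from the true taxon mapping
    dip_mapping = {
        a: t for a, t in tab_dip.taxon_of_allele().items()
        if a in sub.allele_universe
    }
    dip_tree, dip_score = mdc.infer_mdc_tree(sub, dip_mapping)
    rf_dip = normalized_rf(dip_tree, sp_tree)

    # polyploid reconstruction via tabu search
    params = replace(config.tabu, rng_seed=rep_seed)
    result = tabu_search(sub, tab_poly, config.polyploid_label, params)
    truth = {a: s for a, s in tab_poly.truth.items() if a in sub.allele_universe}
    acc = partition_accuracy(result.best_partition, truth)

    # compare against the truth restricted to the remaining diploids + poly
    merged_set = set(merged)
    true_sub = dendropy.Tree.get(
        data=_as_newick(sp_tree) + "\n", schema="newick", rooting="force-rooted",
        preserve_underscores=True,
    )
    rf_poly = best_mapping_rf(result.best_tree, true_sub, sorted(merged_set))

    return dict(
        merged_count=len(merged),
        rf_polyploid=rf_poly,
        rf_diploid=rf_dip,
        accuracy=acc,
        mdc_score=result.best_score.total,
        mdc_score_diploid=dip_score.total,
        n_evaluations=result.n_evaluations,
    )
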