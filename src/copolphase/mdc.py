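"""Minimizing-deep-coalescences (MDC) scoring and species-tree inference.

A rooted gene tree embedded in a rooted species tree requires, on each
species-tree branch, at least one gene lineage exiting towards the root;
every lineage beyond the first is an *extra lineage* (one unit of
deep-coalescence cost).  For the branch above a species-tree node with taxon
cluster B, the minimal number of exiting lineages equals the number of
*maximal* gene-tree clades whose leaves all map into B (Maddison's
parsimony formulation).  The MDC species tree minimizes the summed cost
over all gene trees.

Because the cost of a branch depends only on its cluster B, the optimal
rooted binary species tree is a minimum-weight clade tree and can be found
exactly by dynamic programming over taxon subsets, which is what
:func:`infer_mdc_tree` does ("exhaustive" mode: all subsets are allowed, so
the optimum over *all* rooted binary topologies is returned; "clusters"
mode: only clusters observed in the gene trees, plus singletons, are
allowed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import TYPE_CHECKING, Iterable, Mapping

import dendropy
import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .treeio import GeneTreeSet

logger = logging.getLogger(__name__)

__all__ = [
    "MdcScore",
    "MdcError",
    "count_extra_lineages",
    "total_score",
    "infer_mdc_tree",
]

LeafMapping = Mapping[str, str]

_INF = float("inf")


class MdcError(ValueError):
    pass


@dataclass
class MdcScore:
    """Total extra-lineage count with a per-tree breakdown."""

    total: int
    per_tree: list[tuple[str, int, int]]  # (locus, tree index, extra lineages)

    def __int__(self) -> int:
        return self.total


# ---------------------------------------------------------------------------
# Indexed gene trees (flat arrays for fast repeated scoring)
# ---------------------------------------------------------------------------


class IndexedTree:
    """Flat postorder representation of a rooted (possibly multifurcating) tree.

    ``parents[i]`` is the postorder index of node i's parent (root: -1);
    leaves carry their label.  Built once per dendropy tree and cached, so
    that rescoring under many leaf mappings only recomputes bitmasks.
    """

    __slots__ = ("leaf_labels", "leaf_pos", "parents", "n_nodes")

    def __init__(self, tree: dendropy.Tree):
        order: list = []
        index: dict = {}
        for node in tree.postorder_node_iter():
            index[node] = len(order)
            order.append(node)
        self.n_nodes = len(order)
        self.parents = np.full(self.n_nodes, -1, dtype=np.int64)
        for node in order:
            for child in node.child_nodes():
                self.parents[index[child]] = index[node]
        self.leaf_labels: list[str] = []
        leaf_pos: list[int] = []
        for node in order:
            if not node.child_nodes():
                taxon = node.taxon
                label = taxon.label if taxon is not None else node.label
                if label is None:
                    raise MdcError("gene tree contains an unlabeled leaf")
                self.leaf_labels.append(label)
                leaf_pos.append(index[node])
        self.leaf_pos = np.asarray(leaf_pos, dtype=np.int64)

    def node_masks(self, leaf_bits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Taxon bitmask per node plus per-node parent mask (root: all ones).

        ``leaf_bits[i]`` is the bit of the taxon that leaf i maps to.
        """
        masks = np.zeros(self.n_nodes, dtype=np.int64)
        masks[self.leaf_pos] = leaf_bits
        parents = self.parents
        for i in range(self.n_nodes - 1):  # postorder, root last
            masks[parents[i]] |= masks[i]
        parent_masks = np.full(self.n_nodes, -1, dtype=np.int64)
        has_parent = parents >= 0
        parent_masks[has_parent] = masks[parents[has_parent]]
        return masks, parent_masks


def _indexed(tree: dendropy.Tree) -> IndexedTree:
    cached = getattr(tree, "_copolphase_indexed", None)
    if cached is None:
        cached = IndexedTree(tree)
        tree._copolphase_indexed = cached
    return cached


def _leaf_bits(idx: IndexedTree, mapping: LeafMapping, taxon_index: dict[str, int]) -> np.ndarray:
    bits = np.empty(len(idx.leaf_labels), dtype=np.int64)
    for i, label in enumerate(idx.leaf_labels):
        try:
            taxon = mapping[label]
        except KeyError:
            raise MdcError(f"gene-tree leaf {label!r} has no taxon mapping")
        try:
            bits[i] = 1 << taxon_index[taxon]
        except KeyError:
            raise MdcError(f"taxon {taxon!r} is absent from the species tree")
    return bits


def _lineages_per_cluster(
    masks: np.ndarray, parent_masks: np.ndarray, clusters: np.ndarray
) -> np.ndarray:
    """Number of maximal gene clades inside each cluster bitmask (vectorized)."""
    inv = ~clusters
    inside = (masks[None, :] & inv[:, None]) == 0
    parent_inside = (parent_masks[None, :] & inv[:, None]) == 0
    return (inside & ~parent_inside).sum(axis=1)


# ---------------------------------------------------------------------------
# Scoring against a given species tree
# ---------------------------------------------------------------------------


def _species_clusters(
    species_tree: dendropy.Tree, taxon_index: dict[str, int]
) -> np.ndarray:
    """Bitmask of every non-root cluster (leaf and internal branches)."""
    clusters = []
    masks: dict = {}
    for node in species_tree.postorder_node_iter():
        if not node.child_nodes():
            label = node.taxon.label if node.taxon is not None else node.label
            if label not in taxon_index:
                raise MdcError(f"species-tree leaf {label!r} not in taxon set")
            masks[node] = 1 << taxon_index[label]
        else:
            masks[node] = 0
            for child in node.child_nodes():
                masks[node] |= masks[child]
        if node.parent_node is not None:
            clusters.append(masks[node])
    return np.asarray(clusters, dtype=np.int64)


def count_extra_lineages(
    gene_tree: dendropy.Tree, species_tree: dendropy.Tree, mapping: LeafMapping
) -> int:
    """Minimum number of extra lineages needed to embed one gene tree.

    Sums, over every non-root species-tree branch with cluster B,
    ``max(0, k_B - 1)`` where k_B is the number of maximal gene-tree clades
    whose leaves all map into B.  Equals the minimum over all coalescent
    embeddings of the (rooted) gene tree into the (rooted) species tree.
    """
    sp_labels = sorted(
        (n.taxon.label if n.taxon is not None else n.label)
        for n in species_tree.leaf_node_iter()
    )
    if len(sp_labels) != len(set(sp_labels)):
        raise MdcError("species tree has duplicate leaf labels")
    taxon_index = {t: i for i, t in enumerate(sp_labels)}
    idx = _indexed(gene_tree)
    bits = _leaf_bits(idx, mapping, taxon_index)
    masks, parent_masks = idx.node_masks(bits)
    clusters = _species_clusters(species_tree, taxon_index)
    k = _lineages_per_cluster(masks, parent_masks, clusters)
    return int(np.maximum(k - 1, 0).sum())


def total_score(
    gts: "GeneTreeSet", species_tree: dendropy.Tree, mapping: LeafMapping
) -> MdcScore:
    """Sum of extra lineages over ALL trees of all loci (no averaging)."""
    per_tree = []
    total = 0
    for locus, i, tree in gts.iter_trees():
        xl = count_extra_lineages(tree, species_tree, mapping)
        per_tree.append((locus, i, xl))
        total += xl
    return MdcScore(total=total, per_tree=per_tree)


# ---------------------------------------------------------------------------
# MDC species-tree inference (subset dynamic programming)
# ---------------------------------------------------------------------------


def _cluster_weights(
    gts: "GeneTreeSet", mapping: LeafMapping, taxon_index: dict[str, int]
) -> tuple[np.ndarray, set[int]]:
    """w[B] = summed extra lineages contributed by cluster B over all trees.

    Also returns the union of gene-tree-induced cluster masks (for
    "clusters" mode).
    """
    n = len(taxon_index)
    subsets = np.arange(1, 1 << n, dtype=np.int64)
    w = np.zeros(len(subsets), dtype=np.int64)
    observed: set[int] = set()
    for _, _, tree in gts.iter_trees():
        idx = _indexed(tree)
        bits = _leaf_bits(idx, mapping, taxon_index)
        masks, parent_masks = idx.node_masks(bits)
        k = _lineages_per_cluster(masks, parent_masks, subsets)
        w += np.maximum(k - 1, 0)
        observed.update(int(m) for m in masks)
    return w, observed


def min_partition_score(gts: "GeneTreeSet", mapping: LeafMapping) -> int:
    """Optimal MDC score over all rooted binary species trees (score only).

    Fast path used inside the tabu search, where only the objective value of
    a candidate allele partition is needed.
    """
    taxa = sorted(set(mapping.values()))
    taxon_index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    if n > 16:
        raise MdcError(f"{n} taxa exceed the subset-DP limit of 16")
    w, _ = _cluster_weights(gts, mapping, taxon_index)
    if n < 2:
        return int(w.sum())
    full = (1 << n) - 1
    g = _subset_dp(w, n, None)
    return int(g[full])


def _subset_dp(w: np.ndarray, n: int, allowed: set[int] | None) -> dict[int, float]:
    """g[S] = min total cluster weight strictly inside a subtree on S.

    w is indexed by mask-1.  ``allowed`` restricts usable sub-clusters
    (singletons are always allowed); None means unrestricted.
    """
    full = (1 << n) - 1
    g: dict[int, float] = {}
    by_size: list[list[int]] = [[] for _ in range(n + 1)]
    for s in range(1, full + 1):
        by_size[bin(s).count("1")].append(s)
    for s in by_size[1]:
        g[s] = 0.0
    for size in range(2, n + 1):
        for s in by_size[size]:
            low = s & (-s)
            best = _INF
            # submasks containing the lowest bit (each split visited once)
            t = (s - 1) & s
            while t:
                if t & low:
                    u = s ^ t
                    if allowed is None or (
                        (t in allowed or bin(t).count("1") == 1)
                        and (u in allowed or bin(u).count("1") == 1)
                    ):
                        cand = g[t] + g[u] + w[t - 1] + w[u - 1]
                        if cand < best:
                            best = cand
                t = (t - 1) & s
            g[s] = best
    return g


def _reconstruct(
    w: np.ndarray, g: dict[int, float], s: int, taxa: list[str], allowed: set[int] | None
) -> str:
    """Deterministic optimal subtree (ties -> lexicographically smallest Newick)."""

    @lru_cache(maxsize=None)
    def build(mask: int) -> str:
        if bin(mask).count("1") == 1:
            return taxa[mask.bit_length() - 1]
        low = mask & (-mask)
        best: str | None = None
        t = (mask - 1) & mask
        while t:
            if t & low:
                u = mask ^ t
                ok = allowed is None or (
                    (t in allowed or bin(t).count("1") == 1)
                    and (u in allowed or bin(u).count("1") == 1)
                )
                if ok and g[t] + g[u] + w[t - 1] + w[u - 1] == g[mask]:
                    a, b = build(t), build(u)
                    cand = f"({min(a, b)},{max(a, b)})"
                    if best is None or cand < best:
                        best = cand
            t = (t - 1) & mask
        assert best is not None
        return best

    return build(s)


def infer_mdc_tree(
    gts: "GeneTreeSet",
    mapping: LeafMapping,
    mode: str = "exhaustive",
) -> tuple[dendropy.Tree, MdcScore]:
    """Infer the MDC-optimal rooted binary species tree.

    "exhaustive": exact optimum over all rooted binary topologies on the
    taxon set (subset dynamic program; requires <= 16 taxa).  "clusters":
    the species tree may only use clusters induced by the gene trees (plus
    singletons); falls back to exhaustive with a warning if no tree can be
    assembled.  Ties are broken deterministically towards the
    lexicographically smallest sorted-Newick string.
    """
    if mode not in ("exhaustive", "clusters"):
        raise MdcError(f"unknown mode {mode!r}")
    taxa = sorted(set(mapping.values()))
    n = len(taxa)
    if n > 16:
        raise MdcError(f"{n} taxa exceed the subset-DP limit of 16")
    taxon_index = {t: i for i, t in enumerate(taxa)}
    w, observed = _cluster_weights(gts, mapping, taxon_index)

    if n < 3:
        logger.warning("taxon set of size %d: returning the trivial tree", n)
        newick = taxa[0] if n == 1 else f"({taxa[0]},{taxa[1]})"
        tree = dendropy.Tree.get(
        data=newick + ";",
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
    )
        score = total_score(gts, tree, mapping)
        return tree, score

    allowed = None
    if mode == "clusters":
        full = (1 << n) - 1
        allowed = {m for m in observed if 0 < m <= full}
        allowed.add(full)

    full = (1 << n) - 1
    g = _subset_dp(w, n, allowed)
    if g[full] == _INF:
        logger.warning(
            "clusters mode: gene-tree clusters cannot assemble a full tree; "
            "falling back to exhaustive search"
        )
        allowed = None
        g = _subset_dp(w, n, None)
    newick = _reconstruct(w, g, full, taxa, allowed)
    tree = dendropy.Tree.get(
        data=newick + ";",
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
    )
    score = total_score(gts, tree, mapping)
    assert score.total == int(g[full]), "DP score and rescoring disagree"
    return tree, score
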