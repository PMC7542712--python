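"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: extra lineages are
minimized by enumerating explicit coalescent embeddings (every gene-tree
coalescence assigned to a species-tree branch), and optimal species trees
by literally enumerating all rooted binary topologies.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np


def _parse(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick if newick.endswith(";") else newick + ";",
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
    )


def _label(node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


class _Idx:
    """Simple parent/ancestor bookkeeping for one rooted tree."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.postorder_node_iter())
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.parent = [
            self.index[n.parent_node] if n.parent_node is not None else -1
            for n in self.nodes
        ]
        self.is_leaf = [not n.child_nodes() for n in self.nodes]
        self.label = [_label(n) for n in self.nodes]
        self.children = [
            [self.index[c] for c in n.child_nodes()] for n in self.nodes
        ]
        self.root = self.index[tree.seed_node]
        # ancestors-or-self, as sets of indices
        self.anc: list[set[int]] = [set() for _ in self.nodes]
        for i in range(len(self.nodes) - 1, -1, -1):  # root first in reverse
            p = self.parent[i]
            self.anc[i] = {i} | (self.anc[p] if p >= 0 else set())

    def lca(self, idxs):
        common = None
        for i in idxs:
            common = self.anc[i] if common is None else common & self.anc[i]
        # deepest common ancestor = the one with largest ancestor set
        return max(common, key=lambda j: len(self.anc[j]))


def brute_force_extra_lineages(gene_newick: str, species_newick: str,
                               mapping: dict[str, str]) -> int:
    """Minimum extra lineages over all explicit coalescent embeddings."""
    gt = _Idx(_parse(gene_newick))
    st = _Idx(_parse(species_newick))
    sp_leaf = {st.label[i]: i for i in range(len(st.nodes)) if st.is_leaf[i]}

    # fixed placements for gene leaves; candidates for internal nodes
    place: dict[int, int] = {}
    leaves_below: list[list[int]] = [[] for _ in gt.nodes]
    for i, node in enumerate(gt.nodes):
        if gt.is_leaf[i]:
            place[i] = sp_leaf[mapping[gt.label[i]]]
            leaves_below[i] = [i]
        else:
            for c in gt.children[i]:
                leaves_below[i].extend(leaves_below[c])
    lca_of = {
        i: st.lca([place[l] for l in leaves_below[i]])
        for i in range(len(gt.nodes))
        if not gt.is_leaf[i]
    }
    # reverse postorder = parents before children, so each internal node
    # sees its parent's placement when enumerating its own candidates
    internals = [i for i in reversed(range(len(gt.nodes))) if not gt.is_leaf[i]]

    best = [np.inf]

    def cost(assign: dict[int, int]) -> int:
        lineages = [0] * len(st.nodes)
        for g in range(len(gt.nodes)):
            top = assign[gt.parent[g]] if gt.parent[g] >= 0 else None
            v = assign[g]
            while v != top:
                lineages[v] += 1
                if v == st.root:
                    break
                v = st.parent[v]
        return sum(max(0, lineages[v] - 1) for v in range(len(st.nodes))
                   if v != st.root)

    def rec(pos: int, assign: dict[int, int]) -> None:
        if pos == len(internals):
            best[0] = min(best[0], cost(assign))
            return
        g = internals[pos]
        pg = gt.parent[g]
        allowed = st.anc[lca_of[g]]
        if pg >= 0:
            allowed = allowed & ({assign[pg]} | _desc_or_self(st, assign[pg]))
        for v in sorted(allowed):
            assign[g] = v
            rec(pos + 1, assign)
            del assign[g]

    rec(0, dict(place))
    return int(best[0])


def _desc_or_self(st: _Idx, v: int) -> set[int]:
    return {i for i in range(len(st.nodes)) if v in st.anc[i]}


def all_rooted_topologies(labels) -> list[str]:
    """Every rooted binary topology on ``labels`` as a canonical Newick string."""
    labels = sorted(labels)

    def build(subset: tuple[str, ...]) -> list[str]:
        if len(subset) == 1:
            return [subset[0]]
        first, rest = subset[0], subset[1:]
        out = []
        for r in range(len(rest) + 1):
            for right in itertools.combinations(rest, r):
                left = (first,) + tuple(x for x in rest if x not in right)
                if not right:
                    continue
                for lt in build(left):
                    for rt in build(tuple(right)):
                        out.append(f"({min(lt, rt)},{max(lt, rt)})")
        return out

    return [s + ";" for s in build(tuple(labels))]


def naive_mean_entropy(matrices, perms) -> float:
    """Direct loop-based reimplementation of the alignment objective."""
    mats = []
    for m, perm in zip(matrices, perms):
        out = np.zeros_like(np.asarray(m, dtype=float))
        for j, pj in enumerate(perm):
            out[:, pj] = np.asarray(m)[:, j]
        mats.append(out)
    avg = sum(mats) / len(mats)
    total = 0.0
    for row in avg:
        h = 0.0
        for c in row:
            if c > 0:
                h -= c * np.log(c)
        total += h
    return total / avg.shape[0]
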