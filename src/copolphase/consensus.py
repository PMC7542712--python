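"""Combine replicate reconstructions across label-switched subgenomes.

Replicate runs of the tabu search return equivalent subgenomes under
arbitrary labels (P1 of one run may be P2 of another).  Each replicate's
hard partition is a binary membership matrix (rows: alleles, columns:
subgenomes).  If columns are aligned correctly across replicates, the
element-wise average of the matrices should be sharp: each row close to
one-hot.  Sharpness is quantified by the mean Shannon entropy over rows,
H_i = -sum_j c_ij ln c_ij (with 0 ln 0 = 0), of the averaged coefficients;
column alignment minimizes this mean entropy.  Aligned labels then make the
replicate species trees comparable, so a greedy consensus tree with clade
frequencies can summarize them.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .treeio import ValidationError

__all__ = [
    "ColumnAlignment",
    "partitions_to_matrices",
    "mean_entropy",
    "align_clusters",
    "relabel_trees",
    "greedy_consensus",
]


@dataclass
class ColumnAlignment:
    """One column permutation per replicate; ``perms[i][j]`` is the aligned
    column that replicate i's column j is sent to.  Replicate 0 is pinned to
    the identity (gauge fixing: a common permutation of all replicates
    leaves the objective unchanged)."""

    perms: list[tuple[int, ...]]
    mean_entropy: float


def _check_matrices(matrices: Sequence[np.ndarray]) -> tuple[int, int]:
    if len(matrices) == 0:
        raise ValidationError("no membership matrices given")
    shape = matrices[0].shape
    for m in matrices:
        if m.ndim != 2 or m.shape != shape:
            raise ValidationError("membership matrices have inconsistent shapes")
        if np.any(m.sum(axis=1) == 0):
            raise ValidationError("membership matrix has an all-zero row")
    return shape


def partitions_to_matrices(
    partitions: Sequence, allele_order: Sequence[str] | None = None
) -> tuple[list[np.ndarray], list[str]]:
    """Binary membership matrices for a list of AllelePartition objects."""
    if not partitions:
        raise ValidationError("no partitions given")
    ref = set(partitions[0].assignment)
    k = partitions[0].k
    for p in partitions[1:]:
        if set(p.assignment) != ref or p.k != k:
            raise ValidationError("partitions cover different alleles or k")
    order = list(allele_order) if allele_order is not None else sorted(ref)
    mats = []
    for p in partitions:
        m = np.zeros((len(order), k))
        for i, a in enumerate(order):
            m[i, p.assignment[a] - 1] = 1.0
        mats.append(m)
    return mats, order


def _apply_perm(m: np.ndarray, perm: Sequence[int]) -> np.ndarray:
    out = np.empty_like(m)
    out[:, list(perm)] = m
    return out


def _row_entropy(rows: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(rows > 0, rows * np.log(rows), 0.0)
    return -term.sum(axis=1)


def mean_entropy(
    matrices: Sequence[np.ndarray], alignment: ColumnAlignment | Sequence[Sequence[int]]
) -> float:
    """Mean Shannon entropy of the permutation-averaged coefficients."""
    _check_matrices(matrices)
    perms = alignment.perms if isinstance(alignment, ColumnAlignment) else alignment
    if len(perms) != len(matrices):
        raise ValidationError("one permutation per matrix required")
    avg = np.mean([_apply_perm(m, p) for m, p in zip(matrices, perms)], axis=0)
    return float(_row_entropy(avg).mean())


def align_clusters(
    matrices: Sequence[np.ndarray],
    restarts: int = 10,
    seed: int = 0,
    mode: str = "iterative",
) -> ColumnAlignment:
    """Find column permutations minimizing the mean row entropy.

    "exact" enumerates all (C!)^(K-1) alignments (replicate 0 fixed to the
    identity); "iterative" (default) cycles over replicates, re-optimizing
    one permutation at a time over all C! options until no improvement,
    with random restarts.  Ties break towards the lexicographically
    smallest permutation tuple, so results are deterministic given seed.
    """
    n_rows, c = _check_matrices(matrices)
    k = len(matrices)
    if k < 2:
        raise ValidationError("need at least two replicates to align")
    all_perms = list(itertools.permutations(range(c)))
    identity = tuple(range(c))
    mats = [np.asarray(m, dtype=float) for m in matrices]

    def obj(perms: list[tuple[int, ...]]) -> float:
        avg = np.mean([_apply_perm(m, p) for m, p in zip(mats, perms)], axis=0)
        return float(_row_entropy(avg).mean())

    if mode == "exact":
        n_align = len(all_perms) ** (k - 1)
        if n_align > 500_000:
            raise ValidationError(
                f"exact alignment over {n_align} permutation tuples is infeasible; "
                "use iterative mode"
            )
        best: tuple[float, tuple] | None = None
        for rest in itertools.product(all_perms, repeat=k - 1):
            perms = [identity, *rest]
            cand = (obj(perms), tuple(perms))
            if best is None or cand < best:
                best = cand
        return ColumnAlignment(perms=list(best[1]), mean_entropy=best[0])

    if mode != "iterative":
        raise ValidationError(f"unknown mode {mode!r}")

    rng = random.Random(seed)
    best: tuple[float, tuple] | None = None
    for r in range(restarts):
        if r == 0:
            perms = [identity] * k
        else:
            perms = [identity] + [
                all_perms[rng.randrange(len(all_perms))] for _ in range(k - 1)
            ]
        cur = obj(perms)
        improved = True
        while improved:
            improved = False
            for i in range(1, k):
                local_best = (cur, perms[i])
                for p in all_perms:
                    if p == perms[i]:
                        continue
                    trial = list(perms)
                    trial[i] = p
                    cand = (obj(trial), p)
                    if cand < local_best:
                        local_best = cand
                if local_best < (cur, perms[i]):
                    cur, perms[i] = local_best
                    improved = True
        cand = (cur, tuple(perms))
        if best is None or cand < best:
            best = cand
    return ColumnAlignment(perms=list(best[1]), mean_entropy=best[0])


# ---------------------------------------------------------------------------
# Tree relabeling and consensus
# ---------------------------------------------------------------------------


def relabel_trees(
    trees: Sequence[dendropy.Tree], alignment: ColumnAlignment | Sequence[Sequence[int]]
) -> list[dendropy.Tree]:
    """Rename pseudo-taxon leaves P1..PC of tree i according to its permutation."""
    perms = alignment.perms if isinstance(alignment, ColumnAlignment) else alignment
    if len(perms) != len(trees):
        raise ValidationError("one permutation per tree required")
    out = []
    for tree, perm in zip(trees, perms):
        c = len(perm)
        clone = tree.clone(depth=1)
        clone.taxon_namespace = dendropy.TaxonNamespace()
        found = set()
        for leaf in clone.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else leaf.label
            new_label = label
            if label and label.startswith("P") and label[1:].isdigit():
                j = int(label[1:]) - 1
                if 0 <= j < c:
                    found.add(j)
                    new_label = f"P{perm[j] + 1}"
            leaf.taxon = clone.taxon_namespace.require_taxon(label=new_label)
        if len(found) != c:
            missing = sorted(set(range(c)) - found)
            raise ValidationError(
                f"tree lacks pseudo-taxon leaf(s) P{[m + 1 for m in missing]}"
            )
        out.append(clone)
    return out


def greedy_consensus(
    trees: Sequence[dendropy.Tree], min_frequency: float = 0.0
) -> dendropy.Tree:
    """Greedy (majority-rule-extended) rooted consensus with clade frequencies.

    Clades are ranked by frequency and added in decreasing order whenever
    compatible (nested or disjoint) with those already accepted; clades with
    frequency below ``min_frequency`` are excluded when it is positive.
    Retained internal nodes are labeled with their clade frequency.
    """
    if not trees:
        raise ValidationError("empty tree list")
    leaf_sets = []
    clade_counts: dict[frozenset, int] = {}
    for tree in trees:
        labels = frozenset(
            (l.taxon.label if l.taxon is not None else l.label)
            for l in tree.leaf_node_iter()
        )
        leaf_sets.append(labels)
        seen: set[frozenset] = set()
        for node in tree.postorder_internal_node_iter():
            clade = frozenset(
                (l.taxon.label if l.taxon is not None else l.label)
                for l in node.leaf_iter()
            )
            if 1 < len(clade) < len(labels):
                seen.add(clade)
        for clade in seen:
            clade_counts[clade] = clade_counts.get(clade, 0) + 1
    if len(set(leaf_sets)) != 1:
        raise ValidationError("trees do not share a common leaf set")
    taxa = sorted(leaf_sets[0])
    n = len(trees)

    ranked = sorted(
        clade_counts.items(),
        key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0]))),
    )
    accepted: list[tuple[frozenset, float]] = []
    for clade, count in ranked:
        freq = count / n
        if min_frequency > 0 and freq < min_frequency:
            continue
        compatible = all(
            c.isdisjoint(clade) or c <= clade or clade <= c for c, _ in accepted
        )
        if compatible:
            accepted.append((clade, freq))

    # build the nested-clade tree
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    full = frozenset(taxa)
    nodes: dict[frozenset, dendropy.Node] = {full: tree.seed_node}
    freq_of: dict[frozenset, float] = {full: 1.0}
    for clade, freq in sorted(accepted, key=lambda cf: -len(cf[0])):
        parent = min(
            (c for c in nodes if clade < c), key=len
        )  # smallest enclosing accepted clade
        node = dendropy.Node()
        nodes[parent].add_child(node)
        nodes[clade] = node
        freq_of[clade] = freq
    for taxon in taxa:
        single = frozenset([taxon])
        parent = min((c for c in nodes if single < c), key=len)
        leaf = dendropy.Node()
        leaf.taxon = tns.require_taxon(label=taxon)
        nodes[parent].add_child(leaf)
    for clade, node in nodes.items():
        if clade != full and len(clade) > 1:
            node.label = f"{freq_of[clade]:g}"
    return tree
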