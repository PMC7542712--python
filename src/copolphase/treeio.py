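"""Input/output for gene trees, accession tables and membership matrices.

Gene trees are plain Newick, one tree per line, grouped into loci by a
``loci_spec`` (see :func:`parse_gene_trees`).  The accession table is a TSV
with one row per accession-locus pair::

    accession_id <TAB> taxon_id <TAB> ploidy <TAB> locus_id <TAB> a1,a2,...

Membership matrices are written in a CLUMPP-style "indfile" layout: one
whitespace-separated coefficient block per replicate, blocks separated by a
blank line, with a sidecar file recording the allele row order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "GeneTreeSet",
    "AccessionRecord",
    "AccessionTable",
    "TreeParseError",
    "ValidationError",
    "parse_gene_trees",
    "write_gene_trees",
    "parse_accession_table",
    "write_accession_table",
    "prune_nonfocal_polyploids",
    "write_indfile",
    "read_indfile",
]


class TreeParseError(ValueError):
    """Malformed Newick input (carries the offending line number)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label is not None:
            labels.append(leaf.taxon.label)
        elif leaf.label is not None:
            labels.append(leaf.label)
        else:
            raise ValidationError("gene tree contains an unlabeled leaf")
    return labels


@dataclass
class GeneTreeSet:
    """Rooted allele-labeled gene trees grouped by locus.

    Invariants (checked by :meth:`validate`): every tree is rooted with a
    bifurcating root, all trees of one locus share the same leaf-label set,
    and no label occurs twice within a tree.
    """

    loci: list[str]
    trees_by_locus: dict[str, list[dendropy.Tree]]

    @property
    def allele_universe(self) -> set[str]:
        out: set[str] = set()
        for trees in self.trees_by_locus.values():
            if trees:
                out.update(_leaf_labels(trees[0]))
        return out

    @property
    def n_trees(self) -> int:
        return sum(len(t) for t in self.trees_by_locus.values())

    def iter_trees(self) -> Iterable[tuple[str, int, dendropy.Tree]]:
        for locus in self.loci:
            for i, tree in enumerate(self.trees_by_locus[locus]):
                yield locus, i, tree

    def leaf_labels(self, locus: str) -> set[str]:
        return set(_leaf_labels(self.trees_by_locus[locus][0]))

    def validate(self) -> "GeneTreeSet":
        if set(self.loci) != set(self.trees_by_locus):
            raise ValidationError("loci list and trees_by_locus keys differ")
        for locus in self.loci:
            trees = self.trees_by_locus[locus]
            if not trees:
                raise ValidationError(f"locus {locus!r} has no trees")
            ref: set[str] | None = None
            for tree in trees:
                if len(tree.seed_node.child_nodes()) != 2:
                    raise ValidationError(
                        f"locus {locus!r}: tree root has degree != 2; "
                        "unrooted trees are rejected, not silently rooted"
                    )
                labels = _leaf_labels(tree)
                if len(labels) != len(set(labels)):
                    dup = sorted(l for l in set(labels) if labels.count(l) > 1)
                    raise ValidationError(
                        f"locus {locus!r}: duplicate leaf label(s) {dup}"
                    )
                if ref is None:
                    ref = set(labels)
                elif set(labels) != ref:
                    raise ValidationError(
                        f"locus {locus!r}: leaf sets differ between trees"
                    )
        return self


@dataclass
class AccessionRecord:
    accession_id: str
    taxon_id: str
    ploidy: int
    alleles: dict[str, list[str]] = field(default_factory=dict)  # locus -> alleles

    @property
    def is_polyploid(self) -> bool:
        return self.ploidy >= 4


@dataclass
class AccessionTable:
    """Allele -> accession -> taxon/ploidy mapping.

    ``truth`` optionally records a known allele -> source-taxon assignment
    (used by the simulator to keep ground truth next to the derived table).
    """

    records: list[AccessionRecord]
    truth: dict[str, str] | None = None

    def validate(self) -> "AccessionTable":
        seen_acc: set[str] = set()
        seen_alleles: dict[str, str] = {}
        for rec in self.records:
            if rec.accession_id in seen_acc:
                raise ValidationError(f"duplicate accession {rec.accession_id!r}")
            seen_acc.add(rec.accession_id)
            if rec.ploidy <= 0 or rec.ploidy % 2 != 0:
                raise ValidationError(
                    f"accession {rec.accession_id!r}: ploidy must be a positive "
                    f"even integer, got {rec.ploidy}"
                )
            for locus, alleles in rec.alleles.items():
                if len(alleles) > rec.ploidy:
                    raise ValidationError(
                        f"accession {rec.accession_id!r}, locus {locus!r}: "
                        f"{len(alleles)} alleles exceed ploidy {rec.ploidy}"
                    )
                if len(set(alleles)) != len(alleles):
                    raise ValidationError(
                        f"accession {rec.accession_id!r}, locus {locus!r}: "
                        "duplicate allele in list"
                    )
                for a in alleles:
                    if a in seen_alleles:
                        raise ValidationError(
                            f"allele {a!r} listed for both "
                            f"{seen_alleles[a]!r} and {rec.accession_id!r}"
                        )
                    seen_alleles[a] = rec.accession_id
        return self

    # -- convenience lookups -------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.taxon_id not in out:
                out.append(rec.taxon_id)
        return out

    @property
    def polyploid_taxa(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.is_polyploid and rec.taxon_id not in out:
                out.append(rec.taxon_id)
        return out

    def accessions_of(self, taxon: str) -> list[AccessionRecord]:
        return [r for r in self.records if r.taxon_id == taxon]

    def taxon_of_allele(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for rec in self.records:
            for alleles in rec.alleles.values():
                for a in alleles:
                    out[a] = rec.taxon_id
        return out

    def alleles_of_taxon(self, taxon: str) -> set[str]:
        out: set[str] = set()
        for rec in self.accessions_of(taxon):
            for alleles in rec.alleles.values():
                out.update(alleles)
        return out

    def focal_groups(self, focal_taxon: str) -> list[tuple[str, str, list[str]]]:
        """(accession, locus, alleles) triples for one polyploid taxon.

        These are the capacity-constraint groups of the partition problem:
        within each group at most two alleles may share a subgenome.
        """
        groups = []
        for rec in self.accessions_of(focal_taxon):
            for locus in sorted(rec.alleles):
                if rec.alleles[locus]:
                    groups.append((rec.accession_id, locus, list(rec.alleles[locus])))
        if not groups:
            raise ValidationError(f"no alleles recorded for taxon {focal_taxon!r}")
        return groups


# ---------------------------------------------------------------------------
# Gene tree I/O
# ---------------------------------------------------------------------------

LociSpec = int | Sequence[tuple[str, int]] | Mapping[str, int] | None


def _resolve_loci_spec(loci_spec: LociSpec, n_lines: int) -> list[tuple[str, int]]:
    if loci_spec is None:
        return [(f"L{i + 1}", 1) for i in range(n_lines)]
    if isinstance(loci_spec, int):
        if loci_spec <= 0 or n_lines % loci_spec:
            raise ValidationError(
                f"{n_lines} trees cannot be split into loci of {loci_spec}"
            )
        return [(f"L{i + 1}", loci_spec) for i in range(n_lines // loci_spec)]
    if isinstance(loci_spec, Mapping):
        pairs = list(loci_spec.items())
    else:
        pairs = [tuple(p) for p in loci_spec]
    if sum(c for _, c in pairs) != n_lines:
        raise ValidationError(
            "loci_spec line counts do not sum to the number of input trees"
        )
    return pairs


def _parse_newick_line(line: str, lineno: int) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=line,
            schema="newick",
            rooting="default-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"line {lineno}: malformed Newick ({exc})") from exc
    return tree


def parse_gene_trees(path: str | Path, loci_spec: LociSpec = None) -> GeneTreeSet:
    """Read one-Newick-per-line gene trees and group them into loci.

    ``loci_spec`` may be an int (that many consecutive trees per locus,
    loci auto-named L1..Lk), an ordered mapping/sequence of
    ``(locus_id, n_trees)`` pairs, or None (each line its own locus).
    """
    lines = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.strip():
                lines.append((lineno, raw.strip()))
    if not lines:
        raise TreeParseError(f"{path}: no trees found")
    pairs = _resolve_loci_spec(loci_spec, len(lines))
    trees_by_locus: dict[str, list[dendropy.Tree]] = {}
    loci: list[str] = []
    it = iter(lines)
    for locus, count in pairs:
        loci.append(locus)
        trees_by_locus[locus] = [
            _parse_newick_line(line, lineno) for lineno, line in itertools.islice(it, count)
        ]
    return GeneTreeSet(loci=loci, trees_by_locus=trees_by_locus).validate()


def write_gene_trees(gts: GeneTreeSet, path: str | Path) -> list[tuple[str, int]]:
    """Write trees one per line (locus blocks in order); returns the loci_spec."""
    spec = []
    with open(path, "w") as fh:
        for locus in gts.loci:
            trees = gts.trees_by_locus[locus]
            spec.append((locus, len(trees)))
            for tree in trees:
                fh.write(
                    tree.as_string(
                        schema="newick",
                        suppress_rooting=True,
                        unquoted_underscores=True,
                    ).strip()
                    + "\n"
                )
    return spec


# ---------------------------------------------------------------------------
# Accession table I/O
# ---------------------------------------------------------------------------


def parse_accession_table(path: str | Path) -> AccessionTable:
    """Parse the TSV accession table (header line optional)."""
    recs: dict[str, AccessionRecord] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if lineno == 1 and fields[:2] == ["accession", "taxon"]:
                continue
            if len(fields) != 5:
                raise ValidationError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            acc, taxon, ploidy_s, locus, alleles_s = fields
            try:
                ploidy = int(ploidy_s)
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-integer ploidy {ploidy_s!r}")
            alleles = [a.strip() for a in alleles_s.split(",") if a.strip()]
            rec = recs.get(acc)
            if rec is None:
                rec = recs[acc] = AccessionRecord(acc, taxon, ploidy)
            else:
                if rec.taxon_id != taxon or rec.ploidy != ploidy:
                    raise ValidationError(
                        f"{path}:{lineno}: accession {acc!r} redefined with "
                        "different taxon or ploidy"
                    )
            if locus in rec.alleles:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate row for accession {acc!r}, "
                    f"locus {locus!r}"
                )
            rec.alleles[locus] = alleles
    return AccessionTable(records=list(recs.values())).validate()


def write_accession_table(tab: AccessionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\ttaxon\tploidy\tlocus\talleles\n")
        for rec in tab.records:
            for locus in sorted(rec.alleles):
                fh.write(
                    f"{rec.accession_id}\t{rec.taxon_id}\t{rec.ploidy}\t"
                    f"{locus}\t{','.join(rec.alleles[locus])}\n"
                )


# ---------------------------------------------------------------------------
# Pruning non-focal polyploids
# ---------------------------------------------------------------------------


def prune_nonfocal_polyploids(
    gts: GeneTreeSet, tab: AccessionTable, focal_taxon: str
) -> GeneTreeSet:
    """Drop leaves of every polyploid other than ``focal_taxon``.

    The analysis treats one polyploid at a time; other polyploids' alleles
    carry no usable signal and are removed from every gene tree.  Degree-2
    nodes created by the removal are suppressed; the root is retained.
    """
    if focal_taxon not in tab.taxa:
        raise ValidationError(f"unknown focal taxon {focal_taxon!r}")
    drop: set[str] = set()
    for rec in tab.records:
        if rec.is_polyploid and rec.taxon_id != focal_taxon:
            for alleles in rec.alleles.values():
                drop.update(alleles)
    if not drop:
        return gts
    out: dict[str, list[dendropy.Tree]] = {}
    for locus in gts.loci:
        pruned_trees = []
        for tree in gts.trees_by_locus[locus]:
            keep = [l for l in _leaf_labels(tree) if l not in drop]
            if len(keep) < 2:
                raise ValidationError(
                    f"locus {locus!r}: pruning non-focal polyploids leaves "
                    f"<2 leaves"
                )
            pruned = tree.extract_tree_with_taxa_labels(
                labels=keep, suppress_unifurcations=True
            )
            pruned_trees.append(pruned)
        out[locus] = pruned_trees
    return GeneTreeSet(loci=list(gts.loci), trees_by_locus=out).validate()


# ---------------------------------------------------------------------------
# CLUMPP-style indfiles
# ---------------------------------------------------------------------------


def write_indfile(
    partitions: Sequence["AllelePartition"],  # noqa: F821 (runtime duck-typed)
    path: str | Path,
    allele_order: Sequence[str] | None = None,
) -> list[str]:
    """Write binary membership blocks, one per partition.

    Every partition must cover the same allele set with the same number of
    subgenomes.  A sidecar ``<path>.alleles`` records the row order; the row
    order is identical across blocks.  Returns the allele order used.
    """
    if not partitions:
        raise ValidationError("no partitions to write")
    ref = set(partitions[0].assignment)
    k = partitions[0].k
    for p in partitions[1:]:
        if set(p.assignment) != ref or p.k != k:
            raise ValidationError("partitions cover different alleles or k")
    order = list(allele_order) if allele_order is not None else sorted(ref)
    if set(order) != ref:
        raise ValidationError("allele_order does not match partition alleles")
    path = Path(path)
    with open(path, "w") as fh:
        for i, p in enumerate(partitions):
            if i:
                fh.write("\n")
            for a in order:
                row = ["1" if p.assignment[a] == j + 1 else "0" for j in range(k)]
                fh.write(" ".join(row) + "\n")
    with open(path.with_suffix(path.suffix + ".alleles"), "w") as fh:
        fh.write("\n".join(order) + "\n")
    return order


def read_indfile(path: str | Path) -> tuple[list[np.ndarray], list[str]]:
    """Read coefficient blocks plus the sidecar allele order."""
    path = Path(path)
    blocks: list[list[list[float]]] = [[]]
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                if blocks[-1]:
                    blocks.append([])
                continue
            blocks[-1].append([float(x) for x in line.split()])
    if not blocks[-1]:
        blocks.pop()
    if not blocks:
        raise ValidationError(f"{path}: empty indfile")
    mats = [np.asarray(b, dtype=float) for b in blocks]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValidationError(f"{path}: blocks have inconsistent shapes")
    sidecar = path.with_suffix(path.suffix + ".alleles")
    if sidecar.exists():
        alleles = [l.strip() for l in open(sidecar) if l.strip()]
    else:
        alleles = [f"allele{i + 1}" for i in range(shape[0])]
    if len(alleles) != shape[0]:
        raise ValidationError(f"{sidecar}: allele count does not match rows")
    return mats, alleles
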