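"""Shared fixtures: tiny hand-built trees, tables, and random-tree helpers."""

from __future__ import annotations

import random

import dendropy
import pytest

from copolphase.treeio import AccessionRecord, AccessionTable, GeneTreeSet


def t(newick: str) -> dendropy.Tree:
    """Parse a rooted Newick string (underscores preserved)."""
    if not newick.endswith(";"):
        newick += ";"
    return dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted",
        preserve_underscores=True,
    )


def random_topology(labels, rng: random.Random) -> str:
    """Uniform-ish random rooted binary topology as a Newick string."""
    items = list(labels)
    rng.shuffle(items)
    while len(items) > 1:
        i, j = sorted(rng.sample(range(len(items)), 2))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b})")
    return items[0] + ";"


def gts_from_newicks(newicks_by_locus: dict[str, list[str]]) -> GeneTreeSet:
    return GeneTreeSet(
        loci=list(newicks_by_locus),
        trees_by_locus={
            locus: [t(nw) for nw in newicks]
            for locus, newicks in newicks_by_locus.items()
        },
    ).validate()


@pytest.fixture
def toy_table() -> AccessionTable:
    """Three diploids plus one tetraploid accession, two loci."""
    return AccessionTable(records=[
        AccessionRecord("accA", "A", 2, {"L1": ["a1", "a2"], "L2": ["a3", "a4"]}),
        AccessionRecord("accB", "B", 2, {"L1": ["b1", "b2"], "L2": ["b3", "b4"]}),
        AccessionRecord("accC", "C", 2, {"L1": ["c1", "c2"], "L2": ["c3", "c4"]}),
        AccessionRecord("accX", "X", 4, {"L1": ["x1", "x2", "x3", "x4"],
                                         "L2": ["x5", "x6", "x7", "x8"]}),
    ]).validate()


@pytest.fixture
def toy_gts() -> GeneTreeSet:
    """Two loci over the toy table's alleles; the tetraploid's alleles split
    cleanly into an A-like pair and a B-like pair at both loci."""
    return gts_from_newicks({
        "L1": ["((((a1,a2),(x1,x2)),((b1,b2),(x3,x4))),(c1,c2));"],
        "L2": ["((((a3,a4),(x5,x6)),((b3,b4),(x7,x8))),(c3,c4));"],
    })
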