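"""Tabu search over constrained allele partitions of one polyploid taxon.

The optimization variable is an assignment of every focal-polyploid allele
(at every locus) to one of k hypothetical diploid subgenomes P1..Pk, with
k <= ploidy/2.  Under the single-copy-locus assumption, for each focal
accession and locus at most two of its alleles may share a subgenome.  A
candidate partition is scored by the optimal MDC species tree over the
diploid taxa plus the pseudo-taxa P1..Pk; the search minimizes that score.

Tabu search keeps hill-climbing moves but forbids, for ``tabu_tenure``
iterations, re-placing an allele into the subgenome it just left (a swap
records both of its allele/source pairs), which lets the walk escape local
optima and plateaus.  A tabu move is still admissible if it would improve
the best score found so far (aspiration).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import dendropy

from . import mdc
from .treeio import AccessionTable, GeneTreeSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AllelePartition",
    "TabuParams",
    "SearchResult",
    "Move",
    "random_partition",
    "neighborhood",
    "apply_move",
    "score",
    "tabu_search",
    "true_partition_of",
]

CAPACITY = 2  # max alleles per accession-locus-subgenome (single-copy loci)


@dataclass
class AllelePartition:
    """Assignment of focal alleles to subgenome indices 1..k."""

    focal_taxon: str
    k: int
    assignment: dict[str, int]

    def canonical(self) -> tuple[tuple[str, int], ...]:
        """Label-symmetry-invariant key (subgenomes renamed by first use)."""
        relabel: dict[int, int] = {}
        out = []
        for allele in sorted(self.assignment):
            sg = self.assignment[allele]
            if sg not in relabel:
                relabel[sg] = len(relabel) + 1
            out.append((allele, relabel[sg]))
        return tuple(out)

    def copy(self) -> "AllelePartition":
        return AllelePartition(self.focal_taxon, self.k, dict(self.assignment))

    def validate(self, tab: AccessionTable) -> "AllelePartition":
        for acc, locus, alleles in tab.focal_groups(self.focal_taxon):
            counts: dict[int, int] = {}
            for a in alleles:
                if a not in self.assignment:
                    raise ValidationError(f"focal allele {a!r} unassigned")
                sg = self.assignment[a]
                if not 1 <= sg <= self.k:
                    raise ValidationError(f"allele {a!r}: subgenome {sg} out of range")
                counts[sg] = counts.get(sg, 0) + 1
                if counts[sg] > CAPACITY:
                    raise ValidationError(
                        f"accession {acc!r}, locus {locus!r}: more than "
                        f"{CAPACITY} alleles in subgenome {sg}"
                    )
        return self


@dataclass
class TabuParams:
    tabu_tenure: int = 5
    max_iterations: int = 100
    neighborhood_sample_size: int = 30
    restarts: int = 1
    rng_seed: int = 0

    def validate(self) -> "TabuParams":
        for name in ("tabu_tenure", "max_iterations", "neighborhood_sample_size", "restarts"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        return self


@dataclass
class SearchResult:
    best_partition: AllelePartition
    best_tree: dendropy.Tree
    best_score: mdc.MdcScore
    trace: list[tuple[int, int, int]]  # (iteration, current score, best score)
    params: TabuParams
    n_evaluations: int = 0

    @property
    def best_newick(self) -> str:
        return self.best_tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


@dataclass(frozen=True)
class Move:
    """SHIFT (allele -> other subgenome) or SWAP (two alleles exchange)."""

    kind: str  # "shift" | "swap"
    allele: str
    source: int
    target: int
    allele2: str | None = None  # swap partner (lives in ``target``)

    def attributes(self) -> tuple[tuple[str, int], ...]:
        """(allele, source-subgenome) pairs that become tabu when applied."""
        if self.kind == "shift":
            return ((self.allele, self.source),)
        return ((self.allele, self.source), (self.allele2, self.target))


# ---------------------------------------------------------------------------


def _focal_groups(tab: AccessionTable, focal_taxon: str):
    groups = tab.focal_groups(focal_taxon)
    recs = tab.accessions_of(focal_taxon)
    if not any(r.is_polyploid for r in recs):
        raise ValidationError(f"focal taxon {focal_taxon!r} is not a polyploid")
    return groups


def random_partition(
    tab: AccessionTable,
    focal_taxon: str,
    k: int,
    seed: int | random.Random = 0,
) -> AllelePartition:
    """Uniformly random capacity-valid partition.

    Sampling is uniform over all valid assignments of each accession-locus
    group (rejection sampling; worst-case acceptance ~1/8 for a saturated
    hexaploid locus), hence uniform over the full constrained space.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    groups = _focal_groups(tab, focal_taxon)
    max_half = max(r.ploidy for r in tab.accessions_of(focal_taxon)) // 2
    if k < 1 or k > max_half:
        raise ValidationError(f"k={k} out of range 1..{max_half}")
    assignment: dict[str, int] = {}
    for acc, locus, alleles in groups:
        if len(alleles) > CAPACITY * k:
            raise ValidationError(
                f"accession {acc!r}, locus {locus!r}: {len(alleles)} alleles "
                f"exceed {CAPACITY * k} subgenome slots"
            )
        while True:
            draw = [rng.randrange(k) + 1 for _ in alleles]
            if all(draw.count(sg) <= CAPACITY for sg in set(draw)):
                break
        assignment.update(zip(alleles, draw))
    return AllelePartition(focal_taxon, k, assignment).validate(tab)


def neighborhood(
    p: AllelePartition, groups: list[tuple[str, str, list[str]]]
) -> list[Move]:
    """All validity-preserving SHIFT and SWAP moves, deterministically ordered."""
    moves: list[Move] = []
    for _, _, alleles in groups:
        counts = {sg: 0 for sg in range(1, p.k + 1)}
        for a in alleles:
            counts[p.assignment[a]] += 1
        for a in alleles:
            src = p.assignment[a]
            for tgt in range(1, p.k + 1):
                if tgt != src and counts[tgt] < CAPACITY:
                    moves.append(Move("shift", a, src, tgt))
        for i, a in enumerate(alleles):
            for b in alleles[i + 1 :]:
                sa, sb = p.assignment[a], p.assignment[b]
                if sa != sb:
                    lo, hi = (a, b) if sa < sb else (b, a)
                    moves.append(
                        Move("swap", lo, min(sa, sb), max(sa, sb), allele2=hi)
                    )
    return moves


def apply_move(p: AllelePartition, move: Move) -> AllelePartition:
    q = p.copy()
    if move.kind == "shift":
        q.assignment[move.allele] = move.target
    else:
        q.assignment[move.allele] = move.target
        q.assignment[move.allele2] = move.source
    return q


def build_mapping(
    p: AllelePartition, tab: AccessionTable, gts: GeneTreeSet | None = None
) -> dict[str, str]:
    """Leaf mapping: diploid alleles -> their taxon, focal alleles -> P1..Pk."""
    mapping: dict[str, str] = {}
    for rec in tab.records:
        if rec.taxon_id == p.focal_taxon:
            continue
        if rec.is_polyploid:
            raise ValidationError(
                f"non-focal polyploid {rec.taxon_id!r} present; prune it first"
            )
        for alleles in rec.alleles.values():
            for a in alleles:
                mapping[a] = rec.taxon_id
    for a, sg in p.assignment.items():
        mapping[a] = f"P{sg}"
    if gts is not None:
        universe = gts.allele_universe
        missing = universe - mapping.keys()
        if missing:
            raise ValidationError(
                f"gene-tree alleles missing from table/partition: {sorted(missing)[:5]}"
            )
        mapping = {a: t for a, t in mapping.items() if a in universe}
    return mapping


def score(
    p: AllelePartition, gts: GeneTreeSet, tab: AccessionTable, mode: str = "exhaustive"
) -> tuple[dendropy.Tree, mdc.MdcScore]:
    """MDC-optimal species tree and score for one allele partition."""
    mapping = build_mapping(p, tab, gts)
    return mdc.infer_mdc_tree(gts, mapping, mode=mode)


class _Scorer:
    """Score-only evaluation with a cache keyed by canonical partition."""

    def __init__(self, gts: GeneTreeSet, tab: AccessionTable):
        self.gts = gts
        self.tab = tab
        self.cache: dict[tuple, int] = {}
        self.n_evaluations = 0

    def __call__(self, p: AllelePartition) -> int:
        key = p.canonical()
        val = self.cache.get(key)
        if val is None:
            mapping = build_mapping(p, self.tab, self.gts)
            val = mdc.min_partition_score(self.gts, mapping)
            self.cache[key] = val
            self.n_evaluations += 1
        return val


def tabu_search(
    gts: GeneTreeSet,
    tab: AccessionTable,
    focal_taxon: str,
    params: TabuParams | None = None,
    k: int | None = None,
    debug_validate: bool = False,
) -> SearchResult:
    """Minimize the MDC score over constrained allele partitions.

    Per iteration, up to ``neighborhood_sample_size`` candidate moves are
    sampled uniformly without replacement from the current neighborhood;
    tabu candidates are kept only if they beat the best-known score
    (aspiration).  The best admissible candidate is applied even if it
    worsens the current score; the best partition ever visited is returned.
    Fully reproducible given ``rng_seed``.
    """
    params = (params or TabuParams()).validate()
    rng = random.Random(params.rng_seed)
    groups = _focal_groups(tab, focal_taxon)
    if k is None:
        k = max(r.ploidy for r in tab.accessions_of(focal_taxon)) // 2
    scorer = _Scorer(gts, tab)

    best_p: AllelePartition | None = None
    best_s = float("inf")
    trace: list[tuple[int, int, int]] = []
    it_global = 0

    for restart in range(params.restarts):
        current = random_partition(tab, focal_taxon, k, rng)
        cur_s = scorer(current)
        if cur_s < best_s:
            best_p, best_s = current.copy(), cur_s
        tabu_until: dict[tuple[str, int], int] = {}
        trace.append((it_global, cur_s, int(best_s)))

        for _ in range(params.max_iterations):
            it_global += 1
            moves = neighborhood(current, groups)
            if not moves:
                break
            if len(moves) > params.neighborhood_sample_size:
                moves = rng.sample(moves, params.neighborhood_sample_size)
            chosen: Move | None = None
            chosen_s = float("inf")
            fallback: Move | None = None
            fallback_s = float("inf")
            for mv in moves:
                cand = apply_move(current, mv)
                if debug_validate:
                    cand.validate(tab)
                s = scorer(cand)
                # tabu if the move places an allele back where it recently was
                is_tabu = any(
                    tabu_until.get((a, tgt), -1) >= it_global
                    for (a, tgt) in _placements(mv)
                )
                if is_tabu and not s < best_s:  # aspiration: beat best-ever
                    if s < fallback_s:
                        fallback, fallback_s = mv, s
                    continue
                if s < chosen_s:
                    chosen, chosen_s = mv, s
            if chosen is None:
                # whole sample tabu without aspiration: take least-bad move
                chosen, chosen_s = fallback, fallback_s
                if chosen is None:
                    break
            for attr in chosen.attributes():
                tabu_until[attr] = it_global + params.tabu_tenure
            current = apply_move(current, chosen)
            cur_s = chosen_s
            if cur_s < best_s:
                best_p, best_s = current.copy(), cur_s
            trace.append((it_global, int(cur_s), int(best_s)))
        logger.info(
            "restart %d/%d: best score %s after %d evaluations",
            restart + 1,
            params.restarts,
            best_s,
            scorer.n_evaluations,
        )

    assert best_p is not None
    tree, full_score = score(best_p, gts, tab)
    assert full_score.total == best_s, "incremental and final scoring disagree"
    return SearchResult(
        best_partition=best_p,
        best_tree=tree,
        best_score=full_score,
        trace=trace,
        params=params,
        n_evaluations=scorer.n_evaluations,
    )


def _placements(move: Move) -> tuple[tuple[str, int], ...]:
    """(allele, destination) pairs a move performs (checked against tabu)."""
    if move.kind == "shift":
        return ((move.allele, move.target),)
    return ((move.allele, move.target), (move.allele2, move.source))


def true_partition_of(
    tab: AccessionTable, focal_taxon: str, k: int | None = None
) -> AllelePartition | None:
    """Ground-truth partition from a simulator-annotated table, if present."""
    if tab.truth is None:
        return None
    focal_alleles: set[str] = tab.alleles_of_taxon(focal_taxon)
    sources = sorted({tab.truth[a] for a in focal_alleles})
    if k is None:
        k = len(sources)
    sg_of = {src: i + 1 for i, src in enumerate(sources)}
    assignment = {a: sg_of[tab.truth[a]] for a in focal_alleles}
    return AllelePartition(focal_taxon, k, assignment)
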