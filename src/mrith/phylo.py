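"""Per-patient phylogenies from binary presence/absence matrices.

The tree relates a patient's sampled regions to a germline root (the
all-zero profile). With three or four regions the maximum-parsimony
topology is found by exhaustive search over all rooted multifurcating
shapes; branch lengths are mutation counts assigned per edge by
small-parsimony dynamic programming (Fitch/Hartigan on binary
characters, germline state fixed to 0). Among equally parsimonious
topologies the least resolved is preferred (unsupported internal edges
are not invented), then the lexicographically smallest canonical form.

Trunk mutations are those present in every region; mutation and CNV
timing follow the mutation-copy-number rules (early when the average
mutated copy number exceeds one; clonal losses coupled to genome
doubling are early).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Hashable, Sequence

import numpy as np

from .core_io import MutationCall, SegmentCN
from .cnv import WgdResult

logger = logging.getLogger("mrith")

__all__ = [
    "PresenceMatrix",
    "PhyloTree",
    "presence_matrix",
    "build_tree",
    "trunk_branch_partition",
    "time_snv",
    "time_cnv_gain",
    "time_cnv_loss",
]


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary mutation x region presence matrix for one patient."""

    keys: tuple  # mutation keys, one per row
    regions: tuple  # region ids, one per column (lexicographic)
    matrix: np.ndarray  # bool (n_mutations, n_regions)
    excluded_loh: tuple = ()  # mutation keys dropped for LOH overlap

    def __post_init__(self) -> None:
        if len(self.keys) != self.matrix.shape[0]:
            raise ValueError("row count mismatch")
        if len(self.regions) != self.matrix.shape[1]:
            raise ValueError("column count mismatch")
        if len(self.keys) and not self.matrix.any(axis=1).all():
            raise ValueError("every mutation must be present in >= 1 region")


# A topology is a nested structure: a leaf is a region id (str); an
# internal node is a tuple of child topologies, sorted by canonical form.
Topology = Hashable


def _canon(node: Topology) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(sorted(_canon(c) for c in node)) + ")"


def _n_internal(node: Topology) -> int:
    if isinstance(node, str):
        return 0
    return 1 + sum(_n_internal(c) for c in node)


def _partitions(items: tuple):
    """All set partitions of ``items`` into >= 1 blocks."""
    if len(items) == 1:
        yield [[items[0]]]
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


@lru_cache(maxsize=None)
def _topologies(regions: tuple) -> tuple:
    """All rooted multifurcating topologies with the given leaves."""
    if len(regions) == 1:
        return (regions[0],)
    out = []
    for part in _partitions(regions):
        if len(part) < 2:
            continue
        blocks = [tuple(sorted(b)) for b in part]
        choice_lists = [_topologies(b) for b in blocks]

        def expand(i, acc):
            if i == len(choice_lists):
                out.append(tuple(sorted(acc, key=_canon)))
                return
            for sub in choice_lists[i]:
                expand(i + 1, acc + [sub])

        expand(0, [])
    # deduplicate by canonical form
    seen, uniq = set(), []
    for t in out:
        c = _canon(t)
        if c not in seen:
            seen.add(c)
            uniq.append(t)
    return tuple(uniq)


def _score_pattern(topology: Topology, present: frozenset) -> tuple[int, str]:
    """Min state changes and the trunk-most gain edge for one pattern.

    Returns (parsimony score, canonical id of the child node of the
    edge on which the mutation is placed). The germline root above the
    topology is fixed at state 0; ties in the backtrack prefer state 1,
    pushing gains toward the trunk.
    """
    INF = 10**9

    def cost(node) -> tuple[int, int]:  # (cost state 0, cost state 1)
        if isinstance(node, str):
            p = 1 if node in present else 0
            return (0 if p == 0 else INF, 0 if p == 1 else INF)
        c0 = c1 = 0
        for ch in node:
            k0, k1 = cost(ch)
            c0 += min(k0, k1 + 1)
            c1 += min(k1, k0 + 1)
        return (c0, c1)

    memo: dict[int, tuple[int, int]] = {}

    def cost_m(node):
        key = id(node)
        if key not in memo:
            memo[key] = cost(node)
        return memo[key]

    # germline root (state 0) -> crown via the trunk edge
    k0, k1 = cost_m(topology)
    score = min(k0, k1 + 1)
    # top-down backtrack; BFS so the first gain edge found is trunk-most
    gain_edge = None
    queue: list[tuple[Topology, int]] = []
    crown_state = 1 if k1 + 1 <= k0 else 0  # tie prefers 1 (trunk-most gain)
    queue.append((topology, crown_state))
    if crown_state == 1:
        gain_edge = _canon(topology)
    parent_state = {id(topology): crown_state}
    while queue:
        node, s = queue.pop(0)
        if isinstance(node, str):
            continue
        for ch in sorted(node, key=_canon):
            k0, k1 = cost_m(ch)
            as0 = k0 + (1 if s != 0 else 0)
            as1 = k1 + (1 if s != 1 else 0)
            cs = 1 if as1 <= as0 else 0  # tie prefers 1
            if s == 0 and cs == 1 and gain_edge is None:
                gain_edge = _canon(ch)
            queue.append((ch, cs))
    if gain_edge is None:
        # pattern absent everywhere should not occur; guard anyway
        gain_edge = _canon(topology)
    return score, gain_edge


@dataclass
class PhyloTree:
    """A rooted region tree with mutation counts on edges.

    Edges are keyed by the canonical form of their child node; the trunk
    edge (germline -> MRCA of all regions) is keyed by the crown node.
    """

    topology: Topology
    regions: tuple
    branch_lengths: dict  # edge key -> mutation count
    edge_mutations: dict  # edge key -> list of mutation keys
    parsimony_score: int

    @property
    def trunk_key(self) -> str:
        return _canon(self.topology)

    @property
    def trunk_length(self) -> int:
        return self.branch_lengths.get(self.trunk_key, 0)

    @property
    def total_length(self) -> int:
        return sum(self.branch_lengths.values())

    def newick(self) -> str:
        def fmt(node) -> str:
            key = _canon(node)
            bl = self.branch_lengths.get(key, 0)
            if isinstance(node, str):
                return f"{node}:{bl}"
            inner = ",".join(fmt(c) for c in sorted(node, key=_canon))
            return f"({inner}):{bl}"

        return f"(germline:0,{fmt(self.topology)});"


def presence_matrix(
    calls: Sequence[MutationCall],
    segments: Sequence[SegmentCN] = (),
    regions: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Presence/absence matrix over the union of nonsilent mutations.

    Mutations overlapping an LOH segment (minor_cn = 0 with retained
    copy) in any region are flagged and excluded from tree building.
    Returns an empty matrix (tree skipped upstream) when no mutations
    remain.
    """
    if regions is None:
        regions = sorted({c.region_id for c in calls})
    regions = tuple(regions)
    loh_segs = [s for s in segments if s.is_loh]
    present: dict[tuple, set[str]] = {}
    order: list[tuple] = []
    excluded: list[tuple] = []
    seen_excl: set[tuple] = set()
    for c in calls:
        if c.effect != "nonsilent":
            continue
        if any(s.contains(c.chrom, c.pos) for s in loh_segs):
            if c.key not in seen_excl:
                seen_excl.add(c.key)
                excluded.append(c.key)
            continue
        if c.key not in present:
            present[c.key] = set()
            order.append(c.key)
        present[c.key].add(c.region_id)
    if not order:
        logger.warning("presence_matrix: no usable mutations; tree will be skipped")
    mat = np.zeros((len(order), len(regions)), dtype=bool)
    for i, k in enumerate(order):
        for j, r in enumerate(regions):
            mat[i, j] = r in present[k]
    return PresenceMatrix(
        keys=tuple(order), regions=regions, matrix=mat,
        excluded_loh=tuple(excluded),
    )


def build_tree(pm: PresenceMatrix, max_exhaustive: int = 5) -> PhyloTree:
    """Maximum-parsimony region tree from a presence matrix.

    Exhaustive over all rooted multifurcating topologies (exact for the
    <= 4-5 regions typical of multi-region designs). Equal scores prefer
    the least-resolved topology, then lexicographic canonical order.
    """
    regions = pm.regions
    if len(regions) > max_exhaustive:
        raise NotImplementedError(
            f"exhaustive search supports <= {max_exhaustive} regions"
        )
    patterns: dict[frozenset, int] = {}
    for row in pm.matrix:
        p = frozenset(r for r, b in zip(regions, row) if b)
        patterns[p] = patterns.get(p, 0) + 1

    best = None
    for topo in _topologies(tuple(sorted(regions))):
        if isinstance(topo, str):  # single region: leaf directly under root
            topo_struct: Topology = (topo,)
        else:
            topo_struct = topo
        score = sum(
            _score_pattern(topo_struct, p)[0] * n for p, n in patterns.items()
        )
        rank = (score, _n_internal(topo_struct), _canon(topo_struct))
        if best is None or rank < best[0]:
            best = (rank, topo_struct)
    _, topology = best

    branch_lengths: dict[str, int] = {}
    edge_mutations: dict[str, list] = {}
    pattern_edges = {p: _score_pattern(topology, p)[1] for p in patterns}
    total_score = 0
    for key, row in zip(pm.keys, pm.matrix):
        p = frozenset(r for r, b in zip(regions, row) if b)
        s, edge = _score_pattern(topology, p)
        total_score += s
        branch_lengths[edge] = branch_lengths.get(edge, 0) + 1
        edge_mutations.setdefault(edge, []).append(key)
    # make sure every edge of the chosen topology is reported (length 0 ok)
    def register(node):
        branch_lengths.setdefault(_canon(node), branch_lengths.get(_canon(node), 0))
        if not isinstance(node, str):
            for ch in node:
                register(ch)

    register(topology)
    return PhyloTree(
        topology=topology,
        regions=regions,
        branch_lengths=branch_lengths,
        edge_mutations=edge_mutations,
        parsimony_score=total_score,
    )


def trunk_branch_partition(pm: PresenceMatrix) -> dict[tuple, str]:
    """trunk iff present in every region, else branch."""
    out = {}
    for key, row in zip(pm.keys, pm.matrix):
        out[key] = "trunk" if row.all() else "branch"
    return out


def time_snv(mut_cn: float) -> str:
    """Early iff mutation copy number > 1 (late at the <= 1 boundary)."""
    return "early" if mut_cn > 1 else "late"


def time_cnv_gain(mut_cns_in_segment: Sequence[float], min_mutations: int = 5) -> str:
    """Time a gained segment by the mean mutation copy number inside it.

    Requires at least ``min_mutations`` mutations within the segment
    (returns "NA" otherwise); early iff the mean exceeds 1.
    """
    if len(mut_cns_in_segment) < min_mutations:
        return "NA"
    return "early" if float(np.mean(mut_cns_in_segment)) > 1 else "late"


def time_cnv_loss(clonality: str, wgd: WgdResult | bool | None) -> str:
    """Clonal losses coupled with genome doubling are early; others late."""
    is_wgd = wgd.is_wgd if isinstance(wgd, WgdResult) else bool(wgd)
    return "early" if (clonality == "clonal" and is_wgd) else "late"
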