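"""eBURST variant classification and goeBURST full minimum spanning trees.

STs are compared by Hamming distance over their allele profiles. Single- and
double-locus variant (SLV/DLV) counts drive both the clonal-complex partition
(connected components of the SLV graph; STs with no SLV partner are
singletons) and the goeBURST tiebreak order used when building the full MST
over the complete ST distance graph:

    lower profile distance, then higher SLV counts of the edge endpoints,
    then higher DLV counts, then higher ST frequency (isolate counts),
    then lower ST numbers.

Kruskal's algorithm over edges sorted by this key yields a deterministic
minimum spanning tree regardless of node input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
import pandas as pd

from .scheme_db import AlleleProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class STNode:
    st: int
    profile: AlleleProfile
    frequency: int = 1

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")


@dataclass(frozen=True)
class MSTEdge:
    st_a: int
    st_b: int
    distance: int


def profile_distance(p1: AlleleProfile, p2: AlleleProfile) -> int:
    """Hamming distance: number of loci at which two profiles differ."""
    d1, d2 = p1.as_dict(), p2.as_dict()
    if set(d1) != set(d2):
        raise ValueError("profiles cover different locus sets")
    return sum(1 for locus in d1 if d1[locus] != d2[locus])


def _check_distinct(nodes: Sequence[STNode]) -> None:
    sts = [n.st for n in nodes]
    if len(set(sts)) != len(sts):
        raise ValueError("duplicate ST numbers in node list")


def classify_variants(nodes: Sequence[STNode]) -> dict[int, dict[str, int]]:
    """Per-ST counts of single- and double-locus variants.

    Returns {st: {"slv": ..., "dlv": ...}} where slv/dlv are the numbers of
    other STs at profile distance exactly 1 and 2.
    """
    _check_distinct(nodes)
    counts = {n.st: {"slv": 0, "dlv": 0} for n in nodes}
    for a, b in combinations(nodes, 2):
        d = profile_distance(a.profile, b.profile)
        if d == 1:
            counts[a.st]["slv"] += 1
            counts[b.st]["slv"] += 1
        elif d == 2:
            counts[a.st]["dlv"] += 1
            counts[b.st]["dlv"] += 1
    return counts


def clonal_complexes(
    nodes: Sequence[STNode],
) -> tuple[list[set[int]], set[int]]:
    """Partition STs into clonal complexes and singletons.

    A clonal complex is a connected component (size ≥ 2) of the graph linking
    STs at profile distance 1; an ST with at least two allelic mismatches
    with all other STs is a singleton. Complexes are returned sorted by
    (-size, smallest member) for deterministic output.
    """
    _check_distinct(nodes)
    g = nx.Graph()
    g.add_nodes_from(n.st for n in nodes)
    for a, b in combinations(nodes, 2):
        if profile_distance(a.profile, b.profile) == 1:
            g.add_edge(a.st, b.st)
    complexes = []
    singletons = set()
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            complexes.append(set(comp))
        else:
            singletons.update(comp)
    complexes.sort(key=lambda c: (-len(c), min(c)))
    return complexes, singletons


def goeburst_mst(
    nodes: Sequence[STNode], max_level: int | None = None
) -> list[MSTEdge]:
    """Minimum spanning tree of the complete ST graph with goeBURST tiebreaks.

    Edge weight is the profile distance; ties are broken by (1) higher SLV
    counts of the endpoints, (2) higher DLV counts, (3) higher ST frequency,
    (4) lower ST number — each compared first on the better endpoint, then
    on the worse one. With ``max_level`` edges above that distance are
    dropped after tree construction, yielding a forest for display.
    """
    _check_distinct(nodes)
    if len(nodes) <= 1:
        return []
    variant_counts = classify_variants(nodes)
    freq = {n.st: n.frequency for n in nodes}

    def edge_key(a: STNode, b: STNode, dist: int):
        slv = sorted((variant_counts[a.st]["slv"], variant_counts[b.st]["slv"]), reverse=True)
        dlv = sorted((variant_counts[a.st]["dlv"], variant_counts[b.st]["dlv"]), reverse=True)
        fr = sorted((freq[a.st], freq[b.st]), reverse=True)
        st_pair = sorted((a.st, b.st))
        return (
            dist,
            -slv[0], -slv[1],
            -dlv[0], -dlv[1],
            -fr[0], -fr[1],
            st_pair[0], st_pair[1],
        )

    edges = []
    for a, b in combinations(sorted(nodes, key=lambda n: n.st), 2):
        dist = profile_distance(a.profile, b.profile)
        edges.append((edge_key(a, b, dist), min(a.st, b.st), max(a.st, b.st), dist))
    edges.sort(key=lambda e: e[0])

    parent = {n.st: n.st for n in nodes}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: list[MSTEdge] = []
    for _key, sa, sb, dist in edges:
        ra, rb = find(sa), find(sb)
        if ra == rb:
            continue
        parent[ra] = rb
        tree.append(MSTEdge(st_a=sa, st_b=sb, distance=dist))
        if len(tree) == len(nodes) - 1:
            break
    if max_level is not None:
        dropped = [e for e in tree if e.distance > max_level]
        if dropped:
            logger.info("goeburst_mst: dropped %d edge(s) above level %d", len(dropped), max_level)
        tree = [e for e in tree if e.distance <= max_level]
    return tree


def nodes_from_typing(
    profiles: dict[int, AlleleProfile], st_counts: dict[int, int]
) -> list[STNode]:
    """Build MST nodes from a set of observed STs and their isolate counts.

    Strains with undefined ST are expected to be excluded upstream (their
    profile distance is undefined).
    """
    return [
        STNode(st=st, profile=profiles[st], frequency=st_counts[st])
        for st in sorted(st_counts)
    ]


def mst_edge_frame(edges: Sequence[MSTEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"st_a": e.st_a, "st_b": e.st_b, "distance": e.distance} for e in edges],
        columns=["st_a", "st_b", "distance"],
    )


def mst_to_graph(nodes: Sequence[STNode], edges: Sequence[MSTEdge]) -> nx.Graph:
    """Export the MST as a networkx graph (for GraphML/GML writers)."""
    g = nx.Graph()
    for n in nodes:
        g.add_node(n.st, frequency=n.frequency)
    for e in edges:
        g.add_edge(e.st_a, e.st_b, distance=e.distance)
    return g
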