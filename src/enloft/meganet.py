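"""The integrated heterogeneous enhancer-gene network ("MegaNet").

Enhancer and gene nodes; directed enhancer->gene regulation edges weighted
by the number of tissues in which they are active; undirected gene-gene
interactions stored as two opposite directed edges so that degree counts
neighbors and path-based centralities treat them symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .genomic_io import DIRECT_INTERACTION_KINDS, RegulatoryEdge

REGULATION = "regulation"
INTERACTION = "interaction"


@dataclass
class MegaNet:
    """Wrapper around a directed networkx graph with typed nodes and edges."""

    graph: nx.DiGraph

    @property
    def enhancers(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "enhancer"]

    @property
    def genes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene"]

    @property
    def tissues(self) -> set[str]:
        out: set[str] = set()
        for _, _, d in self.graph.edges(data=True):
            if d["kind"] == REGULATION:
                out.update(d["tissues"])
        return out

    def regulation_edges(self) -> list[tuple[str, str, frozenset[str]]]:
        return [
            (u, v, d["tissues"])
            for u, v, d in self.graph.edges(data=True)
            if d["kind"] == REGULATION
        ]

    def n_interaction_pairs(self) -> int:
        n = sum(1 for _, _, d in self.graph.edges(data=True) if d["kind"] == INTERACTION)
        assert n % 2 == 0, "interaction edges must come in opposite-direction pairs"
        return n // 2

    def targets_of(self, enhancer_id: str) -> list[str]:
        return [
            v
            for _, v, d in self.graph.out_edges(enhancer_id, data=True)
            if d["kind"] == REGULATION
        ]

    def regulators_of(self, gene_id: str) -> list[str]:
        return [
            u
            for u, _, d in self.graph.in_edges(gene_id, data=True)
            if d["kind"] == REGULATION
        ]


@dataclass
class TissueSubnetwork:
    tissue: str
    parent: MegaNet
    graph: nx.DiGraph


def build_meganet(
    reg_edges: Sequence[RegulatoryEdge],
    interactions: Iterable[tuple[str, str, str]] = (),
) -> MegaNet:
    """Assemble the MegaNet from regulation edges and direct gene interactions.

    Duplicate regulation rows for the same (enhancer, gene) pair collapse
    into a single edge with the union of their tissue sets ("without
    replica"). Each undirected gene-gene interaction is added twice in
    opposite directions; repeated pairs collapse with their kinds unioned.
    Interaction kinds outside the direct whitelist, self-interactions, or a
    gene id colliding with an enhancer id are errors.
    """
    g = nx.DiGraph()
    merged: dict[tuple[str, str], set[str]] = {}
    for e in reg_edges:
        if not e.tissues:
            raise ValueError(f"regulation edge {e.enhancer_id}->{e.gene_id} has no tissue")
        merged.setdefault((e.enhancer_id, e.gene_id), set()).update(e.tissues)
    enhancer_ids = {eid for eid, _ in merged}
    for (eid, gid), tissues in merged.items():
        if gid in enhancer_ids:
            raise ValueError(f"id {gid!r} used both as enhancer and gene")
        g.add_node(eid, kind="enhancer")
        g.add_node(gid, kind="gene")
        fs = frozenset(tissues)
        g.add_edge(eid, gid, kind=REGULATION, tissues=fs, weight=len(fs))

    pair_kinds: dict[tuple[str, str], set[str]] = {}
    for g1, g2, kind in interactions:
        if kind not in DIRECT_INTERACTION_KINDS:
            raise ValueError(
                f"interaction kind {kind!r} is not a direct kind "
                f"({sorted(DIRECT_INTERACTION_KINDS)})"
            )
        if g1 == g2:
            raise ValueError(f"self-interaction on {g1!r}")
        if g1 in enhancer_ids or g2 in enhancer_ids:
            raise ValueError("interaction touches an enhancer id; node types disjoint")
        key = (min(g1, g2), max(g1, g2))
        pair_kinds.setdefault(key, set()).add(kind)
    for (g1, g2), kinds in pair_kinds.items():
        for node in (g1, g2):
            if node not in g:
                g.add_node(node, kind="gene")
        fs = frozenset(kinds)
        g.add_edge(g1, g2, kind=INTERACTION, itypes=fs, weight=1)
        g.add_edge(g2, g1, kind=INTERACTION, itypes=fs, weight=1)
    return MegaNet(graph=g)


def extract_tissue_subnetwork(net: MegaNet, tissue: str) -> TissueSubnetwork:
    """Regulation edges active in *tissue* plus all genes and interactions.

    Enhancers left without an active edge are dropped; gene nodes and
    interaction edges are always retained.
    """
    valid = net.tissues
    if tissue not in valid:
        raise ValueError(f"unknown tissue {tissue!r}; valid: {sorted(valid)}")
    sub = nx.DiGraph()
    for n, d in net.graph.nodes(data=True):
        if d["kind"] == "gene":
            sub.add_node(n, **d)
    for u, v, d in net.graph.edges(data=True):
        if d["kind"] == INTERACTION:
            sub.add_edge(u, v, **d)
        elif tissue in d["tissues"]:
            sub.add_node(u, kind="enhancer")
            sub.add_edge(u, v, **d)
    return TissueSubnetwork(tissue=tissue, parent=net, graph=sub)


def neighborhood(net: MegaNet, node_id: str, kind: str | None = None) -> set[str]:
    """Distinct adjacent nodes of *node_id*, optionally filtered by edge kind."""
    if node_id not in net.graph:
        raise KeyError(f"node {node_id!r} not in MegaNet")
    out: set[str] = set()
    for _, v, d in net.graph.out_edges(node_id, data=True):
        if kind is None or d["kind"] == kind:
            out.add(v)
    for u, _, d in net.graph.in_edges(node_id, data=True):
        if kind is None or d["kind"] == kind:
            out.add(u)
    return out
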