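"""Per-enhancer feature vocabulary and design-matrix assembly.

The vocabulary follows the network-feature table of the scoring model:

* enhancer features: EOD (out-degree = genes regulated), ETU (distinct
  tissues the enhancer is active in), per-tissue EOD blocks;
* edge features: EGTUa / EGTUv, the mean and population variance of the
  per-edge tissue counts (e_1..e_n over the n regulated genes);
* gene features aggregated over the enhancer's target genes as mean ("a")
  and population variance ("v"): in-degree GID, closeness GCC, degree
  fraction GDC, PageRank GPRC, eigenvector GEC, indispensability GIS, plus
  per-tissue GIDa blocks from each tissue subnetwork;
* sequence conservation in [0, 1].

All "v" aggregates use population variance (denominator n): an enhancer
with a single target has variance 0, not missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .meganet import REGULATION, MegaNet, TissueSubnetwork

PAGERANK_DAMPING = 0.85

BASE_COLUMNS = [
    "EOD", "ETU", "EGTUa", "EGTUv",
    "GIDa", "GIDv", "GCCa", "GCCv", "GDCa", "GDCv",
    "GPRCa", "GPRCv", "GECa", "GECv", "GISa", "GISv",
    "conservation",
]


def compute_edge_ubiquity_stats(values: Sequence[int]) -> tuple[float, float]:
    """Mean (EGTUa) and population variance (EGTUv) of per-edge tissue counts.

    For the edge list (2, 1): EGTUa = 1.5 and EGTUv = 0.25.
    """
    if len(values) == 0:
        raise ValueError("enhancer with no regulation edges is not a valid node")
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, var


def _population_stats(values: Sequence[float]) -> tuple[float, float]:
    vals = [v for v in values if not (isinstance(v, float) and math.isnan(v))]
    if not vals:
        return float("nan"), float("nan")
    n = len(vals)
    mean = sum(vals) / n
    return mean, sum((v - mean) ** 2 for v in vals) / n


@dataclass
class FeatureMatrix:
    """Design matrix (rows = enhancers) plus a provenance record of edits."""

    data: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    @property
    def enhancer_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


def _incoming_closeness(graph: nx.DiGraph, nodes: Sequence[str]) -> dict[str, float]:
    """Closeness centrality over incoming shortest paths, reach-normalized.

    c(u) = ((r-1)/(N-1)) * ((r-1) / sum of distances) where r counts the
    nodes that can reach u; on a 3-node path the middle node scores 1.0 and
    the ends 2/3.
    """
    rev = graph.reverse(copy=False)
    n_total = graph.number_of_nodes()
    out = {}
    for u in nodes:
        dist = nx.single_source_shortest_path_length(rev, u)
        r = len(dist)  # includes u itself at distance 0
        total = sum(dist.values())
        if r <= 1 or total == 0 or n_total <= 1:
            out[u] = 0.0
        else:
            out[u] = ((r - 1) / (n_total - 1)) * ((r - 1) / total)
    return out


def _degree_fraction(graph: nx.DiGraph, nodes: Sequence[str]) -> dict[str, float]:
    """Fraction of the other nodes a gene touches (distinct neighbors)."""
    n_total = graph.number_of_nodes()
    out = {}
    for u in nodes:
        neigh = set(graph.successors(u)) | set(graph.predecessors(u))
        neigh.discard(u)
        out[u] = len(neigh) / (n_total - 1) if n_total > 1 else 0.0
    return out


def _pagerank(graph: nx.DiGraph) -> dict[str, float]:
    """PageRank with damping 0.85, iterated well below feature tolerance."""
    return nx.pagerank(graph, alpha=PAGERANK_DAMPING, weight=None,
                       tol=1e-12, max_iter=1000)


def _eigenvector(graph: nx.DiGraph) -> dict[str, float]:
    """Eigenvector centrality on the undirected view (symmetrized edges).

    Deterministic by construction: dense symmetric eigendecomposition for
    small graphs, Lanczos with a fixed start vector otherwise (a random
    start would make repeated runs differ at machine precision).
    """
    und = graph.to_undirected()
    nodes = list(und)
    n = len(nodes)
    if n == 0:
        return {}
    A = nx.to_scipy_sparse_array(und, nodelist=nodes, weight=None, dtype=float)
    try:
        if n < 50:
            _, vecs = np.linalg.eigh(A.toarray())
            vec = vecs[:, -1]
        else:
            from scipy.sparse.linalg import eigsh

            _, vecs = eigsh(A, k=1, which="LA", v0=np.full(n, 1.0 / n))
            vec = vecs[:, 0]
    except Exception as exc:
        raise RuntimeError(
            "eigenvector centrality failed to converge; check graph "
            "connectivity or adjust solver tolerance"
        ) from exc
    if vec[int(np.argmax(np.abs(vec)))] < 0:
        vec = -vec
    vec = vec / np.linalg.norm(vec)
    return dict(zip(nodes, (float(x) for x in vec)))


def compute_enhancer_features(
    net: MegaNet,
    subnetworks: Sequence[TissueSubnetwork] = (),
    gis: Mapping[str, float] | None = None,
    conservation: Mapping[str, float] | None = None,
) -> FeatureMatrix:
    """Compute the unpruned feature matrix for every enhancer in the MegaNet.

    Centralities are computed on the full heterogeneous graph (enhancer and
    gene nodes together): PageRank with damping 0.85 on the directed graph,
    eigenvector centrality on the undirected view (regulation edges
    symmetrized for this metric only, which guarantees convergence),
    closeness over incoming paths. Gene-level quantities are aggregated per
    enhancer over its targets with mean and population variance.
    """
    gis = gis or {}
    conservation = conservation or {}
    graph = net.graph
    genes = net.genes
    enhancers = net.enhancers

    closeness = _incoming_closeness(graph, genes)
    degree_frac = _degree_fraction(graph, genes)
    pagerank = _pagerank(graph)
    eig = _eigenvector(graph)
    gid = {g: len(net.regulators_of(g)) for g in genes}

    sub_eod: dict[str, dict[str, int]] = {}
    sub_gid: dict[str, dict[str, int]] = {}
    for sub in subnetworks:
        t = sub.tissue
        eod_t: dict[str, int] = {}
        gid_t: dict[str, int] = {}
        for u, v, d in sub.graph.edges(data=True):
            if d["kind"] == REGULATION:
                eod_t[u] = eod_t.get(u, 0) + 1
                gid_t[v] = gid_t.get(v, 0) + 1
        sub_eod[t] = eod_t
        sub_gid[t] = gid_t

    tissue_cols = []
    for sub in subnetworks:
        tissue_cols += [f"{sub.tissue}__EOD", f"{sub.tissue}__GIDa"]
    tissue_cols.sort()

    rows = []
    for eid in enhancers:
        targets = net.targets_of(eid)
        edge_tissue_counts = [
            len(graph.edges[eid, g]["tissues"]) for g in targets
        ]
        etu = len(frozenset().union(*(graph.edges[eid, g]["tissues"] for g in targets)))
        egtua, egtuv = compute_edge_ubiquity_stats(edge_tissue_counts)
        row: dict[str, float] = {
            "EOD": float(len(targets)),
            "ETU": float(etu),
            "EGTUa": egtua,
            "EGTUv": egtuv,
        }
        for prefix, table in [
            ("GID", gid), ("GCC", closeness), ("GDC", degree_frac),
            ("GPRC", pagerank), ("GEC", eig),
        ]:
            mean, var = _population_stats([table[g] for g in targets])
            row[f"{prefix}a"], row[f"{prefix}v"] = mean, var
        mean, var = _population_stats(
            [gis.get(g, float("nan")) for g in targets]
        )
        row["GISa"], row["GISv"] = mean, var
        row["conservation"] = conservation.get(eid, float("nan"))
        for sub in subnetworks:
            t = sub.tissue
            row[f"{t}__EOD"] = float(sub_eod[t].get(eid, 0))
            mean, _ = _population_stats([float(sub_gid[t].get(g, 0)) for g in targets])
            row[f"{t}__GIDa"] = mean
        rows.append(row)

    df = pd.DataFrame(rows, index=enhancers, columns=BASE_COLUMNS + tissue_cols)
    df.index.name = "enhancer_id"
    return FeatureMatrix(data=df)


def prune_correlated_features(
    m: FeatureMatrix,
    threshold: float = 0.9,
    drop_list: Sequence[str] = (),
) -> FeatureMatrix:
    """Greedy Spearman-correlation pruning of redundant columns.

    Explicitly listed columns are dropped first. Remaining column pairs are
    visited in alphabetical order and whenever |rho| >= threshold the
    later-named column is dropped. Every drop is recorded in provenance.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if m.data.shape[1] < 2:
        raise ValueError("need at least two feature columns to prune")
    provenance = list(m.provenance)
    df = m.data.copy()
    for col in drop_list:
        if col in df.columns:
            df = df.drop(columns=[col])
            provenance.append({"action": "drop", "column": col, "reason": "drop_list"})
    cols = sorted(df.columns)
    ranked = df[cols].rank()
    corr = ranked.corr(method="pearson")  # Pearson of ranks == Spearman rho
    dropped: set[str] = set()
    for i, ci in enumerate(cols):
        if ci in dropped:
            continue
        for cj in cols[i + 1:]:
            if cj in dropped:
                continue
            rho = corr.loc[ci, cj]
            if pd.isna(rho):
                continue  # constant column: undefined rank correlation
            if abs(rho) >= threshold:
                dropped.add(cj)
                provenance.append(
                    {"action": "drop", "column": cj, "reason": f"|rho|={abs(rho):.4f} with {ci}"}
                )
    kept = [c for c in m.data.columns if c not in dropped and c not in set(drop_list)]
    return FeatureMatrix(data=m.data[kept], provenance=provenance)


def impute_missing(
    m: FeatureMatrix,
    policy: str = "median",
    labeled_ids: Sequence[str] = (),
) -> FeatureMatrix:
    """Resolve missing entries by column median, zero fill, or row dropping."""
    provenance = list(m.provenance)
    df = m.data.copy()
    if policy in ("median", "zero"):
        for col in df.columns:
            mask = df[col].isna()
            if not mask.any():
                continue
            if mask.all():
                raise ValueError(f"column {col!r} is entirely missing")
            fill = df[col].median() if policy == "median" else 0.0
            df.loc[mask, col] = fill
            provenance.append(
                {"action": "impute", "column": col, "policy": policy,
                 "n_cells": int(mask.sum()), "fill": float(fill)}
            )
    elif policy == "drop-row":
        bad = df.index[df.isna().any(axis=1)]
        lost = sorted(set(bad) & set(labeled_ids))
        if lost:
            import logging

            logging.getLogger(__name__).warning(
                "drop-row imputation removes labeled enhancers: %s", lost
            )
        df = df.drop(index=bad)
        provenance.append(
            {"action": "drop_rows", "policy": policy, "n_rows": len(bad),
             "labeled_removed": lost}
        )
    else:
        raise ValueError(f"unknown imputation policy {policy!r}")
    assert not df.isna().any().any()
    return FeatureMatrix(data=df, provenance=provenance)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Convenience wrapper used by provenance reporting and tests."""
    rho, _ = stats.spearmanr(np.asarray(x), np.asarray(y))
    return float(rho)
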