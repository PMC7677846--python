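"""Co-switching network reconstruction from binarized expression.

Pairwise mutual information between switching genes' binary profiles
(over pseudotime-ordered cells) is thresholded and pruned with the ARACNE
data-processing-inequality rule: in every fully connected triangle the
weakest edge is removed as likely indirect (up to a tolerance).  Remaining
edges are directed by switch time — the tail gene switched earlier than
the head gene — unless the two switch within ``gap`` cells of each other,
in which case the edge stays undirected ("grey").  Connector genes are
non-pathway switching genes closest (by mean variation of information) to
a pathway gene set; they interconnect the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .pseudotime import vi_distance

__all__ = [
    "mi_matrix",
    "select_connectors",
    "mi_threshold",
    "aracne_dpi",
    "direct_edges",
    "SwitchNetwork",
    "build_network",
]


def mi_matrix(binary: pd.DataFrame) -> pd.DataFrame:
    """Genes x genes empirical mutual information over cells (nats).

    The diagonal holds each gene's marginal entropy (MI of a variable with
    itself); constant genes have MI 0 with everything.
    """
    B = binary.to_numpy(dtype=np.float64)
    g, c = B.shape
    if g < 2:
        raise ValueError("need at least two genes")
    n11 = B @ B.T
    s = B.sum(axis=1)
    n10 = s[:, None] - n11
    n01 = s[None, :] - n11
    n00 = c - n11 - n10 - n01

    def plogp(p):
        out = np.zeros_like(p)
        nz = p > 0
        out[nz] = -p[nz] * np.log(p[nz])
        return out

    Hj = plogp(n11 / c) + plogp(n10 / c) + plogp(n01 / c) + plogp(n00 / c)
    p1 = s / c
    Hm = plogp(p1) + plogp(1 - p1)
    mi = Hm[:, None] + Hm[None, :] - Hj
    mi = np.clip(mi, 0.0, None)
    np.fill_diagonal(mi, Hm)
    return pd.DataFrame(mi, index=binary.index, columns=binary.index)


def select_connectors(
    pathway_genes: list[str],
    candidates: list[str],
    binary: pd.DataFrame,
    k: int = 20,
) -> list[str]:
    """Top-k candidate genes by ascending mean VI to the pathway genes.

    Gene-gene VI is computed over cells; ties break on gene id.
    """
    if not pathway_genes:
        raise ValueError("pathway gene set must be nonempty")
    if set(pathway_genes) & set(candidates):
        raise ValueError("candidates must be disjoint from the pathway genes")
    sub = binary.loc[list(pathway_genes) + list(candidates)]
    d = vi_distance(sub.T)  # VI between gene rows
    mean_vi = d.loc[candidates, pathway_genes].mean(axis=1)
    ranked = sorted(candidates, key=lambda g: (mean_vi[g], g))
    return ranked[:k]


def mi_threshold(
    binary: pd.DataFrame, quantile: float = 0.95, n_perm: int = 30, seed: int = 0
) -> float:
    """Permutation-null MI threshold: each gene's bits are shuffled across
    cells independently, and the given quantile of the null off-diagonal
    MI values is returned."""
    rng = np.random.default_rng(seed)
    null_vals = []
    for _ in range(n_perm):
        perm = binary.to_numpy().copy()
        for row in perm:
            rng.shuffle(row)
        m = mi_matrix(pd.DataFrame(perm, index=binary.index, columns=binary.columns))
        vals = m.to_numpy()[np.triu_indices(len(m), k=1)]
        null_vals.append(vals)
    return float(np.quantile(np.concatenate(null_vals), quantile))


def aracne_dpi(
    mi: pd.DataFrame, tolerance: float = 0.0, threshold: float = 0.0
) -> set[tuple[str, str]]:
    """ARACNE data-processing-inequality pruning of an MI matrix.

    Starting from all pairs with MI > threshold, every triangle (A, B, C)
    marks its weakest edge AC for removal when
    mi(AC) < min(mi(AB), mi(BC)) * (1 - tolerance); removals are applied
    simultaneously after scanning all triangles, so the result does not
    depend on iteration order.  Edges are returned as sorted gene-id pairs.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    genes = list(mi.index)
    m = mi.to_numpy()
    n = len(genes)
    adj = (m > threshold)
    np.fill_diagonal(adj, False)
    def key(i, j):
        return tuple(sorted((genes[i], genes[j])))

    edges = {key(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]}
    doomed = set()
    for i in range(n):
        for j in range(i + 1, n):
            if not adj[i, j]:
                continue
            for k_ in range(j + 1, n):
                if not (adj[i, k_] and adj[j, k_]):
                    continue
                trio = {key(i, j): m[i, j],
                        key(i, k_): m[i, k_],
                        key(j, k_): m[j, k_]}
                weakest = min(trio, key=trio.get)
                others = [v for e, v in trio.items() if e != weakest]
                if trio[weakest] < min(others) * (1 - tolerance):
                    doomed.add(weakest)
    return edges - doomed


@dataclass
class SwitchNetwork:
    graph: nx.DiGraph  # each edge stored once; grey edges have kind="undirected_grey"

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"tail": u, "head": v, "mi": d["mi"], "kind": d["kind"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)


def direct_edges(
    edges: set[tuple[str, str]],
    mi: pd.DataFrame,
    switch_times: dict[str, int],
    gap: int = 10,
) -> SwitchNetwork:
    """Direct each edge from the earlier- to the later-switching gene.

    Genes switching fewer than ``gap`` cells apart keep an undirected grey
    edge (stored tail/head in sorted order with kind="undirected_grey").
    """
    g = nx.DiGraph()
    for a, b in sorted(edges):
        if a not in switch_times or b not in switch_times:
            missing = a if a not in switch_times else b
            raise ValueError(f"no switch time for gene {missing!r}")
        ta, tb = switch_times[a], switch_times[b]
        w = float(mi.at[a, b])
        if abs(ta - tb) >= gap:
            tail, head = (a, b) if ta < tb else (b, a)
            g.add_edge(tail, head, mi=w, kind="directed")
        else:
            g.add_edge(a, b, mi=w, kind="undirected_grey")
    for node in g.nodes:
        g.nodes[node]["switch_time"] = switch_times[node]
    return SwitchNetwork(graph=g)


def build_network(
    binary: pd.DataFrame,
    switch_times: dict[str, int],
    pathway_genes: list[str],
    k_connectors: int = 20,
    tolerance: float = 0.0,
    threshold: float | None = None,
    gap: int = 10,
    seed: int = 0,
) -> SwitchNetwork:
    """Pathway + connector co-switching network, DPI-pruned and directed."""
    candidates = [g for g in binary.index
                  if g in switch_times and g not in set(pathway_genes)]
    connectors = select_connectors(pathway_genes, candidates, binary, k=k_connectors)
    nodes = [g for g in list(pathway_genes) + connectors if g in binary.index]
    sub = binary.loc[nodes]
    if threshold is None:
        threshold = mi_threshold(sub, seed=seed)
    mi = mi_matrix(sub)
    edges = aracne_dpi(mi, tolerance=tolerance, threshold=threshold)
    return direct_edges(edges, mi, switch_times, gap=gap)
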