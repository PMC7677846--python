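"""Pseudotime ordering of cells from binarized expression.

Cells collected at known timepoints are ordered *within* each timepoint
cluster; clusters themselves keep their experimental order.  The distance
between two cells is the variation of information (VI) between their
binary gene-state vectors — a metric that is zero exactly when two cells
induce the same ON/OFF partition of the genes.  Orderings are anchored at
*connecting cells*: cross-cluster cell pairs with the smallest VI.  Each
candidate anchor yields a candidate ordering of its cluster (cells sorted
by VI from the anchor); candidates anchored in the following cluster are
reversed so all sequences run early -> late.  A probabilistic suffix tree
(PST, a variable-order Markov model over cell ids) is trained per cluster
on its candidate orderings, and the consensus ordering is the greedily
generated sequence when generation is unique, otherwise the candidate with
the highest PST log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "vi_distance",
    "find_connecting_pairs",
    "anchor_ordering",
    "CandidateOrdering",
    "PSTModel",
    "build_pst",
    "consensus_order",
    "orient_sequence",
    "PseudotimeOrder",
    "assemble_pseudotime",
    "infer_pseudotime",
]


def _entropy_terms(p: np.ndarray) -> np.ndarray:
    """-p*ln(p) with 0 ln 0 = 0, elementwise."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = -p[nz] * np.log(p[nz])
    return out


def vi_distance(binary: pd.DataFrame) -> pd.DataFrame:
    """Cells x cells variation of information, VI = 2*H(X,Y) - H(X) - H(Y).

    Each cell is a binary random variable over the genes; entropies use the
    empirical joint distribution of gene states (natural log, nats).
    """
    B = binary.to_numpy(dtype=np.float64)
    g, c = B.shape
    if g < 1:
        raise ValueError("need at least one gene")
    n11 = B.T @ B
    s = B.sum(axis=0)
    n10 = s[:, None] - n11
    n01 = s[None, :] - n11
    n00 = g - n11 - n10 - n01
    H_joint = sum(
        _entropy_terms(m / g) for m in (n11, n10, n01, n00)
    )
    p1 = s / g
    H_marg = _entropy_terms(p1) + _entropy_terms(1 - p1)
    vi = 2 * H_joint - H_marg[:, None] - H_marg[None, :]
    vi = np.clip(vi, 0.0, None)
    np.fill_diagonal(vi, 0.0)
    return pd.DataFrame(vi, index=binary.columns, columns=binary.columns)


def find_connecting_pairs(
    d: pd.DataFrame, cluster_a: list[str], cluster_b: list[str], k: int = 100
) -> list[tuple[str, str]]:
    """The k cross-cluster pairs with smallest VI, ascending.

    Ties break lexicographically on (cell_a, cell_b).  Asking for more
    pairs than exist returns all of them.
    """
    if set(cluster_a) & set(cluster_b):
        raise ValueError("clusters must be disjoint")
    if not cluster_a or not cluster_b:
        raise ValueError("clusters must be nonempty")
    block = d.loc[cluster_a, cluster_b]
    pairs = sorted(
        ((block.at[a, b], a, b) for a in cluster_a for b in cluster_b)
    )
    return [(a, b) for _, a, b in pairs[:k]]


@dataclass
class CandidateOrdering:
    cluster: str
    anchor: tuple[str, str]  # (cell in adjacent cluster, cell in this cluster)
    sequence: list[str]


def anchor_ordering(
    cluster: list[str], connecting_cell: str, d: pd.DataFrame
) -> list[str]:
    """Cells sorted ascending by VI from the connecting cell (itself first);
    ties break on cell id."""
    if connecting_cell not in cluster:
        raise ValueError(f"{connecting_cell!r} not in cluster")
    rest = [c for c in cluster if c != connecting_cell]
    rest.sort(key=lambda c: (d.at[connecting_cell, c], c))
    return [connecting_cell] + rest


START = "^"  # virtual start-of-sequence symbol


@dataclass
class PSTModel:
    """Variable-order Markov model of cell-id sequences (contexts <= depth).

    Sequences are implicitly prefixed with a start symbol so that the model
    also captures which cells open an ordering.
    """

    alphabet: list[str]
    depth: int
    smoothing: float
    counts: dict[tuple[str, ...], dict[str, int]] = field(default_factory=dict)

    def _longest_context(self, history: tuple[str, ...]) -> tuple[str, ...]:
        for k in range(min(self.depth, len(history)), -1, -1):
            ctx = history[len(history) - k :]
            if ctx in self.counts:
                return ctx
        return ()

    def prob(self, history: tuple[str, ...], symbol: str) -> float:
        ctx = self._longest_context(tuple(history))
        tab = self.counts.get(ctx, {})
        total = sum(tab.values())
        num = tab.get(symbol, 0) + self.smoothing
        den = total + self.smoothing * len(self.alphabet)
        if den == 0:
            return 1.0 / len(self.alphabet)
        return num / den

    def log_likelihood(self, sequence: list[str]) -> float:
        padded = [START] + list(sequence)
        ll = 0.0
        for i in range(1, len(padded)):
            p = self.prob(tuple(padded[max(0, i - self.depth) : i]), padded[i])
            ll += math.log(p) if p > 0 else -math.inf
        return ll


def build_pst(
    sequences: list[list[str]], depth: int = 3, smoothing: float = 1e-3
) -> PSTModel:
    """Count next-symbol occurrences after every context of length <= depth."""
    if not sequences:
        raise ValueError("need at least one sequence")
    alphabet = sorted({s for seq in sequences for s in seq})
    counts: dict[tuple[str, ...], dict[str, int]] = {}
    for seq in sequences:
        padded = [START] + list(seq)
        for i in range(1, len(padded)):
            sym = padded[i]
            for k in range(0, depth + 1):
                if k > i:
                    break
                ctx = tuple(padded[i - k : i])
                tab = counts.setdefault(ctx, {})
                tab[sym] = tab.get(sym, 0) + 1
    return PSTModel(alphabet=alphabet, depth=depth, smoothing=smoothing, counts=counts)


def consensus_order(
    pst: PSTModel, candidates: list[CandidateOrdering], tie_tol: float = 1e-12
) -> list[str]:
    """Consensus cluster ordering under the PST.

    Greedy generation emits, at each step, the highest-probability unused
    cell given the generated history (starting from the start-of-sequence
    context; exact ties break on cell id).  The generated ordering is the
    consensus when the PST scores it at least as high as every candidate —
    this keeps the invariant that the returned ordering's log-likelihood
    is >= that of every candidate it rejects.  Otherwise generation is
    treated as non-unique and the highest-likelihood candidate wins (ties
    keep the earliest candidate).
    """
    if not candidates:
        raise ValueError("need at least one candidate ordering")
    cand_ll = [pst.log_likelihood(c.sequence) for c in candidates]
    best_i = int(np.argmax(cand_ll))

    generated: list[str] = [START]
    remaining = set(pst.alphabet)
    while remaining:
        history = tuple(generated[-pst.depth :])
        best_p, best_s = -1.0, None
        for s in sorted(remaining):
            p = pst.prob(history, s)
            if p > best_p + tie_tol:
                best_p, best_s = p, s
        generated.append(best_s)
        remaining.discard(best_s)
    generated = generated[1:]

    if pst.log_likelihood(generated) >= cand_ll[best_i]:
        return generated
    return list(candidates[best_i].sequence)


@dataclass
class PseudotimeOrder:
    order: list[str]
    boundaries: list[int]            # start index of each cluster block
    cluster_labels: list[str]
    provenance: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def rank(self) -> pd.Series:
        return pd.Series(np.arange(len(self.order)), index=self.order)


def assemble_pseudotime(
    cluster_orders: dict[str, list[str]],
    group_order: list[str],
    provenance: dict[str, list[tuple[str, str]]] | None = None,
) -> PseudotimeOrder:
    """Concatenate per-cluster orderings in experimental time order."""
    missing = [g for g in group_order if g not in cluster_orders]
    if missing:
        raise ValueError(f"missing cluster order for {missing}")
    order: list[str] = []
    boundaries: list[int] = []
    for g in group_order:
        boundaries.append(len(order))
        order.extend(cluster_orders[g])
    if len(set(order)) != len(order):
        raise ValueError("cluster orders overlap")
    return PseudotimeOrder(order, boundaries, list(group_order), provenance or {})


def orient_sequence(
    seq: list[str],
    binary: pd.DataFrame,
    prev_cells: list[str] | None,
    next_cells: list[str] | None,
) -> list[str]:
    """Orient a cluster ordering so it runs early -> late.

    Within-cluster VI orderings carry no intrinsic direction (and the
    minimal-VI anchor need not be a boundary cell), so direction is fixed
    against the neighbouring timepoints: cells late in the sequence must be
    closer to the next cluster's mean binary profile (and early cells to
    the previous cluster's) in mean absolute deviation.  The sequence is
    reversed when the covariance between position and (distance-to-next
    minus distance-to-previous) is positive.
    """
    if (prev_cells is None and next_cells is None) or len(seq) < 2:
        return seq
    X = binary[seq].to_numpy(dtype=float)  # genes x position
    own = X.mean(axis=1)
    nxt = binary[next_cells].to_numpy(dtype=float).mean(axis=1) if next_cells else None
    prv = binary[prev_cells].to_numpy(dtype=float).mean(axis=1) if prev_cells else None
    if nxt is not None and prv is not None:
        w = nxt - prv
    elif nxt is not None:
        w = nxt - own
    else:
        w = own - prv
    score = w @ X  # per-position projection along the time direction
    pos = np.arange(len(seq), dtype=float)
    cov = float(np.cov(pos, score)[0, 1])
    return seq[::-1] if cov < 0 else seq


def _merge_groups(groups: pd.Series, order: list[str], merges) -> tuple[pd.Series, list[str]]:
    groups = groups.copy()
    order = list(order)
    for pair in merges or []:
        a, b = pair
        label = f"{a}+{b}"
        groups = groups.replace({a: label, b: label})
        order = [label if g == a else g for g in order if g != b]
    return groups, order


def infer_pseudotime(
    binary: pd.DataFrame,
    annotation,
    merges: list[tuple[str, str]] | None = None,
    k: int = 100,
    depth: int = 3,
    smoothing: float = 1e-3,
    d: pd.DataFrame | None = None,
) -> PseudotimeOrder:
    """Full pseudotime construction over all timepoint clusters.

    ``annotation.group_order`` gives the experimental cluster order;
    ``merges`` combines indistinguishable adjacent timepoints before
    ordering.  Middle clusters receive candidates anchored from both
    neighbours (those anchored in the following cluster are reversed to
    run early -> late).
    """
    if annotation.group_order is None:
        raise ValueError("annotation must carry a group_order for pseudotime")
    groups, order_labels = _merge_groups(
        annotation.groups.reindex(binary.columns), annotation.group_order, merges
    )
    if d is None:
        d = vi_distance(binary)
    clusters = {g: list(binary.columns[groups == g]) for g in order_labels}

    cluster_orders: dict[str, list[str]] = {}
    provenance: dict[str, list[tuple[str, str]]] = {}
    for i, g in enumerate(order_labels):
        cells = clusters[g]
        prev_cells = clusters[order_labels[i - 1]] if i > 0 else None
        next_cells = clusters[order_labels[i + 1]] if i < len(order_labels) - 1 else None
        candidates: list[CandidateOrdering] = []
        if prev_cells is not None:
            for prev_cell, cur_cell in find_connecting_pairs(d, prev_cells, cells, k):
                seq = orient_sequence(
                    anchor_ordering(cells, cur_cell, d), binary, prev_cells, next_cells
                )
                candidates.append(CandidateOrdering(g, (prev_cell, cur_cell), seq))
        if next_cells is not None:
            for cur_cell, next_cell in find_connecting_pairs(d, cells, next_cells, k):
                seq = orient_sequence(
                    anchor_ordering(cells, cur_cell, d), binary, prev_cells, next_cells
                )
                candidates.append(CandidateOrdering(g, (next_cell, cur_cell), seq))
        if not candidates:  # single isolated cluster
            candidates = [CandidateOrdering(g, ("", cells[0]), sorted(cells))]
        pst = build_pst([c.sequence for c in candidates], depth, smoothing)
        consensus = consensus_order(pst, candidates)
        cluster_orders[g] = orient_sequence(consensus, binary, prev_cells, next_cells)
        provenance[g] = [c.anchor for c in candidates[:3]]
    return assemble_pseudotime(cluster_orders, order_labels, provenance)
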