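"""Differential transcriptional activity from binarized expression.

Between two cell groups, a bimodal gene's activity change is a shift in the
proportion of ON cells, tested with Fisher's exact test on the 2x2
ON/OFF-by-group table.  The odds ratio orients the change: with the
baseline group given first, OR > 1 means the gene is active in a larger
fraction of cells after differentiation ("upregulated" in the ON-proportion
sense), OR < 1 the reverse.  P-values are Benjamini-Hochberg adjusted
across genes.  A generic hypergeometric gene-set overlap test against GMT
collections replaces web-based signature queries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SwitchTestResult",
    "switch_test",
    "adjust_pvalues",
    "differential_switching",
    "read_gmt",
    "geneset_overlap",
]


@dataclass
class SwitchTestResult:
    gene_id: str
    table: np.ndarray          # [[ON_A, OFF_A], [ON_B, OFF_B]]
    p: float
    odds_ratio: float
    p_adj: float = np.nan
    direction: str = "none"


def switch_test(bits_a: np.ndarray, bits_b: np.ndarray, gene_id: str = "") -> SwitchTestResult:
    """Fisher's exact test for a change in ON proportion from group A to B.

    The sample odds ratio is (ON_B * OFF_A) / (OFF_B * ON_A), with the
    Haldane +0.5 continuity correction applied when any cell is zero.
    """
    a = np.asarray(bits_a)
    b = np.asarray(bits_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    on_a, off_a = int(a.sum()), int(a.size - a.sum())
    on_b, off_b = int(b.sum()), int(b.size - b.sum())
    table = np.array([[on_a, off_a], [on_b, off_b]])
    _, p = fisher_exact(table, alternative="two-sided")
    cells = np.array([on_a, off_a, on_b, off_b], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    on_a_, off_a_, on_b_, off_b_ = cells
    orat = (on_b_ * off_a_) / (off_b_ * on_a_)
    return SwitchTestResult(gene_id=gene_id, table=table, p=float(p), odds_ratio=float(orat))


def adjust_pvalues(ps: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    ps = np.asarray(ps, dtype=float)
    if ((ps < 0) | (ps > 1)).any() or np.isnan(ps).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method != "bh":
        raise ValueError(f"unknown method {method!r}")
    if ps.size == 0:
        return ps
    return multipletests(ps, method="fdr_bh")[1]


def differential_switching(
    binary: pd.DataFrame,
    cells_a: list[str],
    cells_b: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Fisher switch tests A -> B with BH adjustment.

    Returns a DataFrame (gene rows) with on_a/on_b fractions, p, p_adj,
    odds_ratio and direction in {up, down, none} at level ``alpha``.
    """
    A = binary[cells_a].to_numpy()
    B = binary[cells_b].to_numpy()
    results = [switch_test(A[i], B[i], g) for i, g in enumerate(binary.index)]
    p_adj = adjust_pvalues([r.p for r in results])
    rows = {}
    for r, q in zip(results, p_adj):
        r.p_adj = float(q)
        if q < alpha:
            r.direction = "up" if r.odds_ratio > 1 else "down"
        rows[r.gene_id] = {
            "on_frac_a": r.table[0, 0] / r.table[0].sum(),
            "on_frac_b": r.table[1, 0] / r.table[1].sum(),
            "odds_ratio": r.odds_ratio,
            "p": r.p,
            "p_adj": r.p_adj,
            "direction": r.direction,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def geneset_overlap(
    query: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail overlap test of a query against gene sets.

    Sets are clipped to the universe; p = P(overlap >= observed) when
    drawing |query| genes from the universe; q is BH across sets.
    """
    if not query or not universe:
        raise ValueError("query and universe must be nonempty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = {}
    for name, genes in collection.items():
        genes_u = genes & universe
        k = len(query & genes_u)
        K = len(genes_u)
        p = float(hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows[name] = {"set_size": K, "overlap": k, "p": p}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["q"] = adjust_pvalues(out["p"].to_numpy()) if len(out) else []
    return out.sort_values("p")
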