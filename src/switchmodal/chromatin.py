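"""Promoter chromatin-state calls from H3K4me3 / H3K27me3 peak intervals.

In embryonic stem cells many promoters are *bivalent* — marked by both the
activating H3K4me3 and the repressive H3K27me3 histone modifications — and
held poised for resolution to a monovalent state upon differentiation.
This module calls each gene's promoter state (bivalent, k4_only, k27_only,
unmarked) by intersecting peak BED intervals with a strand-aware window
around the TSS, and intersects state calls with bimodal gene sets.

The promoter definition (default +/-2 kb around the TSS, >=1 bp overlap)
is an explicit, configurable convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "PromoterAnnotation",
    "read_peaks",
    "read_promoters",
    "call_promoter_state",
    "intersect_states",
]

STATES = ("bivalent", "k4_only", "k27_only", "unmarked")


@dataclass
class PromoterAnnotation:
    gene_id: str
    chrom: str
    tss: int
    strand: str  # "+" or "-"


def read_peaks(path: str | Path) -> pd.DataFrame:
    """BED (3+ columns, 0-based half-open) -> DataFrame(chrom, start, end)."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: non-integer interval") from e
        if start >= end:
            raise ValueError(f"{path}:{ln}: start {start} >= end {end}")
        rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_promoters(path: str | Path) -> list[PromoterAnnotation]:
    """TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene_id", "chrom", "tss", "strand"])
    return [
        PromoterAnnotation(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def promoter_window(p: PromoterAnnotation, upstream: int, downstream: int) -> tuple[int, int]:
    """Strand-aware half-open promoter window around the TSS base."""
    if upstream < 0 or downstream < 0:
        raise ValueError("window extents must be nonnegative")
    if p.strand == "+":
        return p.tss - upstream, p.tss + downstream
    if p.strand == "-":
        return p.tss + 1 - downstream, p.tss + 1 + upstream
    raise ValueError(f"bad strand {p.strand!r} for {p.gene_id}")


def _trees(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"])
        )
    return trees


def call_promoter_state(
    k4_peaks: pd.DataFrame,
    k27_peaks: pd.DataFrame,
    promoters: list[PromoterAnnotation],
    upstream: int = 2000,
    downstream: int = 2000,
) -> pd.Series:
    """Per-gene chromatin state from >=1 bp peak/promoter-window overlap."""
    k4 = _trees(k4_peaks)
    k27 = _trees(k27_peaks)
    calls = {}
    for p in promoters:
        lo, hi = promoter_window(p, upstream, downstream)
        has4 = bool(k4.get(p.chrom, IntervalTree()).overlap(lo, hi))
        has27 = bool(k27.get(p.chrom, IntervalTree()).overlap(lo, hi))
        calls[p.gene_id] = (
            "bivalent" if has4 and has27
            else "k4_only" if has4
            else "k27_only" if has27
            else "unmarked"
        )
    return pd.Series(calls, name="state")


def intersect_states(
    bimodal_genes: set[str] | list[str],
    calls: pd.Series,
    wanted: set[str] | list[str] = ("bivalent",),
) -> set[str]:
    """Bimodal genes whose promoter state is among the wanted states."""
    bad = set(wanted) - set(STATES)
    if bad:
        raise ValueError(f"unknown state(s) {sorted(bad)}")
    in_state = set(calls.index[calls.isin(list(wanted))])
    return set(bimodal_genes) & in_state
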