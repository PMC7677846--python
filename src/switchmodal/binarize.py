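"""Binarization of bimodal genes and windowed fractional activity.

For a bimodal gene, the binarization threshold is the expression value at
the local minimum (density valley) between the OFF and ON modes; cells at
or above the threshold are active (1), cells strictly below are inactive
(0).  Windowed fractional activity averages the bits over random windows of
cells drawn within each cell group, giving an ON-proportion profile that is
much smoother than individual cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .bimodality import MixtureFit
from .io import CellAnnotation

__all__ = [
    "FractionalProfile",
    "binarization_threshold",
    "binarize",
    "fractional_windows",
]


def binarization_threshold(
    values: np.ndarray, fit: MixtureFit, n_grid: int = 512
) -> float:
    """Density-valley threshold between the extreme component means.

    A Gaussian-kernel density (Silverman bandwidth) is scanned on the open
    interval between the smallest and largest component means; the interior
    argmin is the threshold.  If the density has no interior minimum (or is
    degenerate) the midpoint of the two smallest means is used.
    """
    if not fit.is_bimodal:
        raise ValueError(f"gene {fit.gene_id!r} is not bimodal")
    lo, hi = float(fit.means[0]), float(fit.means[-1])
    midpoint = 0.5 * (fit.means[0] + fit.means[1])
    if not hi > lo:
        return float(midpoint)
    x = np.asarray(values, dtype=float)
    try:
        kde = gaussian_kde(x, bw_method="silverman")
    except np.linalg.LinAlgError:
        return float(midpoint)
    grid = np.linspace(lo, hi, n_grid)[1:-1]
    dens = kde(grid)
    k = int(np.argmin(dens))
    if k == 0 or k == len(grid) - 1:  # monotone between the modes
        return float(midpoint)
    return float(grid[k])


def binarize(logtpm: pd.DataFrame, thresholds: pd.Series) -> pd.DataFrame:
    """Genes x cells bit matrix: 1 iff value >= threshold (OFF is strictly
    below the threshold, so a value exactly at it counts as ON)."""
    missing = logtpm.index.difference(thresholds.index)
    if len(missing):
        raise ValueError(f"missing threshold for gene(s): {list(missing[:5])}")
    th = thresholds.reindex(logtpm.index)
    bits = (logtpm.to_numpy() >= th.to_numpy()[:, None]).astype(np.int8)
    return pd.DataFrame(bits, index=logtpm.index, columns=logtpm.columns)


@dataclass
class FractionalProfile:
    """Per-window ON fractions with the windows' group provenance."""

    fractions: pd.DataFrame       # genes x windows, values in [0, 1]
    window_groups: pd.Series      # window label -> group
    window_cells: dict[str, list[str]]


def fractional_windows(
    binary: pd.DataFrame,
    annotation: CellAnnotation,
    n_windows: int = 30,
    seed: int = 0,
) -> FractionalProfile:
    """Average bits over random windows of cells within each group.

    Each group receives a share of the ``n_windows`` windows proportional
    to its size (at least one); cells are shuffled with the given seed and
    split into contiguous chunks, so windows never span groups.
    """
    n_cells = binary.shape[1]
    if n_windows > n_cells:
        raise ValueError(f"n_windows={n_windows} exceeds {n_cells} cells")
    rng = np.random.default_rng(seed)
    groups = annotation.groups.reindex(binary.columns)
    labels = (
        annotation.group_order
        if annotation.group_order is not None
        else sorted(groups.unique())
    )
    sizes = np.array([(groups == g).sum() for g in labels], dtype=float)
    # largest-remainder apportionment of windows, minimum one per group
    raw = n_windows * sizes / sizes.sum()
    alloc = np.maximum(np.floor(raw).astype(int), 1)
    while alloc.sum() > n_windows:
        alloc[np.argmax(alloc)] -= 1
    rem = raw - np.floor(raw)
    while alloc.sum() < n_windows:
        k = int(np.argmax(np.where(alloc >= 1, rem, -np.inf)))
        alloc[k] += 1
        rem[k] = -np.inf

    frac_cols, wgroups, wcells = {}, {}, {}
    for g, n_w in zip(labels, alloc):
        cells = list(binary.columns[groups == g])
        rng.shuffle(cells)
        for w, chunk in enumerate(np.array_split(cells, n_w)):
            label = f"{g}:w{w}"
            frac_cols[label] = binary[list(chunk)].mean(axis=1)
            wgroups[label] = g
            wcells[label] = list(chunk)
    return FractionalProfile(
        fractions=pd.DataFrame(frac_cols),
        window_groups=pd.Series(wgroups),
        window_cells=wcells,
    )
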