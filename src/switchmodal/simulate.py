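"""Synthetic expression data with known ON/OFF structure.

The generator emulates the zero-inflated two-state expression model: a
cell is either OFF — emitting an exact zero (dropout / undetected) or a
small near-zero value — or ON, emitting a value whose log1p is Gaussian
around a clearly positive mean.  Group simulations give each gene a
per-group ON fraction; time-course simulations give each switching gene a
true switch position along a latent cell time at which its ON probability
steps between a low and a high level, with observation noise flipping
states at a fixed rate.  Ground truth (flags, fractions, switch positions,
separating thresholds) is returned alongside, so every pipeline stage can
be scored without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CellAnnotation, ExpressionMatrix

__all__ = ["SimConfig", "GroundTruth", "simulate_groups", "simulate_timecourse"]


@dataclass
class SimConfig:
    """Parameters of the zero-inflated two-state generator.

    Values live on the logTPM scale: an ON cell draws ln(Y+1) from
    N(on_mean, on_sd^2); an OFF cell is an exact zero with probability
    ``zero_prob`` and otherwise draws ln(Y+1) from a truncated
    N(off_mean, off_sd^2).  ``dropout`` forces an ON cell's value to zero.
    """

    n_genes: int = 100
    n_cells: int = 500
    groups: dict[str, int] | None = None       # label -> cell count
    on_fraction: dict[str, np.ndarray] | float = 0.5  # per group (or scalar)
    on_mean: float | np.ndarray = 2.0   # scalar or per-gene
    on_sd: float | np.ndarray = 0.3
    off_mean: float = 0.1
    off_sd: float = 0.2
    zero_prob: float = 0.5
    dropout: float = 0.1
    seed: int = 0
    # time course
    switch_positions: np.ndarray | None = None  # per gene; -1 = non-switching
    switch_up: np.ndarray | None = None         # True: OFF -> ON at the switch
    p_lo: float = 0.1
    p_hi: float = 0.9
    flip_noise: float = 0.1
    n_timepoints: int = 3
    drift: bool = False   # staggered monotone ON-probability drifts instead of steps
    label_noise: float = 0.1  # sd of collection-label noise, as fraction of n_cells

    def __post_init__(self) -> None:
        for name in ("dropout", "zero_prob", "p_lo", "p_hi", "flip_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes <= 0 or self.n_cells <= 0:
            raise ValueError("n_genes and n_cells must be positive")


@dataclass
class GroundTruth:
    bimodal: pd.Series                      # per gene: True if two states exist
    on_fraction: pd.DataFrame | None = None  # genes x groups
    threshold: pd.Series | None = None       # separating logTPM value
    switch_position: pd.Series | None = None
    switch_up: pd.Series | None = None
    states: pd.DataFrame | None = None       # true ON/OFF per gene x cell
    cell_time: pd.Series | None = None


def _emit(rng: np.random.Generator, states: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """logTPM values for a gene x cell matrix of true ON(1)/OFF(0) states."""
    shape = states.shape
    on_mean = np.broadcast_to(np.atleast_1d(cfg.on_mean)[:, None]
                              if np.ndim(cfg.on_mean) else cfg.on_mean, shape)
    on_sd = np.broadcast_to(np.atleast_1d(cfg.on_sd)[:, None]
                            if np.ndim(cfg.on_sd) else cfg.on_sd, shape)
    on_vals = rng.normal(on_mean, on_sd, shape)
    off_vals = np.clip(rng.normal(cfg.off_mean, cfg.off_sd, shape), 0.0, None)
    off_vals[rng.random(shape) < cfg.zero_prob] = 0.0
    vals = np.where(states == 1, on_vals, off_vals)
    vals[(states == 1) & (rng.random(shape) < cfg.dropout)] = 0.0
    return np.clip(vals, 0.0, None)


def _matrix(vals: np.ndarray, genes, cells) -> ExpressionMatrix:
    logtpm = pd.DataFrame(vals, index=genes, columns=cells)
    return ExpressionMatrix({"logtpm": logtpm, "tpm": np.expm1(logtpm)})


def simulate_groups(cfg: SimConfig) -> tuple[ExpressionMatrix, CellAnnotation, GroundTruth]:
    """Genes x cells matrix with group-specific ON fractions.

    ``cfg.groups`` maps group labels to cell counts (default: one group of
    ``n_cells``); ``cfg.on_fraction`` is a scalar or per-group arrays of
    length n_genes.  A gene with ON fraction 0 or 1 everywhere is
    unimodal; anything in between is a true bimodal gene.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = cfg.groups or {"all": cfg.n_cells}
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    cells, labels, state_cols, frac = [], [], [], {}
    for glabel, count in groups.items():
        f = cfg.on_fraction[glabel] if isinstance(cfg.on_fraction, dict) \
            else np.full(cfg.n_genes, float(cfg.on_fraction))
        f = np.asarray(f, dtype=float)
        if ((f < 0) | (f > 1)).any():
            raise ValueError("ON fractions must lie in [0, 1]")
        frac[glabel] = f
        states = (rng.random((cfg.n_genes, count)) < f[:, None]).astype(np.int8)
        state_cols.append(states)
        new = [f"{glabel}_c{i:04d}" for i in range(count)]
        cells += new
        labels += [glabel] * count
    states = np.concatenate(state_cols, axis=1)
    vals = _emit(rng, states, cfg)

    matrix = _matrix(vals, genes, cells)
    ann = CellAnnotation(pd.Series(labels, index=cells), group_order=list(groups))
    frac_df = pd.DataFrame(frac, index=genes)
    truth = GroundTruth(
        bimodal=pd.Series(((frac_df > 0) & (frac_df < 1)).any(axis=1), index=genes),
        on_fraction=frac_df,
        threshold=pd.Series(0.5 * (cfg.off_mean + cfg.on_mean), index=genes),
        states=pd.DataFrame(states, index=genes, columns=cells),
    )
    return matrix, ann, truth


def simulate_timecourse(cfg: SimConfig) -> tuple[ExpressionMatrix, CellAnnotation, GroundTruth]:
    """Time course with per-gene switching of the ON probability.

    Cells carry a latent true time 0..n_cells-1 (the generated column
    order); gene g's ON probability is ``p_lo`` before its switch position
    and ``p_hi`` after (reversed for switch-down genes).  Non-switching
    genes (position -1) stay at ``p_lo``.  Observation noise flips each
    cell's emitted state with probability ``flip_noise``.  Cells are
    labeled into ``n_timepoints`` equal timepoint groups (t0, t1, ...).
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.switch_positions is None and not cfg.drift:
        raise ValueError("timecourse config needs switch_positions (or drift=True)")
    up = (np.ones(cfg.n_genes, dtype=bool) if cfg.switch_up is None
          else np.asarray(cfg.switch_up, dtype=bool))
    t = np.arange(cfg.n_cells)

    if cfg.drift:
        # staggered monotone drifts: each gene's ON probability ramps
        # logistically from p_lo to p_hi around its own midpoint, emulating
        # sequential waves of activation/deactivation along differentiation
        pos = rng.integers(0, cfg.n_cells, cfg.n_genes)
        width = cfg.n_cells / 6.0
        ramp = 1.0 / (1.0 + np.exp(-(t[None, :] - pos[:, None]) / width))
        p_up = cfg.p_lo + (cfg.p_hi - cfg.p_lo) * ramp
        p_on = np.where(up[:, None], p_up, cfg.p_lo + cfg.p_hi - p_up)
    else:
        pos = np.asarray(cfg.switch_positions, dtype=int)
        if pos.size != cfg.n_genes:
            raise ValueError("switch_positions must have one entry per gene")
        if ((pos >= cfg.n_cells) | ((pos < 0) & (pos != -1))).any():
            raise ValueError("switch positions must lie in [0, n_cells) or be -1")
        p_on = np.full((cfg.n_genes, cfg.n_cells), cfg.p_lo)
        for gi in range(cfg.n_genes):
            if pos[gi] < 0:
                continue
            after = t >= pos[gi]
            if up[gi]:
                p_on[gi, after] = cfg.p_hi
            else:
                p_on[gi, :] = cfg.p_hi
                p_on[gi, after] = cfg.p_lo
    true_states = (rng.random(p_on.shape) < p_on).astype(np.int8)
    observed = true_states ^ (rng.random(p_on.shape) < cfg.flip_noise)
    vals = _emit(rng, observed.astype(np.int8), cfg)

    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    cells = [f"c{i:04d}" for i in range(cfg.n_cells)]
    tp_labels = [f"t{i}" for i in range(cfg.n_timepoints)]
    # collection timepoints track progression imperfectly: cells are binned
    # by a noisy copy of their true time, so adjacent clusters overlap in
    # progression (differentiation is asynchronous within a timepoint)
    noisy_t = t + rng.normal(0.0, cfg.label_noise * cfg.n_cells, cfg.n_cells)
    bins = np.empty(cfg.n_cells, dtype=int)
    bins[np.argsort(noisy_t, kind="stable")] = (
        np.arange(cfg.n_cells) * cfg.n_timepoints // cfg.n_cells
    )
    assignment = [tp_labels[b] for b in bins]
    matrix = _matrix(vals, genes, cells)
    ann = CellAnnotation(pd.Series(assignment, index=cells), group_order=tp_labels)
    truth = GroundTruth(
        bimodal=pd.Series(pos >= 0, index=genes),
        threshold=pd.Series(0.5 * (cfg.off_mean + cfg.on_mean), index=genes),
        switch_position=pd.Series(pos, index=genes),
        switch_up=pd.Series(up, index=genes),
        states=pd.DataFrame(observed, index=genes, columns=cells),
        cell_time=pd.Series(t, index=cells),
    )
    return matrix, ann, truth
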