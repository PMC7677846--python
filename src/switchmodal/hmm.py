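"""Two-state hidden Markov model for transcriptional switch calling.

Along the pseudotime ordering, each gene's binarized expression is modeled
as noisy emissions from a hidden ON/OFF transcriptional state with sticky
transitions.  Parameters are fitted per gene by Baum-Welch from a fixed
sticky initialization, the most likely state path is decoded with the
Viterbi algorithm (deterministic tie-breaking toward OFF), and switch
points are the positions where the decoded path changes state.  Genes are
classified into switch groups by (initial state, final state, number of
switches): group 1 = switched on once (OFF -> ON), group 2 = switched off
once (ON -> OFF), and further groups enumerate higher switch counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HMMParams",
    "SwitchProfile",
    "fit_hmm",
    "viterbi",
    "detect_switches",
    "classify_switch_group",
    "is_switching",
    "fit_switch_profiles",
    "aggregate_active",
]

OFF, ON = 0, 1


@dataclass
class HMMParams:
    pi: np.ndarray   # initial state probabilities (OFF, ON)
    A: np.ndarray    # 2x2 transition matrix, rows sum to 1
    B: np.ndarray    # P(observe 1 | state), B[ON] >= B[OFF] after relabel
    degenerate: bool = False
    log_likelihood: float = np.nan

    def validate(self) -> None:
        if not (np.allclose(self.pi.sum(), 1) and np.allclose(self.A.sum(1), 1)):
            raise ValueError("pi and rows of A must sum to 1")
        if ((self.B < 0) | (self.B > 1)).any():
            raise ValueError("emission probabilities must lie in [0, 1]")


def _default_init() -> HMMParams:
    return HMMParams(
        pi=np.array([0.5, 0.5]),
        A=np.array([[0.99, 0.01], [0.01, 0.99]]),
        B=np.array([0.1, 0.9]),
    )


def fit_hmm(
    seq: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    prob_floor: float = 1e-6,
) -> HMMParams:
    """Baum-Welch fit of the two-state Bernoulli HMM to one binary sequence.

    Starts from the fixed sticky initialization (stay probability 0.99,
    emissions 0.1/0.9, uniform pi).  A constant sequence is degenerate: the
    initialization is returned with the flag set (emissions floored away
    from 0/1 so decoding stays defined).  States are relabeled afterwards
    so that B[ON] >= B[OFF].
    """
    y = np.asarray(seq, dtype=int)
    if y.size < 10:
        raise ValueError("need a sequence of length >= 10")
    if y.min() < 0 or y.max() > 1:
        raise ValueError("sequence must be binary")
    params = _default_init()
    if (y == y[0]).all():
        params.degenerate = True
        return params

    pi, A, B = params.pi.copy(), params.A.copy(), params.B.copy()
    T = y.size
    prev_ll = -np.inf
    for _ in range(max_iter):
        em = np.where(y[:, None] == 1, B[None, :], 1 - B[None, :])  # T x 2
        # scaled forward-backward
        alpha = np.zeros((T, 2))
        scale = np.zeros(T)
        alpha[0] = pi * em[0]
        scale[0] = alpha[0].sum()
        alpha[0] /= scale[0]
        for t in range(1, T):
            alpha[t] = (alpha[t - 1] @ A) * em[t]
            scale[t] = alpha[t].sum()
            alpha[t] /= scale[t]
        beta = np.zeros((T, 2))
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta[t] = (A @ (em[t + 1] * beta[t + 1])) / scale[t + 1]
        ll = float(np.log(scale).sum())

        gamma = alpha * beta
        gamma /= gamma.sum(1, keepdims=True)
        xi_sum = np.zeros((2, 2))
        for t in range(T - 1):
            xi = (alpha[t][:, None] * A) * (em[t + 1] * beta[t + 1])[None, :]
            xi_sum += xi / xi.sum()
        pi = gamma[0]
        A = xi_sum / xi_sum.sum(1, keepdims=True)
        B = (gamma * y[:, None]).sum(0) / gamma.sum(0)
        B = np.clip(B, prob_floor, 1 - prob_floor)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll

    if B[ON] < B[OFF]:  # relabel so ON is the emission-rich state
        pi, B = pi[::-1].copy(), B[::-1].copy()
        A = A[::-1, ::-1].copy()
    out = HMMParams(pi=pi, A=A, B=B, log_likelihood=ll)
    out.validate()
    return out


def viterbi(seq: np.ndarray, params: HMMParams) -> np.ndarray:
    """Maximum-probability state path; ties resolve toward OFF, then toward
    staying in the previous state (deterministic).

    Implemented as a backward dynamic program followed by a greedy forward
    selection, which yields the lexicographically smallest argmax path
    (OFF < ON) — the stated tie-break order.
    """
    y = np.asarray(seq, dtype=int)
    params.validate()
    with np.errstate(divide="ignore"):
        logA = np.log(params.A)
        logpi = np.log(params.pi)
        logB = np.log(np.array([1 - params.B, params.B]))  # obs x state
    em = logB[y]  # T x 2
    if np.isneginf(em).all(axis=1).any():
        raise ValueError("an observation has zero probability under both states")
    T = y.size
    W = np.zeros((T, 2))
    W[-1] = em[-1]
    for t in range(T - 2, -1, -1):
        W[t] = em[t] + (logA + W[t + 1][None, :]).max(axis=1)
    path = np.zeros(T, dtype=int)
    start = logpi + W[0]
    path[0] = int(start[ON] > start[OFF])
    for t in range(1, T):
        score = logA[path[t - 1]] + W[t]
        path[t] = int(score[ON] > score[OFF])
    return path


def detect_switches(path: np.ndarray) -> np.ndarray:
    """Indices of the first cell of each new state along the path."""
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("empty path")
    return np.flatnonzero(np.diff(path) != 0) + 1


def classify_switch_group(
    initial_state: int, final_state: int, n_switches: int, max_switches: int | None = None
) -> int:
    """Deterministic switch-group id from (initial, final, #switches).

    Group 1: OFF -> ON with one switch; group 2: ON -> OFF with one switch;
    groups 2k-1 / 2k: k switches starting from OFF / ON.  Zero switches
    returns 0 (not a switching gene).
    """
    if n_switches < 0:
        raise ValueError("n_switches must be >= 0")
    if n_switches == 0:
        return 0
    expected_final = initial_state ^ (n_switches % 2)
    if final_state != expected_final:
        raise ValueError("final state inconsistent with initial state and switch count")
    k = n_switches if max_switches is None else min(n_switches, max_switches)
    return 2 * k - 1 if initial_state == OFF else 2 * k


def is_switching(params: HMMParams, path: np.ndarray, margin: float = 0.3) -> bool:
    """A gene switches if its path changes state at least once and the two
    emission distributions are well separated (B[ON] - B[OFF] >= margin)."""
    return detect_switches(path).size >= 1 and (params.B[ON] - params.B[OFF]) >= margin


@dataclass
class SwitchProfile:
    gene_id: str
    path: np.ndarray
    switch_indices: np.ndarray
    initial_state: int
    final_state: int
    n_switches: int
    group_id: int
    is_switching: bool
    params: HMMParams = field(repr=False, default=None)

    @property
    def first_switch(self) -> int | None:
        return int(self.switch_indices[0]) if self.n_switches else None


def fit_switch_profiles(
    binary: pd.DataFrame,
    order: list[str],
    margin: float = 0.3,
    max_switches: int | None = None,
) -> dict[str, SwitchProfile]:
    """Fit the HMM and decode switches for every gene over ordered cells."""
    mat = binary[list(order)].to_numpy()
    profiles = {}
    for i, gene in enumerate(binary.index):
        y = mat[i]
        params = fit_hmm(y)
        path = viterbi(y, params)
        sw = detect_switches(path)
        prof = SwitchProfile(
            gene_id=gene,
            path=path,
            switch_indices=sw,
            initial_state=int(path[0]),
            final_state=int(path[-1]),
            n_switches=int(sw.size),
            group_id=classify_switch_group(int(path[0]), int(path[-1]), int(sw.size),
                                           max_switches),
            is_switching=bool(is_switching(params, path, margin)),
            params=params,
        )
        profiles[gene] = prof
    return profiles


def aggregate_active(
    profiles: dict[str, SwitchProfile],
    genes: list[str],
    n_windows: int | None = None,
) -> np.ndarray:
    """Number of genes (from the subset) in the ON state at each pseudotime
    position; optionally averaged over consecutive windows."""
    if not genes:
        lengths = {len(p.path) for p in profiles.values()}
        return np.zeros(lengths.pop() if len(lengths) == 1 else 0)
    missing = [g for g in genes if g not in profiles]
    if missing:
        raise ValueError(f"no switch profile for gene(s): {missing[:5]}")
    paths = np.stack([profiles[g].path for g in genes])
    counts = paths.sum(axis=0).astype(float)
    if n_windows:
        counts = np.array([w.mean() for w in np.array_split(counts, n_windows)])
    return counts
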