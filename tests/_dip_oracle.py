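"""Exact small-n oracle for the dip statistic, independent of switchmodal.dip.

The dip of F_n is min over unimodal CDFs G of sup_x |F_n(x) - G(x)|.  For a
sample with unique values x_0 < ... < x_{m-1} and cumulative fractions C_k,
the mode of G either sits at a value x_j (where an atom is allowed) or at a
position m* inside an open gap (x_{j-1}, x_j).  For a fixed mode position
the sup-norm fit at half-width d is a linear feasibility problem in the
values v_k = G(x_k) (plus the left limit and post-jump value at the mode):

  value band       C_k - d <= v_k <= C_{k-1} + d   (the jump at the mode
                   relaxes the upper bound there to C_j + d)
  monotonicity     v_k <= v_{k+1}, 0 <= v <= 1
  convexity        chord slopes non-decreasing along the branch up to the
                   mode's left limit, including a distant virtual anchor
                   (x_0 - W, 0) enforcing G -> 0
  concavity        chord slopes non-increasing from the mode rightwards

Minimising d per mode with an LP gives that mode's exact optimum.  Atom
modes are enumerated exactly; gap modes are scanned on a grid, so the
reported ``dip_lp_bounds`` are (lower, upper) with

  lower = min over atom LPs and junction-relaxed gap LPs  <=  dip
  upper = min over atom LPs and gridded gap LPs           >=  dip

and the two coincide whenever the optimal mode is (a limit of) an atom.
"""

import numpy as np
from scipy.optimize import linprog


def _solve(x, C, Cprev, W, j, mode_x=None, relax_gap=False):
    """Min d for mode at x_j (mode_x None) or at mode_x in (x_{j-1}, x_j)."""
    m = len(x)
    # variables: v_0..v_{m-1}, L (left limit at mode), H (value at mode), d
    iL, iH, iD = m, m + 1, m + 2
    A_ub, b_ub = [], []

    def con(coefs, rhs):
        row = np.zeros(m + 3)
        for k, c in coefs:
            row[k] += c
        A_ub.append(row)
        b_ub.append(rhs)

    atom = mode_x is None
    for k in range(m):
        con([(k, -1.0), (iD, -1.0)], -C[k])  # v_k >= C_k - d
        upper = C[j] if (atom and k == j) else Cprev[k]
        con([(k, 1.0), (iD, -1.0)], upper)   # v_k <= upper + d
    for k in range(m - 1):
        con([(k, 1.0), (k + 1, -1.0)], 0.0)

    xL = x[j] if atom else mode_x
    left = [(-W + x[0], None)] + [(x[k], k) for k in range(j)]
    if j >= 1 and not relax_gap:
        left.append((xL, iL))
        con([(j - 1, 1.0), (iL, -1.0)], 0.0)    # v_{j-1} <= L
        con([(iL, 1.0), (iD, -1.0)], Cprev[j])  # L <= C_{j-1} + d
        if atom:
            con([(iL, 1.0), (j, -1.0)], 0.0)    # L <= v_j
    for (xa, ka), (xb, kb), (xc, kc) in zip(left, left[1:], left[2:]):
        coefs = [(kb, (xc - xb) + (xb - xa)), (kc, -(xb - xa))]
        if ka is not None:
            coefs.append((ka, -(xc - xb)))
        con(coefs, 0.0)

    right = [(x[k], k) for k in range(j, m)]
    if not atom and not relax_gap:
        right = [(mode_x, iH)] + right
        con([(iL, 1.0), (iH, -1.0)], 0.0)       # L <= H (jump up at mode)
        con([(iH, 1.0), (j, -1.0)], 0.0)        # H <= v_j
        con([(iH, 1.0), (iD, -1.0)], Cprev[j])  # H <= C_{j-1} + d
        con([(iH, -1.0), (iD, -1.0)], -Cprev[j])  # H >= C_{j-1} - d
    for (xa, ka), (xb, kb), (xc, kc) in zip(right, right[1:], right[2:]):
        coefs = [(kb, -((xc - xb) + (xb - xa))), (kc, (xb - xa))]
        if ka is not None:
            coefs.append((ka, (xc - xb)))
        con(coefs, 0.0)

    c = np.zeros(m + 3)
    c[iD] = 1.0
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  bounds=[(0.0, 1.0)] * (m + 2) + [(0.0, 0.5)], method="highs")
    return res.fun if res.status == 0 else np.inf


def dip_lp_bounds(sample: np.ndarray, n_grid: int = 15) -> tuple[float, float]:
    x, counts = np.unique(np.asarray(sample, dtype=float), return_counts=True)
    m = x.size
    if m == 1:
        return 0.0, 0.0
    C = np.cumsum(counts) / counts.sum()
    Cprev = np.concatenate([[0.0], C[:-1]])
    W = 1000.0 * (x[-1] - x[0] + 1.0)

    lower = upper = np.inf
    for j in range(m):
        d_atom = _solve(x, C, Cprev, W, j)
        lower = min(lower, d_atom)
        upper = min(upper, d_atom)
        if j >= 1:
            lower = min(lower, _solve(x, C, Cprev, W, j, mode_x=0.5 * (x[j - 1] + x[j]),
                                      relax_gap=True))
            for t in np.linspace(0.001, 0.999, n_grid):
                mx = x[j - 1] + t * (x[j] - x[j - 1])
                upper = min(upper, _solve(x, C, Cprev, W, j, mode_x=mx))
    return float(lower), float(upper)
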