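"""Hartigan's dip statistic and Monte-Carlo calibrated dip test.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and the class of unimodal distribution functions
(convex below the mode, concave above it, with an atom allowed only at the
mode).  It is the basis of Hartigan & Hartigan's test of unimodality: large
dips indicate that no single-mode distribution fits the sample.

The statistic is computed on the count scale with the classic iterative
greatest-convex-minorant / least-concave-majorant (GCM/LCM) construction:
the candidate modal interval is shrunk until the gap between the two hull
curves no longer exceeds the fitting error outside the interval, and the
dip is half the largest one-sided deviation, divided by n.

P-values are calibrated by Monte-Carlo simulation against the n-sample
Uniform(0,1) null (the conventional, slightly conservative reference for
continuous data).  Null tables are cached per sample size so that scanning
thousands of genes at a common cell count costs one table.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue", "DipCalibrator"]


def _lower_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull of (x, y), x non-decreasing."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # pop b if it lies on or above segment a->i
            if (x[i] - x[a]) * (y[b] - y[a]) >= (x[b] - x[a]) * (y[i] - y[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=np.intp)


def _upper_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (x[i] - x[a]) * (y[b] - y[a]) <= (x[b] - x[a]) * (y[i] - y[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=np.intp)


def _interp_on_hull(x: np.ndarray, touch: np.ndarray, i: int, lower: bool) -> float:
    """Value of the piecewise-linear hull curve (through counts) at point i.

    ``touch`` holds absolute indices of hull vertices (ascending).  Vertical
    segments (tied x) are evaluated from the left for the GCM (lowest value)
    and from the right for the LCM (highest value).
    """
    pos = int(np.searchsorted(touch, i))
    if pos < len(touch) and touch[pos] == i:
        return float(touch[pos] + 1)  # count at a touch vertex is index+1
    a, b = touch[pos - 1], touch[pos]
    if x[b] == x[a]:
        return float((a if lower else b) + 1)
    t = (x[i] - x[a]) / (x[b] - x[a])
    return (a + 1) + t * (b - a)


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan's dip statistic of a 1-D sample.

    Parameters
    ----------
    values
        At least 4 finite observations.  Ties are allowed; a constant
        sample has the degenerate dip 0.

    Returns
    -------
    float
        The dip, in [0, 0.25].
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError(f"dip statistic requires n >= 4, got n={n}")
    if not np.isfinite(x).all():
        raise ValueError("dip statistic requires finite values")
    if x[0] == x[-1]:
        return 0.0

    counts = np.arange(1.0, n + 1.0)  # ECDF upper corners, count scale
    low, high = 0, n - 1
    D = 1.0  # count-scale dip*2n lower bound: any sample fits within 1/(2n)

    for _ in range(n):
        xs = x[low : high + 1]
        cs = counts[low : high + 1]
        gcm = _lower_hull(xs, cs) + low  # absolute indices, ascending
        lcm = _upper_hull(xs, cs) + low

        # largest gap between the LCM curve (upper corners) and the GCM
        # curve shifted to lower corners, over the current interval
        d = 0.0
        ig_lo, ih_hi = low, high
        if len(gcm) > 2 or len(lcm) > 2:
            for li in lcm:
                g_at = _interp_on_hull(x, gcm, int(li), lower=True)
                gap = (li + 1) + 1.0 - g_at
                if gap > d:
                    d = gap
                    pos = int(np.searchsorted(gcm, li, side="right")) - 1
                    ig_lo = int(gcm[max(pos, 0)])
                    ih_hi = int(li)
            for g in gcm:
                l_at = _interp_on_hull(x, lcm, int(g), lower=False)
                gap = l_at - ((g + 1) - 1.0)
                if gap > d:
                    d = gap
                    ig_lo = int(g)
                    pos = int(np.searchsorted(lcm, g, side="left"))
                    ih_hi = int(lcm[min(pos, len(lcm) - 1)])
        else:
            d = 1.0

        if d <= D:
            break

        # fitting error of the ECDF against the hulls outside [ig_lo, ih_hi]
        dip_l = 0.0
        for i in range(low, ig_lo + 1):
            dev = (i + 1) + 1.0 - _interp_on_hull(x, gcm, i, lower=True)
            if dev > dip_l:
                dip_l = dev
        dip_u = 0.0
        for i in range(ih_hi, high + 1):
            dev = _interp_on_hull(x, lcm, i, lower=False) - ((i + 1) - 1.0)
            if dev > dip_u:
                dip_u = dev
        D = max(D, dip_l, dip_u)

        if (ig_lo, ih_hi) == (low, high):
            break
        low, high = ig_lo, ih_hi

    return D / (2.0 * n)


class DipCalibrator:
    """Monte-Carlo null tables of the dip statistic, cached per sample size.

    The dip test's null reference is the n-sample Uniform(0,1) distribution.
    A table of ``n_boot`` null dips is simulated once per distinct n and
    reused for every gene with that cell count.
    """

    def __init__(self, n_boot: int = 2000, seed: int = 0):
        if n_boot < 1:
            raise ValueError("n_boot must be positive")
        self.n_boot = int(n_boot)
        self.seed = int(seed)
        self._tables: dict[int, np.ndarray] = {}

    def null_table(self, n: int) -> np.ndarray:
        if n not in self._tables:
            rng = np.random.default_rng((self.seed, n))
            tab = np.array(
                [dip_statistic(rng.random(n)) for _ in range(self.n_boot)]
            )
            tab.sort()
            self._tables[n] = tab
        return self._tables[n]

    def pvalue(self, dip: float, n: int) -> float:
        """P(dip_null >= dip) with the standard +1 Monte-Carlo correction."""
        tab = self.null_table(n)
        n_ge = tab.size - int(np.searchsorted(tab, dip, side="left"))
        return (1.0 + n_ge) / (self.n_boot + 1.0)


def dip_pvalue(
    values: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    calibrator: DipCalibrator | None = None,
) -> tuple[float, float]:
    """Dip statistic and Monte-Carlo p-value of a sample.

    A constant sample (dip 0) has p = 1 by convention.  Pass a shared
    :class:`DipCalibrator` when testing many genes of equal length.
    """
    x = np.asarray(values, dtype=float)
    d = dip_statistic(x)
    if d == 0.0:
        return 0.0, 1.0
    if calibrator is None:
        calibrator = DipCalibrator(n_boot=n_boot, seed=seed)
    return d, calibrator.pvalue(d, x.size)
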