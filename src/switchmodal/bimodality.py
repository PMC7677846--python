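"""Bimodal gene detection from a zero-inflated lognormal mixture.

A gene toggling between an inactive (OFF) and an active (ON) transcriptional
state has logTPM values drawn from a mixture

    ln(Y + 1)  ~  delta(0) + N(mu'_OFF, sigma_OFF^2) + N(mu'_ON, sigma_ON^2)

where the point mass at zero collects cells in which the transcript is
absent or undetected.  Adding a small Gaussian noise N(0, eps^2) to the
transformed values turns the point mass into a narrow Gaussian that the
smallest-mean component of an ordinary Gaussian mixture can absorb, so the
whole model is fit as a 2- or 3-center mixture on noised logTPM.

Genes are screened with Hartigan's dip test (Monte-Carlo calibrated
p-values); those with dip p below ``p_cut`` and a smallest component mean
below ``mu1_max`` (OFF states live below logTPM 1) are called bimodal.  The
noise level eps is a tuning parameter: too little leaves the zero point
mass degenerate, too much blurs the valley between states, and the sweep in
:func:`optimize_noise` picks the eps that maximises the number of bimodal
genes detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .dip import DipCalibrator, dip_statistic

__all__ = [
    "MixtureFit",
    "add_noise",
    "fit_mixture",
    "select_bimodal",
    "detect_bimodal",
    "optimize_noise",
]

_SIGMA_FLOOR = 1e-4
_MAX_ITER = 500
_TOL = 1e-8


@dataclass
class MixtureFit:
    """Per-gene dip test result and sorted Gaussian-mixture parameters."""

    gene_id: str
    dip: float
    dip_p: float
    n_components: int
    means: np.ndarray       # ascending
    sds: np.ndarray
    weights: np.ndarray     # sum to 1
    epsilon: float
    is_bimodal: bool = False
    failed: bool = False
    threshold_hint: float | None = field(default=None)

    @property
    def mu1(self) -> float:
        return float(self.means[0])

    @property
    def lambda1(self) -> float:
        return float(self.weights[0])


def add_noise(values: np.ndarray, epsilon: float, seed: int) -> np.ndarray:
    """Add i.i.d. N(0, epsilon^2) noise; epsilon=0 returns the input copy."""
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    values = np.asarray(values, dtype=float)
    if epsilon == 0:
        return values.copy()
    rng = np.random.default_rng(seed)
    return values + rng.normal(0.0, epsilon, size=values.shape)


def fit_mixture(
    values: np.ndarray,
    n_components: int,
    seed: int = 0,
    gene_id: str = "",
    epsilon: float = 0.0,
    n_restarts: int = 3,
) -> MixtureFit:
    """EM fit of a K-center Gaussian mixture on (noised) logTPM values.

    Components are returned sorted by mean.  Initialization is k-means with
    the given seed; a fit whose smallest sd collapses to the floor after all
    restarts is flagged ``failed``.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if n_components not in (2, 3):
        raise ValueError("n_components must be 2 or 3")
    if x.size < 10 * n_components:
        raise ValueError(f"need at least {10 * n_components} values for K={n_components}")

    best = None
    failed = True
    for r in range(n_restarts):
        import warnings

        with warnings.catch_warnings():
            # the tight tol deliberately lets EM run to max_iter on some genes
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            gm = GaussianMixture(
                n_components=n_components,
                covariance_type="diag",
                reg_covar=_SIGMA_FLOOR**2,
                tol=_TOL,
                max_iter=_MAX_ITER,
                init_params="k-means++",
                random_state=seed + r,
            ).fit(x)
        if best is None or gm.lower_bound_ > best.lower_bound_:
            best = gm
        # sds are floored at _SIGMA_FLOOR by reg_covar (a zero-inflation
        # spike legitimately sits on the floor); the EM failure mode left to
        # detect is a component starved of weight or non-finite parameters
        if (gm.weights_ > 1.0 / x.size).all() and np.isfinite(gm.means_).all():
            failed = False
            break

    order = np.argsort(best.means_.ravel())
    return MixtureFit(
        gene_id=gene_id,
        dip=np.nan,
        dip_p=np.nan,
        n_components=n_components,
        means=best.means_.ravel()[order],
        sds=np.sqrt(best.covariances_.ravel())[order],
        weights=best.weights_[order],
        epsilon=epsilon,
        failed=failed,
    )


def _fit_best_k(values, seed, gene_id, epsilon) -> MixtureFit:
    """Fit K=2 and K=3, keep the BIC-preferred fit."""
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    fits = {}
    bics = {}
    for k in (2, 3):
        if x.size < 10 * k:
            continue
        fit = fit_mixture(values, k, seed=seed, gene_id=gene_id, epsilon=epsilon)
        gm_bic = _bic(x, fit)
        fits[k], bics[k] = fit, gm_bic
    k_best = min(bics, key=bics.get)
    return fits[k_best]


def _bic(x: np.ndarray, fit: MixtureFit) -> float:
    n = x.size
    from scipy.stats import norm

    dens = np.zeros(n)
    for m, s, w in zip(fit.means, fit.sds, fit.weights):
        dens += w * norm.pdf(x.ravel(), m, s)
    ll = np.log(np.clip(dens, 1e-300, None)).sum()
    n_par = 3 * fit.n_components - 1
    return -2 * ll + n_par * np.log(n)


def select_bimodal(
    fits: list[MixtureFit],
    p_cut: float = 0.01,
    mu1_max: float = 1.0,
    lambda1_max: float | None = None,
) -> list[str]:
    """Genes with dip p < p_cut and smallest component mean < mu1_max.

    ``lambda1_max`` switches on the legacy additional criterion that the
    smallest component's weight stays below the given bound (0.6 in the
    method's early form); by default only the dip/mean rule is applied.
    """
    out = []
    for f in fits:
        ok = (not f.failed) and f.dip_p < p_cut and f.mu1 < mu1_max
        if ok and lambda1_max is not None:
            ok = f.lambda1 < lambda1_max
        f.is_bimodal = bool(ok)
        if ok:
            out.append(f.gene_id)
    return out


def detect_bimodal(
    logtpm: pd.DataFrame,
    epsilon: float = 1e-5,
    seed: int = 0,
    p_cut: float = 0.01,
    mu1_max: float = 1.0,
    lambda1_max: float | None = None,
    n_boot: int = 2000,
    calibrator: DipCalibrator | None = None,
    fit_mixtures: bool = True,
) -> tuple[list[str], dict[str, MixtureFit]]:
    """Run the full per-gene bimodality screen on a logTPM matrix.

    Noise is added once to the whole matrix (a single realization shared by
    all genes), then each gene is dip-tested and, when the dip is at all
    informative, mixture-fitted with K chosen by BIC.

    Returns the selected gene ids and all per-gene fits.
    """
    if calibrator is None:
        calibrator = DipCalibrator(n_boot=n_boot, seed=seed + 1)
    noised = add_noise(logtpm.to_numpy(), epsilon, seed)
    n_cells = noised.shape[1]

    fits: dict[str, MixtureFit] = {}
    for i, gene in enumerate(logtpm.index):
        row = noised[i]
        d = dip_statistic(row)
        p = 1.0 if d == 0.0 else calibrator.pvalue(d, n_cells)
        if p < p_cut and fit_mixtures:
            fit = _fit_best_k(row, seed, gene, epsilon)
        else:
            # not a candidate: skip the EM, record a placeholder 2-center fit
            fit = MixtureFit(gene, d, p, 2,
                             means=np.array([row.mean(), row.mean()]),
                             sds=np.array([row.std() + _SIGMA_FLOOR] * 2),
                             weights=np.array([0.5, 0.5]), epsilon=epsilon)
        fit.dip, fit.dip_p = d, p
        fits[gene] = fit

    selected = select_bimodal(
        list(fits.values()), p_cut=p_cut, mu1_max=mu1_max, lambda1_max=lambda1_max
    )
    return selected, fits


def optimize_noise(
    logtpm: pd.DataFrame,
    epsilon_grid: list[float],
    seed: int = 0,
    **kwargs,
) -> tuple[float, pd.Series]:
    """Sweep the added-noise sd over a grid; return the eps maximizing the
    number of bimodal genes (ties -> smallest eps) and the full count curve."""
    if not len(epsilon_grid):
        raise ValueError("epsilon grid must be nonempty")
    counts = {}
    calibrator = DipCalibrator(n_boot=kwargs.pop("n_boot", 2000), seed=seed + 1)
    for eps in epsilon_grid:
        selected, _ = detect_bimodal(
            logtpm, epsilon=eps, seed=seed, calibrator=calibrator,
            fit_mixtures=kwargs.get("fit_mixtures", True), **{
                k: v for k, v in kwargs.items() if k != "fit_mixtures"},
        )
        counts[eps] = len(selected)
    curve = pd.Series(counts).sort_index()
    best = curve.index[np.argmax(curve.to_numpy())]  # first argmax = smallest eps
    return float(best), curve
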