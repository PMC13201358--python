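"""Predictive-accuracy evaluation of polygenic scores.

The accuracy of a score is its incremental R-squared: the gain in
variance explained when the PRS is added to a covariate-only base model
(ordinary least squares for quantitative traits, logistic regression
with a correlation-based observed-scale R-squared for binary traits).
Binary-trait estimates are converted to the liability scale with the
Lee et al. (2012) transformation given the population prevalence K and
the sample case proportion P.  Uncertainty comes from the percentile
bootstrap over individuals (default 1000 replicates, 95% interval).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AccuracyResult",
    "incremental_r2",
    "liability_r2",
    "lee_conversion_factor",
    "observed_to_liability",
    "bootstrap_ci",
    "relative_accuracy_observed",
]


@dataclass
class AccuracyResult:
    """Incremental R-squared with its bootstrap 95% interval."""

    r2_incremental: float
    scale: str  # "observed" or "liability"
    ci_low: float = np.nan
    ci_high: float = np.nan
    n: int = 0
    n_boot: int = 0

    def __repr__(self) -> str:  # compact, table-friendly
        ci = ""
        if np.isfinite(self.ci_low):
            ci = f", 95% CI [{self.ci_low:.4g}, {self.ci_high:.4g}]"
        return f"AccuracyResult(R2={self.r2_incremental:.4g} [{self.scale}]{ci}, n={self.n})"


def _design(covariates: np.ndarray | None, n: int, *extra: np.ndarray) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    for e in extra:
        cols.append(np.asarray(e, dtype=float)[:, None])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear columns in the design; least-squares fit uses "
                      "the minimum-norm solution (R2 is unaffected)")
    return X


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 0.0
    return 1.0 - float(resid @ resid) / tss


def _logistic_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Observed-scale R2 for a binary trait: squared Pearson correlation
    between the outcome and the fitted probabilities of an (unpenalized)
    logistic regression."""
    from sklearn.linear_model import LogisticRegression

    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
    model.fit(X[:, 1:] if X.shape[1] > 1 else np.zeros((len(y), 1)), y)
    p = model.predict_proba(X[:, 1:] if X.shape[1] > 1 else np.zeros((len(y), 1)))[:, 1]
    if p.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(y, p)[0, 1] ** 2)


def _incremental(y: np.ndarray, prs: np.ndarray, covariates: np.ndarray | None,
                 binary: bool) -> float:
    n = len(y)
    r2_fn = _logistic_r2 if binary else _ols_r2
    base = r2_fn(y, _design(covariates, n))
    full = r2_fn(y, _design(covariates, n, prs))
    return full - base


def incremental_r2(phenotype: np.ndarray, prs: np.ndarray,
                   covariates: np.ndarray | None = None,
                   n_boot: int = 0, seed: int | None = None) -> AccuracyResult:
    """Incremental R-squared of the PRS over the covariate-only model.

    Negative values (sampling noise around a null score) are reported as
    computed, not truncated, so the bootstrap interval stays valid.  A
    constant PRS yields exactly 0 with a warning.
    """
    y = np.asarray(phenotype, dtype=float)
    prs = np.asarray(prs, dtype=float)
    if len(y) != len(prs):
        raise ValueError("phenotype and PRS lengths differ")
    if prs.std() == 0:
        warnings.warn("constant PRS: incremental R2 is 0")
        return AccuracyResult(0.0, "observed", n=len(y))
    est = _incremental(y, prs, covariates, binary=False)
    lo = hi = np.nan
    if n_boot:
        lo, hi = bootstrap_ci(
            lambda idx: _incremental(y[idx], prs[idx],
                                     None if covariates is None else np.asarray(covariates)[idx],
                                     binary=False),
            len(y), n_boot=n_boot, seed=seed)
    return AccuracyResult(est, "observed", lo, hi, n=len(y), n_boot=n_boot)


def lee_conversion_factor(K: float, P: float | None = None) -> float:
    """Multiplier taking an observed-scale R2 to the liability scale
    (Lee et al. 2012): ``K^2 (1-K)^2 / (z^2 P (1-P))`` with ``z`` the
    standard-normal density at the liability threshold ``Phi^-1(1-K)``.
    For a population sample ``P = K`` and the factor reduces to
    ``K(1-K)/z^2``."""
    if not 0.0 < K < 1.0:
        raise ValueError("prevalence K must lie in (0, 1)")
    if P is None:
        P = K
    if not 0.0 < P < 1.0:
        raise ValueError("case proportion P must lie in (0, 1)")
    z = stats.norm.pdf(stats.norm.ppf(1.0 - K))
    return K ** 2 * (1.0 - K) ** 2 / (z ** 2 * P * (1.0 - P))


def observed_to_liability(r2_observed: float, K: float, P: float | None = None) -> float:
    return r2_observed * lee_conversion_factor(K, P)


def liability_r2(binary_phenotype: np.ndarray, prs: np.ndarray,
                 covariates: np.ndarray | None = None,
                 prevalence_K: float | None = None,
                 n_boot: int = 0, seed: int | None = None) -> AccuracyResult:
    """Liability-scale incremental R-squared for a binary trait.

    The observed-scale increment comes from logistic regressions with and
    without the PRS; it is then multiplied by the Lee conversion factor.
    ``prevalence_K`` defaults to the sample case proportion (appropriate
    for a population-based cohort).
    """
    y = np.asarray(binary_phenotype, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary phenotype must be coded 0/1")
    P = float(y.mean())
    K = P if prevalence_K is None else float(prevalence_K)
    factor = lee_conversion_factor(K, P)
    prs = np.asarray(prs, dtype=float)
    if prs.std() == 0:
        warnings.warn("constant PRS: incremental R2 is 0")
        return AccuracyResult(0.0, "liability", n=len(y))
    est = factor * _incremental(y, prs, covariates, binary=True)
    lo = hi = np.nan
    if n_boot:
        def stat(idx):
            yb = y[idx]
            if yb.min() == yb.max():  # no cases (or no controls) in replicate
                return np.nan
            fb = lee_conversion_factor(K, float(yb.mean()))
            return fb * _incremental(yb, prs[idx],
                                     None if covariates is None else np.asarray(covariates)[idx],
                                     binary=True)
        lo, hi = bootstrap_ci(stat, len(y), n_boot=n_boot, seed=seed)
    return AccuracyResult(est, "liability", lo, hi, n=len(y), n_boot=n_boot)


def bootstrap_ci(statistic_fn: Callable[[np.ndarray], float], n: int,
                 n_boot: int = 1000, seed: int | None = None,
                 alpha: float = 0.05, max_redraw: int = 100) -> tuple[float, float]:
    """Percentile bootstrap interval for a statistic of ``n`` individuals.

    ``statistic_fn`` receives an index array (a resample with replacement)
    and returns the statistic on that replicate.  Replicates on which the
    statistic is undefined (NaN) are redrawn with a logged count.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    n_redraw = 0
    for b in range(n_boot):
        for _ in range(max_redraw):
            idx = rng.integers(0, n, size=n)
            v = statistic_fn(idx)
            if np.isfinite(v):
                vals[b] = v
                break
            n_redraw += 1
        else:
            raise RuntimeError("statistic undefined on every redraw")
    if n_redraw:
        logger.info("bootstrap: redrew %d undefined replicates", n_redraw)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def relative_accuracy_observed(result_target: AccuracyResult,
                               result_discovery: AccuracyResult) -> float:
    """Observed relative accuracy: target-population R2 over discovery-
    population R2 for the same score on the same scale."""
    if result_target.scale != result_discovery.scale:
        raise ValueError("results must be on the same scale")
    if result_discovery.r2_incremental <= 0:
        raise ValueError("relative accuracy undefined: discovery R2 <= 0")
    return result_target.r2_incremental / result_discovery.r2_incremental
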