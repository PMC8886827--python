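"""Two-component Gaussian mixture on M-values and the high/low boundary.

Pooled array M-values are strongly bimodal (an unmethylated and a methylated
peak) even when the beta histogram is compressed against 0 and 1. Fitting a
two-component univariate Gaussian mixture by EM and taking the point between
the component means where the two weighted component densities are equal
(the Bayes decision boundary) yields a principled high/low methylation
cutoff, which is then mapped back to the beta scale.

EM is initialized deterministically from a median split of the data, so the
fit does not depend on a random start; the seed only drives optional
subsampling of very large pooled vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import DomainError, FitError
from .meth_transforms import m_to_beta

logger = logging.getLogger(__name__)

_MIN_VALUES = 100
_MIN_SD = 1e-6
_MIN_WEIGHT = 1e-4


@dataclass
class MixtureFit:
    """Fitted two-component Gaussian mixture plus its decision boundary.

    Components are ordered so ``means[0] < means[1]`` (unmethylated peak
    first). ``boundary_m`` is the equal-weighted-density point between the
    means; ``boundary_beta`` is its image under the logistic M->beta map.
    """

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    boundary_m: float
    boundary_beta: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)


def _log_density(x: np.ndarray, means, sds, weights) -> np.ndarray:
    """Per-observation, per-component weighted log density, shape (n, 2)."""
    x = x[:, None]
    mu = np.asarray(means)[None, :]
    sd = np.asarray(sds)[None, :]
    w = np.asarray(weights)[None, :]
    return (np.log(w) - 0.5 * np.log(2 * np.pi) - np.log(sd)
            - 0.5 * ((x - mu) / sd) ** 2)


def fit_m_mixture(m_values, seed: int = 0, max_iter: int = 500,
                  tol: float = 1e-8, subsample: int | None = None) -> MixtureFit:
    """Fit the two-component mixture by EM; deterministic given ``seed``.

    ``tol`` is the relative log-likelihood change declaring convergence.
    The log-likelihood is asserted non-decreasing at every iteration.
    Raises ``FitError`` on degenerate fits (component sd < 1e-6 or weight
    < 1e-4), which signals too little or constant data.
    """
    x = np.asarray(m_values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < _MIN_VALUES:
        raise FitError(f"need >= {_MIN_VALUES} finite M-values, got {x.size}")
    if subsample is not None and x.size > subsample:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=subsample, replace=False)
    if np.ptp(x) < 1e-12:
        raise FitError("all M-values identical; mixture fit is degenerate "
                       "(provide more varied data)")

    # deterministic initialization: split at the median
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # heavy ties at the median
        lo, hi = x[x < med], x[x >= med]
    means = np.array([lo.mean(), hi.mean()])
    sds = np.array([max(lo.std(), 0.05), max(hi.std(), 0.05)])
    weights = np.array([lo.size, hi.size], dtype=float) / x.size

    trace: list[float] = []
    loglik = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_comp = _log_density(x, means, sds, weights)
        log_norm = logsumexp(log_comp, axis=1)
        new_loglik = float(log_norm.sum())
        # EM guarantees monotone likelihood; tolerate only rounding noise
        assert new_loglik >= loglik - 1e-8 * max(1.0, abs(loglik)), \
            "EM log-likelihood decreased"
        trace.append(new_loglik)
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk / x.size < _MIN_WEIGHT):
            raise FitError("mixture component weight collapsed; need more data")
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(sds < _MIN_SD):
            raise FitError("mixture component variance collapsed; need more data")
        weights = nk / x.size
        if np.isfinite(loglik) and \
                abs(new_loglik - loglik) <= tol * max(1.0, abs(loglik)):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    fit = MixtureFit(
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        weights=(float(weights[0]), float(weights[1])),
        boundary_m=np.nan, boundary_beta=np.nan,
        loglik=loglik, n_iter=n_iter, converged=converged,
        loglik_trace=trace,
    )
    fit.boundary_m, fit.boundary_beta = decision_boundary(fit)
    return fit


def decision_boundary(fit: MixtureFit) -> tuple[float, float]:
    """Equal-weighted-density point between the two component means.

    Solves w1*N(x; m1, s1) = w2*N(x; m2, s2) for x in (m1, m2) — a quadratic
    in x (linear when the variances agree; the plain midpoint when both
    variances and weights agree). If no root lies strictly between the means
    (possible for extreme weight/variance imbalance), the weight-averaged
    mean is returned with a logged warning.
    """
    (m1, m2), (s1, s2), (w1, w2) = fit.means, fit.sds, fit.weights
    a = 0.5 / s2 ** 2 - 0.5 / s1 ** 2
    b = m1 / s1 ** 2 - m2 / s2 ** 2
    c = (m2 ** 2 / (2 * s2 ** 2) - m1 ** 2 / (2 * s1 ** 2)
         + np.log((w1 * s2) / (w2 * s1)))
    if abs(a) < 1e-14:  # equal variances: linear equation
        roots = [] if abs(b) < 1e-14 else [-c / b]
    else:
        disc = b * b - 4 * a * c
        roots = [] if disc < 0 else [(-b + s * np.sqrt(disc)) / (2 * a) for s in (+1, -1)]
    inside = [r for r in roots if m1 < r < m2]
    if inside:
        boundary_m = float(inside[0])
    else:
        boundary_m = float(w1 * m1 + w2 * m2)
        logger.warning("no density crossing between component means; "
                       "falling back to weighted midpoint %.4f", boundary_m)
    return boundary_m, float(m_to_beta(boundary_m))


def choose_beta_threshold(fit: MixtureFit | None = None,
                          override: float | None = None) -> float:
    """Working beta threshold: override if given, else boundary rounded to 2 dp.

    Rounding to two decimals turns a fitted boundary such as 0.205 into the
    practical cutoff 0.2 used for classification.
    """
    if override is not None:
        if not 0 < override < 1:
            raise DomainError(f"beta threshold override {override} outside (0, 1)")
        return float(override)
    if fit is None:
        raise DomainError("need a mixture fit or an override")
    return round(float(fit.boundary_beta), 2)
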