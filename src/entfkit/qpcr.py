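"""qPCR standard-curve quantification and censored-normal ML fitting.

Absolute copy numbers come from a serial-dilution standard curve,
``Cq = intercept + slope * log10(copies)`` (slope near -3.32 at 100 %
efficiency).  Samples whose Cq sits close to the limit of detection
yield replicate sets in which some reactions are known only to lie
below the LOD; those are treated as left-censored observations and the
sample mean/SD on the log10-copies scale is recovered by maximum
likelihood, with the censored reactions contributing the normal-CDF
term::

    LL(mu, sigma) = sum_uncensored log( phi((x - mu)/sigma) / sigma )
                    + n_censored * log( Phi((lod - mu)/sigma) )

The number of below-LOD reactions is known (replicates are counted), so
the data are censored rather than truncated.  Censoring is modeled on
the log10-copies scale by default; a Cq-scale fit works identically
because the two scales are affinely related.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "StandardCurve",
    "CqObservation",
    "CensoredNormalFit",
    "fit_standard_curve",
    "cq_to_copies",
    "copies_to_cq",
    "censored_ml",
    "censored_loglik",
]


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Cq on log10(copies) over a serial dilution."""

    slope: float      # Cq per log10 copies; negative
    intercept: float  # Cq at 1 copy
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class CqObservation:
    """One qPCR reaction: a Cq value, or a censored below-LOD record."""

    cq: float | None
    censored: bool
    lod_log10_copies: float

    def __post_init__(self) -> None:
        if self.censored and self.cq is not None:
            raise ValueError("censored observations carry no Cq value")
        if not self.censored and self.cq is None:
            raise ValueError("uncensored observations need a Cq value")


@dataclass(frozen=True)
class CensoredNormalFit:
    mean: float
    sd: float
    loglik: float
    n_censored: int
    converged: bool


def fit_standard_curve(
    copies: Sequence[float], cq: Sequence[float]
) -> StandardCurve:
    """Least-squares standard curve from a serial dilution (>= 3 points)."""
    x = np.asarray(copies, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.size != y.size:
        raise ValueError("copies and cq must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 dilution points")
    if np.any(x <= 0):
        raise ValueError("copy numbers must be positive")
    res = stats.linregress(np.log10(x), y)
    return StandardCurve(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def cq_to_copies(cq: float, curve: StandardCurve, scale: float = 1.0) -> float:
    """Copies per unit from a Cq value: ``scale * 10^((cq-b)/m)``.

    ``scale`` converts reaction copies to the reporting basis (e.g.
    elution volume over input mass for copies per gram of feces).
    """
    if curve.slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    return scale * 10.0 ** ((cq - curve.intercept) / curve.slope)


def copies_to_cq(copies: float, curve: StandardCurve) -> float:
    if copies <= 0:
        raise ValueError("copy number must be positive")
    return curve.intercept + curve.slope * math.log10(copies)


def censored_loglik(
    mu: float, sigma: float, observed: np.ndarray, n_censored: int, lod: float
) -> float:
    """Left-censored normal log-likelihood at (mu, sigma)."""
    if sigma <= 0:
        return -math.inf
    ll = float(np.sum(stats.norm.logpdf(observed, loc=mu, scale=sigma)))
    if n_censored:
        ll += n_censored * float(stats.norm.logcdf(lod, loc=mu, scale=sigma))
    return ll


def censored_ml(
    observations: Sequence[CqObservation] | Sequence[float],
    lod: float | None = None,
    censored: Sequence[bool] | None = None,
    tol: float = 1e-8,
) -> CensoredNormalFit:
    """ML mean/SD from left-censored observations on the log10-copies scale.

    Accepts either :class:`CqObservation` records (already on the
    log10-copies scale via a standard curve, with per-record LOD) or a
    plain value array plus ``lod`` and an optional ``censored`` mask.
    Optimization is a derivative-free simplex over (mu, log sigma) from
    moment-based starting values; non-convergence is flagged, never
    silent.
    """
    if len(observations) and isinstance(observations[0], CqObservation):
        obs_records = list(observations)
        lods = {o.lod_log10_copies for o in obs_records}
        if lod is None:
            if len(lods) != 1:
                raise ValueError("records carry differing LODs; pass lod explicitly")
            lod = lods.pop()
        observed = np.array([o.cq for o in obs_records if not o.censored], float)
        n_cens = sum(o.censored for o in obs_records)
        n_total = len(obs_records)
    else:
        values = np.asarray(observations, dtype=float)
        if lod is None:
            raise ValueError("lod is required for plain value input")
        mask = (
            np.asarray(censored, dtype=bool)
            if censored is not None else values < lod
        )
        observed = values[~mask]
        n_cens = int(mask.sum())
        n_total = values.size
    if n_total < 3:
        raise ValueError("need at least 3 observations")
    if observed.size == 0:
        raise ValueError("all observations censored; mean/SD not estimable")

    mu0 = float(observed.mean())
    sd0 = float(observed.std(ddof=1)) if observed.size > 1 else 1.0
    sd0 = max(sd0, 1e-3)

    def nll(theta: np.ndarray) -> float:
        return -censored_loglik(theta[0], math.exp(theta[1]), observed, n_cens, lod)

    res = optimize.minimize(
        nll, x0=np.array([mu0, math.log(sd0)]), method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": tol, "maxiter": 5000},
    )
    mu, sigma = float(res.x[0]), float(math.exp(res.x[1]))
    return CensoredNormalFit(
        mean=mu, sd=sigma, loglik=-float(res.fun),
        n_censored=n_cens, converged=bool(res.success),
    )
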