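"""Metabolite-formation, permeability, and serum-kinetics estimators.

Three fits cover the in vitro / in vivo kinetics of the pipeline:

* first-order metabolite formation ``F(t) = F_inf * (1 - exp(-k t))``,
  whose reported quantity is the *initial* formation rate
  ``r = F_inf * k`` in % min^-1;
* apparent permeability ``P_app = (dQ/dt) / (A * C0)`` from cumulative
  Transwell receiver amounts, with the standard correction for the
  volume removed (and replaced with buffer) at each prior sampling;
* a biexponential serum profile fitted phase-wise by log-linear
  regression — a distribution/early phase over 0–30 min giving
  ``(A, alpha)`` and a terminal phase over 30–x min giving ``(B, beta)``
  — with a closed-form daily-exposure integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy import stats

__all__ = [
    "TimeCourse",
    "FormationFit",
    "PermeabilityFit",
    "BiexpProfile",
    "fit_formation",
    "fit_papp",
    "cumulative_amounts",
    "fit_biexponential",
    "exposure",
    "exposure_ratio",
]


@dataclass(frozen=True)
class TimeCourse:
    """A (time, response) series with a unit tag.

    Units used by the fitters: ``percent_formed`` (formation),
    ``receiver_conc_mol_per_ul`` or ``amount_mol`` (Transwell),
    ``nM`` (serum concentration).
    """

    times: tuple[float, ...]  # min
    responses: tuple[float, ...]
    unit: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if t.size != r.size:
            raise ValueError("times and responses must have equal length")
        if t.size == 0:
            raise ValueError("empty time course")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "responses", tuple(float(x) for x in r))

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.responses)


@dataclass(frozen=True)
class FormationFit:
    k: float            # min^-1
    f_inf: float        # % of initial substrate
    rate: float         # initial slope F_inf * k, % min^-1
    sse: float


@dataclass(frozen=True)
class PermeabilityFit:
    slope: float        # dQ/dt, mol s^-1
    area: float         # cm^2
    c0: float           # mol cm^-3
    papp: float         # cm s^-1
    intercept: float


@dataclass(frozen=True)
class BiexpProfile:
    A: float            # nM
    alpha: float        # min^-1
    B: float            # nM
    beta: float         # min^-1
    breakpoint: float = 30.0  # min


def fit_formation(tc: TimeCourse) -> FormationFit:
    """Least-squares fit of first-order formation; rate = F_inf * k.

    All-zero responses return the degenerate fit k = 0, rate = 0;
    negative responses are rejected.
    """
    t, y = tc.t, tc.y
    if t.size < 4:
        raise ValueError("need at least 4 time points for the formation fit")
    if np.any(y < 0):
        raise ValueError("formation responses must be non-negative")
    if np.all(y == 0):
        return FormationFit(k=0.0, f_inf=0.0, rate=0.0, sse=0.0)

    def model(tt: np.ndarray, f_inf: float, k: float) -> np.ndarray:
        return f_inf * (1.0 - np.exp(-k * tt))

    f0 = max(float(y.max()), 1e-9)
    # crude initial k from the earliest nonzero response
    nz = np.nonzero(y)[0]
    i0 = nz[0] if t[nz[0]] > 0 else (nz[1] if nz.size > 1 else nz[0])
    k0 = min(max(y[i0] / (f0 * max(t[i0], 1e-9)), 1e-6), 1.0)
    popt, _ = curve_fit(
        model, t, y, p0=(f0, k0),
        bounds=((0.0, 0.0), (np.inf, np.inf)), maxfev=20000,
    )
    f_inf, k = float(popt[0]), float(popt[1])
    sse = float(np.sum((model(t, f_inf, k) - y) ** 2))
    return FormationFit(k=k, f_inf=f_inf, rate=f_inf * k, sse=sse)


def cumulative_amounts(
    concentrations: Sequence[float],
    receiver_volume_ul: float,
    sample_volume_ul: float,
) -> np.ndarray:
    """Sampling-corrected cumulative transported amounts (mol).

    ``Q_k = C_k * V_receiver + sum_{j<k} C_j * V_sample`` — the amount in
    the receiver at sampling k plus everything carried away by earlier
    aliquots.  Concentrations are per microliter of receiver fluid.
    """
    c = np.asarray(concentrations, dtype=float)
    removed = np.concatenate(([0.0], np.cumsum(c[:-1] * sample_volume_ul)))
    return c * receiver_volume_ul + removed


def fit_papp(
    tc: TimeCourse,
    area_cm2: float = 1.12,
    c0_mol_per_cm3: float = 1e-9,
    sample_volume_ul: float = 300.0,
    receiver_volume_ul: float = 1500.0,
) -> PermeabilityFit:
    """Apparent permeability from a Transwell time course.

    If the time course carries receiver concentrations
    (``receiver_conc_mol_per_ul``), they are first converted to
    sampling-corrected cumulative amounts; ``amount_mol`` responses are
    used as-is.  P_app = slope(Q vs t_seconds) / (A * C0), in cm s^-1.
    """
    if area_cm2 <= 0 or c0_mol_per_cm3 <= 0:
        raise ValueError("area and donor concentration must be positive")
    if tc.t.size < 3:
        raise ValueError("need at least 3 sampling points")
    if tc.unit == "amount_mol":
        q = tc.y
    else:
        q = cumulative_amounts(tc.y, receiver_volume_ul, sample_volume_ul)
    t_s = tc.t * 60.0
    slope, intercept, _, _, _ = stats.linregress(t_s, q)
    return PermeabilityFit(
        slope=float(slope), area=area_cm2, c0=c0_mol_per_cm3,
        papp=float(slope) / (area_cm2 * c0_mol_per_cm3),
        intercept=float(intercept),
    )


def fit_biexponential(tc: TimeCourse, breakpoint: float = 30.0) -> BiexpProfile:
    """Phase-wise log-linear fit of a biexponential serum profile.

    Points with t <= breakpoint feed ``ln C = ln A - alpha t``; points
    with t > breakpoint feed ``ln C = ln B - beta t``.  The breakpoint is
    fixed (default 30 min), not estimated.
    """
    t, y = tc.t, tc.y
    early = t <= breakpoint
    late = t > breakpoint
    if early.sum() < 2 or late.sum() < 2:
        raise ValueError("need at least 2 points in each phase")
    if np.any(y[early | late] <= 0):
        raise ValueError("concentrations must be positive for log-linear fitting")
    sa, ia, _, _, _ = stats.linregress(t[early], np.log(y[early]))
    sb, ib, _, _, _ = stats.linregress(t[late], np.log(y[late]))
    return BiexpProfile(
        A=float(np.exp(ia)), alpha=float(-sa),
        B=float(np.exp(ib)), beta=float(-sb),
        breakpoint=breakpoint,
    )


def exposure(profile: BiexpProfile, x: float) -> float:
    """Closed-form exposure integral over [0, x] minutes, in nM*min.

    ``A/alpha * (1 - exp(-alpha*bp)) + B/beta * (exp(-beta*bp) - exp(-beta*x))``
    with bp the phase breakpoint (30 min).
    """
    if profile.alpha <= 0 or profile.beta <= 0:
        raise ValueError("decay constants must be positive")
    bp = profile.breakpoint
    if x < bp:
        raise ValueError(f"exposure window must extend past the {bp}-min breakpoint")
    first = profile.A / profile.alpha * (1.0 - math.exp(-profile.alpha * bp))
    second = profile.B / profile.beta * (
        math.exp(-profile.beta * bp) - math.exp(-profile.beta * x)
    )
    return first + second


def exposure_ratio(
    treated: BiexpProfile, endogenous_conc_nm: float, window_min: float = 1440.0
) -> float:
    """Treated daily exposure over a constant endogenous exposure (fold).

    The endogenous exposure is modeled as a constant serum level over the
    window: ``endogenous_conc * window``.
    """
    if endogenous_conc_nm <= 0:
        raise ValueError("endogenous concentration must be positive")
    return exposure(treated, window_min) / (endogenous_conc_nm * window_min)
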