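"""Positivity rules for calling EntF* present in a chromatographic feature.

Four instrument methods are supported.  The two low-resolution MRM
methods (``LC1MS1``, reversed-phase; ``LC2MS1``, HILIC) judge a feature
on retention time, quantifier/qualifier area ratio, signal-to-noise,
and — for the serum RP method only — a concentration above the limit of
quantification.  The two high-resolution methods (``LC1MS2``, Q-TOF;
``LC1MS3``, Q-Orbitrap) require a minimum number of matched daughter
ions and isotope peaks of the precursor within an m/z tolerance.

All inputs are already-integrated features; no raw signal processing
happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LOWRES_METHODS",
    "HIGHRES_METHODS",
    "ChromFeatureRecord",
    "PositivityCriteria",
    "DetectionResult",
    "criteria_for",
    "classify_lowres",
    "classify_highres",
    "classify",
    "summarize_serum",
    "match_ions",
]

LOWRES_METHODS = ("LC1MS1", "LC2MS1")
HIGHRES_METHODS = ("LC1MS2", "LC1MS3")


@dataclass(frozen=True)
class ChromFeatureRecord:
    """One candidate detection event for a single analyte."""

    method: str
    retention_time: float  # min
    quantifier_area: float = 0.0
    qualifier_area: float = 0.0
    quantifier_sn: float = 0.0
    qualifier_sn: float = 0.0
    concentration_pm: float | None = None
    daughter_mzs: tuple[float, ...] = ()
    isotope_mzs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in LOWRES_METHODS + HIGHRES_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.retention_time <= 0:
            raise ValueError("retention time must be positive")
        for name in ("quantifier_area", "qualifier_area",
                     "quantifier_sn", "qualifier_sn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PositivityCriteria:
    rt_window: tuple[float, float]
    ratio_bounds: tuple[float, float] = (2.0, 4.0)
    sn_threshold: float = 3.0
    loq_pm: float | None = 100.0  # None disables the concentration rule
    hr_mz_tolerance: float = 0.05
    min_daughters: int = 4
    min_isotopes: int = 3

    def __post_init__(self) -> None:
        if self.rt_window[0] >= self.rt_window[1]:
            raise ValueError("rt_window must be an increasing interval")
        if self.ratio_bounds[0] >= self.ratio_bounds[1]:
            raise ValueError("ratio_bounds must be ordered")
        if self.hr_mz_tolerance <= 0:
            raise ValueError("m/z tolerance must be positive")


#: Per-method defaults: retention-time windows and ion-count thresholds.
_DEFAULT_CRITERIA: dict[str, PositivityCriteria] = {
    # serum RP-MRM: RT 4.25-4.45 min, ratio 2-4, S/N > 3, conc > 100 pM
    "LC1MS1": PositivityCriteria(rt_window=(4.25, 4.45), loq_pm=100.0),
    # HILIC-MRM: same rules, RT 4.85-4.95 min, no concentration rule
    "LC2MS1": PositivityCriteria(rt_window=(4.85, 4.95), loq_pm=None),
    # Q-TOF: >=4 daughters and >=3 isotope parent peaks within +/-0.05
    "LC1MS2": PositivityCriteria(
        rt_window=(3.40, 3.50), hr_mz_tolerance=0.05,
        min_daughters=4, min_isotopes=3,
    ),
    # Q-Orbitrap: >=2 daughters and >=4 isotope peaks within +/-0.005
    "LC1MS3": PositivityCriteria(
        rt_window=(4.13, 4.16), hr_mz_tolerance=0.005,
        min_daughters=2, min_isotopes=4,
    ),
}


def criteria_for(method: str) -> PositivityCriteria:
    """Default positivity criteria for one of the four methods."""
    try:
        return _DEFAULT_CRITERIA[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}") from None


@dataclass(frozen=True)
class DetectionResult:
    positive: bool
    failed_rules: frozenset[str]

    def __post_init__(self) -> None:
        assert self.positive == (not self.failed_rules)


def _result(failed: set[str]) -> DetectionResult:
    return DetectionResult(positive=not failed, failed_rules=frozenset(failed))


def classify_lowres(
    record: ChromFeatureRecord, criteria: PositivityCriteria | None = None
) -> DetectionResult:
    """Apply the MRM positivity rules to a low-resolution feature.

    Rule identifiers: ``retention_time``, ``ratio`` (quantifier/qualifier
    area ratio outside bounds), ``ratio_undefined`` (qualifier area zero),
    ``sn_quantifier``, ``sn_qualifier``, ``loq``.
    """
    if record.method not in LOWRES_METHODS:
        raise ValueError(f"classify_lowres expects one of {LOWRES_METHODS}")
    if criteria is None:
        criteria = criteria_for(record.method)
    failed: set[str] = set()
    lo, hi = criteria.rt_window
    if not lo <= record.retention_time <= hi:
        failed.add("retention_time")
    if record.qualifier_area == 0:
        failed.add("ratio_undefined")
    else:
        ratio = record.quantifier_area / record.qualifier_area
        if not criteria.ratio_bounds[0] <= ratio <= criteria.ratio_bounds[1]:
            failed.add("ratio")
    if not record.quantifier_sn > criteria.sn_threshold:
        failed.add("sn_quantifier")
    if not record.qualifier_sn > criteria.sn_threshold:
        failed.add("sn_qualifier")
    if criteria.loq_pm is not None:
        conc = record.concentration_pm
        if conc is None or not conc > criteria.loq_pm:
            failed.add("loq")
    return _result(failed)


def match_ions(
    observed: Sequence[float], reference: Sequence[float], tolerance: float
) -> int:
    """Count reference ions matched by observed ions within a tolerance.

    Greedy: reference ions are processed in ascending m/z order; each
    takes the nearest unused observed ion within the tolerance, ties
    broken toward the lower observed m/z.
    """
    if not reference:
        raise ValueError("reference ion list must be non-empty")
    obs = sorted(observed)
    used = [False] * len(obs)
    matched = 0
    for ref in sorted(reference):
        best_k = -1
        best_d = math.inf
        for k, o in enumerate(obs):
            if used[k]:
                continue
            d = abs(o - ref)
            # strict < keeps the lower observed m/z on ties
            if d <= tolerance and d < best_d:
                best_d = d
                best_k = k
        if best_k >= 0:
            used[best_k] = True
            matched += 1
    return matched


def classify_highres(
    record: ChromFeatureRecord,
    criteria: PositivityCriteria | None = None,
    reference_daughters: Sequence[float] = (),
    reference_isotopes: Sequence[float] = (),
) -> DetectionResult:
    """Apply the high-resolution positivity rules.

    Rule identifiers: ``retention_time``, ``daughters`` (too few matched
    daughter ions), ``isotopes`` (too few matched isotope parent peaks).
    The reference ion lists are caller-supplied.
    """
    if record.method not in HIGHRES_METHODS:
        raise ValueError(f"classify_highres expects one of {HIGHRES_METHODS}")
    if criteria is None:
        criteria = criteria_for(record.method)
    if not reference_daughters or not reference_isotopes:
        raise ValueError("reference daughter and isotope ion lists are required")
    failed: set[str] = set()
    lo, hi = criteria.rt_window
    if not lo <= record.retention_time <= hi:
        failed.add("retention_time")
    tol = criteria.hr_mz_tolerance
    if match_ions(record.daughter_mzs, reference_daughters, tol) < criteria.min_daughters:
        failed.add("daughters")
    if match_ions(record.isotope_mzs, reference_isotopes, tol) < criteria.min_isotopes:
        failed.add("isotopes")
    return _result(failed)


def classify(
    record: ChromFeatureRecord,
    criteria: PositivityCriteria | None = None,
    reference_daughters: Sequence[float] = (),
    reference_isotopes: Sequence[float] = (),
) -> DetectionResult:
    """Dispatch to the low- or high-resolution rule set by record method."""
    if record.method in LOWRES_METHODS:
        return classify_lowres(record, criteria)
    return classify_highres(record, criteria, reference_daughters, reference_isotopes)


def summarize_serum(
    concentrations: Sequence[float], loq: float
) -> tuple[float, float, int, int]:
    """Mean/SEM of serum concentrations with below-LOQ values set to zero.

    Returns ``(mean, sem, n, n_above_loq)``.  Values below the LOQ are
    replaced by zero before the mean and SEM are formed; ``n_above_loq``
    counts values at or above the LOQ.  SEM is NaN for n = 1.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("need at least one concentration")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    clipped = np.where(conc < loq, 0.0, conc)
    n = conc.size
    mean = float(clipped.mean())
    sem = float(clipped.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return mean, sem, n, int(np.sum(conc >= loq))
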