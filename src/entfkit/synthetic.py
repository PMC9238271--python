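"""Seeded generators emulating the statistical structure of each assay.

Every generator is a pure function of its arguments: the same seed and
parameters give bit-identical output.  One global seed expands into
fixed per-scenario substreams, so adding a scenario never perturbs the
draws of an existing one.

Default parameters are the study conditions of the assays they emulate:
formation rates 1.71 % min^-1 (feces, n=4) and 0.11 % min^-1 (colon,
n=7) on the 0-180 min sampling grid; Transwell P_app 3.67e-9 cm s^-1
(area 1.12 cm^2, 1 uM donor, 300 uL aliquots from a 1500 uL receiver at
30/60/90/120 min, n=6); a biexponential serum profile whose 24-h
exposure integral encodes a 5-fold ratio over a constant 0.329 nM
endogenous level; blot intensities with placebo 100 %, active peptide
62 %, and planted analog effects (positions 1/2/10 placebo-like 95 %,
3/9 intermediate 80 %, others active-like 65 %); and log10-copy qPCR
draws left-censored at the detection limit with six replicates per
sample.  Noise models: additive Gaussian with SD a fraction of the
noiseless dynamic range for time courses (default 2 %), multiplicative
lognormal for blot intensities (default CV 10 %), Gaussian on the
log10-copies scale for qPCR.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .detection import ChromFeatureRecord, criteria_for
from .kinetics import BiexpProfile, TimeCourse, exposure
from .alascan import BlotMeasurement
from .qpcr import CqObservation
from . import peptides

__all__ = [
    "scenario_rng",
    "gen_metabolization",
    "gen_transwell",
    "gen_pk_profile",
    "pk_params_for_ratio",
    "gen_blots",
    "gen_cq",
    "gen_chrom_records",
    "SCENARIOS",
]

# fixed substream keys; append-only so existing scenarios stay stable
_SCENARIO_KEYS = {
    "metabolization": 1,
    "transwell": 2,
    "pk_profile": 3,
    "blots": 4,
    "cq": 5,
    "chrom_records": 6,
}


def scenario_rng(seed: int, scenario: str) -> np.random.Generator:
    """Deterministic per-scenario substream of a single global seed."""
    if scenario not in _SCENARIO_KEYS:
        raise ValueError(f"unknown scenario {scenario!r}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_SCENARIO_KEYS[scenario],))
    return np.random.default_rng(ss)


def _check_noise(sd: float) -> None:
    if sd < 0:
        raise ValueError("noise SD must be non-negative")


def gen_metabolization(
    seed: int,
    rate: float = 1.71,
    f_inf: float = 100.0,
    n: int = 4,
    times: Sequence[float] = (0, 5, 10, 30, 60, 120, 180),
    noise_frac: float = 0.02,
) -> list[TimeCourse]:
    """First-order formation curves, % of initial substrate, plus noise.

    ``rate`` is the initial slope F_inf * k in % min^-1 (so
    k = rate / F_inf); noise SD is ``noise_frac`` of the noiseless
    dynamic range.  Responses are floored at zero, as measured
    percentages are.
    """
    if rate <= 0 or n < 1:
        raise ValueError("rate must be positive and n >= 1")
    _check_noise(noise_frac)
    rng = scenario_rng(seed, "metabolization")
    t = np.asarray(times, dtype=float)
    k = rate / f_inf
    model = f_inf * (1.0 - np.exp(-k * t))
    sd = noise_frac * (model.max() - model.min())
    out = []
    for i in range(n):
        y = np.clip(model + rng.normal(0.0, sd, size=t.size), 0.0, None)
        out.append(TimeCourse(tuple(t), tuple(y), unit="percent_formed",
                              replicate=f"rep{i+1}"))
    return out


def gen_transwell(
    seed: int,
    papp: float = 3.67e-9,
    area_cm2: float = 1.12,
    c0_mol_per_cm3: float = 1e-9,
    n: int = 6,
    times: Sequence[float] = (30, 60, 90, 120),
    receiver_volume_ul: float = 1500.0,
    sample_volume_ul: float = 300.0,
    noise_frac: float = 0.02,
) -> list[TimeCourse]:
    """Transwell receiver concentrations with volume-replacement effects.

    A constant flux ``papp * A * C0`` (sink conditions) fills the
    receiver; at each sampling a ``sample_volume`` aliquot is withdrawn
    and replaced with buffer, diluting the receiver.  Responses are the
    measured receiver concentrations (mol per uL) at each sampling.
    """
    if papp <= 0 or area_cm2 <= 0 or c0_mol_per_cm3 <= 0:
        raise ValueError("papp, area, and C0 must be positive")
    t = np.asarray(times, dtype=float)
    if t.size < 3 or np.any(np.diff(t) <= 0) or t[0] <= 0:
        raise ValueError("sampling grid must be >= 3 strictly increasing positive times")
    _check_noise(noise_frac)
    rng = scenario_rng(seed, "transwell")
    flux = papp * area_cm2 * c0_mol_per_cm3  # mol / s
    out = []
    conc_true = np.empty(t.size)
    amount = 0.0
    prev_t = 0.0
    for idx, tk in enumerate(t):
        amount += flux * (tk - prev_t) * 60.0
        conc_true[idx] = amount / receiver_volume_ul
        amount *= 1.0 - sample_volume_ul / receiver_volume_ul
        prev_t = tk
    sd = noise_frac * (conc_true.max() - conc_true.min())
    for i in range(n):
        y = np.clip(conc_true + rng.normal(0.0, sd, size=t.size), 0.0, None)
        out.append(TimeCourse(tuple(t), tuple(y),
                              unit="receiver_conc_mol_per_ul",
                              replicate=f"run{i+1}"))
    return out


def pk_params_for_ratio(
    ratio: float = 5.0,
    endogenous_nm: float = 0.329,
    window_min: float = 1440.0,
    alpha: float = 0.05,
    beta: float = 0.01,
    a_over_b: float = 100.0 / 60.0,
) -> BiexpProfile:
    """Biexponential parameters whose exposure encodes a target ratio.

    Keeps the phase shape (alpha, beta, A/B) fixed and scales the
    amplitudes so ``exposure(profile, window) == ratio * endogenous *
    window``.
    """
    base = BiexpProfile(A=a_over_b, alpha=alpha, B=1.0, beta=beta)
    scale = ratio * endogenous_nm * window_min / exposure(base, window_min)
    return BiexpProfile(A=a_over_b * scale, alpha=alpha, B=scale, beta=beta)


def gen_pk_profile(
    seed: int,
    profile: BiexpProfile | None = None,
    times: Sequence[float] = (5, 10, 15, 20, 25, 30, 45, 60, 90, 120, 150, 180),
    cv: float = 0.05,
) -> TimeCourse:
    """Noisy serum concentrations from a biexponential profile (nM).

    Early points (t <= breakpoint) follow ``A e^{-alpha t}``, later ones
    ``B e^{-beta t}``; measurement noise is multiplicative lognormal
    with the given CV.
    """
    if profile is None:
        profile = pk_params_for_ratio()
    _check_noise(cv)
    rng = scenario_rng(seed, "pk_profile")
    t = np.asarray(times, dtype=float)
    conc = np.where(
        t <= profile.breakpoint,
        profile.A * np.exp(-profile.alpha * t),
        profile.B * np.exp(-profile.beta * t),
    )
    if cv > 0:
        sdlog = math.sqrt(math.log(1.0 + cv * cv))
        conc = conc * np.exp(rng.normal(0.0, sdlog, size=t.size))
    return TimeCourse(tuple(t), tuple(conc), unit="nM", replicate="pk")


#: Planted analog effects: mean relative expression (%) per position.
_DEFAULT_BLOT_EFFECTS = {pos: 95.0 for pos in (1, 2, 10)}
_DEFAULT_BLOT_EFFECTS.update({pos: 80.0 for pos in (3, 9)})


def gen_blots(
    seed: int,
    n_per_group: int = 15,
    cv: float = 0.10,
    placebo_mean: float = 100.0,
    active_mean: float = 62.0,
    other_mean: float = 65.0,
    effects: dict[int, float] | None = None,
    n_positions: int = 15,
    placebo_group: str = "placebo",
    active_group: str = "EntF*",
    base_intensity: float = 10.0,
) -> list[BlotMeasurement]:
    """Lognormal blot lanes for a placebo / active / analog-scan design.

    Analog groups are labeled ``"1A"`` ... ``"<n>A"``.  Group means (as %
    of placebo) default to the planted importance structure; per-lane
    total-protein normalizers vary lognormally (CV 5 %) and intensities
    carry multiplicative lognormal noise with the given CV.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 lanes per group")
    _check_noise(cv)
    if effects is None:
        effects = dict(_DEFAULT_BLOT_EFFECTS)
    rng = scenario_rng(seed, "blots")
    group_means = {placebo_group: placebo_mean, active_group: active_mean}
    for pos in range(1, n_positions + 1):
        group_means[f"{pos}A"] = effects.get(pos, other_mean)
    sdlog = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    out = []
    for group, mean in group_means.items():
        for _ in range(n_per_group):
            normalizer = float(np.exp(rng.normal(0.0, 0.05)))
            signal = base_intensity * mean / 100.0
            if sdlog > 0:
                signal *= float(np.exp(rng.normal(0.0, sdlog)))
            out.append(BlotMeasurement(group=group,
                                       intensity=signal * normalizer,
                                       total_protein=normalizer))
    return out


def gen_cq(
    seed: int,
    mu: float = 5.0,
    sigma: float = 1.0,
    lod_log10: float = 4.5,
    n: int = 6,
) -> list[CqObservation]:
    """Normal log10-copy draws, left-censored at the detection limit.

    Values below ``lod_log10`` become censored records (no value, only
    the LOD), mirroring undetected qPCR replicates.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = scenario_rng(seed, "cq")
    draws = rng.normal(mu, sigma, size=n)
    return [
        CqObservation(cq=None, censored=True, lod_log10_copies=lod_log10)
        if x < lod_log10
        else CqObservation(cq=float(x), censored=False, lod_log10_copies=lod_log10)
        for x in draws
    ]


_LOWRES_RULES = ("retention_time", "ratio", "sn_quantifier", "sn_qualifier", "loq")
_HIGHRES_RULES = ("retention_time", "daughters", "isotopes")


def _entfstar_reference_ions() -> tuple[list[float], list[float]]:
    """Singly charged y/b reference daughters and doubly charged
    precursor isotope peaks of the bridged metabolite."""
    pep = peptides.ENTF_STAR
    daughters = [
        peptides.fragment_mz(pep, "b", 2),
        peptides.fragment_mz(pep, "b", 3),
        peptides.fragment_mz(pep, "y", 11),
        peptides.fragment_mz(pep, "y", 12),
        peptides.fragment_mz(pep, "y", 9),
        peptides.fragment_mz(pep, "y", 10),
    ]
    mono = peptides.monoisotopic_mass(pep)
    neutron = 1.00287  # average m/z spacing of peptide isotope peaks
    isotopes = [(mono + i * neutron + 2 * peptides.PROTON) / 2 for i in range(5)]
    return daughters, isotopes


def gen_chrom_records(
    seed: int,
    n: int = 10,
    method: str = "LC1MS1",
    violation: str | None = None,
) -> list[ChromFeatureRecord]:
    """Candidate detection records, all-pass by default.

    ``violation`` plants exactly one named rule breach in every record
    (one of ``retention_time``, ``ratio``, ``sn_quantifier``,
    ``sn_qualifier``, ``loq`` for the MRM methods; ``retention_time``,
    ``daughters``, ``isotopes`` for the high-resolution methods).
    """
    crit = criteria_for(method)
    if method in ("LC1MS1", "LC2MS1"):
        rules: tuple[str, ...] = _LOWRES_RULES
        if crit.loq_pm is None:  # HILIC serum criteria have no LOQ rule
            rules = tuple(r for r in rules if r != "loq")
    else:
        rules = _HIGHRES_RULES
    if violation is not None and violation not in rules:
        raise ValueError(f"unknown violation {violation!r} for method {method}")
    rng = scenario_rng(seed, "chrom_records")
    lo, hi = crit.rt_window
    records = []
    for _ in range(n):
        rt = float(rng.uniform(lo, hi))
        if violation == "retention_time":
            rt = hi + float(rng.uniform(0.5, 1.0))
        if method in ("LC1MS1", "LC2MS1"):
            ratio = float(rng.uniform(*crit.ratio_bounds))
            if violation == "ratio":
                ratio = crit.ratio_bounds[1] + float(rng.uniform(0.5, 2.0))
            qual_area = float(rng.uniform(1e3, 1e5))
            sn_q = float(rng.uniform(5.0, 50.0))
            sn_l = float(rng.uniform(5.0, 50.0))
            if violation == "sn_quantifier":
                sn_q = float(rng.uniform(0.1, crit.sn_threshold))
            if violation == "sn_qualifier":
                sn_l = float(rng.uniform(0.1, crit.sn_threshold))
            conc = float(rng.uniform(150.0, 1000.0))
            if violation == "loq":
                conc = float(rng.uniform(1.0, crit.loq_pm or 100.0))
            records.append(ChromFeatureRecord(
                method=method, retention_time=rt,
                quantifier_area=ratio * qual_area, qualifier_area=qual_area,
                quantifier_sn=sn_q, qualifier_sn=sn_l,
                concentration_pm=conc,
            ))
        else:
            daughters, isotopes = _entfstar_reference_ions()
            tol = crit.hr_mz_tolerance
            jitter = lambda mzs: tuple(
                float(m + rng.uniform(-0.3 * tol, 0.3 * tol)) for m in mzs
            )
            obs_d = jitter(daughters)
            obs_i = jitter(isotopes)
            if violation == "daughters":
                obs_d = obs_d[: crit.min_daughters - 1]
            if violation == "isotopes":
                obs_i = obs_i[: crit.min_isotopes - 1]
            records.append(ChromFeatureRecord(
                method=method, retention_time=rt,
                daughter_mzs=obs_d, isotope_mzs=obs_i,
            ))
    return records


SCENARIOS = {
    "metabolization": gen_metabolization,
    "transwell": gen_transwell,
    "pk_profile": gen_pk_profile,
    "blots": gen_blots,
    "cq": gen_cq,
    "chrom_records": gen_chrom_records,
}
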