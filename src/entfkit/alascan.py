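"""Alanine-scan importance ranking and the study's general statistics.

The scan compares normalized E-cadherin blot intensities between a
placebo group, the active peptide (EntF*), and one single-substitution
analog per position.  Post-ANOVA Fisher's-LSD p-values feed the combined
score

    score = (1 - p_placebo_vs_analog) * p_active_vs_analog

which is near zero when the analog behaves like placebo (substitution
abolished activity — the position matters) and near one when the analog
behaves like the active peptide.  Positions are then classified into K
importance classes by Ward hierarchical clustering of the scores, with
a Jenks natural-breaks assignment computed alongside as a cross-check;
class 1 (lowest scores) is the most important.

Because combined scores are products of p-values and span orders of
magnitude, clustering operates on a variance-stabilized significance
axis by default (see :func:`rank_positions`); linear, log10, and probit
axes are available as options.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "BlotMeasurement",
    "LSDTable",
    "ImportanceRanking",
    "normalize_blot",
    "anova_lsd",
    "combined_pscore",
    "jenks_breaks",
    "rank_positions",
    "scan_pipeline",
    "cohen_d",
    "hedges_g",
    "bootstrap_median_diff",
    "mann_whitney",
    "compare_slopes",
]

_PMIN = 1e-300  # guard for log10 of underflowed p-values


@dataclass(frozen=True)
class BlotMeasurement:
    """One lane: group label, band intensity, total-protein normalizer."""

    group: str
    intensity: float
    total_protein: float

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        if self.total_protein == 0:
            raise ValueError("total-protein normalizer must be non-zero")


def normalize_blot(
    measurements: Sequence[BlotMeasurement], placebo_group: str = "placebo"
) -> dict[str, list[float]]:
    """Per-lane relative expression (%) with the placebo mean at 100.

    Each lane's intensity is divided by its total-protein normalizer and
    the whole data set is rescaled so the placebo-group mean is 100 %.
    """
    groups: dict[str, list[float]] = {}
    for m in measurements:
        groups.setdefault(m.group, []).append(m.intensity / m.total_protein)
    if placebo_group not in groups:
        raise ValueError(f"no lanes with placebo group {placebo_group!r}")
    scale = 100.0 / float(np.mean(groups[placebo_group]))
    return {g: [v * scale for v in vals] for g, vals in groups.items()}


@dataclass(frozen=True)
class LSDTable:
    """Group means, pooled MSE, error df, and pairwise LSD p-values."""

    means: dict[str, float]
    ns: dict[str, int]
    mse: float
    df_error: int
    pairwise_p: dict[tuple[str, str], float]

    def p(self, a: str, b: str) -> float:
        key = (a, b) if (a, b) in self.pairwise_p else (b, a)
        return self.pairwise_p[key]


def anova_lsd(
    groups: Mapping[str, Sequence[float]],
    alternative: str = "two-sided",
) -> LSDTable:
    """One-way ANOVA with Fisher's-LSD pairwise comparisons.

    Every pair (i, j) is tested with
    ``t = (m_i - m_j) / sqrt(MSE * (1/n_i + 1/n_j))`` on N - k error
    degrees of freedom.  ``alternative`` may be ``two-sided``,
    ``greater`` (mean_i > mean_j), or ``less``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 observations")
    n_total = sum(a.size for a in arrays.values())
    k = len(arrays)
    df_error = n_total - k
    sse = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays.values())
    mse = sse / df_error
    if mse == 0:
        raise ValueError("degenerate ANOVA: all within-group values identical")
    means = {g: float(a.mean()) for g, a in arrays.items()}
    ns = {g: int(a.size) for g, a in arrays.items()}
    pairwise: dict[tuple[str, str], float] = {}
    for gi, gj in itertools.combinations(arrays, 2):
        se = math.sqrt(mse * (1.0 / ns[gi] + 1.0 / ns[gj]))
        t = (means[gi] - means[gj]) / se
        if alternative == "two-sided":
            p = 2.0 * stats.t.sf(abs(t), df_error)
        elif alternative == "greater":
            p = stats.t.sf(t, df_error)
        elif alternative == "less":
            p = stats.t.cdf(t, df_error)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        pairwise[(gi, gj)] = float(min(p, 1.0))
    return LSDTable(means=means, ns=ns, mse=mse, df_error=df_error,
                    pairwise_p=pairwise)


def combined_pscore(p_pbs_vs_ala: float, p_entf_vs_ala: float) -> float:
    """``(1 - p_placebo_vs_analog) * p_active_vs_analog``; low = important."""
    for name, p in (("p_pbs_vs_ala", p_pbs_vs_ala), ("p_entf_vs_ala", p_entf_vs_ala)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    return (1.0 - p_pbs_vs_ala) * p_entf_vs_ala


def jenks_breaks(values: Sequence[float], k: int) -> list[int]:
    """Jenks natural-breaks classification of 1-D values into k classes.

    Exact dynamic program (Fisher's optimal partitioning) minimizing the
    total within-class sum of squared deviations over contiguous classes
    of the sorted values.  Returns a 1-based class index per input value,
    classes numbered in ascending value order.  Deterministic.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    order = np.argsort(vals, kind="stable")
    x = vals[order]
    # within-class SSE of sorted slice [i, j] via prefix sums
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(i: int, j: int) -> float:  # inclusive endpoints, 0-based
        s = cs[j + 1] - cs[i]
        s2 = cs2[j + 1] - cs2[i]
        m = j - i + 1
        return s2 - s * s / m

    INF = math.inf
    # cost[c][j]: minimal SSE splitting x[0..j] into c classes
    cost = np.full((k + 1, n), INF)
    back = np.zeros((k + 1, n), dtype=int)
    for j in range(n):
        cost[1][j] = sse(0, j)
    for c in range(2, k + 1):
        for j in range(c - 1, n):
            best, arg = INF, c - 1
            for i in range(c - 1, j + 1):
                cand = cost[c - 1][i - 1] + sse(i, j)
                if cand < best:
                    best, arg = cand, i
            cost[c][j] = best
            back[c][j] = arg
    # recover class boundaries
    classes_sorted = np.zeros(n, dtype=int)
    j = n - 1
    for c in range(k, 0, -1):
        i = back[c][j] if c > 1 else 0
        classes_sorted[i : j + 1] = c
        j = i - 1
    out = np.zeros(n, dtype=int)
    out[order] = classes_sorted
    return out.tolist()


@dataclass(frozen=True)
class ImportanceRanking:
    """Per-position combined scores, importance classes, and multipliers.

    Class 1 holds the lowest (most important) scores.  ``multipliers``
    maps each position to the alignment weight its class confers:
    class 1 -> 3, class 2 -> 2, all others -> 1.
    ``jenks_disagreement`` lists positions where the Jenks natural-breaks
    assignment differs from the clustering-based classes.
    """

    scores: dict[int, float]
    classes: dict[int, int]
    k: int
    jenks_classes: dict[int, int]
    jenks_disagreement: tuple[int, ...]

    @property
    def multipliers(self) -> dict[int, int]:
        return {
            pos: 3 if c == 1 else (2 if c == 2 else 1)
            for pos, c in self.classes.items()
        }

    def positions_in_class(self, c: int) -> set[int]:
        return {pos for pos, cc in self.classes.items() if cc == c}


def _classification_values(raw: np.ndarray, scale: str) -> np.ndarray:
    if scale == "linear":
        return raw.copy()
    if scale == "log10":
        return np.log10(np.clip(raw, _PMIN, None))
    z = stats.norm.ppf(np.clip(raw, _PMIN, 1.0 - 1e-16))
    if scale == "probit":
        return z
    if scale == "root-probit":
        return np.sign(z) * np.sqrt(np.abs(z))
    raise ValueError(f"unknown scale {scale!r}")


def rank_positions(
    scores: Mapping[int, float], k: int = 5, scale: str = "root-probit"
) -> ImportanceRanking:
    """Classify positions into k importance classes from combined scores.

    Ward agglomerative clustering of the 1-D scores is cut at k clusters
    and classes are relabeled by ascending mean score; a Jenks
    natural-breaks assignment on the same values is computed as a
    confirmation, with any disagreement reported (never silently
    resolved).

    ``scale`` sets the axis on which classes are separated.  Combined
    scores are products of p-values: on the raw (``linear``) or
    ``log10`` axes their sampling spread varies wildly with magnitude,
    so class boundaries chase noise.  ``probit`` (normal-quantile,
    ``z = Phi^-1(score)``) equalizes the spread across magnitudes —
    a score's z sits near the underlying t statistic, whose sampling
    spread is about 1 everywhere.  The default ``root-probit``
    (``sign(z) * sqrt(|z|)``) additionally compresses the far tail so
    strongly significant groups form tight clusters and the class
    budget resolves structure among the weaker positions instead of
    sampling noise within the strong ones.
    """
    if len(scores) < k:
        raise ValueError(f"need at least k={k} positions, got {len(scores)}")
    positions = sorted(scores)
    raw = np.array([scores[p] for p in positions], dtype=float)
    if np.all(raw == raw[0]):
        raise ValueError("degenerate ranking: all combined scores identical")
    vals = _classification_values(raw, scale)
    Z = linkage(vals.reshape(-1, 1), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters 1..k by ascending mean value
    cluster_means = {
        lab: vals[labels == lab].mean() for lab in np.unique(labels)
    }
    order = sorted(cluster_means, key=cluster_means.get)
    relabel = {lab: i + 1 for i, lab in enumerate(order)}
    classes = {pos: relabel[lab] for pos, lab in zip(positions, labels)}
    jenks = dict(zip(positions, jenks_breaks(vals, k)))
    disagreement = tuple(p for p in positions if classes[p] != jenks[p])
    return ImportanceRanking(
        scores={p: float(scores[p]) for p in positions},
        classes=classes, k=k, jenks_classes=jenks,
        jenks_disagreement=disagreement,
    )


def scan_pipeline(
    measurements: Sequence[BlotMeasurement],
    placebo_group: str = "placebo",
    active_group: str = "EntF*",
    k: int = 5,
    scale: str = "root-probit",
) -> ImportanceRanking:
    """Full scan: normalize -> pooled ANOVA/LSD -> combined scores -> rank.

    Analog group labels must be ``"<position><residue>"`` (e.g. ``"1A"``);
    the leading integer is the 1-based query position.
    """
    rel = normalize_blot(measurements, placebo_group=placebo_group)
    table = anova_lsd(rel)
    scores: dict[int, float] = {}
    for g in rel:
        if g in (placebo_group, active_group):
            continue
        pos = int("".join(ch for ch in g if ch.isdigit()))
        scores[pos] = combined_pscore(table.p(placebo_group, g),
                                      table.p(active_group, g))
    return rank_positions(scores, k=k, scale=scale)


# ---------------------------------------------------------------------------
# general effect-size and hypothesis-test helpers


def cohen_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardized mean difference with the pooled standard deviation."""
    a, b = np.asarray(x, float), np.asarray(y, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def hedges_g(x: Sequence[float], y: Sequence[float]) -> float:
    """Small-sample-corrected Cohen's d: ``g = d * (1 - 3/(4n - 9))``."""
    n = len(x) + len(y)
    return cohen_d(x, y) * (1.0 - 3.0 / (4.0 * n - 9.0))


def bootstrap_median_diff(
    x: Sequence[float],
    y: Sequence[float],
    b: int = 1000,
    seed: int | None = None,
    ci: float = 95.0,
) -> tuple[float, tuple[float, float]]:
    """Median difference with a seeded percentile bootstrap CI.

    Each of the ``b`` iterations resamples both groups with replacement
    and records ``median(x*) - median(y*)``; the interval is the
    percentile CI of that distribution.
    """
    if b < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    a, c = np.asarray(x, float), np.asarray(y, float)
    if a.size < 2 or c.size < 2:
        raise ValueError("need at least 2 observations per group")
    rng = np.random.default_rng(seed)
    diffs = np.empty(b)
    for i in range(b):
        diffs[i] = np.median(rng.choice(a, a.size)) - np.median(rng.choice(c, c.size))
    lo, hi = np.percentile(diffs, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    point = float(np.median(a) - np.median(c))
    return point, (float(lo), float(hi))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration when both samples are small (min n < 10) and
    tie-free; otherwise the normal approximation with tie correction.
    All values tied across both groups gives p = 1.
    """
    a, c = np.asarray(x, float), np.asarray(y, float)
    if a.size < 1 or c.size < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, c])
    if np.all(combined == combined[0]):
        return float(a.size * c.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (min(a.size, c.size) < 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, c, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_slopes(
    times_a: Sequence[float], values_a: Sequence[float],
    times_b: Sequence[float], values_b: Sequence[float],
) -> tuple[float, float]:
    """t-test for equality of two linear-regression slopes.

    Pooled residual variance, ``df = n_a + n_b - 4``; returns
    ``(slope_a - slope_b, two-sided p)``.  Two noiseless series with
    identical slopes give p = 1.
    """
    ta, ya = np.asarray(times_a, float), np.asarray(values_a, float)
    tb, yb = np.asarray(times_b, float), np.asarray(values_b, float)
    if ta.size < 3 or tb.size < 3:
        raise ValueError("need at least 3 points per series")
    fit_a = stats.linregress(ta, ya)
    fit_b = stats.linregress(tb, yb)
    sxx_a = float(np.sum((ta - ta.mean()) ** 2))
    sxx_b = float(np.sum((tb - tb.mean()) ** 2))
    sse_a = float(np.sum((ya - (fit_a.intercept + fit_a.slope * ta)) ** 2))
    sse_b = float(np.sum((yb - (fit_b.intercept + fit_b.slope * tb)) ** 2))
    df = ta.size + tb.size - 4
    s2 = (sse_a + sse_b) / df
    diff = float(fit_a.slope - fit_b.slope)
    se = math.sqrt(s2 * (1.0 / sxx_a + 1.0 / sxx_b))
    if se == 0:
        return diff, (1.0 if diff == 0 else 0.0)
    t = diff / se
    return diff, float(2.0 * stats.t.sf(abs(t), df))
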