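"""Importance-weighted Smith-Waterman local alignment and ligand screen.

Local alignment with BLOSUM62 and affine gaps (a gap of length L costs
``open + extend * L``), extended with per-position weights on the query:
the substitution score of any residue aligned to a rank-1 query position
is multiplied by 3, to a rank-2 position by 2 (weights come from the
alanine-scan importance ranking).  "Aligned" means any non-gap residue
pair at the weighted position, identity or not.

Two weighting modes exist: ``dp`` (default) builds the weighted
position-specific score table into the dynamic program, so the optimum
is taken over adjusted scores; ``post`` finds the unweighted optimal
alignment and re-scores it with the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "ScreenResult",
    "blosum62",
    "weighted_matrix",
    "smith_waterman",
    "screen_ligands",
    "ENTF_STAR_MULTIPLIERS",
]

_NEG = float("-inf")

#: Default EntF* alignment weights from the alanine scan:
#: rank 1 (S1, N2, L10) -> x3; rank 2 (L3, S9) -> x2.
ENTF_STAR_MULTIPLIERS: dict[int, int] = {1: 3, 2: 3, 10: 3, 3: 2, 9: 2}


def blosum62() -> dict[tuple[str, str], float]:
    """BLOSUM62 as a plain symmetric dict keyed by residue pairs."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            out[(a, b)] = float(mat[a, b])
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties, and query-position weights.

    ``position_multipliers`` maps 1-based query positions to integer
    factors >= 1 (missing positions default to 1).
    """

    matrix: Mapping[tuple[str, str], float] | None = None
    gap_open: float = 10.0
    gap_extend: float = 0.5
    position_multipliers: Mapping[int, int] = field(default_factory=dict)
    mode: str = "dp"  # "dp" | "post"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if any(m < 1 for m in self.position_multipliers.values()):
            raise ValueError("position multipliers must be >= 1")
        if self.mode not in ("dp", "post"):
            raise ValueError(f"unknown weighting mode {self.mode!r}")
        if self.matrix is None:
            object.__setattr__(self, "matrix", blosum62())

    def multiplier(self, query_pos: int) -> int:
        return int(self.position_multipliers.get(query_pos, 1))


@dataclass(frozen=True)
class LocalAlignment:
    """An optimal local alignment with raw and importance-adjusted scores.

    ``pairs`` lists the aligned (query, subject) 1-based index pairs of
    the non-gap columns; gaps appear as breaks in the index progression.
    """

    query: str
    subject: str
    pairs: tuple[tuple[int, int], ...]
    raw_score: float
    adjusted_score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    def aligned_strings(self) -> tuple[str, str]:
        """Gapped query/subject strings over the aligned region."""
        q_out, s_out = [], []
        prev_q, prev_s = None, None
        for qi, sj in self.pairs:
            if prev_q is not None:
                for g in range(prev_q + 1, qi):
                    q_out.append(self.query[g - 1])
                    s_out.append("-")
                for g in range(prev_s + 1, sj):
                    q_out.append("-")
                    s_out.append(self.subject[g - 1])
            q_out.append(self.query[qi - 1])
            s_out.append(self.subject[sj - 1])
            prev_q, prev_s = qi, sj
        return "".join(q_out), "".join(s_out)


def weighted_matrix(
    query: str,
    scheme: ScoringScheme,
) -> np.ndarray:
    """Position-specific score table: ``table[i][aa] = mult(i+1) * matrix``.

    Rows follow the query (0-based); columns follow a fixed residue
    alphabet returned alongside via ``table.dtype.metadata`` — use
    :func:`position_score` for lookups instead.
    """
    alphabet = sorted({b for (_, b) in scheme.matrix})
    table = np.zeros((len(query), len(alphabet)))
    for i, q in enumerate(query):
        mult = scheme.multiplier(i + 1)
        for j, aa in enumerate(alphabet):
            if (q, aa) not in scheme.matrix:
                raise KeyError(f"residue pair ({q}, {aa}) not in matrix")
            table[i, j] = mult * scheme.matrix[(q, aa)]
    return table


def _pair_score(scheme: ScoringScheme, q: str, s: str, qpos: int, weighted: bool) -> float:
    try:
        base = scheme.matrix[(q, s)]
    except KeyError:
        raise KeyError(f"residue pair ({q}, {s}) not in substitution matrix") from None
    return base * (scheme.multiplier(qpos) if weighted else 1)


def _score_alignment(
    scheme: ScoringScheme,
    query: str,
    subject: str,
    pairs: Sequence[tuple[int, int]],
    weighted: bool,
) -> float:
    """Score an explicit alignment: pair scores minus affine gap costs."""
    total = 0.0
    prev_q, prev_s = None, None
    for qi, sj in pairs:
        if prev_q is not None:
            for gap_len in (qi - prev_q - 1, sj - prev_s - 1):
                if gap_len > 0:
                    total -= scheme.gap_open + scheme.gap_extend * gap_len
        total += _pair_score(scheme, query[qi - 1], subject[sj - 1], qi, weighted)
        prev_q, prev_s = qi, sj
    return total


def _sw_dp(
    query: str, subject: str, scheme: ScoringScheme, weighted: bool
) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Core affine-gap local DP; returns (best score, aligned pairs).

    Traceback preference on ties: diagonal > up (gap in subject) > left;
    the traceback starts from the highest-scoring cell, lowest query
    index first on ties.
    """
    n, m = len(query), len(subject)
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), _NEG)  # query residue against a gap
    Iy = np.full((n + 1, m + 1), _NEG)  # subject residue against a gap
    open_cost = scheme.gap_open + scheme.gap_extend
    for i in range(1, n + 1):
        qc = query[i - 1]
        for j in range(1, m + 1):
            s = _pair_score(scheme, qc, subject[j - 1], i, weighted)
            M[i, j] = max(0.0, max(M[i-1, j-1], Ix[i-1, j-1], Iy[i-1, j-1]) + s)
            Ix[i, j] = max(M[i-1, j] - open_cost, Ix[i-1, j] - scheme.gap_extend)
            Iy[i, j] = max(M[i, j-1] - open_cost, Iy[i, j-1] - scheme.gap_extend)
    best = float(M.max())
    if best <= 0:
        return 0.0, ()
    # lowest query index, then lowest subject index, among maximal cells
    bi, bj = np.argwhere(M == M.max())[0]
    pairs: list[tuple[int, int]] = []
    state, i, j = "M", int(bi), int(bj)
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] == 0:
                break
            pairs.append((i, j))
            prevs = (("M", M[i-1, j-1]), ("Ix", Ix[i-1, j-1]), ("Iy", Iy[i-1, j-1]))
            best_prev = max(v for _, v in prevs)
            state = next(st for st, v in prevs if v == best_prev)
            i, j = i - 1, j - 1
        elif state == "Ix":
            state = "M" if M[i-1, j] - open_cost >= Ix[i-1, j] - scheme.gap_extend else "Ix"
            i -= 1
        else:
            state = "M" if M[i, j-1] - open_cost >= Iy[i, j-1] - scheme.gap_extend else "Iy"
            j -= 1
    pairs.reverse()
    return best, tuple(pairs)


def smith_waterman(
    query: str, subject: str, scheme: ScoringScheme | None = None
) -> LocalAlignment:
    """Optimal local alignment under the (possibly weighted) scheme.

    In ``dp`` mode the DP optimizes the adjusted score directly and the
    raw score re-scores the found alignment without weights; in ``post``
    mode the DP optimizes the raw score and the adjustment re-scores the
    found alignment with weights.
    """
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    if scheme is None:
        scheme = ScoringScheme()
    weighted_dp = scheme.mode == "dp" and bool(scheme.position_multipliers)
    score, pairs = _sw_dp(query, subject, scheme, weighted=weighted_dp)
    if weighted_dp:
        adjusted = score
        raw = _score_alignment(scheme, query, subject, pairs, weighted=False)
    else:
        raw = score
        adjusted = (
            _score_alignment(scheme, query, subject, pairs, weighted=True)
            if pairs else 0.0
        )
        if not scheme.position_multipliers:
            adjusted = raw
    if pairs:
        q_span = (pairs[0][0], pairs[-1][0])
        s_span = (pairs[0][1], pairs[-1][1])
    else:
        q_span = s_span = (0, 0)
    return LocalAlignment(
        query=query, subject=subject, pairs=pairs,
        raw_score=float(raw), adjusted_score=float(adjusted),
        query_span=q_span, subject_span=s_span,
    )


@dataclass(frozen=True)
class ScreenResult:
    """Ligand domains ranked by adjusted alignment score, descending."""

    entries: tuple[tuple[str, str, LocalAlignment], ...]  # (name, seq, aln)

    def ranking(self) -> list[tuple[str, float, float]]:
        return [
            (name, aln.adjusted_score, aln.raw_score)
            for name, _, aln in self.entries
        ]


def screen_ligands(
    query: str,
    domains: Sequence[tuple[str, str]],
    scheme: ScoringScheme | None = None,
) -> ScreenResult:
    """Align the query to each candidate ligand domain and rank them.

    Sorting is by adjusted score descending; ties break alphabetically
    by domain name (stable for duplicates).
    """
    if not domains:
        raise ValueError("need at least one candidate domain")
    if scheme is None:
        scheme = ScoringScheme(position_multipliers=dict(ENTF_STAR_MULTIPLIERS))
    scored = [
        (name, seq, smith_waterman(query, seq, scheme)) for name, seq in domains
    ]
    scored.sort(key=lambda e: (-e[2].adjusted_score, e[0]))
    return ScreenResult(entries=tuple(scored))
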