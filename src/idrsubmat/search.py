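"""Local-alignment search with E-values, desk-scale SSEARCH stand-in.

Smith-Waterman with affine gaps: the first residue of a gap costs ``open``
and each further residue ``extend`` (total open + (k-1)*extend for a gap of
length k, the FASTA/SSEARCH -f/-g convention; both penalties are negative).
Statistical significance follows the extreme-value behaviour of optimal
local scores on unrelated sequences: per query, the score distribution
against the database is fit to a Gumbel by the method of moments (top 2%
trimmed to censor true homologs) and E = db_size * P(S >= s) under that fit.
Rankings, not absolute E-values, are the contract; externally produced
SSEARCH tabular output can be ingested instead via :mod:`idrsubmat.io`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .io import HitRecord, ProteinSequence
from .matrices import ScoringMatrix

EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap penalties (negative): first gap residue ``open``, rest ``extend``."""

    open: int
    extend: int

    def __post_init__(self) -> None:
        if not (self.open <= self.extend < 0):
            raise ValueError(
                f"require open <= extend < 0, got open={self.open} extend={self.extend}"
            )


@dataclass(frozen=True)
class LocalAlignment:
    raw_score: int
    aligned_query: str
    aligned_subject: str
    q_span: tuple[int, int]  # 0-based half-open on the query
    s_span: tuple[int, int]
    identities: int

    @property
    def length(self) -> int:
        return len(self.aligned_query)


@dataclass(frozen=True)
class GumbelFit:
    """Location/scale of a Gumbel fit to a raw-score sample."""

    mu: float
    beta: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"Gumbel scale must be positive, got {self.beta}")


@dataclass(frozen=True)
class SearchResult:
    query_id: str
    hits: tuple[HitRecord, ...]
    db_size: int


@njit(cache=True)
def _sw_fill(q: np.ndarray, s: np.ndarray, score: np.ndarray, gap_open: int, gap_extend: int):
    """Fill affine-gap local DP matrices H (best), F (vertical), E (horizontal)."""
    n, m = q.shape[0], s.shape[0]
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + gap_extend
            eo = H[i, j - 1] + gap_open
            if eo > e:
                e = eo
            E[i, j] = e
            f = F[i - 1, j] + gap_extend
            fo = H[i - 1, j] + gap_open
            if fo > f:
                f = fo
            F[i, j] = f
            h = H[i - 1, j - 1] + score[qi, s[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


def _encode(seq: str, index: dict[str, int]) -> np.ndarray:
    try:
        return np.array([index[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in matrix alphabet") from None


def smith_waterman(
    query: ProteinSequence,
    subject: ProteinSequence,
    matrix: ScoringMatrix,
    gaps: GapPenalties,
) -> LocalAlignment:
    """Optimal local alignment of ``query`` and ``subject``.

    Traceback is deterministic: ties resolve diagonal, then up (gap in
    subject), then left (gap in query); the best cell is the first maximum
    in row-major order. Score is floored at zero (empty alignment).
    """
    if not query.residues or not subject.residues:
        raise ValueError("empty sequence")
    index = {a: i for i, a in enumerate(matrix.alphabet)}
    q = _encode(query.residues, index)
    s = _encode(subject.residues, index)
    smat = matrix.scores.astype(np.int64)
    H, E, F = _sw_fill(q, s, smat, gaps.open, gaps.extend)
    best = int(H.max())
    if best == 0:
        return LocalAlignment(0, "", "", (0, 0), (0, 0), 0)
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    i, j = int(i), int(j)
    aq: list[str] = []
    asub: list[str] = []
    identities = 0
    end_i, end_j = i, j
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + smat[q[i - 1], s[j - 1]]:
                aq.append(query.residues[i - 1])
                asub.append(subject.residues[j - 1])
                if query.residues[i - 1] == subject.residues[j - 1]:
                    identities += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # vertical: consume query, gap in subject
            aq.append(query.residues[i - 1])
            asub.append("-")
            closes = F[i, j] == H[i - 1, j] + gaps.open
            i -= 1
            if closes:
                state = "H"
        else:  # horizontal: consume subject, gap in query
            aq.append("-")
            asub.append(subject.residues[j - 1])
            closes = E[i, j] == H[i, j - 1] + gaps.open
            j -= 1
            if closes:
                state = "H"
    return LocalAlignment(
        raw_score=best,
        aligned_query="".join(reversed(aq)),
        aligned_subject="".join(reversed(asub)),
        q_span=(i, end_i),
        s_span=(j, end_j),
        identities=identities,
    )


def sw_score(
    query: ProteinSequence,
    subject: ProteinSequence,
    matrix: ScoringMatrix,
    gaps: GapPenalties,
) -> int:
    """Optimal local score only (no traceback)."""
    if not query.residues or not subject.residues:
        raise ValueError("empty sequence")
    index = {a: i for i, a in enumerate(matrix.alphabet)}
    H, _, _ = _sw_fill(
        _encode(query.residues, index),
        _encode(subject.residues, index),
        matrix.scores.astype(np.int64),
        gaps.open,
        gaps.extend,
    )
    return int(H.max())


def percent_identity(aln: LocalAlignment) -> float:
    """Identities over alignment columns (gapped columns count), in [0, 100]."""
    if aln.length == 0:
        raise ValueError("percent identity undefined for an empty alignment")
    return 100.0 * aln.identities / aln.length


MIN_FIT_SAMPLES = 30
TRIM_FRACTION = 0.02


def fit_gumbel(scores: Sequence[float], trim: float = TRIM_FRACTION) -> GumbelFit:
    """Method-of-moments Gumbel fit; the top ``trim`` fraction is dropped first.

    beta = sqrt(6 var)/pi, mu = mean - gamma*beta. Trimming censors the
    (presumed homologous) extreme right tail before fitting the null; it
    biases beta slightly low on a pure null sample, which makes E-values
    conservative. Pass trim=0 to fit an uncensored sample.
    """
    arr = np.sort(np.asarray(scores, dtype=float))
    if arr.size < MIN_FIT_SAMPLES:
        raise ValueError(f"need >= {MIN_FIT_SAMPLES} scores, got {arr.size}")
    n_trim = int(math.ceil(trim * arr.size)) if trim > 0 else 0
    if n_trim:
        arr = arr[:-n_trim]
    var = float(arr.var(ddof=1))
    if var == 0:
        raise ValueError("zero variance: cannot fit a Gumbel")
    beta = math.sqrt(6.0 * var) / math.pi
    mu = float(arr.mean()) - EULER_GAMMA * beta
    return GumbelFit(mu=mu, beta=beta, n_samples=int(arr.size))


def evalue_of_score(s: float, fit: GumbelFit, db_size: int) -> float:
    """Expected number of db hits scoring >= s under the fitted null."""
    if db_size < 1:
        raise ValueError("db_size must be >= 1")
    z = (s - fit.mu) / fit.beta
    # 1 - exp(-exp(-z)), computed stably for large z
    p = -math.expm1(-math.exp(-z)) if z > -30 else 1.0
    return db_size * p


def _alignment_stats(aln: LocalAlignment) -> tuple[int, int]:
    """(mismatches, gap_opens) from the gapped strings."""
    mismatches = 0
    gap_opens = 0
    prev_gap_q = prev_gap_s = False
    for a, b in zip(aln.aligned_query, aln.aligned_subject):
        if a == "-":
            if not prev_gap_q:
                gap_opens += 1
            prev_gap_q, prev_gap_s = True, False
        elif b == "-":
            if not prev_gap_s:
                gap_opens += 1
            prev_gap_q, prev_gap_s = False, True
        else:
            if a != b:
                mismatches += 1
            prev_gap_q = prev_gap_s = False
    return mismatches, gap_opens


def search_all_vs_all(
    db: Sequence[ProteinSequence],
    matrix: ScoringMatrix,
    gaps: GapPenalties,
) -> list[SearchResult]:
    """Every sequence queried against every other; E-values per query.

    Scores are computed once per unordered pair (Smith-Waterman is
    symmetric). Each query's Gumbel null is fit on its own score set unless
    the database is too small (< 31 sequences), in which case one pooled fit
    is used with a warning.
    """
    n = len(db)
    if n < 2:
        raise ValueError("database must hold at least 2 sequences")
    alignments: dict[tuple[int, int], LocalAlignment] = {}
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = smith_waterman(db[i], db[j], matrix, gaps)
            alignments[(i, j)] = aln
            scores[i, j] = scores[j, i] = aln.raw_score

    pooled_fit: GumbelFit | None = None
    if n - 1 < MIN_FIT_SAMPLES + 1:
        warnings.warn(
            f"database of {n} sequences too small for per-query statistics; "
            "using one pooled Gumbel fit",
            stacklevel=2,
        )
        pooled = scores[np.triu_indices(n, k=1)]
        if pooled.size >= MIN_FIT_SAMPLES:
            pooled_fit = fit_gumbel(pooled)
        else:
            # too few pairs even pooled: moment fit without trimming,
            # guarding against a degenerate (constant) score sample
            var = float(pooled.var(ddof=1)) if pooled.size > 1 else 0.0
            beta = math.sqrt(6.0 * var) / math.pi if var > 0 else 1.0
            mu = float(pooled.mean()) - EULER_GAMMA * beta
            pooled_fit = GumbelFit(mu=mu, beta=beta, n_samples=int(pooled.size))

    results: list[SearchResult] = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        fit = pooled_fit or fit_gumbel(scores[i, others])
        hits: list[HitRecord] = []
        for j in others:
            aln = alignments[(i, j)] if i < j else alignments[(j, i)]
            swapped = i > j
            aq = aln.aligned_subject if swapped else aln.aligned_query
            asub = aln.aligned_query if swapped else aln.aligned_subject
            q_span = aln.s_span if swapped else aln.q_span
            s_span = aln.q_span if swapped else aln.s_span
            mismatches, gap_opens = _alignment_stats(aln)
            if aln.length == 0:
                pid, length = 0.0, 0
                q_start = q_end = s_start = s_end = 1
            else:
                pid = percent_identity(aln)
                length = aln.length
                q_start, q_end = q_span[0] + 1, q_span[1]
                s_start, s_end = s_span[0] + 1, s_span[1]
            hits.append(
                HitRecord(
                    query_id=db[i].id,
                    subject_id=db[j].id,
                    percent_identity=pid,
                    alignment_length=length,
                    mismatches=mismatches,
                    gap_opens=gap_opens,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=s_start,
                    s_end=s_end,
                    e_value=evalue_of_score(aln.raw_score, fit, db_size=n - 1),
                    bit_or_raw_score=float(aln.raw_score),
                )
            )
        hits.sort(key=lambda h: (h.e_value, h.subject_id))
        results.append(SearchResult(query_id=db[i].id, hits=tuple(hits), db_size=n - 1))
    return results
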