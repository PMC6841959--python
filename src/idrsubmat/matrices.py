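"""Substitution-matrix estimation from alignment blocks.

The estimator is block-based counting in the BLOSUM tradition: every
unordered pair of residues co-occurring in an alignment column contributes
one count; counts over all 210 unordered canonical pairs give observed
target frequencies q_ij, residue backgrounds p_i and independence-expected
frequencies e_ij; the matrix entry is the scaled, rounded log-odds
s_ij = round(log2(q_ij / e_ij) / scale). Matrices are summarized by their
matrix average (mean of the 210 pair scores), expected score
E = sum_ij p_i p_j s_ij (negative for a usable local-alignment matrix) and
relative entropy H = sum q_ij log2(q_ij / e_ij) in bits.

Because rounding to integers perturbs the log-odds, the rounded matrix also
has *implicit* statistics: the Karlin-Altschul scale lambda (unique positive
root of sum p_i p_j exp(lambda s_ij) = 1) defines the target frequencies the
integer matrix actually encodes and their entropy. Both block-level and
implicit H are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .blocks import DisorderedBlockSet
from .io import CANONICAL_ALPHABET, FormatError

N_AA = 20
N_UNORDERED_PAIRS = N_AA * (N_AA + 1) // 2  # 210
_AA_INDEX = {a: i for i, a in enumerate(CANONICAL_ALPHABET)}
_UPPER = np.triu_indices(N_AA)


def _round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer, ties away from zero (BLOSUM convention)."""
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass
class PairCounts:
    """Symmetric unordered-pair counts f_ij over the canonical alphabet.

    ``f`` is a symmetric 20x20 array; the count of unordered pair (i, j) is
    read at either index. ``total`` sums each unordered pair once.
    """

    f: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (N_AA, N_AA):
            raise ValueError(f"pair-count array shape {self.f.shape}")
        if not np.allclose(self.f, self.f.T):
            raise ValueError("pair counts must be symmetric")
        if (self.f < 0).any():
            raise ValueError("negative pair count")

    @property
    def total(self) -> float:
        return float(self.f[_UPPER].sum())

    def pair(self, a: str, b: str) -> float:
        return float(self.f[_AA_INDEX[a], _AA_INDEX[b]])

    def __add__(self, other: "PairCounts") -> "PairCounts":
        return PairCounts(self.f + other.f)


@dataclass(frozen=True)
class SubstitutionModel:
    """Target (q), background (p) and expected (e) frequencies.

    q and e are symmetric 20x20 arrays whose *unordered* pairs sum to 1;
    p is the length-20 background vector p_i = q_ii + sum_{j != i} q_ij / 2.
    """

    q: np.ndarray
    p: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        for name, arr, total in (("q", self.q, 1.0), ("e", self.e, 1.0)):
            s = float(np.asarray(arr)[_UPPER].sum())
            if abs(s - total) > 1e-9:
                raise ValueError(f"{name} sums to {s}, expected {total}")
        if abs(float(self.p.sum()) - 1.0) > 1e-9:
            raise ValueError("backgrounds p do not sum to 1")


@dataclass
class ScoringMatrix:
    """Integer log-odds matrix with its alphabet and scale (bits per unit)."""

    alphabet: str
    scores: np.ndarray
    scale: float = 0.5
    name: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise ValueError(
                f"score shape {self.scores.shape} for alphabet of {n} letters"
            )
        if not np.array_equal(self.scores, self.scores.T):
            raise ValueError("scoring matrix must be symmetric")
        if not np.allclose(self.scores, np.round(self.scores)):
            raise ValueError("scores must be integer-valued")
        self.scores = self.scores.astype(np.int32)
        self._index = {a: i for i, a in enumerate(self.alphabet)}

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self._index[a], self._index[b]])

    def canonical_submatrix(self) -> np.ndarray:
        """The 20x20 block in canonical alphabet order."""
        idx = [self._index[a] for a in CANONICAL_ALPHABET]
        return self.scores[np.ix_(idx, idx)]

    def has_canonical_alphabet(self) -> bool:
        return all(a in self._index for a in CANONICAL_ALPHABET)


@dataclass(frozen=True)
class MatrixParameters:
    """Summary statistics of a matrix paired with its generating model."""

    matrix_average: float
    expected_score: float
    relative_entropy: float  # bits per aligned pair


@dataclass(frozen=True)
class ImplicitStatistics:
    """Karlin-Altschul statistics of the rounded integer matrix."""

    lambda_ka: float
    implicit_target_freqs: np.ndarray  # ordered-pair q*_ij = p_i p_j e^{lambda s_ij}
    implicit_entropy: float  # bits


def count_column_pairs(column: Iterable[str]) -> PairCounts:
    """Henikoff pair counts for one gap-free block column.

    With residue multiplicities n_a: f_aa = n_a(n_a - 1)/2 and
    f_ab = n_a n_b for a != b, so the total is C(n, 2).
    Columns of depth < 2 contribute nothing (warned).
    """
    col = list(column)
    f = np.zeros((N_AA, N_AA))
    if len(col) < 2:
        warnings.warn("block column of depth < 2 skipped", stacklevel=2)
        return PairCounts(f)
    counts: dict[str, int] = {}
    for r in col:
        if r not in _AA_INDEX:
            raise ValueError(f"non-canonical residue {r!r} in block column")
        counts[r] = counts.get(r, 0) + 1
    letters = sorted(counts)
    for ai, a in enumerate(letters):
        ia = _AA_INDEX[a]
        na = counts[a]
        f[ia, ia] = na * (na - 1) / 2
        for b in letters[ai + 1 :]:
            ib = _AA_INDEX[b]
            f[ia, ib] = f[ib, ia] = na * counts[b]
    return PairCounts(f)


def accumulate_counts(
    blocks: DisorderedBlockSet, pseudocount: float = 0.0
) -> PairCounts:
    """Sum pair counts over all block columns, then add a flat pseudocount."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if blocks.n_columns == 0 and pseudocount == 0:
        raise ValueError("empty block set and no pseudocount: nothing to count")
    f = np.zeros((N_AA, N_AA))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for col in blocks:
            if len(col) >= 2:
                f += count_column_pairs(col).f
    if pseudocount > 0:
        f += pseudocount  # every ordered cell; unordered pairs each gain pseudocount
        # keep diagonal at +pseudocount as well (already uniform)
    return PairCounts(f)


def estimate_frequencies(counts: PairCounts) -> SubstitutionModel:
    """Observed/background/expected frequencies from raw pair counts."""
    T = counts.total
    if T <= 0:
        raise ValueError("total pair count is zero")
    q = counts.f / T
    p = np.diag(q) + (q.sum(axis=1) - np.diag(q)) / 2.0
    e = 2.0 * np.outer(p, p)
    np.fill_diagonal(e, p**2)
    return SubstitutionModel(q=q, p=p, e=e)


def compute_lod(
    model: SubstitutionModel, scale_bits: float = 0.5, name: str = ""
) -> ScoringMatrix:
    """Scaled, rounded log-odds matrix from a frequency model.

    Half-bit scale (0.5 bits per score unit) is the default, as for the
    BLOSUM series. Any zero target frequency is a hard error; rebuild the
    counts with a pseudocount to smooth sparse corpora.
    """
    if scale_bits <= 0:
        raise ValueError("scale must be positive")
    if (model.q <= 0).any():
        zeros = [
            f"{CANONICAL_ALPHABET[i]}{CANONICAL_ALPHABET[j]}"
            for i, j in zip(*np.nonzero(model.q <= 0))
            if i <= j
        ]
        raise ValueError(
            f"zero target frequency for pair(s) {', '.join(zeros[:5])}"
            f"{'...' if len(zeros) > 5 else ''}; "
            "re-count with pseudocount > 0"
        )
    lod = np.log2(model.q / model.e) / scale_bits
    scores = _round_half_away(lod).astype(int)
    return ScoringMatrix(
        alphabet=CANONICAL_ALPHABET, scores=scores, scale=scale_bits, name=name
    )


def matrix_parameters(
    matrix: ScoringMatrix, model: SubstitutionModel
) -> MatrixParameters:
    """Matrix average, expected score E and relative entropy H.

    The matrix average is the unweighted mean of the 210 unordered-pair
    integer scores; E weights the integer scores by background pair
    probabilities (ordered sum), and must be negative for local-alignment
    statistics to apply; H is computed from the model's block-level
    frequencies, in bits.
    """
    if not matrix.has_canonical_alphabet():
        raise ValueError("matrix alphabet does not cover the 20 canonical residues")
    s = matrix.canonical_submatrix().astype(float)
    avg = float(s[_UPPER].mean())
    expected = float(np.einsum("i,j,ij->", model.p, model.p, s))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(model.q > 0, model.q * np.log2(model.q / model.e), 0.0)
    entropy = float(terms[_UPPER].sum())
    return MatrixParameters(
        matrix_average=avg, expected_score=expected, relative_entropy=entropy
    )


def matrix_average(matrix: ScoringMatrix) -> float:
    """Unweighted mean of the 210 unordered canonical-pair scores."""
    if not matrix.has_canonical_alphabet():
        raise ValueError("matrix alphabet does not cover the 20 canonical residues")
    return float(matrix.canonical_submatrix()[_UPPER].mean())


def karlin_altschul_stats(
    matrix: ScoringMatrix, p: np.ndarray
) -> ImplicitStatistics:
    """Solve for the Karlin-Altschul lambda of an integer matrix.

    lambda is the unique positive root of
    f(lambda) = sum_ij p_i p_j exp(lambda s_ij) - 1; it exists when the
    expected score is negative and some score is positive. The implicit
    target frequencies q*_ij = p_i p_j exp(lambda s_ij) then sum to 1 and
    their relative entropy (in bits) is lambda * sum q*_ij s_ij / ln 2.
    """
    p = np.asarray(p, dtype=float)
    if len(p) == len(matrix.alphabet):
        s = matrix.scores.astype(float)
    elif len(p) == N_AA and matrix.has_canonical_alphabet():
        s = matrix.canonical_submatrix().astype(float)
    else:
        raise ValueError(
            f"background vector of length {len(p)} does not match "
            f"alphabet of {len(matrix.alphabet)} letters"
        )
    pp = np.outer(p, p)
    expected = float((pp * s).sum())
    if expected >= 0:
        raise ValueError(f"expected score {expected:.4f} is not negative")
    if s.max() <= 0:
        raise ValueError("matrix has no positive score; no positive lambda exists")

    def f(lam: float) -> float:
        return float((pp * np.exp(lam * s)).sum()) - 1.0

    lo = 1e-8
    while f(lo) >= 0:  # pragma: no cover - expected < 0 guarantees f(lo) < 0
        lo /= 10.0
        if lo < 1e-300:
            raise RuntimeError("failed to bracket lambda from below")
    hi = 1.0
    while f(hi) <= 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("failed to bracket lambda from above")
    lam = float(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))
    assert abs(f(lam)) < 1e-10
    q_star = pp * np.exp(lam * s)
    implicit_h = lam * float((q_star * s).sum()) / math.log(2.0)
    return ImplicitStatistics(
        lambda_ka=lam, implicit_target_freqs=q_star, implicit_entropy=implicit_h
    )


_AMBIGUITY_GROUPS = {"B": "ND", "Z": "EQ", "X": CANONICAL_ALPHABET}
EXTENDED_ALPHABET = CANONICAL_ALPHABET + "BZX*"


def extend_alphabet(
    matrix: ScoringMatrix, model: SubstitutionModel
) -> ScoringMatrix:
    """Add B/Z/X ambiguity rows and a stop column to a 20-letter matrix.

    Ambiguity scores are background-weighted averages of the member
    residues' scores (weights renormalized within the group), rounded like
    the primary scores. '*' scores the minimum off-diagonal value, except
    '*'-'*' which scores 1.
    """
    if matrix.alphabet != CANONICAL_ALPHABET:
        raise ValueError("extend_alphabet expects a 20-letter canonical matrix")
    base = matrix.scores.astype(float)
    n_ext = len(EXTENDED_ALPHABET)
    ext = np.zeros((n_ext, n_ext))
    ext[:N_AA, :N_AA] = base
    off_diag_min = int(base[~np.eye(N_AA, dtype=bool)].min())

    def group_weights(letters: str) -> np.ndarray:
        w = np.array([model.p[_AA_INDEX[a]] for a in letters])
        total = w.sum()
        if total <= 0:
            w = np.ones(len(letters))
            total = float(len(letters))
        return w / total

    amb_letters = ["B", "Z", "X"]
    # residue-vs-ambiguity scores
    for amb in amb_letters:
        gi = EXTENDED_ALPHABET.index(amb)
        members = _AMBIGUITY_GROUPS[amb]
        w = group_weights(members)
        midx = [_AA_INDEX[a] for a in members]
        for a in range(N_AA):
            ext[a, gi] = ext[gi, a] = float(w @ base[midx, a])
    # ambiguity-vs-ambiguity scores (double-weighted average)
    for amb_a in amb_letters:
        ga = EXTENDED_ALPHABET.index(amb_a)
        wa = group_weights(_AMBIGUITY_GROUPS[amb_a])
        ia = [_AA_INDEX[x] for x in _AMBIGUITY_GROUPS[amb_a]]
        for amb_b in amb_letters:
            gb = EXTENDED_ALPHABET.index(amb_b)
            wb = group_weights(_AMBIGUITY_GROUPS[amb_b])
            ib = [_AA_INDEX[x] for x in _AMBIGUITY_GROUPS[amb_b]]
            ext[ga, gb] = float(wa @ base[np.ix_(ia, ib)] @ wb)
    ext = _round_half_away(ext)
    star = EXTENDED_ALPHABET.index("*")
    ext[star, :] = off_diag_min
    ext[:, star] = off_diag_min
    ext[star, star] = 1
    return ScoringMatrix(
        alphabet=EXTENDED_ALPHABET,
        scores=ext.astype(int),
        scale=matrix.scale,
        name=matrix.name,
    )


def write_matrix(
    matrix: ScoringMatrix, path: str | Path, comments: Iterable[str] = ()
) -> None:
    """Write NCBI-format ASCII (BLAST/SSEARCH '-s' compatible)."""
    with open(path, "w") as fh:
        header = [
            f"{matrix.name or 'substitution matrix'}",
            f"scale: {matrix.scale} bits per score unit",
            f"written: {date.today().isoformat()}",
        ]
        for line in list(header) + list(comments):
            fh.write(f"# {line}\n")
        letters = list(matrix.alphabet)
        fh.write("   " + " ".join(f"{a:>3}" for a in letters) + "\n")
        for i, a in enumerate(letters):
            row = " ".join(f"{int(matrix.scores[i, j]):>3}" for j in range(len(letters)))
            fh.write(f"{a}  {row}\n")


def read_matrix(path: str | Path, scale: float = 0.5) -> ScoringMatrix:
    """Read an NCBI-format ASCII matrix.

    A non-symmetric file is symmetrized by averaging (with rounding) after a
    warning; letters outside the extended amino-acid alphabet are an error.
    The scale is not encoded in the format and must be supplied (half-bits
    by default).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = substitution_matrices.read(str(path))
    alphabet = "".join(arr.alphabet)
    allowed = set(CANONICAL_ALPHABET + "BZXU*OJ")
    unknown = set(alphabet) - allowed
    if unknown:
        raise FormatError(f"{path}: unknown matrix letters {sorted(unknown)}")
    scores = np.asarray(arr, dtype=float)
    if not np.array_equal(scores, scores.T):
        warnings.warn(
            f"{path}: matrix not symmetric; symmetrizing by averaging", stacklevel=2
        )
        scores = _round_half_away((scores + scores.T) / 2.0)
    return ScoringMatrix(
        alphabet=alphabet,
        scores=scores.astype(int),
        scale=scale,
        name=path.stem,
    )


def build_matrix_from_blocks(
    blocks: DisorderedBlockSet,
    scale_bits: float = 0.5,
    pseudocount: float = 0.0,
    name: str = "",
) -> tuple[ScoringMatrix, SubstitutionModel, MatrixParameters, ImplicitStatistics]:
    """Convenience pipeline: counts -> model -> LOD matrix -> parameters."""
    counts = accumulate_counts(blocks, pseudocount=pseudocount)
    model = estimate_frequencies(counts)
    matrix = compute_lod(model, scale_bits=scale_bits, name=name)
    params = matrix_parameters(matrix, model)
    implicit = karlin_altschul_stats(matrix, model.p)
    return matrix, model, params, implicit
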