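"""Benchmarking homology searches: coverage, bootstrap, and E-value analyses.

A pooled, E-value-sorted hit list over all queries is labeled true positive
(same family) or false positive (different family). Walking the list, the
number of false positives per query (EPQ) rises; the accepted prefix is the
largest whose EPQ stays within a limit (0.01 by default: one false positive
per hundred queries). Sensitivity is the quadratically normalized coverage

    Q_quad = (1/S) * sum_i t_i / (s_i^2 - s_i)

where family i of size s_i contributed t_i true-positive relations to the
accepted prefix; relations are ordered pairs, so a family of size s has
s^2 - s of them, and families of size 1 are excluded. Confidence comes from
a Bayesian bootstrap: per replicate, sequences receive Dirichlet(1,...,1)
weights and each family's coverage ratio is reweighted by w_q * w_h; the
same weight draws are shared ("concerted") across the matrices being
compared, so two bootstrap distributions are comparable through the
Z statistic z = (mean_M - mean_P) / sqrt((var_M + var_P)/N), significant at
|z| >= 1.96.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io import FamilyTable, HitRecord, ProteinSequence
from .matrices import ScoringMatrix
from .search import GapPenalties, search_all_vs_all

DEFAULT_EPQ = 0.01
Z_SIGNIFICANCE = 1.96
E_VALUE_FLOOR = 1e-300


@dataclass(frozen=True)
class Relation:
    """One query-subject relation; (q, h) and (h, q) are distinct."""

    query_id: str
    subject_id: str
    e_value: float
    is_tp: bool


@dataclass(frozen=True)
class RelationSet:
    """Pooled relations sorted by ascending E-value, plus the family context."""

    relations: tuple[Relation, ...]
    n_queries: int
    families: FamilyTable


@dataclass(frozen=True)
class CoverageResult:
    q_quad: float
    epq: float
    per_family_t: dict[str, int]
    per_family_s: dict[str, int]
    threshold_evalue: float | None
    accepted_tp: tuple[tuple[str, str], ...]  # (query, subject) pairs in the prefix
    n_accepted_fp: int


@dataclass(frozen=True)
class BootstrapDistribution:
    replicates: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return int(self.replicates.size)

    @property
    def mean(self) -> float:
        return float(self.replicates.mean())

    @property
    def variance(self) -> float:
        return float(self.replicates.var(ddof=1))


@dataclass(frozen=True)
class ComparisonReport:
    z: float
    matrix_ids: tuple[str, str]
    significant: bool


def label_relations(hits: Iterable[HitRecord], families: FamilyTable) -> RelationSet:
    """Tag pooled hits TP/FP by family co-membership; self-hits dropped.

    The list is sorted by ascending E-value; equal E-values stay grouped.
    Every id must be present in the family table.
    """
    relations: list[Relation] = []
    queries: set[str] = set()
    for hit in hits:
        fq = families.family_of(hit.query_id)
        fs = families.family_of(hit.subject_id)
        queries.add(hit.query_id)
        if hit.query_id == hit.subject_id:
            continue
        relations.append(
            Relation(
                query_id=hit.query_id,
                subject_id=hit.subject_id,
                e_value=hit.e_value,
                is_tp=fq == fs,
            )
        )
    relations.sort(key=lambda r: r.e_value)
    return RelationSet(
        relations=tuple(relations), n_queries=len(queries), families=families
    )


def _tie_groups(relations: Sequence[Relation]) -> list[list[Relation]]:
    groups: list[list[Relation]] = []
    for rel in relations:
        if groups and groups[-1][0].e_value == rel.e_value:
            groups[-1].append(rel)
        else:
            groups.append([rel])
    return groups


def coverage_at_epq(rels: RelationSet, epq_limit: float = DEFAULT_EPQ) -> CoverageResult:
    """Q_quad over the largest E-value prefix with EPQ <= ``epq_limit``.

    Tie groups (equal E-values) are accepted or rejected whole, since
    ordering within a tie is arbitrary.
    """
    if epq_limit <= 0:
        raise ValueError("epq_limit must be positive")
    if rels.n_queries == 0:
        raise ValueError("relation set has no queries")
    accepted: list[Relation] = []
    n_fp = 0
    threshold: float | None = None
    for group in _tie_groups(rels.relations):
        fp_in_group = sum(1 for r in group if not r.is_tp)
        if (n_fp + fp_in_group) / rels.n_queries > epq_limit:
            break
        n_fp += fp_in_group
        accepted.extend(group)
        threshold = group[0].e_value
    sizes = rels.families.sizes()
    t: dict[str, int] = {fid: 0 for fid in sizes}
    for r in accepted:
        if r.is_tp:
            t[rels.families.family_of(r.query_id)] += 1
    eligible = [fid for fid, s in sizes.items() if s >= 2]
    if not eligible:
        raise ValueError("no family of size >= 2")
    q_quad = sum(t[fid] / (sizes[fid] ** 2 - sizes[fid]) for fid in eligible) / len(
        eligible
    )
    return CoverageResult(
        q_quad=q_quad,
        epq=n_fp / rels.n_queries,
        per_family_t={fid: t[fid] for fid in eligible},
        per_family_s={fid: sizes[fid] for fid in eligible},
        threshold_evalue=threshold,
        accepted_tp=tuple(
            (r.query_id, r.subject_id) for r in accepted if r.is_tp
        ),
        n_accepted_fp=n_fp,
    )


DEFAULT_BOOTSTRAP_REPS = 500


def bayesian_bootstrap(
    rels: RelationSet,
    n_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
    epq_limit: float = DEFAULT_EPQ,
    weights: np.ndarray | None = None,
) -> BootstrapDistribution:
    """Dirichlet-weighted coverage replicates over a fixed accepted prefix.

    Per replicate, one weight per sequence is drawn from Dirichlet(1,...,1)
    over the whole database (weights are assigned to sequence ids in sorted
    order, so two relation sets over the same database receive identical
    draws from the same seed — the concerted scheme). Each family's ratio
    becomes sum of w_q*w_h over accepted TP relations divided by the same
    sum over all ordered within-family pairs. The accepted prefix is held
    at the unweighted EPQ solution. ``weights`` (a test hook) bypasses the
    Dirichlet draw with one fixed weight vector for every replicate.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    cov = coverage_at_epq(rels, epq_limit)
    seq_ids = sorted(rels.families.membership)
    idx = {sid: i for i, sid in enumerate(seq_ids)}
    fams = rels.families.families
    eligible = [fid for fid in sorted(fams) if len(fams[fid]) >= 2]
    fam_members = [np.array([idx[s] for s in fams[fid]]) for fid in eligible]
    tp_by_family: dict[str, list[tuple[int, int]]] = {fid: [] for fid in eligible}
    for q, h in cov.accepted_tp:
        tp_by_family[rels.families.family_of(q)].append((idx[q], idx[h]))
    tp_pairs = [
        (np.array([a for a, _ in tp_by_family[fid]], dtype=int),
         np.array([b for _, b in tp_by_family[fid]], dtype=int))
        for fid in eligible
    ]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    for r in range(n_reps):
        if weights is not None:
            w = np.asarray(weights, dtype=float)
        else:
            w = rng.dirichlet(np.ones(len(seq_ids)))
        total = 0.0
        for members, (qi, hi) in zip(fam_members, tp_pairs):
            wm = w[members]
            denom = wm.sum() ** 2 - (wm**2).sum()  # ordered within-family pairs
            if denom <= 0:
                continue
            num = float((w[qi] * w[hi]).sum()) if qi.size else 0.0
            total += num / denom
        reps[r] = total / len(eligible)
    return BootstrapDistribution(replicates=reps, seed=seed)


def z_score(
    m: BootstrapDistribution,
    p: BootstrapDistribution,
    matrix_ids: tuple[str, str] = ("M", "P"),
) -> ComparisonReport:
    """Z statistic between two concerted bootstrap distributions."""
    if m.n != p.n:
        raise ValueError(f"replicate counts differ: {m.n} vs {p.n}")
    var_sum = m.variance + p.variance
    diff = m.mean - p.mean
    if var_sum == 0:
        z = 0.0 if diff == 0 else math.inf * (1 if diff > 0 else -1)
    else:
        z = diff / math.sqrt(var_sum / m.n)
    return ComparisonReport(
        z=z, matrix_ids=matrix_ids, significant=abs(z) >= Z_SIGNIFICANCE
    )


def common_homolog_evalues(
    hits_a: Iterable[HitRecord],
    hits_b: Iterable[HitRecord],
    families: FamilyTable,
    epq_limit: float = DEFAULT_EPQ,
) -> pd.DataFrame:
    """Paired log10 E-values of TP relations accepted by both searches.

    Zero E-values (possible in ingested SSEARCH output) are floored to
    1e-300 before the log. Columns: query_id, subject_id, log10_e_a,
    log10_e_b.
    """
    def accepted_tp_evalues(hits: Iterable[HitRecord]) -> dict[tuple[str, str], float]:
        rels = label_relations(hits, families)
        cov = coverage_at_epq(rels, epq_limit)
        accepted = set(cov.accepted_tp)
        return {
            (r.query_id, r.subject_id): r.e_value
            for r in rels.relations
            if r.is_tp and (r.query_id, r.subject_id) in accepted
        }

    ea = accepted_tp_evalues(hits_a)
    eb = accepted_tp_evalues(hits_b)
    rows = [
        {
            "query_id": q,
            "subject_id": h,
            "log10_e_a": math.log10(max(ea[(q, h)], E_VALUE_FLOOR)),
            "log10_e_b": math.log10(max(eb[(q, h)], E_VALUE_FLOOR)),
        }
        for (q, h) in sorted(set(ea) & set(eb))
    ]
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "log10_e_a", "log10_e_b"])


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float] | None = None
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, normal approximation.

    Accepts either paired samples (a, b) or precomputed differences (a
    alone). Zero differences are dropped; midranks handle ties; the
    statistic is W = min(W+, W-) and the two-sided p-value uses the normal
    approximation with tie and continuity corrections. All-zero differences
    give p = 1 by convention.
    """
    d = np.asarray(a, dtype=float)
    if b is not None:
        d = d - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    if n < 6:
        raise ValueError("need >= 6 non-zero differences for the normal approximation")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    mean_w = n * (n + 1) / 4.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var_w <= 0:
        return w, 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return w, p


def optimize_gap_penalties(
    db: Sequence[ProteinSequence],
    matrix: ScoringMatrix,
    families: FamilyTable,
    grid: Sequence[GapPenalties] | None = None,
    epq_limit: float = DEFAULT_EPQ,
) -> tuple[GapPenalties, pd.DataFrame]:
    """Grid search over gap penalties maximizing accepted true positives.

    Default grid: open -5..-20 by -1, extend -1..-3 by -1. Ties break by
    higher Q_quad, then smaller |open|. Returns the winner and the full
    per-grid-point table (open, extend, accepted_tp, q_quad, epq).
    """
    if grid is None:
        grid = [
            GapPenalties(open=o, extend=e)
            for o in range(-5, -21, -1)
            for e in range(-1, -4, -1)
            if o <= e
        ]
    if not grid:
        raise ValueError("empty gap-penalty grid")
    rows = []
    best: tuple | None = None
    best_gaps: GapPenalties | None = None
    for gaps in grid:
        results = search_all_vs_all(db, matrix, gaps)
        hits = [h for res in results for h in res.hits]
        cov = coverage_at_epq(label_relations(hits, families), epq_limit)
        n_tp = len(cov.accepted_tp)
        rows.append(
            {
                "open": gaps.open,
                "extend": gaps.extend,
                "accepted_tp": n_tp,
                "q_quad": cov.q_quad,
                "epq": cov.epq,
            }
        )
        key = (n_tp, cov.q_quad, -abs(gaps.open))
        if best is None or key > best:
            best = key
            best_gaps = gaps
    assert best_gaps is not None
    return best_gaps, pd.DataFrame(rows)
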