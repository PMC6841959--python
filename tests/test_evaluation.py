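"""Coverage at fixed EPQ, Bayesian bootstrap, Z-score and paired E-values."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from idrsubmat.evaluation import (
    BootstrapDistribution,
    bayesian_bootstrap,
    common_homolog_evalues,
    coverage_at_epq,
    label_relations,
    optimize_gap_penalties,
    wilcoxon_signed_rank,
    z_score,
)
from idrsubmat.io import FamilyTable, HitRecord, ProteinSequence
from idrsubmat.matrices import ScoringMatrix
from idrsubmat.search import GapPenalties

def hit(q, s, e):
    return HitRecord(
        query_id=q, subject_id=s, percent_identity=50.0, alignment_length=10,
        mismatches=5, gap_opens=0, q_start=1, q_end=10, s_start=1, s_end=10,
        e_value=e, bit_or_raw_score=42.0,
    )


TWO_FAMILIES = FamilyTable(
    membership={"a": "f1", "b": "f1", "c": "f1", "d": "f2", "e": "f2"}
)


class TestLabelRelations:
    def test_tp_fp_and_self_hit(self):
        hits = [hit("a", "b", 1e-5), hit("a", "d", 1e-3), hit("a", "a", 0.0)]
        rels = label_relations(hits, TWO_FAMILIES)
        assert [r.is_tp for r in rels.relations] == [True, False]
        assert rels.n_queries == 1

    def test_counts_conserved(self):
        hits = [hit("a", "b", 1e-5), hit("b", "a", 1e-4), hit("a", "a", 0.0),
                hit("d", "c", 2.0)]
        rels = label_relations(hits, TWO_FAMILIES)
        assert len(rels.relations) == 3  # input minus self-hits

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            label_relations([hit("a", "zz", 1.0)], TWO_FAMILIES)

    def test_sorted_by_evalue(self):
        hits = [hit("a", "b", 1e-3), hit("b", "c", 1e-9), hit("c", "a", 1e-6)]
        rels = label_relations(hits, TWO_FAMILIES)
        evs = [r.e_value for r in rels.relations]
        assert evs == sorted(evs)


def brute_force_q_quad(relations, families, n_queries, epq_limit):
    """Independent double-loop implementation of the coverage measure."""
    rels = sorted(relations, key=lambda r: r[2])  # (q, s, e, tp)
    groups = []
    for r in rels:
        if groups and groups[-1][0][2] == r[2]:
            groups[-1].append(r)
        else:
            groups.append([r])
    accepted, fp = [], 0
    for g in groups:
        g_fp = sum(1 for r in g if not r[3])
        if (fp + g_fp) / n_queries > epq_limit:
            break
        fp += g_fp
        accepted.extend(g)
    sizes = {fid: len(m) for fid, m in families.families.items()}
    eligible = [fid for fid, s in sizes.items() if s >= 2]
    total = 0.0
    for fid in eligible:
        t_i = 0
        for q, s, e, tp in accepted:
            if tp and families.family_of(q) == fid:
                t_i += 1
        total += t_i / (sizes[fid] ** 2 - sizes[fid])
    return total / len(eligible)


class TestCoverageAtEpq:
    def worked_example_relations(self):
        # accepted prefix holds exactly the five TP relations of the spec'd
        # two-family walk-through, then one FP beyond the EPQ budget
        hits = [
            hit("a", "b", 1e-10), hit("b", "a", 1e-9), hit("a", "c", 1e-8),
            hit("d", "e", 1e-7), hit("e", "d", 1e-6),
            hit("a", "d", 1e-2), hit("b", "d", 1e-2),
        ]
        return label_relations(hits, TWO_FAMILIES)

    def test_worked_two_family_example(self):
        rels = self.worked_example_relations()
        cov = coverage_at_epq(rels, epq_limit=0.01)
        # t = (3, 2), denominators (6, 2) -> (3/6 + 2/2)/2
        assert cov.q_quad == pytest.approx(0.75)
        assert cov.per_family_t == {"f1": 3, "f2": 2}
        assert cov.n_accepted_fp == 0

    def test_first_entry_fp_truncates_prefix(self):
        families = FamilyTable(
            membership={"a": "f1", "b": "f1", "c": "f2", "d": "f2"}
        )
        hits = [hit("a", "c", 1e-12), hit("a", "b", 1e-5), hit("b", "a", 1e-4),
                hit("c", "d", 1e-3), hit("d", "c", 1e-2)]
        rels = label_relations(hits, families)
        assert rels.n_queries == 4
        cov = coverage_at_epq(rels, epq_limit=0.01)
        # first relation is FP: EPQ would jump to 0.25, so nothing is accepted
        assert cov.q_quad == 0.0
        assert len(cov.accepted_tp) == 0

    def test_perfect_coverage(self):
        hits = [
            hit(q, s, 1e-9)
            for q, s in itertools.permutations(["a", "b", "c"], 2)
        ] + [hit(q, s, 1e-9) for q, s in itertools.permutations(["d", "e"], 2)]
        cov = coverage_at_epq(label_relations(hits, TWO_FAMILIES), 0.01)
        assert cov.q_quad == 1.0

    def test_zero_tp_prefix(self):
        hits = [hit("a", "d", 1e-30)]
        cov = coverage_at_epq(label_relations(hits, TWO_FAMILIES), 10.0)
        assert cov.q_quad == 0.0

    def test_matches_brute_force_on_fuzzed_sets(self, rng):
        ids = [f"s{i}" for i in range(12)]
        for trial in range(100):
            fam_of = {sid: f"f{rng.integers(0, 4)}" for sid in ids}
            families = FamilyTable(membership=fam_of)
            if not any(
                s >= 2 for s in families.sizes().values()
            ):
                continue
            hits = []
            for _ in range(int(rng.integers(5, 60))):
                q, s = rng.choice(ids, size=2, replace=False)
                # coarse e-value grid so ties actually occur
                e = float(10.0 ** -int(rng.integers(0, 6)))
                hits.append(hit(str(q), str(s), e))
            rels = label_relations(hits, families)
            limit = float(rng.choice([0.01, 0.1, 0.5]))
            got = coverage_at_epq(rels, limit).q_quad
            expected = brute_force_q_quad(
                [(r.query_id, r.subject_id, r.e_value, r.is_tp) for r in rels.relations],
                families, rels.n_queries, limit,
            )
            assert got == pytest.approx(expected), trial

    def test_monotone_in_epq_limit(self, rng):
        rels = self.worked_example_relations()
        values = [
            coverage_at_epq(rels, limit).q_quad
            for limit in (0.01, 0.2, 0.5, 1.0, 2.0)
        ]
        assert values == sorted(values)


class TestBayesianBootstrap:
    def test_equal_weights_reproduce_point_estimate(self):
        rels = TestCoverageAtEpq().worked_example_relations()
        point = coverage_at_epq(rels, 0.01).q_quad
        n = len(rels.families.membership)
        boot = bayesian_bootstrap(
            rels, n_reps=10, seed=0, weights=np.full(n, 1.0 / n)
        )
        assert np.allclose(boot.replicates, point)

    def test_seeded_reproducibility_and_mean_consistency(self):
        rels = TestCoverageAtEpq().worked_example_relations()
        point = coverage_at_epq(rels, 0.01).q_quad
        b1 = bayesian_bootstrap(rels, n_reps=500, seed=7)
        b2 = bayesian_bootstrap(rels, n_reps=500, seed=7)
        assert np.array_equal(b1.replicates, b2.replicates)
        se = math.sqrt(b1.variance / b1.n)
        assert abs(b1.mean - point) < 3 * se

    def test_different_seeds_agree_within_three_se(self):
        rels = TestCoverageAtEpq().worked_example_relations()
        b1 = bayesian_bootstrap(rels, n_reps=500, seed=1)
        b2 = bayesian_bootstrap(rels, n_reps=500, seed=2)
        se = math.sqrt((b1.variance + b2.variance) / 500)
        assert abs(b1.mean - b2.mean) < 3 * se


class TestZScore:
    def test_identical_distributions(self):
        b = BootstrapDistribution(replicates=np.array([0.5, 0.6, 0.7]), seed=0)
        report = z_score(b, b)
        assert report.z == 0.0
        assert not report.significant

    def test_derived_example(self, rng):
        """Mean difference 0.1, both variances 0.01, N = 500 -> z = 15.81."""
        base = rng.normal(0, 1, size=500)
        base = (base - base.mean()) / base.std(ddof=1)  # exact mean 0, sd 1
        m = BootstrapDistribution(replicates=0.6 + 0.1 * base, seed=0)
        p = BootstrapDistribution(replicates=0.5 + 0.1 * base, seed=0)
        report = z_score(m, p)
        assert report.z == pytest.approx(0.1 / math.sqrt(0.02 / 500), abs=0.01)
        assert report.significant

    def test_threshold_is_inclusive(self):
        n = 500
        base = np.linspace(-1, 1, n)
        base = (base - base.mean()) / base.std(ddof=1)
        sd = 0.1
        delta = 1.96 * math.sqrt(2 * sd**2 / n)
        m = BootstrapDistribution(replicates=delta + sd * base, seed=0)
        p = BootstrapDistribution(replicates=0.0 + sd * base, seed=0)
        report = z_score(m, p)
        assert report.z == pytest.approx(1.96, rel=1e-9)
        assert report.significant

    def test_n_mismatch(self):
        m = BootstrapDistribution(replicates=np.zeros(5), seed=0)
        p = BootstrapDistribution(replicates=np.zeros(6), seed=0)
        with pytest.raises(ValueError):
            z_score(m, p)


class TestCommonHomologEvalues:
    def hits_for(self, evalues):
        return [hit(q, s, e) for (q, s), e in evalues.items()]

    def test_identical_hit_sets_give_zero_differences(self):
        evs = {("a", "b"): 1e-9, ("b", "a"): 1e-8, ("d", "e"): 1e-7}
        table = common_homolog_evalues(
            self.hits_for(evs), self.hits_for(evs), TWO_FAMILIES
        )
        assert len(table) == 3
        assert (table["log10_e_a"] == table["log10_e_b"]).all()

    def test_count_bounded_by_smaller_tp_set(self):
        a = {("a", "b"): 1e-9, ("b", "a"): 1e-8, ("d", "e"): 1e-7}
        b = {("a", "b"): 1e-6}
        table = common_homolog_evalues(
            self.hits_for(a), self.hits_for(b), TWO_FAMILIES
        )
        assert len(table) <= 1

    def test_zero_evalue_floored(self):
        evs = {("a", "b"): 0.0}
        table = common_homolog_evalues(
            self.hits_for(evs), self.hits_for(evs), TWO_FAMILIES
        )
        assert table["log10_e_a"].iloc[0] == -300.0

    def test_set_logic_oracle_on_fuzzed_inputs(self, rng):
        ids = ["a", "b", "c", "d", "e"]
        for _ in range(20):
            def random_hits():
                out = {}
                for _ in range(int(rng.integers(2, 12))):
                    q, s = rng.choice(ids, size=2, replace=False)
                    out[(str(q), str(s))] = float(10.0 ** -int(rng.integers(0, 12)))
                return out
            ha, hb = random_hits(), random_hits()
            table = common_homolog_evalues(
                self.hits_for(ha), self.hits_for(hb), TWO_FAMILIES, epq_limit=10.0
            )
            def tp_set(h):
                return {
                    (q, s) for (q, s) in h
                    if TWO_FAMILIES.family_of(q) == TWO_FAMILIES.family_of(s)
                }
            expected = tp_set(ha) & tp_set(hb)
            got = set(zip(table["query_id"], table["subject_id"]))
            assert got == expected


class TestWilcoxon:
    def test_all_zero_differences(self):
        w, p = wilcoxon_signed_rank([0.0] * 10)
        assert p == 1.0

    def test_antisymmetry(self, rng):
        a = rng.normal(0, 1, size=30)
        b = rng.normal(0.5, 1, size=30)
        w1, p1 = wilcoxon_signed_rank(a, b)
        w2, p2 = wilcoxon_signed_rank(b, a)
        assert w1 == w2
        assert p1 == pytest.approx(p2)

    def test_exact_enumeration_oracle_eight_pairs(self):
        """Normal-approximation p within 0.02 of the exact permutation p.

        The exact two-sided p enumerates all 2^8 sign assignments of the
        absolute differences and counts assignments with min(W+, W-) at
        most the observed one.
        """
        diffs = [1.3, -0.7, 2.1, 3.4, -0.2, 1.8, 2.6, 0.9]
        w_obs, p_approx = wilcoxon_signed_rank(diffs)
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(diffs))
        total = ranks.sum()
        count = 0
        for signs in itertools.product([0, 1], repeat=len(diffs)):
            w_plus = sum(r for r, sgn in zip(ranks, signs) if sgn)
            w = min(w_plus, total - w_plus)
            if w <= w_obs:
                count += 1
        p_exact = count / 2 ** len(diffs)
        assert p_approx == pytest.approx(p_exact, abs=0.02)

    def test_matches_scipy_on_larger_sample(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        d = rng.normal(0.3, 1.0, size=60)
        d = d[d != 0]
        w, p = wilcoxon_signed_rank(d)
        ref = scipy_wilcoxon(d, correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_few_nonzero_differences(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, -1.0, 2.0, 0, 0, 0])


class TestOptimizeGapPenalties:
    def make_db(self, rng):
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        db, membership = [], {}
        for f in range(3):
            base = "".join(rng.choice(list(alphabet), size=60))
            for m in range(2):
                mutated = list(base)
                for pos in rng.choice(60, size=12, replace=False):
                    mutated[pos] = alphabet[int(rng.integers(20))]
                sid = f"f{f}m{m}"
                db.append(ProteinSequence(id=sid, residues="".join(mutated)))
                membership[sid] = f"fam{f}"
        return db, FamilyTable(membership=membership)

    def identity_matrix(self):
        scores = np.full((20, 20), -1)
        np.fill_diagonal(scores, 2)
        return ScoringMatrix(alphabet="ACDEFGHIKLMNPQRSTVWY", scores=scores)

    def test_single_point_grid(self, rng):
        db, families = self.make_db(rng)
        only = GapPenalties(-10, -2)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, table = optimize_gap_penalties(
                db, self.identity_matrix(), families, grid=[only]
            )
        assert best == only
        assert len(table) == 1

    def test_table_covers_grid_and_argmax_reproducible(self, rng):
        db, families = self.make_db(rng)
        grid = [GapPenalties(-10, -2), GapPenalties(-8, -1), GapPenalties(-12, -3)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best1, table1 = optimize_gap_penalties(
                db, self.identity_matrix(), families, grid=grid
            )
            best2, table2 = optimize_gap_penalties(
                db, self.identity_matrix(), families, grid=grid
            )
        assert len(table1) == len(grid)
        assert best1 == best2
        pd.testing.assert_frame_equal(table1, table2)
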