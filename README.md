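# idrsubmat

Substitution scoring matrices for intrinsically disordered regions (IDRs),
and the machinery to benchmark them in homology searches.

## The problem

Intrinsically disordered regions of proteins lack a stable fold, are
depleted in bulky hydrophobic residues, enriched in polar and charged ones,
and substitute faster than ordered regions. General-purpose matrices such as
the BLOSUM series were estimated from alignment blocks that are essentially
devoid of disorder, so they mis-score exactly the substitutions that
dominate IDR evolution. `idrsubmat` estimates disorder-specific matrices
from disorder-annotated protein family alignments and provides a complete
evaluation framework — local-alignment search with E-values, coverage at a
fixed error rate, a concerted Bayesian bootstrap, and paired E-value
comparisons — for anyone building or comparing substitution matrices for
IDR-rich proteins.

## The method

**Matrix estimation.** A residue is annotated disordered when its disorder
score (IUPred-style, in [0, 1]) reaches 0.5 *and* its predicted secondary
structure is coil. Alignment columns in which every residue is disordered
and no row is gapped form *disordered blocks*. Within a column with residue
multiplicities nₐ, pair counts follow block counting: f_aa = nₐ(nₐ−1)/2 and
f_ab = nₐn_b, summed over all columns into the 210 unordered pair counts.
From these,

- target frequencies q_ij = f_ij / T,
- backgrounds p_i = q_ii + Σ_{j≠i} q_ij / 2,
- expected frequencies e_ii = p_i², e_ij = 2 p_i p_j,
- scores s_ij = round( log₂(q_ij / e_ij) / 0.5 ) (half-bit scale).

Each matrix is summarized by its matrix average (mean of the 210 pair
scores), expected score E = Σ p_i p_j s_ij (must be negative for local
alignment statistics), and relative entropy H = Σ q_ij log₂(q_ij / e_ij) in
bits; the Karlin–Altschul λ of the rounded matrix gives its implicit target
frequencies and implicit entropy.

**Evaluation.** All-vs-all Smith–Waterman searches (affine gaps, per-query
Gumbel E-values) produce a pooled, E-value-sorted relation list labeled
true/false positive by family co-membership. At an errors-per-query limit
(EPQ = 0.01: one false positive per hundred queries) sensitivity is the
quadratically normalized coverage

    Q_quad = (1/S) Σᵢ tᵢ / (sᵢ² − sᵢ)

over the S families of size sᵢ ≥ 2, with tᵢ accepted true relations for
family i. Confidence comes from a Bayesian bootstrap with Dirichlet(1,…,1)
sequence weights shared across the matrices under comparison ("concerted"),
compared by z = (Q̄_M − Q̄_P) / √((σ²_M + σ²_P)/N), significant at
|z| ≥ 1.96; common-homolog E-values are compared pairwise with the Wilcoxon
signed-rank test.

A synthetic family generator (ordered/disordered architecture, biased
compositions, star phylogeny with per-regime substitution rates, exact
ground-truth alignments and annotations) backs every stage without any
download.

## Worked example

```python
from idrsubmat import (
    generate_benchmark, build_matrix_from_blocks, GapPenalties,
    search_all_vs_all, extend_alphabet, label_relations, coverage_at_epq,
)
from idrsubmat.benchmark import extract_state_blocks
from idrsubmat.blocks import ResidueLabel
from idrsubmat.synthetic import scaled_regimes

# a corpus of 10 highly disordered families, and its disordered blocks
corpus = generate_benchmark(n_families=10, disorder_fraction=0.6, seed=7)
blocks = extract_state_blocks(corpus, ResidueLabel.DISORDERED)
matrix, model, params, implicit = build_matrix_from_blocks(
    blocks, pseudocount=1, name="DisMat62-like"
)
print(f"blocks counted:    {blocks.n_columns} columns")
print(f"matrix average:    {params.matrix_average:.3f}")
print(f"expected score E:  {params.expected_score:.4f}")
print(f"relative entropy H: {params.relative_entropy:.4f} bits "
      f"(implicit {implicit.implicit_entropy:.4f})")

# search a more divergent benchmark with the new matrix
test = generate_benchmark(n_families=10, disorder_fraction=0.6, seed=8,
                          regimes=scaled_regimes(5.0))
db = [s for fam in test.families for s in fam.members]
results = search_all_vs_all(db, extend_alphabet(matrix, model),
                            GapPenalties(-11, -2))
hits = [h for r in results for h in r.hits]
cov = coverage_at_epq(label_relations(hits, test.table), epq_limit=0.01)
print(f"coverage Q_quad:   {cov.q_quad:.4f} at EPQ <= 0.01 "
      f"({len(cov.accepted_tp)} true relations accepted)")
```

prints

```
blocks counted:    1440 columns
matrix average:    -0.590
expected score E:  -0.8448
relative entropy H: 0.6838 bits (implicit 0.5952)
coverage Q_quad:   1.0000 at EPQ <= 0.01 (120 true relations accepted)
```

The matrix average and expected score are negative (mismatches are
penalized on balance, a precondition for meaningful local alignments), the
block entropy ~0.68 bits sits in the range typical of disorder-specific
matrices, and on this small ten-family benchmark every within-family
relation is recovered before the first false positive.

The same steps are available from the shell via the `idrsubmat` console
script (`simulate`, `cluster`, `blocks`, `build`, `search`, `evaluate`,
`compare`; see `idrsubmat --help`).

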