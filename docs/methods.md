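# Methods

## Scope and model

`idrsubmat` covers the full path from disorder-annotated family alignments
to a benchmarked substitution matrix:

1. **Annotation.** Per-residue disorder scores in [0, 1] plus 3-state
   secondary structure (H/E/C). A residue is *disordered* iff
   score ≥ threshold (default 0.5, the conventional midpoint of
   IUPred-style predictors) **and** state = C. The conjunction is
   deliberate: coil-and-disordered positions evolve like disorder, while
   high-scoring residues inside helices/strands behave like ordered sites.
2. **Blocks.** Labels are projected through the gapped alignment; a column
   is kept iff it has no gap and every residue is disordered ("mixed
   structural states" are read as mixing across sequences within a column —
   the within-sequence reading would make the column filter a no-op).
   Ordered-column extraction is the symmetric operation and supplies control
   matrices.
3. **Counting and log-odds.** Block counting over the 210 unordered
   canonical pairs: f_aa = n_a(n_a−1)/2, f_ab = n_a·n_b per column. Target
   frequencies q = f/T, backgrounds p_i = q_ii + Σ_{j≠i} q_ij/2, expected
   e under independence, scores s_ij = round(log2(q_ij/e_ij)/scale). No
   within-block sequence weighting is applied: identity-level pre-clustering
   to centroids (the `cluster_sequences` operation, greedy UCLUST-style)
   plays that role, and the clustering identity level *is* the matrix's
   level. Non-canonical residues (X, B, Z, U) never enter counts.
4. **Search.** Smith–Waterman with affine gaps; a gap of length k costs
   open + (k−1)·extend (FASTA/SSEARCH convention — the quoted penalty grids
   −5…−20 / −1…−3 are pairs in that convention). Traceback tie order is
   diagonal > up > left, making reported alignments deterministic. E-values
   come from a per-query method-of-moments Gumbel fit to the query's raw
   scores against the database, with the top 2% trimmed to censor presumed
   homologs; E(s) = db_size · (1 − exp(−exp(−(s−μ)/β))). This is simpler
   than SSEARCH's length-regression statistics: absolute E-values differ,
   rankings are the contract. Externally produced 12-column tabular hit
   lists can be ingested instead for exact replication work.
5. **Evaluation.** Pooled relations are sorted by E-value; tie groups are
   accepted or rejected whole (ordering within a tie is arbitrary). The
   accepted prefix is the largest with (#FP)/(#queries) ≤ EPQ (default
   0.01). Q_quad averages tᵢ/(sᵢ²−sᵢ) over families of size ≥ 2 (a
   singleton family has no within-family relation and would divide by
   zero). The Bayesian bootstrap draws one Dirichlet(1,…,1) weight vector
   per replicate over the *whole* database, assigned to sequence ids in
   sorted order so that two hit sets over the same database receive
   identical draws from the same seed — this is what makes the bootstrap
   "concerted" and the Z statistic a paired comparison. The accepted prefix
   is held fixed at the unweighted EPQ solution rather than re-derived per
   replicate: re-thresholding inside replicates would mix acceptance noise
   into the weight distribution and is not needed for a paired comparison.
   The Wilcoxon test on common-homolog log10 E-values is the paired
   signed-rank variant (the samples are the same homolog pairs), normal
   approximation with midranks, tie and continuity corrections; external
   E-values of exactly 0 are floored to 1e-300 before the log.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| disorder threshold | 0.5 | score | predictor convention |
| LOD scale | 0.5 | bits/unit | half-bit, BLOSUM convention |
| pseudocount | 0 (1 recommended for small corpora) | counts/pair | zero-count pairs are a hard error by default so smoothing is never silent |
| gap open / extend | −11 / −2 | score units | common protein defaults; `optimize_gap_penalties` scans −5…−20 × −1…−3 |
| EPQ limit | 0.01 | FP/query | one false positive per hundred queries |
| bootstrap replicates | 500 | — | enough for a stable variance at desk scale |
| Z significance | 1.96 | — | 97.5th percentile of the normal |
| min sequence length | 100 | residues | family-database inclusion filter |

## The synthetic generator

Families evolve on a star phylogeny from a segment-wise ancestor: each
site substitutes with probability 1 − exp(−rate) per branch, replacements
drawn from the regime composition conditioned on change. Disordered
segments use a polar/charged/small-enriched composition (P, E, S, Q, K, R,
G, A, D, N carry 75% of the mass) at 0.5 substitutions/site/branch;
ordered segments a hydrophobic-enriched composition (W, C, F, I, Y, V, L,
M at 60%) at 0.1 — the rate ordering and compositional bias that
characterize real IDRs. Annotations are exact (score 0.9/C in disordered
segments, 0.1/H in ordered), and with no indels the emitted alignment is
the positional ground truth. The closed-form leaf-pair distribution
(`stationary_pair_distribution`) is the oracle for parameter-recovery
tests.

Indels are off by default (the alignment is then strictly positional);
`evolve_family(..., indel_rate=...)` switches on geometric-length
insertions and per-site deletions confined to disordered segments —
mirroring where indels accumulate in real proteins — and the emitted
alignment remains the ground truth, not a re-alignment.

What the generator does **not** emulate: site-rate heterogeneity
within a regime, non-star phylogenies, linear motifs inside IDRs, and
annotation noise (real IUPred/SSpro calls are imperfect; here they are
perfect by construction). Passing tests therefore demonstrate the
correctness of counting, scoring and evaluation machinery and the
direction of the disordered-vs-ordered effect — not absolute performance
on real proteomes.

## Benchmark design

The summary experiment (`idrsubmat.benchmark.run_headline_comparison`,
also behind `scripts/acceptance.py`) splits matrix estimation from
testing, as real matrix studies do:

- **Corpus** (matrix training): 30 families × 4 members × 240 residues,
  60% disordered, default rates. Its disordered blocks give block
  relative entropy ≈ 0.65 bits — the entropy band where disorder-specific
  matrices live — and its ordered columns give the control matrix.
- **Test database**: same architecture, fresh seed, substitution rates
  scaled ×5 (`scaled_regimes(5.0)`), i.e. remote homologs: disordered
  segments near substitution saturation, ordered segments ≈ 40% identity.
  At ×1 divergence every matrix saturates coverage at 1.0 and no
  comparison is possible; ×5 puts detection in the regime where matrix
  quality decides the outcome.

Problem sizes were chosen so the whole experiment runs in well under ten
minutes on one CPU; they are stated in the JSON report's `n` fields.

A full-scale reproduction against the original study's data is possible
but out of desk scope: download the published family datasets and matrix
files, run SSEARCH (or this engine) over the HD/MD/LD test sets across the
gap-penalty grid, ingest the tabular hits via `read_hits_tabular`, and
evaluate with `coverage_at_epq`/`bayesian_bootstrap` exactly as above.
The published matrix files, once placed under `tests/data/published/`,
activate the matrix-average regression checks in the test suite.

## Numerical choices

- Rounding of log-odds: nearest integer, ties away from zero.
- Karlin–Altschul λ: bracketed Brent root of Σ p_i p_j e^{λ s_ij} − 1 to
  |f| < 1e-10; requires E < 0 and a positive score. Two entropies are
  reported per matrix — the block-level H of the unrounded frequencies and
  the implicit H of the rounded integer matrix — because rounding loses
  information and the two genuinely differ.
- Gumbel fit: β = √(6·var)/π, μ = mean − γβ. Trimming the top 2% biases β
  slightly low on a pure null sample (conservative E-values); fits with
  `trim=0` are exact on Gumbel data.
- Greedy clustering identity: matches / alignment columns of a global
  alignment (match +1, mismatch −1, gap −2), terminal gap columns
  excluded; ties on length break by input order.
- Degenerate inputs: columns of depth < 2 contribute nothing (warned);
  databases smaller than 31 sequences fall back to a pooled Gumbel fit
  (warned); empty block sets error unless a pseudocount is given.
- Dirichlet weights depend only on (seed, sorted sequence ids), never on
  the hit sets, so comparisons stay paired by construction.

## Known limitations

- E-values are calibrated per query by moments, not by length regression;
  they order hits correctly but are not exchangeable with SSEARCH's.
- The greedy clustering emulates UCLUST semantics; it is order-dependent
  by design and not identical to any proprietary implementation.
- `optimize_gap_penalties` re-runs the full search per grid point; at the
  default 33-point grid this is meant for small databases.
- The synthetic benchmark shows directionality (disordered-block matrices
  beat ordered-column matrices on disordered remote homologs), not
  magnitudes comparable to real-proteome coverage values.
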