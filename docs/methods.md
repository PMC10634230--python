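# Methods

## Sequence metrics

All sequences are uppercased with T mapped to U on read; N is allowed and
treated as a non-U, non-matching base. Coordinates are 1-based and
inclusive at both ends, so the interval 105..851 has length 747 nt. When
a gene has several transcript variants under the same symbol only the
longest is analyzed, with length ties broken by the lexicographically
smallest accession so results are deterministic.

Two UU-counting conventions are implemented:

* **non-overlapping** (default): greedy left-to-right disjoint matches of
  `UU`, the semantics of ordinary string-count functions (Python
  `str.count`, R `stringr::str_count`). The default follows the original
  analysis tooling of this kind of screen, which counted motifs with
  string-count semantics; within a run of k uridines it counts ⌊k/2⌋.
* **overlapping**: every position i with s[i] = s[i+1] = U; a run of k
  uridines counts k − 1.

The two agree except inside U-runs of length ≥ 3, and always satisfy
overlapping ≥ non-overlapping ≥ ⌈overlapping/2⌉. The maximum UU richness
evaluates every window start (step 1) and attributes a UU to a window
only when both bases lie inside it; sequences shorter than the window
form a single window. The reported start is the smallest position
attaining the maximum. Motif search is exact (no IUPAC degeneracy), with
overlapping hits reported in ascending order.

## Expression processing

The low-count filter drops a gene when the fraction of samples with
fewer than `threshold` (25) reads is ≥ `fraction` (0.10); the fraction
boundary is inclusive, the read boundary strict. Filtering is applied per
tissue, and TPM is then recomputed on the retained gene universe so that
abundances remain comparable across the genes actually analyzed (columns
sum to 10⁶ after filtering). Gene length for TPM is the length of the
selected longest variant.

Sex bias is log2 of the ratio of female to male mean TPM with a
pseudocount (default 0.01 TPM) added to both means. The pseudocount keeps
single-sex genes finite while perturbing strong ratios (the hundreds-fold
regime) by well under 1%. The ranking stage uses this raw-mean fold
change and the mean TPM in female samples as the expression criterion;
both choices are configurable. The eight anatomically sex-specific
tissues (uterus, vagina, breast, ovary, cervix uteri, fallopian tube,
prostate, testis) are excluded before any sex comparison.

## Moderated differential expression

Gene-wise two-group tests on log2(TPM + pseudocount) use a moderated t
with empirical-Bayes variance shrinkage. With pooled variance s²_g on
d = n − 2 df, the posterior variance is s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d)
and t_g = Δ_g / (s̃_g √(1/n_F + 1/n_M)) is referred to Student's t on
d₀ + d df. The hyperparameters come from a closed-form method of moments
on the scaled-F marginal s²/s₀² ~ F(d, d₀): with r = Var[s²]/E[s²]²,
d₀ = (4rd + 2d − 4)/(rd − 2) and s₀² = E[s²](d₀ − 2)/d₀ when rd > 2,
otherwise d₀ = ∞ (homogeneous variances; the test then uses the common
variance and a normal reference). Genes with zero variance in both
groups remain testable through the moderation; a zero difference there
yields p = 1 by definition, not NaN. This moderated-t formulation is a
deliberate, documented stand-in for a negative-binomial GLM eBayes fit:
it is closed-form, calibration-testable, and operates on the same
log-expression scale as the fold-change criterion. Multiple testing uses
Benjamini–Yekutieli (α = 0.05), which controls FDR under arbitrary
dependence at the price of the harmonic-sum factor c(m) = Σ 1/k.

## Ligation score

Each of the four criteria — total UU count, maximum UU richness, sex
bias (strongest male bias ranked 1), expression — is ranked ascending
with average ranks on ties (this conserves total rank mass: every
criterion's ranks average (N+1)/2). The TLR7 ligation score is the sum
of the four ranks, so it is invariant under any strictly monotone
transform of the criterion values. Per tissue the score is normalized by
the tissue maximum; the cross-tissue summary averages the normalized
score over tissues where the gene passed filters (presence-only
averaging; zero-filling would penalize tissue-restricted genes for
missingness, so the number of contributing tissues is reported instead).
Percentile positions are reported from the descending score position,
rounded half-up to two decimals (rank 4 of 15,003 → top 0.03%).

## Single-cell module score and screen

The per-cell module score is gene-set mean minus control mean, with
controls matched on expression: genes are assigned to `n_bins` (24)
equal-frequency bins by average expression across cells (ties broken by
a seeded shuffle), and each gene-set gene draws `n_ctrl` (100) control
genes with replacement from its own bin. These defaults are the
long-standing defaults of this score in the single-cell literature.
Subtraction of bin-matched controls cancels any cell-constant offset
exactly. The gene set itself is *not* excluded from the control pool
(so in a degenerate one-gene-per-bin configuration the score is exactly
zero); consequently, in very small gene universes where the set
dominates its bins the score contrast shrinks — real applications have
thousands of genes per bin and the effect is negligible.

The patient screen drops patients contributing fewer than `min_cells`
(10) cells, averages score and gene expression per patient, and computes
per-gene Pearson r (two-sided p) across patients, flagging positive
correlates (r > 0, p < 0.05). At least 3 retained patients are required;
constant genes get r = NaN rather than a fabricated value. The IFN gene
set is a required input file — membership is defined by the upstream
literature, not re-derived here — and removal of contaminating cell
types is delegated to the input cell whitelist.

## Assay formulas

ΔΔCt fold change 2^−ΔΔCt; released-RNA relative quantity 2^(Ct_ref −
Ct_target) × R, oriented so a more abundant target (lower Ct) raises the
output, with R the treated/live RNA-yield ratio; reporter fold induction
(A_treated − A_untreated)/(A_comparator − A_untreated), undefined when
the comparator equals the untreated baseline.

## Synthetic-data generators

The generators define the conditions under which the pipeline is
validated. Background transcripts are i.i.d. uniform A/C/G/U (a
human-like U fraction is configurable), lengths uniform on 300–3,000 nt;
the planted gene is 3,000 nt with a 5' block of 820 nt at U-density 0.8
starting at nucleotide 181 (emulating a U-rich repeat region) and one
embedded GUCCUUCAA copy at a recorded position. Counts are negative
binomial (dispersion 0.1) with lognormal per-gene means (meanlog 7.5,
sdlog 1.2 — deep enough that the 25-read filter bites only the low
tail), per-tissue lognormal wobble (sdlog 0.3), and log-uniform
library-size factors within 3×. The planted gene has male mean 200 and a
female:male ratio of 472, the regime of a female-specific lncRNA that is
simultaneously the most sex-biased and among the most abundant
transcripts. The single-cell generator draws a per-patient IFN intensity
uniform on 0.2–2.0 and shifts the 20 IFN-module genes plus one tracking
gene by `effect × intensity` on a clipped-normal log-like scale
(baselines uniform 0.1–4.0, noise SD 0.5); one patient is always emitted
with 9 cells. A master seed splits into fixed per-stage streams
(`default_rng([seed, stage])`), making every output a pure function of
(config, seed).

What the generators do *not* emulate: real tissue–tissue expression
covariance, GC/length biases, single-cell dropout and depth variation,
and correlated gene programs beyond the planted one. Passing tests
therefore demonstrate correctness of the computations and recoverability
of a strong planted signal, not performance on real GTEx-scale data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the screen at reduced scale
chosen to exercise every code path with comfortable statistical margins:
120–400 genes, 2–3 tissues, 8–20 samples per sex, 50 (tests) or 25
(script) independent recovery seeds, 2,000-gene null calibrations, and a
15-patient / 600-cell single-cell matrix. Sequence-metric oracles are
brute-force re-implementations checked up to 5 kb. TPM column sums are
verified to 10⁻⁶ relative tolerance; rank arithmetic is exact. Where the
variance-prior moment equations have no valid solution the code falls
back to d₀ = ∞ rather than clipping into an arbitrary finite prior.

## Known limitations

* The moderated-t stand-in is not numerically identical to an edgeR
  NB-GLM analysis; fold-change ranking (which drives the ligation score)
  does not depend on it.
* TPM is compositional: a planted gene taking ~10% of the female library
  compresses its own TPM fold change a few percent below the count-level
  ratio; the same effect exists in any TPM-based analysis.
* Exact-match motif search only; degenerate motifs and RNA secondary
  structure are out of scope.
* The full-length reference-transcript check (total and windowed UU
  counts of human XIST) requires the RefSeq NR_001564 sequence at
  `data/xist_refseq.fasta`; it is not bundled.
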