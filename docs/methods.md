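# Methods

This note records the models, numerical conventions and design choices
behind `emtscore`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The signed 2KS EMT score

Within one sample, genes are ranked by expression ascending with mid-ranks
for ties (ties therefore never create artificial separations: a constant
sample scores exactly 0). Writing `ECDF_Epi` and `ECDF_Mes` for the
empirical CDFs of the Epi- and Mes-signature gene ranks, the score is

    score = +sup(ECDF_Epi − ECDF_Mes)  if that supremum strictly dominates,
            −sup(ECDF_Mes − ECDF_Epi)  if the opposite dominates,
            0                          on an exact tie of the two suprema.

`|score|` equals the two-sample KS statistic D except in the (measure-zero)
tie case, where the score is defined as 0 but D is still used for the
p-value. Positive scores mean mesenchymal-like: highly expressed Mes genes
sit at high ranks, so the Epi ECDF rises first. The signed-supremum
convention and the tie rules (score 0 → intermediate-Epi) are this package's
documented choices; the underlying publication record for this family of
scores does not fix them.

**p-values.** Default: asymptotic Kolmogorov distribution evaluated at
`D·sqrt(n_epi·n_mes/(n_epi+n_mes))`, matching common 2KS implementations.
An exact mode enumerates the permutation distribution of D over all label
assignments for `n_epi + n_mes ≤ 20`, assuming untied ranks.

**Coverage.** At least 3 genes per signature side must be present in the
matrix (degenerate 1–2 gene ECDFs are uninformative); a warning is emitted
when under half of a side is found. Signature weights are provenance only —
the ECDF construction is unweighted.

## ssGSEA enrichment

Genes are walked in descending expression order (ties broken by gene
position, deterministically). `P_in` accumulates mass proportional to
(ascending mid-rank)^α over in-set genes, normalized to total 1; `P_out`
accumulates uniform mass `1/(n−k)` over out-of-set genes. The enrichment
score is `Σ_i (P_in(i) − P_out(i))` over all positions — the running-sum
integral form, positive when the set concentrates at high expression. The
exponent defaults to α = 0.25 (configurable in [0, 1]); at α = 0 the score
is a pure rank statistic, invariant under strictly increasing transforms
and exactly negated by reversing the expression ordering. No cross-sample
normalization is applied; comparing ES across cohorts is the caller's
responsibility.

## SAM

`d_g = (mean_Mes − mean_Epi)/(s_g + s0)` with the pooled per-gene standard
error `s_g` and fudge factor `s0`, by default the 5th percentile of the
`s_g` distribution; the coefficient-of-variation minimization over
percentile candidates {0, 5, …, 100} is available as `s0_method="tusher"`.
When the requested permutation count meets or exceeds the number of
distinct label assignments, the null is enumerated exhaustively (and then
label-swap symmetry of q is exact; with sampled permutations it holds in
distribution only). The q-value% at a gene's |d| cut is

    q = 100 · median over permutations of #{|d*| ≥ cut} / #{|d| ≥ cut},

capped at 100 and made monotone non-increasing in |d| by a running minimum
from the least-significant end. Genes whose moderated denominator is
exactly zero (constant data) receive d = 0.

A structural property of this median-based q worth knowing: under a pure
null, the top-ranked gene receives q = 0 exactly when the observed maximum
|d| exceeds the median of the permutation maxima, which by label
exchangeability happens in about half of null datasets. A q = 0 call on a
single gene is therefore *not* strong evidence by itself; the derivation
pipeline couples it with the per-gene ROC threshold, and real signatures
rest on effect sizes far outside the permutation range.

## Per-gene ROC

AUC = P(random Mes value > random Epi value) + ½·P(tie), computed from
mid-ranks (equivalent to normalized Mann–Whitney U). Swapping the labels
maps AUC to 1 − AUC.

## Gene selection

Mes: q ≤ 0% and AUC > 0.8 and d > 0; Epi: q ≤ 0% and AUC < 0.2 and d < 0
(all thresholds configurable; the upper/lower ROC endpoints 0.85/0.15 are
reachable via flags). Genes with conflicting d/ROC directions are excluded
with a warning. Selection is monotone in the thresholds: relaxing any of
them never removes a selected gene.

## Metagene probit phenotype prediction

The phenotype classifier is a deterministic approximation of Bayesian
binary probit regression on metagenes: genes are standardized over the
pooled training samples (sd via ddof = 1; constant genes get sd 1), the
top-k left singular vectors of the standardized training matrix define
metagene loadings (k = 2 by default), each sign-fixed so its loading on the
Mes-group mean is positive, and a probit of phenotype (Mes = 1) on the
metagene coordinates is fitted by Newton/IRLS with an L2 penalty
(ridge = 1e-3, intercept unpenalized) and step halving on the penalized
objective. The ridge keeps coefficients finite on separable training
groups. Prediction standardizes new samples with the training moments;
model genes absent from a matrix are imputed at the training mean (zero
after standardization) with a warning, and more than 50% missing is an
error. No claim of numerical equivalence with any MCMC-based probit
implementation is made — the model family (probit on SVD metagenes) is the
same, the fit is maximum penalized likelihood.

## Derivation pipeline

Stages: ssGSEA on the published sets → marker-based orientation (the chosen
set maximizes |mean ρ over Mes markers − mean ρ over Epi markers|; the sign
orients the ranking so that higher = more Mes) → probit training on
`n_seed` extremes per side (default 15, warning outside 10–20) → phenotype
probabilities for all samples → extreme selection (25% per side for cell
lines, 100 per side for tumours) → SAM/ROC selection → per-gene statistics
(log2 fold-change mean_Mes − mean_Epi, q%, AUC, cohort size). Stages 1–3
can be iterated (`max_iter`); iteration stops early when the training
extreme membership is unchanged. Inputs are assumed log2-scale and
normalized upstream; duplicate gene rows are collapsed by arithmetic mean
on the log2 scale at load time (a documented choice — probe-collapse
practice varies), and gene identifiers are matched by exact trimmed string.

## Generic combination

The per-gene weight over the D diseases whose signature contains the gene:

    w_g = Σ_d |fc_gd| · (1 − q_gd/100) · 2·|ROC_gd − 0.5| · √n_d.

Each factor is monotone in the direction required of it (large fold-change,
small q, ROC far from chance, large cohort); the √n damping prevents one
huge cohort from dominating. This concrete algebraic form is a
reconstruction from those qualitative requirements — the historically used
expression was never published in reproducible form — and is isolated in
`gene_weight` so that substituting another form is a one-function change.
Weights are z-transformed (population = all genes in ≥1 disease signature,
ddof = 0 so the z population has exactly unit variance) and genes are kept
when they satisfy the membership rule (default: present in all D), have
z > 3.09 strictly (the upper 0.001 normal quantile), and carry a consistent
direction; direction conflicts are excluded with a warning. The z threshold
is only meaningful when consensus genes are a minority of the scored
population — if most scored genes are consensus, no gene can sit 3 standard
deviations above the mean.

## Synthetic cohorts

`generate_cohort` draws `x_gs = μ_g + β_g·φ_s + ε_gs` with per-sample EMT
position φ ∈ [−1, +1] (uniform, or two clusters at ±0.8 ± N(0, 0.1) for
two-group designs), β = +b for the Mes block, −b for the Epi block, 0 for
background, baselines μ_g ~ N(7, 1) (log2-microarray-like) and noise
ε ~ N(0, σ²). Defaults: 200 samples, 500 background genes, 50 + 50 block
genes, b = 2 (log2 units), σ = 0.5 — a clearly detectable but noisy axis.
Because baselines spread with sd 1, a σ = 0 extreme sample scores exactly
±1 only when b dominates the baseline spread between block genes (at b = 2
an inversion between one Mes and one Epi gene has probability
Φ(−2b/√2) ≈ 0.2% per pair); exactness tests therefore use b = 8, where that
probability is ~1e−8. `generate_multidisease` defaults (D = 6, 10 + 10
shared consensus genes, 60 disease-private signature genes per disease, 120
samples and 300 background genes per cohort, two-cluster φ) make consensus
genes ~5% of the pooled signature population, so their expected z under the
weight above is ≈ 4 — comfortably but not trivially past the 3.09 cut.

What the generator does **not** emulate: probe-level artifacts, batch
structure, stromal admixture, correlated background genes, non-linear
response to the EMT axis, or dropout. Passing recovery tests therefore
demonstrates correctness of the computational chain under a linear
single-factor model, not performance on real cohorts.

## Problem sizes and determinism

Recovery experiments run at the generator defaults above (a 600 × 200
matrix for single-cohort derivation; six 380 × 120 matrices for the
multi-disease pipeline; 1000 sampled label permutations for SAM, exhaustive
enumeration for small groups). All stochastic steps take explicit integer
seeds; the same seed reproduces matrices bit-identically. Floating-point
output uses 17-significant-digit formatting so matrix round trips are
exact.

## Known limitations

* Gene identifiers are matched literally; alias/probe mapping is upstream.
* The exact permutation p-value assumes untied ranks.
* The probit stand-in reports no posterior uncertainty.
* The reconstructed combination weight is one of several forms consistent
  with the stated qualitative behaviour.
* Survival analysis, meta-analysis and batch correction are out of scope;
  standard tools (lifelines, R survival/metafor, ComBat) apply downstream.
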