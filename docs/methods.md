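# Methods

This note documents the statistical procedures `panprost` implements, the
defaults it ships, the design decisions taken where choices were genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Study containers and harmonization

A study bundle holds up to three assays (log2 expression, discretized
copy-number calls in {−2…2}, long-format mutation calls) plus a clinical
table, all indexed by sample id; every assay sample must appear in the
clinical table. The clinical dictionary is deliberately small: sample types
{primary, metastatic, normal, BPH, atrophic}, grade groups {≤6, 7, ≥8},
binary event indicators, non-negative follow-up times in months. Validation
produces a violation list rather than exceptions — dirty clinical data is a
data-quality finding, not a crash. Matching of controlled vocabulary is
case-sensitive; case-only mismatches are flagged with a normalization hint.
The missing-value tokens are a literal `NA` or an empty cell.

Gene harmonization maps row symbols through an alias dictionary to
canonical symbols. An alias claimed by more than one canonical symbol is
unresolvable without an explicit priority flag; such rows are dropped and
logged rather than guessed — the same philosophy as reporting 1-to-many
matches as unusable in coverage reports. Rows that collapse onto one
canonical symbol are averaged by default (replicate probes measuring one
transcript), with a max-variance alternative for users who prefer the most
informative probe. Harmonization is idempotent.

Grade-group mapping uses precedence reported sum > primary+secondary > ISUP
(1 → ≤6, 2–3 → 7, 4–5 → ≥8). A sum outside 2–10 is rejected; completely
missing inputs yield a missing group, since absence of grading is data.

## Signature scoring

A signature is a list of (gene, aliases, direction, weight, group)
components plus a per-gene normalization (z-score with sample sd,
fractional average-rank percentile in (0,1], or mean-centering) and a
combination rule:

- mean: s_j = (1/m) Σ d_i x̃_ij
- weighted sum: s_j = Σ w_i d_i x̃_ij
- grouped linear: s_j = Σ_g w_g (1/|g|) Σ_{i∈g} d_i x̃_ij
- signed percentile mean: mean percentile of up-markers − mean percentile
  of down-markers

Only genes with exactly one matching row (after aliases) are scored;
1-to-many matches are excluded as unusable. Scoring requires at least
`min_fraction` (default 0.5) of the signature's genes present, and ≥3
samples for z-score/percentile normalization (a 2-sample z-score is
meaningless). A zero-variance gene's z-score is set to 0 and logged rather
than propagating infinities.

The AR score uses the mean of z-scores rather than the sum: the two are
identical up to the factor m at full coverage, but the mean remains
comparable when genes are missing, which is precisely the regime the
dropout benchmark studies.

Shipped signature constants (the Oncotype DX group weights, the Decipher
marker list and directions, the Prolaris gene list) are research
reconstructions transcribed from the published research-use descriptions of
these assays; the scoring engine, not the constants, is the tested
contract, and the JSON files under `panprost/data/signatures/` are the
single place to edit if a user has better-sourced lists. Outputs are on
research scales (z-score or percentile units), not commercial report
scales. Published descriptions of the Decipher panel disagree on its size
(17 vs 20 vs 22 usable markers depending on platform); we ship 20 markers
and let coverage reports surface whatever subset a dataset actually
contains.

## Dropout robustness benchmark

For each k in the requested range, k-subsets of the signature's genes are
drawn without replacement (all C(m,k) subsets enumerated when fewer than
the requested count), the score is recomputed without those genes, and
Pearson-correlated with the full-gene score across samples (Spearman via
flag). Defaults follow the benchmark design the resource used: 100
combinations (50 recommended for the 34-gene cell-cycle signature, whose
subset space is large), k = 1…10 for 20+-gene signatures and 1…5 for
12-gene ones. Each k derives its own child RNG stream from the root seed,
so extending the k-range never perturbs existing rows. k = 0 is allowed as
a sanity mode and returns correlations exactly 1.

For m i.i.d. standardized genes under the mean rule, the reduced score is
the mean of m−k of the m z-variables, giving corr² ≈ (m−k)/m; the test
suite verifies the empirical mean corr² within ±0.05 of this closed form at
1,000 combinations.

## Moderated t and cross-study combination

Per study, logFC is the difference of group means of log2 expression
(grade ≥8 minus ≤6), complete-case per gene per group; groups need ≥2
samples each. The per-gene pooled variance s²_g on d_g = n_h + n_l − 2 df
is shrunk toward an empirical-Bayes prior (d₀, s₀²) estimated by
moment-matching the log-variances: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of Var(e) over the mean
of ψ′(d_g/2) estimates ψ′(d₀/2), inverted by Newton iteration (tolerance
1e-8); s₀² follows from the mean of e. Non-positive excess falls back to
d₀ = ∞ (all genes share s₀²). The moderated statistic is
t̃ = logFC / √(s̃² (1/n_h + 1/n_l)) with s̃² = (d₀s₀² + d_g s²_g)/(d₀+d_g),
two-sided p on d₀ + d_g df (normal when d₀ = ∞). Setting the prior df to 0
recovers the ordinary pooled t-test; both limits are exposed and tested.
The implementation is validated against an independent literal
transcription of these formulas (with an independent bracketed root-finder
for the trigamma inversion) to 1e-10, and its type-I error is calibrated on
10,000 null genes with correctly specified inverse-gamma variances.

Across studies, genes present in every study are combined by Fisher's
method on the two-sided p-values (X² = −2Σ ln pᵢ, upper tail of χ² with 2k
df), BH-adjusted across genes. Direction is enforced by a separate
sign-consistency filter — selected genes must have logFC of one sign in
every study — rather than by one-sided combination, which keeps the
combination symmetric and the direction rule explicit. Pairwise logFC
Pearson correlations and Spearman correlations of per-gene
anchor-correlation profiles (e.g. against AR or ERG) quantify cross-study
agreement; constant genes yield missing correlations, logged.

## Alterations and mutual exclusivity

A sample is altered in a gene iff its copy-number call is non-zero or it
carries ≥1 non-silent mutation. The non-zero rule is read literally:
shallow ±1 calls count, with a `deep_only` toggle for the stricter ±2
convention. Samples lacking one assay contribute no alterations from it and
are flagged — alteration fractions are then acknowledged undercounts, never
imputed. The pair statistic is OR = (Both × Neither)/(A-only × B-only) with
a two-sided Fisher exact test (point-probability rule), BH across a screen,
and stars at p < 0.05. A zero denominator with a positive numerator yields
OR = +∞ (labelled co-occurring); a Haldane-corrected OR (+0.5 to each cell)
is emitted alongside for plotting. The exact test is verified against
exhaustive hypergeometric enumeration for every 2×2 table with n ≤ 30.

## Survival

Tertile stratification takes the ⌈n/3⌉ highest scores as "high" by rank
(ties broken by ascending sample id — deterministic, no interpolated
quantile ambiguity). Kaplan–Meier estimation, the log-rank test, and Cox
fitting are delegated to lifelines behind the module's interface; the Cox
default is Efron tie handling with Wald CIs, and the fit reports its tie
method and convergence flag in the output metadata since published analyses
rarely state them. Complete separation or non-convergence produces a
flagged fit with a diagnostic, not an exception. Grade groups enter
univariate Cox models as the ordinal coding ≤6→0, 7→1, ≥8→2, so the
reported HR is per unit increase of grade group. The package also computes
the Cox partial-likelihood score statistic at β = 0 in closed form; for a
binary covariate without tied event times this equals the log-rank
chi-square, an identity the tests check against the independent log-rank
routine.

## Synthetic data

The generator's defaults describe the study conditions the tests run under:
4 studies × 60 primary tumors, 1,000 genes, grade-group probabilities
(0.35, 0.35, 0.30), 50 planted grade genes at |logFC| = 1 (the ≥8 group
shifted by the full δ, grade 7 by δ/2), gene variances from a scaled
inverse chi-square prior with d₀ = 4 and s₀² = 0.05 (microarray-like log2
noise; a log-normal misspecified mode exists to probe robustness), a
20-marker latent program with loading 0.5 whose per-sample N(0,1) score
drives exponential recurrence at hazard ∝ exp(β·score) with β = ln 2 and
baseline 0.02 events/month, uniform censoring tuned by bisection to a 30%
censored fraction, 90% per-study gene-universe retention (planted and
marker genes always kept), and an 8-gene alteration block at pairwise
OR = 3 with mutation probability 0.15 and silent fraction 0.3. Calibration
tests override sizes explicitly (e.g. 5,000 genes, 100 planted, two
extreme grade groups at 30/30 for meta-analysis recovery; n = 500 with 30%
censoring for Cox recovery); these sizes were chosen as the smallest at
which the corresponding asymptotic guarantees are meaningful.

Alteration pairs are drawn from the exact joint 2×2 distribution implied by
the margins and target OR (p₁₁ solves the OR quadratic; feasibility is
checked). `simulate_multistudy` returns `(studies, truth)` where the truth
object records planted genes, latent scores, and the true β and OR for
recovery tests; the CLI writes it as `truth.json`.

What the generator does **not** emulate: platform/batch effects, probe-level
noise, correlated gene-gene structure beyond the single latent factor,
informative censoring, or realistic CNA segment structure. Passing tests
therefore demonstrate correctness of the statistical machinery under its
own assumptions, not performance on any real cohort; the published
quantities that depend on specific external cohorts (printed dropout
correlations, meta-analysis gene counts, inter-study correlations, hazard
ratios) are out of reach by design and are not asserted anywhere.

## Numerical choices

- Sample sd (n−1) for z-scores; average ranks for percentile ties.
- Trigamma inversion by Newton iteration, tolerance 1e-8; p-values clipped
  to [tiny, 1] to avoid log(0) downstream.
- Fisher's method requires p ∈ (0,1]; p = 0 is a domain error, since a true
  zero p-value is evidence of an upstream bug, not of infinite evidence.
- Odds ratios report +∞/0/NaN faithfully for degenerate tables; only the
  Haldane-corrected companion is finite by construction.
- RNG throughout is numpy's PCG64 via `default_rng`; child streams are
  derived from (seed, tag) pairs so components are independently
  reproducible.
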