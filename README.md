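# panprost

Harmonized multi-study prostate-cancer omics analysis in Python.

Prostate cancer molecular studies are scattered across platforms and
repositories, with inconsistent gene symbols, clinical vocabularies, and
endpoint definitions. `panprost` implements the computational core needed to
work with such a harmonized multi-study resource:

- **Study containers** (`panprost.studydata`): per-study bundles of log2
  expression, GISTIC-style discretized copy-number calls (−2 deep loss … +2
  amplification), MAF-like mutation tables, and a clinical table validated
  against a controlled data dictionary (sample types, Gleason grade groups
  ≤6 / 7 / ≥8, biochemical-recurrence and overall-survival endpoints).
  Gene symbols are harmonized to canonical (HGNC-style) symbols through an
  alias dictionary; duplicate rows collapse by mean (or max variance);
  ISUP groups 1–5 map onto the Gleason grade groups (1 → ≤6, 2–3 → 7,
  4–5 → ≥8).
- **Signature scoring** (`panprost.signatures`): a scoring engine covering
  per-gene z-score / percentile-rank / centering normalization and mean,
  weighted-sum, grouped-linear, and signed-percentile-mean combination
  rules. Shipped signatures: a 20-gene androgen-receptor (AR) activity
  score (mean of z-scores, s_j = (1/m) Σ_i z_ij), a 12-gene Oncotype
  DX-style grouped linear model, a 34-gene Prolaris-style cell-cycle
  progression mean, and a 20-marker Decipher-style signed percentile mean.
  Coverage reports classify each signature gene as a 1-to-1 match,
  1-to-many, or missing in a dataset; only 1-to-1 matches are scored.
- **Dropout robustness** (`panprost.missingness`): remove random k-subsets
  of a signature's genes, rescore, and correlate with the full-gene score —
  quantifying how robust a score is on platforms that lack some genes.
- **Cross-study differential expression** (`panprost.metade`): per-study
  logFC (mean log2 expression, grade ≥8 minus ≤6) with an empirical-Bayes
  moderated t-test (per-gene variance s²_g shrunk toward a moment-matched
  prior: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), t̃ on d₀ + d_g df), Fisher's
  method across studies (X² = −2 Σ ln pᵢ on 2k df), Benjamini–Hochberg
  adjustment, and a sign-consistency filter.
- **Alteration statistics** (`panprost.alterations`): a sample is altered
  in a gene iff it has any non-diploid copy-number call or a non-silent
  mutation; gene pairs are tested for co-occurrence/mutual exclusivity with
  OR = (Both × Neither)/(A-only × B-only) and a two-sided Fisher exact
  test.
- **Survival analysis** (`panprost.survival`): top-tertile (top 1/3 vs
  bottom 2/3) stratification, Kaplan–Meier curves, log-rank tests, and
  univariate Cox proportional-hazards fits (Efron ties), with grade groups
  coded 0/1/2 for per-unit-increase hazard ratios.
- **Synthetic studies** (`panprost.simdata`): a seeded generator producing
  dictionary-conformant multi-study bundles with planted differential
  genes, inverse-gamma gene variances, a latent program driving recurrence,
  and alteration pairs at a chosen odds ratio — so the whole pipeline is
  testable without any downloads.

## Worked example

```python
import panprost as pp

cfg = pp.SimConfig(seed=1)                      # 4 studies x 60 primary tumors
studies, truth = pp.simulate_multistudy(cfg)

# cross-study meta-differential-expression between Gleason grade groups
des = [pp.differential_expression(b) for b in studies]
res = pp.meta_de(des, q_threshold=0.01)
r, p, n = pp.pairwise_logfc_correlation(des[0], des[1])

# latent-program score -> tertile stratification -> Cox / log-rank
b = studies[0]
sv = pp.marker_score(truth.marker_genes, b.expression)
lab = pp.stratify_top_tertile(sv.scores)
sd = pp.make_survival(b.clinical.data, lab, endpoint="bcr")
fit = pp.cox_univariate(sd)
chi2, lp = pp.logrank_test(sd, lab)

# mutual exclusivity of copy-number + mutation alterations
am = pp.binarize_alterations(cna=b.cna, mutations=b.mutations)
t = pp.mutual_exclusivity(am, "PTEN", "TP53")
```

This prints, with the formatting used in the example script:

```
meta-DE: 25 up, 25 down of 652 common genes
study1 vs study2 logFC correlation: r=0.83 (n=833 genes)
top tertile vs rest: HR=2.74 [1.42, 5.31], Wald p=0.002754
log-rank: chi2=9.70, p=0.001846
PTEN/TP53: both=10 a_only=8 b_only=12 neither=30 OR=3.12 p=0.0781 (co-occurring)
```

Reading: of the 50 planted grade-group genes, the four-study Fisher
combination recovers all 50 (25 up, 25 down) at q < 0.01 with consistent
signs; samples in the top tertile of the latent-program score recur about
2.7× faster than the rest; and PTEN/TP53 alterations co-occur (OR > 1) but
do not reach significance at this study size.

The same pipeline is available from the shell:

```bash
panprost simulate --seed 7 --outdir sim/
panprost validate --clinical sim/study1_clinical.tsv
panprost score --expr sim/study1_expression.tsv --signature my_signature.json --out scores.tsv
panprost benchmark-missingness --expr sim/study1_expression.tsv --signature my_signature.json \
    --k-min 1 --k-max 5 --combos 100 --seed 42 --out bench.tsv
panprost meta-de --studies studies.yaml --q 0.01 --out-prefix de
panprost mutex --cna sim/study1_cna.tsv --maf sim/study1_mutations.maf --out mutex.tsv
panprost survival --scores scores.tsv --clinical sim/study1_clinical.tsv \
    --endpoint bcr --covariate top-tertile --out cox.tsv
```

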