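# Methods

## The experimental design being modelled

Differentiated primary human airway epithelial cultures from `n_donors = 4`
donors, each exposed for the differentiation period to four conditions:
control, IL-17A (10 ng/ml), dexamethasone (10 nM), and the combination —a
paired 2×2 factorial with donors as blocks, one insert per donor×condition.
Readouts are bulk RNA-seq counts and a FITC-dextran permeability assay
(higher basolateral tracer concentration = leakier epithelial barrier).

## Synthetic-data generator (`simdata`)

Counts for gene *g* in sample *j* are negative binomial with

```
mean_gj = s_j · µ_g · 2^( β_il17·I_j + β_dex·D_j + β_int·I_j·D_j + d_donor(j) + c_gj )
Var     = mean + α_g · mean²
```

- `µ_g ~ LogNormal(meanlog 5.5, sdlog 1.5)` — median baseline ≈ 245 counts,
  spanning roughly 10–10⁵, a realistic bulk-RNA-seq dynamic range. No
  library-size information is available for the emulated study, so these
  are documented defaults, and size factors `s_j` default to 1 with an
  optional log-normal multiplier (`libsize_sdlog`) so that normalization
  can be exercised on and off.
- `α_g = a0 + a1/µ_g` with `a0 = 0.01`, `a1 = 2` — the standard decreasing
  mean–dispersion trend; biological CV ≈ 10% for highly expressed genes.
- `d ~ Normal(0, donor_sd = 0.25)` log2 donor offsets shared across a
  donor's four samples, which is what makes the paired design informative.
- Gene classes (fractions chosen to mirror the observed imbalance of many
  IL-17A genes, few dexamethasone genes, very few pure-interaction genes):
  `il17_up_resistant` 10% (β_int = 0), `il17_up_sensitive` 2%
  (β_int = −β_il17, the combination returns to baseline), `il17_down` 5%,
  `dex_only` 2% (β_il17 = 0 and, by default, β_int = −β_dex: IL-17A
  abolishes the dexamethasone response), `interaction_only` 1%, `null` 80%.
  Genes are allocated by largest-remainder rounding with ties broken by
  class-name order, so counts are deterministic. Planted magnitudes are
  |log2FC| ~ Normal(2, 0.5) truncated at 0.1.
- Effects are parameterized in log2 and converted to natural log internally,
  because every reported fold change is log2-scale.

The permeability phenotype is
`P_j = base + gain·I_j·(1 − rescue·D_j) + ε`, defaults
`base 0.2, gain 0.6, rescue 0.8, noise sd 0.05` on a normalized
concentration scale: IL-17A disrupts the barrier, dexamethasone reverses
most of the disruption. A `n_cilia_genes = 50` "cilia" set — drawn from the
null class so the coupling is their only signal — has its log2 mean tilted
by `−cilia_coupling·(P_j − P̄)` with `cilia_coupling = 2`: leakier barrier,
lower cilia-gene expression.

What the generator does **not** emulate: batch effects beyond donor, GC or
length bias, outlier counts, correlated genes within pathways (class
membership is the only structure), or single-cell features. Passing tests
therefore demonstrate correctness of the estimators under a clean NB world,
not robustness to every artefact of real libraries.

## Differential expression (`decore`)

A deliberately small, fully documented NB pipeline rather than a wrapper
around an existing DE package:

- **Size factors**: median-of-ratios over genes nonzero in all samples,
  rescaled to geometric mean 1; a positive-counts fallback (with a warning)
  covers matrices with no all-nonzero gene.
- **Dispersions**: per-gene method-of-moments `α̂ = max((var−mean)/mean², 1e−8)`
  with the within-condition variance pooled across the four cells, a robust
  (Huber) regression of `α(µ) = a0 + a1/µ` over informative genes, and a
  log-scale convex combination `exp(w·log α̂ + (1−w)·log α_trend)` with
  `w = 0.5`. The shrinkage stabilizes the 4-replicate gene-wise estimates
  enough to keep Wald tests close to nominal.
- **GLM**: per-gene IRLS with log link and offset `log s_j`; working
  weights `µ/(1+αµ)`; convergence at 1e−8 in the coefficients, 100
  iterations maximum; |β| capped at 32 log2 units, and capped or
  non-converged genes flagged (p set to 1 in contrasts) rather than
  dropped. Standard errors from the inverse expected information.
  All-zero genes are removed before fitting (their fold changes are
  undefined) and reported via the row counts.
- **Design**: intercept, donor indicator blocks (fixed effects — with four
  donors, fixed blocks are stable and testable; random effects would buy
  nothing here), IL-17A, dexamethasone, interaction; donor pairing is a
  flag since the emulated analysis may or may not have paired. Contrasts:
  `il17_vs_ctrl`, `dex_vs_ctrl`, `combo_vs_ctrl` (= sum of the three
  effect coefficients), `interaction`.
- **Testing**: two-sided normal reference for the Wald statistic;
  Benjamini–Hochberg within each contrast (per-comparison adjusted p is the
  convention being mirrored). Omitted by design: fold-change shrinkage,
  independent filtering, outlier replacement.

Under the global null (2000 simulated genes, default trend) the observed
false-positive fraction at Padj < 0.05 is ≤ 0.2% per contrast and the Wald
p distribution for well-expressed genes sits within Kolmogorov distance
≈ 0.02–0.05 of uniform — the small-sample Wald test is mildly
anticonservative at n = 16, which the dispersion shrinkage keeps in check.

## Resistance score and signatures (`scoring`)

The score is computed on the log2 scale from the two contrast estimates:
`r = Δ_combo / Δ_il17`, `score = 100·clamp(r, 0, 1)`. The log scale makes
up- and down-regulated genes symmetric; clamping encodes "normalized to
100%": overshoot past baseline counts as fully reversed, amplification as
fully resistant. Eligibility is the point estimate |Δ_il17| ≥ log2(1.5)
with no significance filter by default (an optional Padj filter exists,
since an eligible-universe definition by fold change alone or jointly with
significance are both defensible). Sensitive ⇔ score < 50%. Percentages are
rounded half-away-from-zero to two decimals and reconciled by largest
remainder so the pair always sums to 100.00.

Z-scores standardize `log2(count/s + 1)` per gene across all samples
(ddof = 1); the pseudocount makes the transform defined at zero, and
constant genes are excluded with a warning since they cannot be
standardized. (The printed z-score formula in the emulated study applies a
log to the standardized value itself, which is undefined for values below
the mean; standardizing the log-expression is the computable reading and is
what is implemented.) A signature score is the mean z over the set's
present genes per sample; group summaries report both the difference from
the control group and the ratio to it — the ratio is suppressed (NA) when
the control mean is within 1e−6 of zero, where it is meaningless.

## Enrichment (`enrich`)

Classic weighted running-sum statistic: over the list ranked by the signed
Wald statistic (log2FC and signed −log10 p are options), a member gene at
rank *i* adds `|score_i|^p / Σ_hits|score|^p` (default p = 1) and a
non-member subtracts `1/(N − N_hits)`; ES is the signed extremum. The
extremum search is exact and O(k): the maximum is always attained just
after a hit and the minimum just before one, and a |max| = |min| tie
resolves positive (with a 1e−12 guard so floating-point summation order
cannot flip a genuine tie).

The null permutes **gene labels** (uniform re-draws of the member
positions, same set size). Sample permutation is the classical default but
is unusable here: a 4-donors-per-arm design has far too few distinct
relabelings. `NES = ES / mean(|null ES| of the same sign)`;
`p = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign null)`;
q is the standard tail-ratio FDR over pooled null and observed NES, with a
BH-on-permutation-p fallback whenever a sign stratum holds fewer than 50
null values. Set-size filters 10–500; `n_perm < 50` is refused outright.
Random sets reject at 3–6% at nominal α = 0.05 over 400 calibration runs.

## Phenotype association (`phenoassoc`)

The permeability phenotype is standardized (per-SD coefficients, since raw
fluorescence units are plate-reader dependent) and enters the NB-GLM as the
only non-block covariate next to donor indicators — covariate inclusion in
the count model, not post-hoc correlation of residuals, though a Spearman
mode is provided for comparison. Direction "up" = expression rises with
leakiness; the sign convention (higher FITC concentration = lower barrier
integrity) is fixed and documented here. Significant genes can be
cross-annotated with their IL-17A direction to reproduce the
up-with/down-with bookkeeping of a combined analysis.

Assay helpers: OLS standard curve `concentration = a·F + b` with flags for
negative (clamped) and out-of-calibration-range predictions; ΔΔCt with the
reference Ct as the arithmetic mean of the reference genes' Cts (geometric
mean on the expression scale — standard multi-reference practice),
`RQ = 2^(−ΔΔCt)` relative to the mean control ΔCt.

## Pipeline (`io`/`pipeline`/`cli`)

TSV in, TSV out ("NA" for missing), validation errors with file and line
numbers, a JSON manifest with config snapshot, seed, per-stage row counts
and sha256 checksums of every emitted file. Every number in a results file
is produced by the corresponding library function; the pipeline layer only
sequences and serializes. Stages are individually skippable; identical
config + seed reproduces all outputs byte-exactly.

## Problem sizes and numerical choices

Simulation-based checks use 2000 genes × 16 samples for calibration and
recovery (one NB-GLM fit per gene takes ~0.5 ms), 300–500 genes for
repeated-run studies (100 seeded runs for signature separation, 12 for
enrichment power), 199–500 permutations for permutation tests, and 400
draws for enrichment calibration — sizes at which the Monte-Carlo error of
each reported rate is comfortably below the margin being asserted.
Dispersion floor 1e−8; IRLS tolerance 1e−8; coefficient cap 32 log2 units;
ties in every ranking broken deterministically (gene id, set name).

## Known limitations

- The Wald test is asymptotic; at 4 donors it is mildly anticonservative
  for low-count genes (hence the mean-count conditioning in the calibration
  checks). No exact or quasi-likelihood small-sample correction is offered.
- The exact invariance of fold changes to rescaling one sample's counts
  holds on saturated designs; with replication the NB likelihood weights a
  deeper sample slightly more, shifting estimates at the 1e−3 level.
- The resistance score is a point-estimate ratio; no propagation of the
  two contrasts' standard errors into a score uncertainty is attempted.
- Gene-label permutation treats genes as exchangeable and ignores
  inter-gene correlation, which inflates enrichment confidence on strongly
  co-regulated real data; with four donors per arm there is no practical
  sample-permutation alternative.
- Headline gene counts of the emulated study (2861 IL-17A genes, 64
  dexamethasone genes, 9 interaction genes, 749 permeability-associated
  genes) depend on the unpublished raw data and are not reproduction
  targets; the package reproduces the published worked-example arithmetic
  and the qualitative structure on planted truth.
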