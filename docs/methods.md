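# Methods

## Droplet digital PCR quantification

A well partitions the reaction into `n` droplets of volume `V` µL
(default 8.5e-4, the nominal droplet volume of the QX200-class
generators; always a parameter, never a constant inside the math).  With
template concentration λ copies/µL and Poisson occupancy, a droplet is
negative with probability `exp(−λV)`, so from `k` positives out of `n`
the MLE is `λ̂ = −ln((n−k)/n)/V`.  This closed form is the exact
maximizer of the binomial likelihood; the test suite checks it against a
brute-force grid maximization to 1e-6 relative error.

The 95% CI uses the delta method on `−ln(p̂_neg)`:
`SE(λ̂) = sqrt((1−p̂_neg)/(n·p̂_neg))/V`, `CI = λ̂ ± 1.96·SE` floored at
zero.  Measured coverage over λV ∈ [0.05, 5] is ≈ 96%.  An exact
Clopper–Pearson transform would also be valid; the delta method was
chosen for transparency, and the CI computation is isolated in one place
so the method is swappable.

Boundary handling: all-negative wells report 0 with an `empty` flag;
all-positive wells are `saturated` and carried as *missing* (the MLE is
unbounded; assigning a lower bound would silently bias group means —
downstream, missing cells simply reduce the per-gene sample count).
Wells under 10,000 droplets are kept but flagged `low_droplet_count`.
These QC defaults are this package's own; instrument vendors do not
publish theirs.  Replicate wells for the same gene and sample are pooled
by summing droplets and positives before estimation.

Amplitude thresholding (when per-droplet fluorescence is available)
finds the contiguous two-partition of the sorted amplitudes minimizing
within-cluster variance (the 1-D optimal 2-means, O(n) by cumulative
sums) and thresholds at the midpoint of the inter-cluster gap.  A well
whose two "clusters" are separated by fewer than 4 pooled within-cluster
SDs is declared unimodal (`no_positive_cluster`, all droplets negative)
rather than guessed at: splitting a single Gaussian always produces a
separation of ≈ 2.65 pooled SDs and a uniform ≈ 3.46, while genuinely
bimodal ddPCR wells sit far above 4.

## RNA-seq differential expression

The engine is a deliberately transparent two-group negative-binomial
fitter, not a re-implementation of a full DE framework: no dispersion
shrinkage trend, no fold-change shrinkage, no independent filtering.
The screen requires calibrated two-group tests over ~300 genes; the
simpler machinery keeps every step auditable.

* **Size factors** — median-of-ratios over genes expressed in every
  sample, reported unnormalized.
* **TPM** — reads per kilobase rescaled to 1e6 per sample (exact by
  construction; asserted to 1e-6 relative in tests).
* **Dispersion** — per-gene method of moments on normalized counts
  `y = K/s`: pooled within-group variance vs. `q̄·mean(1/s) + α q̄²`,
  clipped to [1e-8, 10].  The floor and cap stabilize the estimate at
  n = 5 per group.
* **Fit** — IRLS for `log μ = log s + b0 + b1·x` (log link, offset),
  vectorized across all genes; coefficients clipped at |b| ≤ 20 so
  one-group-all-zero genes converge to a finite, huge-SE estimate rather
  than overflow (their Wald p goes to 1, which is the conservative and
  correct small-sample behaviour).
* **Inference** — Wald `z = b1/SE(b1)` referred to **t with n − 2 df**.
  With the dispersion known the normal reference is exactly calibrated
  (measured type-I 0.050), but with the plug-in moment dispersion at
  n = 5 vs 5 the normal reference inflates to 0.083 at α = 0.05; the t
  correction (the same device quasi-likelihood DE engines use) restores
  0.044–0.049 across expression levels and vanishes as n grows.
* **FDR** — Benjamini–Hochberg step-up across testable genes, NaN
  passthrough for untestable ones; verified exactly against a
  brute-force implementation of the definition and against statsmodels.

Genes with zero counts everywhere are untestable.  Significance for the
screen is BH-adjusted p < 0.05 (the sequencing arm is the multiplicity-
corrected one).

## The screen

Gates, in order, each a config key:

1. `sde_both` — RNA-seq BH p < α₁ *and* ddPCR raw p < α₂ (defaults
   0.05/0.05; the ddPCR arm follows the convention of testing each gene
   at the nominal level without panel-wide correction).
2. `direction_agree` — sign(RNA-seq log2FC) = sign(ddPCR mean
   difference); zero effect counts as disagreement.  Evaluated only for
   genes passing gate 1.
3. `correlated` — per-gene Spearman p < α₃ between the gene's TPM and
   copies/µL values pooled across all samples of both groups (log
   transforms are irrelevant under rank correlation and not applied).
   Saturated/missing ddPCR cells reduce the pair count; fewer than 4
   pairs makes the gene untestable and fails the gate.

Candidates are genes passing all three.  Raising any α never removes a
candidate (monotone gates; property-tested).  The report carries per-gene
records, a funnel summary recomputed from the records on every
construction, and the pooled all-genes × all-samples Spearman rho.
Literature novelty and druggability are not computable quantities; they
enter only through an optional user-supplied annotation table whose
`has_modulator` / `previously_studied` flags rank the candidate
shortlist (druggable and unstudied first).

## Small-sample statistics

Two-group comparisons follow the normality-gated convention: Shapiro–
Wilk per group at α = 0.05; both normal → unpaired equal-variance
Student t; otherwise Mann–Whitney U, exact by enumeration when the
pooled sample is tie-free with ≤ 12 observations, else the normal
approximation with tie correction.  `force_t` and `force_mwu` bypass the
gate (echo panels conventionally use Student's t; both modes are
first-class).  Two constant, equal groups return p = 1, flagged
degenerate.

Spearman's rho is the Pearson correlation of average ranks.  For n ≤ 8
the two-sided p enumerates all n! permutations; beyond that the t
approximation with n − 2 df is used.  At n = 8 the two differ by at most
≈ 0.024, and only near p ≈ 1; in the decision range (p < 0.5) they agree
within 0.02, and away from |rho| ≈ 0.55–0.75 they always agree on the
0.05 call.

Dunnett's many-to-one comparisons (multivariate-t with equal-correlation
structure, via scipy with a fixed internal rng because the tail
probability is quasi-Monte Carlo, accurate to ~1e-4) are computed only
when the one-way ANOVA F reaches p < 0.05, otherwise suppressed with a
flag.

The optional outlier rule is Tukey's 1.5·IQR fences iterated to a fixed
point (a single pass is not idempotent — removing a point shrinks the
IQR — so the rule is applied until stable, keeping at least 4 points).
It is off by default everywhere and is a documented, transparent
substitute for proprietary robust-regression outlier detection, which is
not reimplemented.

## Echocardiographic derivations

`LVSV = LVEDV − LVESV`; `LVEF = LVSV/LVEDV·100`;
`LVCO = HR·LVSV/1000`; `LVFS = (LVEDD − LVESD)/LVEDD·100`;
`RWT = 2·LVPWTd/LVEDD`;
`LVMass = 1.04·(((LVEDD + LVAWTd + LVPWTd)³ − LVEDD³)·0.8 + 0.6)`.

Design notes: the mass formula is the modified cubic ("cubed") formula —
the outer minus inner diameter cubes approximate the myocardial shell
volume and 1.04 g/mL is myocardial density, so cm inputs yield grams;
the diastolic internal diameter (LVIDd in some conventions) is LVEDD.
The additive 0.6 and the 1.04 prefactor make the expression
unit-inhomogeneous for non-cm inputs, so units pass through untouched
and cm is the documented recommendation.  The fractional-shortening
formula is the standard one.  Records violating physiology (LVESV ≥
LVEDV, non-positive lengths or heart rate) are skipped with a log entry.
Group comparison defaults to `force_t` (the echo-panel convention),
reporting mean ± SEM per group.

## Synthetic-data generator

The generator's defaults are the emulated study conditions: 288 panel
genes, 2 × 5 samples, 40 planted DE genes (`frac_de = 40/288`), droplet
counts uniform in [15000, 20000], droplet volume 8.5e-4 µL, NB
dispersion 0.1, size factors uniform in [0.7, 1.3], baselines log-uniform
over 10^[0.5, 3.5], gene lengths uniform in [500, 5000] bp.  Planted
|log2FC| is normal(1.5, 0.5) truncated below at 1.0 (planted effects are
meant to be unambiguous two-fold-or-larger changes), signed up with
probability 0.5.

RNA-seq counts: `K_gj ~ NB(s_j · q_g · 2^(lfc_g x_j), α)`.

Cross-platform linkage: the true ddPCR concentration is
`λ_gj = ddpcr_scale · TPM_true(g, group_j) · f_g · u_gj`, with
`TPM_true` the length-normalized relative abundance against the
*group-independent baseline* denominator (the panel is a tiny slice of
the transcriptome, so planted effects inside it must not shift every
other gene's relative abundance — a panel-only denominator would create
a compositional artifact that whole-transcriptome TPM does not have),
`f_g = lognormal(0, 1.5)` a gene-specific assay-efficiency factor and
`u_gj = lognormal(0, 0.25)` the per-animal replicate deviation.  The two
platforms therefore correlate by construction but imperfectly: the
defaults give an overall pooled Spearman rho ≈ 0.8.  Real dual-platform
panels sit lower still (≈ 0.6) because their dynamic range is wider and
low-expression wells quantize near zero; the generator does not fully
emulate that regime, so passing tests demonstrate the machinery, not
field-level concordance.  The replicate-deviation term exists because
without it within-group ddPCR variance would be pure droplet-sampling
noise (CV < 3%), making the ddPCR t-test unrealistically powerful
against 5 biological replicates.

Droplets: `n ~ U[15000, 20000]`, positives `~ Binom(n, 1 − e^{−λV})`.
Wells whose expected negative count falls below 1 are emitted saturated
and flagged (`simulated_saturation`) rather than silently clipped.
Optional per-droplet amplitudes come from two Gaussian clusters (defaults
2000 ± 200 and 8000 ± 400 fluorescence units) plus a uniform "rain"
fraction between the cluster means; hidden labels are returned so
thresholders can be scored.  A warning is raised when the clusters are
closer than 2 pooled SDs.

Randomness: one independent child stream per artifact (design/truth,
counts, droplets, amplitudes) from the master seed, so outputs are
bit-reproducible and adding an artifact type never perturbs the others.

What the generator does *not* emulate: read-level sequencing artifacts,
transcript isoforms, GC/length biases beyond the TPM length term,
droplet-volume variation, fluorescence physics beyond two clusters plus
rain, and the correlated biological co-regulation of real transcriptomes.

## Problem sizes and numerical choices

The default test-suite and acceptance-script runs use the full emulated
design (288 × 10, one well per gene × sample), 10,000 genes for null
calibration, 2,000 wells for CI coverage, 1,000 vectors for the BH
equivalence, and 100 wells for the MLE-vs-grid check — sizes chosen so
each property is measured with Monte-Carlo error well inside its
assertion band while the whole suite stays fast.  Frozen reference
values (candidate set, recovery rate, overall rho, rain-thresholder
error rate, echo significance pattern) were recorded from a first
verified run at the default seeds and asserted with bands of ±3
Monte-Carlo SDs where sampling noise applies, or exactly where the
computation is deterministic.

IRLS runs to a 1e-10 coefficient tolerance with a 100-iteration cap;
tables are plain TSV whose float round-trip is exact (shortest-repr
serialization); JSON artifacts are key-sorted and timestamp-free so a
pipeline run is byte-for-byte reproducible from its seed.

## Known limitations

* The NB engine is intentionally minimal; with very few genes the BH
  correction is coarse, and with n = 2 per group the moment dispersion
  is unreliable.
* ddPCR per-gene tests are run at the nominal level without panel-wide
  multiplicity correction (a config key away from changing).
* The correlation gate pools both groups, so a strong group effect can
  produce a significant rho from group separation alone — which is
  exactly the behaviour the screen exploits, but means the gate is not
  evidence of within-group concordance.
* Literature-derived candidate annotations are user input, not computed.
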