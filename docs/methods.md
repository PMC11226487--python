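# Methods

## Model and assumptions

`gutmr` performs two-sample summary-statistic Mendelian randomization. For
each instrument j, the exposure GWAS supplies an estimated per-allele effect
β_Xj with standard error σ_Xj, and the outcome GWAS (a binary trait on the
log-odds scale) supplies β_Yj with σ_Yj, both expressed for the same effect
allele after harmonization. Under the three instrumental-variable
assumptions (relevance: the variant is associated with the exposure;
independence: no variant–confounder association; exclusion: the variant
affects the outcome only through the exposure), each Wald ratio
θ̂_j = β_Yj/β_Xj estimates the causal log-odds slope θ, and the estimators
differ in how they aggregate the θ̂_j when exclusion fails for some
instruments.

The two samples are assumed non-overlapping, so exposure and outcome
sampling errors are independent. The ratio standard error is the first-order
delta method, σ_j = σ_Yj/|β_Xj|, which ignores the exposure-side noise
term; the weak-instrument filter (F = β_Xj²/σ_Xj² > 10) keeps the neglected
term at most ~10% of the ratio variance, and in the simulation experiments
instruments are generated substantially stronger (per-SNP F mostly 20–200)
so the approximation error is negligible there. This is the dominant
convention in summary-statistic MR and is a documented limitation for
marginal instruments.

## Instrument selection

Exposure records are screened at p < p_threshold (default 1e-5, strict
inequality), then clumped greedily: candidates are ordered by ascending
p-value (ties by chromosome, position, snp_id, so the result is
deterministic); the best remaining record becomes an index SNP and every
remaining record on the same chromosome within window_kb (default 10,000 kb)
with r² ≥ r2_threshold (default 0.001) against it is discarded. Two
missing-LD conventions are supported: with no LD table at all, any pair
inside the window is treated as linked (pure distance pruning — the
conservative reading when no reference is available); with a table that
lacks a pair, the pair is treated as independent. Selection runs on the
exposure GWAS before harmonization (instrument choice belongs to the
exposure study); instruments absent from the outcome GWAS are simply lost at
the harmonization intersection — no proxy lookup is attempted. The F > 10
filter is applied last, on harmonized exposure statistics (F is
sign-invariant, so ordering relative to harmonization is immaterial).

## Harmonization

Outcome records are aligned to the exposure's effect allele: swapped alleles
negate β_Y and complement-allele matches are resolved as strand flips before
alignment; allele pairs that match neither way are dropped. Palindromic
variants (A/T, C/G) cannot be strand-resolved from letters; the default
policy drops them when either study's effect-allele frequency lies in
(0.42, 0.58) or is missing, and otherwise aligns them by frequency side.
Policies `freq_infer` (always align by frequency) and `keep` (trust the
letters) are available. These defaults are explicit package choices in the
spirit of common practice — they are configurable, and nothing downstream
depends on the particular ambiguity window.

## Estimators

All estimators consume the harmonized ratios θ̂_j with weights
w_j = 1/σ_j² = β_Xj²/σ_Yj², report two-sided normal p-values, and
odds ratios exp(β) with 95% CIs exp(β ± z₀.₉₇₅·SE). Normal rather than t
reference distributions follow summary-statistic MR convention; at the
instrument counts this pipeline targets (roughly 4–20 per taxon) the
difference is small and is absorbed into the calibration experiments.

* **IVW.** Fixed effects: β = Σw_jθ̂_j/Σw_j, SE = √(1/Σw_j) — identical to
  weighted least squares of β_Y on β_X through the origin with weights
  1/σ_Yj². Multiplicative random effects inflate the SE by
  max(1, √(Q/(J−1))) where Q is Cochran's Q at the fixed-effects estimate;
  the floor at 1 means the random-effects SE never undercuts the
  fixed-effects one.
* **MR-Egger.** Instruments are internally oriented so β_Xj > 0 (the
  regression is not orientation-invariant, so a convention is mandatory and
  is invisible to callers), then β_Y is regressed on β_X with a free
  intercept, weights 1/σ_Yj², via weighted least squares. Slope and
  intercept SEs carry the multiplicative overdispersion scale
  max(1, √(RSS_w/(J−2))). A small intercept p-value flags directional
  pleiotropy; the slope remains consistent under the InSIDE assumption
  (instrument strength independent of direct effects).
* **Weighted median.** Ratios are sorted; with normalized weights w′_j the
  cumulative midpoints s_j = Σ_{k≤j}w′_k − w′_j/2 define a weighted
  empirical CDF that is linearly interpolated at 0.5. The SE is a seeded
  parametric bootstrap: β_Xj and β_Yj are re-drawn from normals with their
  SEs, the ratios and weights recomputed, and the SD over n_boot draws
  (default 1000) taken.
* **Weighted mode.** The maximizer of a weighted Gaussian kernel density
  over the θ̂_j, bandwidth h = φ·0.9·min(sd, IQR/1.34)·J^(−1/5) (Silverman
  form; φ defaults to 1). The point estimate uses a 2001-point grid over the
  ratio range refined by bounded scalar minimization (tolerance 1e-10);
  bootstrap draws use a 256-point grid, which is ample for an SE. If the
  IQR collapses under ties the sd alone sets the bandwidth; if all ratios
  coincide, that common value is returned. The weighted mode is computed and
  reported but deliberately takes no part in the decision logic, which
  relies on IVW, the Egger intercept, Q, and MR-PRESSO.

Degenerate inputs: a single instrument falls back to the Wald ratio; a zero
exposure effect raises an undefined-ratio error; zero variance in β_X raises
a collinearity error for Egger; estimator minimums (IVW 2, Egger/median/mode
3, PRESSO 4) raise insufficient-instrument errors, which the pipeline
converts into a `no_instruments` status rather than a crash.

## Diagnostics and decision rules

**Cochran's Q** = Σw_j(θ̂_j − β_IVW)², referred to χ²(J−1). Q's p < 0.05
switches the headline IVW to multiplicative random effects; otherwise fixed
effects are used (p ≥ 0.05 inclusive).

**MR-PRESSO.** The observed statistic is the leave-one-out residual sum of
squares RSS = Σ_j w_j(β_Yj − b̂₍₋ⱼ₎β_Xj)² with w_j = 1/σ_Yj² and b̂₍₋ⱼ₎ the
through-origin IVW slope excluding SNP j. The null distribution comes from
n_sim (default 1000) parametric draws β*_Yj ~ N(b̂₍₋ⱼ₎β_Xj, σ_Yj),
β*_Xj ~ N(β_Xj, σ_Xj), recomputing the statistic per draw; all empirical
p-values use (1+k)/(1+n_sim) so they can never be exactly zero. Per-SNP
residual contributions compared against their simulated counterparts give
outlier p-values, Bonferroni-adjusted over J against outlier_alpha (default
0.05). Note the Bonferroni floor: with n_sim = 1000 an outlier can only be
declared while J·(1/1001) < 0.05, i.e. J ≤ 50 — raise n_sim for larger
instrument sets. When the global p < 0.05 and outliers are flagged, the
pipeline removes them and re-estimates once (no iterative hunting). A
distortion assessment (percent change of the corrected slope, with an
empirical p against random equal-size removals) is reported descriptively
and never gates anything.

**Leave-one-out.** IVW re-estimated once per excluded SNP plus the full-set
row; the qualitative stability flag is true when every leave-one-out CI
overlaps the full-set CI and no nominally significant leave-one-out fit
flips sign. No formal test is layered on top.

**Banding.** The per-rank Bonferroni threshold is alpha divided by the
number of taxa at the exposure's rank in the manifest (alpha 0.05 by
default; 119 genera → 4.2×10⁻⁴, 32 families → 1.56×10⁻³, 20 orders →
2.5×10⁻³, 16 classes → 3.125×10⁻³, 9 phyla → 5.6×10⁻³). Headline IVW
p < threshold → `corrected_significant`; threshold ≤ p < alpha →
`suggestive`; otherwise `null`. `wm_consistent` records whether the weighted
median agrees with the headline in sign and is nominally significant.
Non-null pairs trigger a reverse-direction run (roles swapped, screen at
reverse_p_threshold, default 1e-5 and configurable to 5e-8); a flag can
force reverse runs for all taxa.

## Randomness and reproducibility

All stochastic components (bootstraps, PRESSO resampling, the generator) are
driven by explicit integer seeds. The panel runner expands one master seed
deterministically per taxon × outcome via CRC32 of the pair label, so
results are byte-identical across reruns with the same config and seed and
independent of panel iteration order.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
per-SNP exposure effects γ_j ~ U(0.05, 0.3) with random sign observed with
noise (σ_Xj ~ U(0.02, 0.05)); outcome effects θγ_j + α_j on the log-odds
scale observed with σ_Yj ~ U(0.05, 0.15), matching the effect and SE
magnitudes of instrument-grade associations from a ~18k-sample quantitative
microbiome GWAS against a few hundred cases vs ~390k controls; 15
instruments per taxon by default (real post-selection counts run roughly
4–19). Pleiotropy modes: `none`; `balanced` (α ~ N(0, α_sd)); `directional`
(α co-oriented with sign(γ) and mean α_mean — the co-orientation keeps
"directional" meaningful under allele recoding, which flips γ and α
together); `outlier` (α = outlier_scale·σ_Yj for planted SNPs). Optional
extras: null SNPs for screening tests, outcome-only loci (effects and SEs
drawn at instrument-grade strength, since they model genuine disease loci
that the reverse screen must find), palindromic alleles, and LD blocks with
prescribed within-block r². Positions are spaced beyond the clumping window
so selection keeps every associated SNP unless LD is planted. The default
196-taxon panel comprises 119 genera, 32 families, 20 orders, 16 classes,
and 9 phyla, with disjoint SNP sets and position ranges per taxon and a
shared outcome table.

What the generator does not model — and hence what passing tests do not
establish about real data: sample overlap between the two GWAS, realistic LD
from a reference panel, winner's curse at the genome-wide screen beyond what
arises mechanically from screening on the simulated statistics, population
stratification, and non-normal effect-size distributions. Individual-level
logistic sampling is also skipped: outcome betas are drawn directly on the
log-odds scale because the pipeline consumes only summary statistics and the
validation experiments need thousands of replicates.

## Validation protocol and observed behavior

The experiment drivers (`gutmr.experiments`) fix the problem sizes used by
the acceptance tests and script: CI coverage at 500 replicates of 50 strong
instruments with θ = log 2 (all four estimators ≥ 90%, IVW typically ~93%
— slightly under 95% because the delta-method SE omits exposure noise);
type-I calibration at 400 replicates (headline IVW ~4–5%; Egger intercept
~4.6%, mildly conservative from the overdispersion floor; PRESSO global
~4–5%); outlier decision logic at 100 replicates of 20 clean instruments
plus one SNP offset by 10·σ_Y (detection ≥ 95%; removal cuts the mean
absolute error of the headline estimate roughly in half — individual
replicates can move away from θ when the post-removal estimate's own noise
dominates, which is why the improvement claim is about the error
distribution, not every run). Reverse-direction runs under a forward-only
effect are non-significant in ~91% of replicates rather than 95%: screening
reverse instruments on the same statistics being tested induces a small
winner's-curse inflation on top of the nominal 5%, a behavior real
two-sample analyses share.
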