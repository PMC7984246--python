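# Methods

This note documents the statistical models behind `evodiv`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions used throughout.

## Variance decomposition of catabolic profiles

A population is observed as a G × S matrix X of growth endpoints (OD₆₆₀),
G clones by S substrates. Components:

- **V_P** — mean Euclidean distance between all G(G−1)/2 clone profile
  pairs (OD units). A distance-based total: zero iff all clones are
  phenotypically identical.
- **V_G** — between-clone variance (OD²). Two estimators exist in the
  literature this analysis descends from: the sample variance of per-clone
  mean growth (variation in overall catabolic ability), and the
  between-clone variance computed per substrate and averaged. They answer
  subtly different questions — the first ignores, the second includes,
  clone-by-substrate interaction variance (compare `V_G` and
  `V_G_substrate` in the output: for a specialist population the second is
  much larger). The clone-means estimator is the default; both are always
  reported and selectable.
- **V_E** — sample variance across substrates of the mean clone growth
  (OD²).
- **Responsiveness** R = Σ_{i≠j} (σᵢ−σⱼ)²/2 / G(G−1) and
  **inconsistency** I = Σ_{i≠j} σᵢσⱼ(1−ρᵢⱼ) / G(G−1), with σᵢ the
  sample SD of clone i across substrates and ρᵢⱼ the Pearson correlation
  of profiles. Sums run over ordered pairs, matching the G(G−1)
  denominator (equivalently: unordered pairs × 2). The two components
  partition the pairwise difference-profile variance:
  R + I = mean over ordered pairs of Var(xᵢ−xⱼ)/2, an identity the test
  suite verifies to 1e-10 against a brute-force oracle.

Conventions: sample (n−1) variances and SDs everywhere (the common
statistical-software default; the defining formulas do not fix the
denominator). A clone with a constant profile has undefined ρ; its pair
terms are set to 0, the limit of a vanishing signal. Correlations within
1e-12 of ±1 are snapped to ±1 so identical or exactly opposed profiles
give exact zero/maximal pair terms.

**Substrate filtering** retains a substrate iff the minimum OD over *all*
clones in *all* populations of the experiment is strictly above the
threshold (default 0.1). The global rule produces one common substrate
panel for every population — the design the downstream comparisons
assume. A per-treatment variant would yield non-comparable panels.

Treatment differences per component are tested with the nested-model F
test below on the 6 + 6 population-level values.

## Group-comparison statistics

- `lm_f_test`: the F test between the intercept-only and group-means
  Gaussian linear models. For one categorical predictor this is one-way
  ANOVA; it orders models identically to a likelihood-ratio test, so it is
  the exact-distribution form of "model comparison" for this design.
  Under the null (verified by simulation at n = 6 + 6) its type-I rate at
  α = 0.05 is 0.05 within Monte-Carlo error.
- `ranksum_w`: Wilcoxon rank-sum reported as W = midrank sum of x minus
  n_x(n_x+1)/2 (the Mann–Whitney U of x); exact p for small untied
  samples, tie-corrected normal approximation otherwise, two-sided. For
  two groups this coincides with a two-sample Kruskal–Wallis test, so one
  implementation serves both names.
- `holm_adjust`: step-down Holm–Bonferroni (monotone, capped at 1).

## Competition fitness

Relative fitness is the odds ratio w = [f₇(1−f₀)]/[f₀(1−f₇)] of the focal
strain's mixture fractions; fractions are dilution-invariant, so raw
colony counts are used without dilution correction. Fractions of exactly
0 or 1 raise an explicit fixation/extinction error rather than returning
an infinity. The Malthusian-parameter ratio ln(N_A7/N_A0)/ln(N_B7/N_B0)
is reported alongside when computable from the raw counts; the two
statistics coincide only under conditions that rarely hold exactly, and
no equivalence is asserted.

Treatment structure is tested with targeted fixed-effect contrasts
between (evolution env, competition env) cells: paired t when the two
cells contain the same populations (the home-vs-away contrast of one
evolved set), Welch t otherwise, Holm-adjusted across the requested
family. This deliberately replaces a linear mixed model with a population
random effect and Kenward–Roger degrees of freedom: for this balanced
design the paired contrast carries the same within-population pairing
information, at the cost of slightly different degrees of freedom in the
cross-treatment contrast, and avoids REML machinery peripheral to the
quantities the pipeline defines.

## Pooled-sequencing diversity

For variants at proportions pᵢ ∈ (0,1]: genetic distance Σpᵢ; variant
count = distinct (chrom, pos, ref, alt) keys with p ≥ the detection floor
(default 0.1, the pooled-detection cut-off; configurable); alpha
diversity Σ(1−pᵢ²−qᵢ²) = Σ2pᵢ(1−pᵢ), a per-site expected heterozygosity
summed over sites (so α ≤ 0.5 × number of variants). Variant identity
follows VCF semantics — 1-based positions, type (SNP/indel) as annotation
only. The whitelist filter intersects pooled calls with the clonal-
sequencing variant set; it is idempotent and can only decrease every
metric.

**Detection model.** The pooled detection process is modelled at the
allele-count level: a variant with carrier fraction p is observed through
alt ~ Binomial(depth, p(1−e) + (1−p)e) reads and called when
alt/depth ≥ cutoff. This isolates the statistical logic of
proportion-cut-off detection (e.g. a 1-in-10 carrier variant at 100×
depth and cut-off 0.1 is detected with probability ≈ 0.55 — near a coin
flip, which is why pooled counts near the floor are unreliable) without
re-running read mapping and variant calling, which are upstream of this
pipeline's inputs. The pseudo-pool mixer operates on real FASTQ records
(each read kept independently with probability `fraction`, default 10%),
so the read-level validation path is exercised too.

## Multivariate comparison

The feature matrix is populations × variant keys, entries = proportions,
0 where absent. On its Euclidean distance matrix:

- **PERMANOVA**: SS_total = (1/n)Σ_{i<j}d²ᵢⱼ,
  SS_within = Σ_g (1/n_g)Σ_{i<j∈g}d²ᵢⱼ, pseudo-F and R² from the
  partition, p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1) over whole-sample
  label permutations (default 9,999), so p > 0 always and its resolution
  is 1/(n_perm+1). On 1-D Euclidean data the pseudo-F equals the
  classical ANOVA F (tested to 1e-10), and the statistic is cross-checked
  against scikit-bio's independent implementation.
- **Beta-dispersion**: samples are embedded by principal-coordinate
  decomposition (Gower-centred −d²/2; components with positive
  eigenvalues kept — exact for Euclidean input, a documented
  approximation for non-Euclidean matrices where negative eigenvalues are
  dropped rather than handled imaginarily); distances to own-group
  centroids are compared by one-way ANOVA.
- **NMDS**: delegated to scikit-learn's non-metric SMACOF with seeded
  random restarts (8 by default); Kruskal stress-1 is reported. The
  contract enforced by tests is rank fidelity at low stress and seeded
  determinism, not a particular optimiser trajectory.

The ordination/PERMANOVA stage accepts an optional clonal whitelist and
applies it before building the feature matrix (the conservative default
of the analysis); pass `clonal_whitelist=None` to analyse unfiltered
tables.

## Synthetic-data generators

The generators emulate the *measured data layer* of a
heterogeneous-vs-homogeneous evolution experiment: 6 populations per
treatment, 10 clones per population, a 96-substrate panel, a 10⁸-CFU
50:50 competition inoculum, and variant tables whose treatment structure
includes one variant carried by all homogeneous populations and one by
4 of 6 heterogeneous populations. They do not simulate the evolution
itself — no compost chemistry, spatial diffusion or mutation dynamics.

- **Growth matrices.** Specialist mode assigns clones cyclically to
  `n_specialist_types` disjoint substrate niches (random blocks of
  `niche_size` substrates per population); a clone grows at
  baseline + gain on its niche and baseline − loss elsewhere, which
  forces the negative cross-type profile correlations that inconsistency
  detects. Generalist mode is flat at `generalist_mean`. Noise is i.i.d.
  additive Gaussian truncated at 0 — the simplest model preserving OD
  non-negativity; no empirical noise magnitude was available, so the OD
  scale is a free choice, set a priori to baseline 0.6, gain 0.5, loss
  0.3, noise SD 0.05 (off-niche growth then sits 4 SDs above the 0.1
  filtering floor, so the default panel survives filtering nearly
  intact). These defaults are documented, not calibrated.
- **Variant tables.** Private variants per population: Poisson count
  (default means 2.5 for heterogeneous and 1.0 for homogeneous
  populations in the pipeline driver, reflecting the faster molecular
  evolution expected in the heterogeneous environment) with
  Beta(1, 2)-distributed proportions (mean 1/3 — most variants at
  low-to-moderate proportion). Shared-variant specs may fix the
  proportion (used for the treatment-diagnostic variants, planted at
  0.95) or draw it from the same Beta. Because planted shared variants
  add to the private counts, homogeneous populations end with slightly
  more variants than the emulated median — acceptable, as counts feed
  rank-based tests. The first half of populations is labelled
  heterogeneous, the second homogeneous.
- **Competition.** Growth between timepoints is deterministic — the final
  fraction solves the odds-ratio equation for the true fitness — and all
  stochasticity is binomial plating noise (default 200 colonies per
  plate), isolating estimator behaviour. Draws producing fixation are
  resampled with bounded retries. The estimator recovers true fitness in
  {1.0, 1.5, 2.0} within 5% over 1,000 assays.
- **Clone reads.** A random genome (default 10 kb), uniform read starts,
  planted SNPs substituted in carrier clones, per-base errors at
  `error_rate` replacing a base with a uniformly random different one,
  Phred+33 Q40 qualities. The truth table lists carrier fractions —
  what an ideal equal-weight pool would observe.

Every generator is deterministic given its scenario seed; per-population
substreams are spawned from one root RNG, and pipeline runs record all
stage seeds in `manifest.json` (which deliberately excludes timestamps so
fixed-seed reruns are byte-identical).

What passing tests on these generators show: the statistics detect the
structure they are defined to detect, at realistic sample sizes, under
clean Gaussian/binomial/Poisson noise. What they do not show: robustness
to plate-reader artefacts, clone mis-pooling, uneven sequencing depth
across the genome, linked variants, or mapping/calling errors — none of
which the generators emulate.

## Problem sizes in the test and reproduction runs

The reproduction script uses 20 replicate specialist/generalist
experiments (12 populations each) for the recovery rate, 1,000 simulated
assays for fitness recovery, 10,000 variants for the pooled-detection
rate, and 9,999 permutations for the PERMANOVA on one simulated study —
sizes at which Monte-Carlo error is comfortably below the effects being
measured while a full run stays in the seconds range. The null-calibration
test uses 10,000 simulations for the F test's type-I rate and 300
exchangeable datasets at 99 permutations for PERMANOVA p uniformity.

## Known limitations

- Single-endpoint OD only; no kinetic growth-curve fitting.
- Single categorical predictor in PERMANOVA/beta-dispersion; no strata or
  multi-factor designs.
- No mixed models; the contrast scheme above is the supported inference
  for the competition design.
- Pooled detection is modelled downstream of variant calling; structural
  variants and caller-specific error modes are out of scope.
- The VCF reader handles the minimal single-allele dialect with a
  proportion INFO key (default `AF`); split multi-allelic records first.
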