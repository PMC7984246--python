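# evodiv

Analysis toolkit for quantifying the **evolutionary diversification of
microbial populations** that evolved under different degrees of spatial
resource heterogeneity, aimed at experimental-evolution labs working with
soil bacteria such as *Pseudomonas fluorescens*.

The pipeline takes three experimental data streams and asks one question of
each: did populations from the spatially heterogeneous environment
diversify into resource specialists, while homogeneous-environment
populations stayed generalist?

1. **Catabolic profiles** (`phenotype_gxe`) — each population is a G × S
   matrix of growth endpoints (OD₆₆₀) of G clones on S single-carbon-source
   substrates. After dropping substrates where any clone fails to grow
   (minimum OD₆₆₀ > 0.1), the phenotypic variation is decomposed into
   genotypic (V_G), environmental (V_E) and genotype-by-environment
   components:

   - responsiveness  R = Σ_{i≠j} (σᵢ − σⱼ)²⁄2 / G(G−1)
   - inconsistency   I = Σ_{i≠j} σᵢσⱼ(1 − ρᵢⱼ) / G(G−1)

   where σᵢ is clone *i*'s standard deviation of growth across substrates
   and ρᵢⱼ the Pearson correlation of two clones' profiles. High I —
   clones rank-switching across substrates — is the signature of resource
   specialisation. Treatments are compared per component with a
   nested-linear-model F test.

2. **Competition assays** (`fitness_assays`) — an evolved clone mix
   competed 50:50 against a marked ancestor; relative fitness is the odds
   ratio of its mixture fractions at the start and end,
   w = [f₇(1−f₀)] / [f₀(1−f₇)], with paired/Welch contrasts between
   evolution × competition environment cells and Holm–Bonferroni
   adjustment.

3. **Pooled sequencing** (`pool_diversity`, `multivariate_stats`) — from
   per-population variant proportions p: genetic distance Σp, variant
   counts above a 0.1 detection floor, alpha diversity Σ2p(1−p) (summed
   expected heterozygosity), rank-sum treatment comparisons, and on the
   populations × variants Euclidean distance matrix: PERMANOVA (pseudo-F,
   R², 9,999-permutation p), beta-dispersion and NMDS ordination. A
   binomial pooled-detection simulator and a pseudo-pool FASTQ mixer
   (10% of each clone's reads) validate what pooling can and cannot
   detect.

A first-class synthetic-data module (`synthetic_data`) generates every
input with the structure the analysis assumes — specialist clones with
disjoint substrate niches and growth trade-offs, Beta-distributed variant
proportions with treatment-diagnostic shared variants, binomial plating
noise around a known true fitness, and tiny clone genomes with planted
SNPs — so the whole pipeline is testable end to end without external data.

## Worked example

Simulate six specialist-evolved and six generalist-evolved populations
(10 clones × 96 substrates each), filter the substrate panel and compare
inconsistency between treatments:

```python
from evodiv.synthetic_data import BiologScenario, generate_biolog
from evodiv.phenotype_gxe import filter_substrates, decompose
from evodiv.stats_core import lm_f_test

matrices = (generate_biolog(BiologScenario(seed=42), "specialist")
            + generate_biolog(BiologScenario(seed=43), "generalist"))
filtered, retained = filter_substrates(matrices, threshold=0.1)
print(f"{len(retained)} of 96 substrates retained")

values, groups = [], []
for m in filtered:
    c = decompose(m)
    values.append(c.I)
    groups.append(m.treatment)
res = lm_f_test(values, groups)
print(f"inconsistency, heterogeneous vs homogeneous: "
      f"F({res.df1},{res.df2}) = {res.statistic:.1f}, p = {res.p:.3g}")
```

prints

```
95 of 96 substrates retained
inconsistency, heterogeneous vs homogeneous: F(1,10) = 5623.1, p = 4.34e-15
```

A representative specialist population here has I ≈ 0.046 against
I ≈ 0.002 for a generalist population: clones from the heterogeneous
environment trade off growth on different substrates (negative profile
correlations), which is exactly what inconsistency measures. The F test
compares the 6 + 6 population-level values between treatments.

The same analyses are available from the shell:

```sh
evodiv pipeline -o run1 --seed 1          # simulate + all stages
evodiv gxe -i run1/od_matrices -o gxe1    # variance decomposition only
```

Every run writes a `manifest.json` (config, seeds, version); rerunning
with the same seed reproduces the outputs byte for byte.

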