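# Methods

`sociobiome` analyses how group living and social relationships structure
gut microbiome composition in band-living mammals (harem-forming equids are
the motivating system: bands of one stallion, several mares, and their
immature offspring). The package couples two data streams — a sample × SV
(sequence-variant) count table with taxonomy and per-sample metadata, and a
daily sighting log with proximity categories — and asks, at each level of
organisation, how much compositional variance that level explains and
whether specific relationships (mother–offspring, stallion–mare, strong
association ties) predict microbiome similarity.

## The analysis chain

1. **Preprocessing** (`sociobiome.io`). SVs longer than 260 bp are removed
   (strictly greater; the report states the removed share both of total
   reads and of SVs, since "fraction removed" is ambiguous between the two).
   SVs detected in negative controls are removed from all samples at any
   nonzero control count — a deliberately conservative contamination rule.
   Taxonomy is back-filled from the deepest assigned rank
   (`Genus = "Family_Prevotellaceae"` when only the family is known) so that
   rank agglomeration never drops unassigned SVs; counts are converted to
   relative abundance per sample. The per-individual "average microbiome" is
   the arithmetic mean of the individual's raw sample counts (kept
   real-valued), normalised afterwards.
2. **Core microbiome** (`sociobiome.metrics`). An SV is core when its
   relative abundance reaches the detection threshold (default 0.001%) in at
   least `ceil(prevalence × n_samples)` samples (default prevalence 99.9%).
   The core-restricted table is *not* re-normalised: distances are computed
   on retained columns as-is, keeping the detection threshold meaningful.
   Prevalence counts samples by default; an individual-level mode exists
   because the two units differ when individuals contribute unequal sample
   numbers.
3. **Divergence metrics**. Bray–Curtis dissimilarity (scipy's
   implementation; equals half the L1 distance on normalised rows) and
   Jensen–Shannon divergence with **natural logarithms**, so JSD ∈ [0,
   ln 2 ≈ 0.693] and √JSD is a metric. 0·log 0 ≡ 0.
4. **Association index** (`sociobiome.association`). Daily proximity scores:
   close/interacting → 2, medium → 1, far or not co-sighted → 0; repeated
   observations of a dyad within a day collapse to the maximum. The edge
   weight is a proximity-weighted simple ratio index,
   `E_AB = x_SUM / (2·x_COUNT + y_AB + y_A + y_B)`,
   with `x_COUNT` the days the dyad scored ≥ 1, `x_SUM` the summed scores,
   and the `y` terms the usual seen-apart / seen-alone tallies. `y_AB`
   counts days both were observed at score 0. Dyads with a zero denominator
   (neither member ever observed) are scored 0 and flagged rather than
   dropped, so association matrices stay fully populated for the matrix
   correlation. When every joint sighting scores 2, `x_SUM = 2·x_COUNT` and
   E reduces to the simple-ratio form `x_SUM / (x_SUM + y)`.
5. **Ordination** (`sociobiome.ordination`). Non-metric multidimensional
   scaling minimising Kruskal stress-1, alternating monotone (isotonic)
   regression of configuration distances on dissimilarity ranks — primary
   treatment of ties — with SMACOF/Guttman updates. Disparities are
   rescaled each iteration to the configuration's sum of squared distances;
   an update that would increase stress is rejected, so the accepted stress
   sequence is non-increasing. The first start is a deterministic
   classical-scaling (PCoA) configuration and the remaining `n_starts − 1`
   (default 19) are random; the best final stress wins. PCoA initialisation
   makes the winning basin effectively seed-independent — with purely random
   starts, two seeds on a 25-sample Bray–Curtis matrix settled in local
   optima ~7 × 10⁻⁴ apart. Defaults: k = 2, convergence when the stress
   drop falls below 1e-6, max 300 iterations.
6. **Variance partitioning** (`sociobiome.stats.permanova`). The distance
   matrix is Gower-centered (−½ J D² J); sums of squares are partitioned
   sequentially (Type-I, in user-given term order) via projections onto
   nested dummy-coded design spaces; pseudo-F per term uses the residual
   mean square. p-values come from free permutation of sample labels,
   `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`; permutations that reproduce
   the observed grouping tie with the observed F up to floating-point
   jitter, so exceedance is counted with a small tolerance — a permutation
   test that drops ties is invalid. An exhaustive mode (n ≤ 8) enumerates
   every relabelling and reports the plain proportion, identity included.
7. **Matrix correlation** (`sociobiome.stats.mantel_kendall`). Kendall
   tau-b (tie-corrected) between the strictly-lower-triangle vectors of the
   association matrix and a microbiome distance matrix; significance by
   node-label permutation of one matrix (Mantel scheme), two-sided. The
   microbiome distances default to Euclidean distances in NMDS space of the
   average microbiomes; raw Bray–Curtis/JSD matrices can be supplied
   instead.
8. **Indicator taxa** (`sociobiome.stats.indicator_analysis`). For each
   genus and group, specificity A = the group's share of summed group mean
   abundances, fidelity B = occurrence fraction within the group, IndVal =
   √(A·B); each genus is assigned to its arg-max group and tested by
   permuting group labels on the max statistic. Designed for the two-group
   contrast (nursing foals vs weaned sub-adults).
9. **Dyadic comparisons** (`sociobiome.stats.dyad_mixed_model`,
   `band_jsd_anova`). Distances are grouped into comparison families:
   within- vs between-individual (sample-level JSD, same band only);
   within- vs between-band (average-microbiome JSD, one-way ANOVA over the
   six band/band-pair cells with Tukey HSD); mare–juvenile dyads split into
   mother–offspring / non-maternal (mare has offspring in the band) /
   foal-less mare; stallion–mare vs mare–mare. Mixed-model families use a
   Gaussian LMM fitted by ML with **crossed random intercepts for both dyad
   members and for band**, and a likelihood-ratio χ² for the category
   effect. Both members enter because every individual recurs across many
   dyads (a multi-membership structure); modelling only one member left the
   null test anticonservative (rejection 0.18 instead of 0.05 in a 50-rep
   check), while the crossed structure restores nominal calibration at no
   cost in power. The response is continuous, so the model is Gaussian
   rather than a GLM. Three-category families get Bonferroni-adjusted Wald
   z pairwise contrasts. Singular fits are refit without the band term and
   flagged; a zero-variance response short-circuits to χ² = 0, p = 1.

## The synthetic-data generator

`sociobiome.simulate` emulates the hierarchical structure such a study
assumes, so every stage is testable without any download:

* population baseline drawn from a symmetric Dirichlet (concentration 0.5
  over 300 SVs — a realistically skewed community);
* multiplicative lognormal effects shared within band (σ_band), per
  individual (σ_ind), and per sample (σ_sample), plus **one shared**
  lognormal shift applied to all foals (a common milk-diet-like community —
  shared, so foals separate as a group in ordination);
* convex mixing of expected profiles along bonded dyads: mares toward the
  band stallion (λ_stallion), then offspring toward the mother's mixed
  profile (λ_mother) — mixing order chosen so λ_mother = 1 makes an
  offspring's profile exactly its mother's;
* multinomial read sampling at a uniform depth in 8 000–43 000 reads, 3–5
  samples per individual;
* daily sightings over 10 days: each band is observed as one cohesive unit
  with probability 0.8, else a random cohesive subset; within a unit,
  bonded dyads are close with probability 0.9 vs 0.2 for ordinary dyads,
  other co-sighted dyads medium; every individual is guaranteed ≥ 5
  sighting days. Cross-band dyads are never associated.

The demo layout is three bands of 9, 13, and 8 individuals (one stallion
each, 6/7/4 mares, and juveniles with assigned mothers, leaving some mares
foal-less). Default variance components were calibrated once against the
variance shares such a study reports — σ_band = 0.55, σ_ind = 0.7,
σ_sample = 0.9, foal shift 1.1, λ_mother = 0.25, λ_stallion = 0.15 —
yielding, on sample-level Bray–Curtis PERMANOVA, ≈ 51–53% of variance for
individual identity, ≈ 13–17% for band, ≈ 7% for life stage, ≈ 1% for sex,
and mean within-individual JSD below between-individual JSD.

What the generator does **not** emulate: read-level sequencing error and
chimeras, seasonal/dietary drift, spatial autocorrelation beyond band
membership, compositional zero-inflation structure beyond the
Dirichlet-multinomial, or transmission dynamics (dyadic convergence is a
static mixture, not a process). Passing tests therefore show the analysis
machinery is correct and calibrated under this generative family, not that
the biological effect sizes of any real population are recovered.

## Calibration experiments (`sociobiome.experiments`)

* **Type-I error.** The band test's permutation scheme is free permutation
  of samples, so its null calibration is checked on an *exchangeable* null:
  no band effect, no shared foal community, no dyadic mixing, and one
  sample per individual. With repeated samples per individual the band term
  rejects at ~0.4 — pseudoreplication inherent to unrestricted PERMANOVA on
  nested data, not an implementation defect; users with repeated measures
  should interpret sample-level band tests accordingly (or aggregate to
  individuals first).
* **Power.** At default effect sizes the band term is significant in
  ≥ 90% of reduced-study replicates, and mean band R² increases across a
  σ_band grid (0.25, 0.55, 1.0).
* **Social signal.** With dyadic convergence on, the association–distance
  Kendall correlation is negative in ≥ 90% of replicates and
  mother–offspring dyads diverge less than non-maternal mare–juvenile dyads
  (category p < 0.05) in ≥ 90%. The maternal power fixture scales
  *replication* (6 bands of 10, 3–4 samples per individual), never effect
  sizes. With λ = 0 and σ_band = 0, tau is centred on zero and the maternal
  test rejects at the nominal rate. Note that λ = 0 alone is not a null for
  tau: band structure makes both association and microbiome similarity
  band-patterned, so tau is negative without any dyadic mixing.
* Replicate seeds derive from one base seed via `numpy.random.SeedSequence`
  spawning — the same convention the pipeline uses to fan a single global
  seed out to per-stage streams, so toggling stages never shifts another
  stage's random draw.

## Numerical conventions and edge cases

* Monte-Carlo permutation p-values use (1 + exceedances)/(1 + n_perm) and
  therefore never reach 0; exhaustive enumeration reports plain
  proportions.
* Similarity networks invert distances (1/d); zero distances are clamped to
  the largest finite similarity and flagged; edges strictly below the mean
  off-diagonal similarity are dropped.
* The length filter treats "longer than 260 bp" strictly; SVs without
  recorded lengths make the filter an explicit error rather than a silent
  no-op.
* Distance matrices validate symmetry, zero diagonal and non-negativity on
  construction; Bray–Curtis accepts rows that do not sum to 1 (the core
  subset), JSD requires proper distributions.
* All tabular outputs are written with a fixed float format, and the run
  manifest checksums them (PNG figures excluded — their encoders embed
  metadata), so a pipeline rerun with the same inputs and seed is
  bit-identical.

## Known limitations

* PERMANOVA offers only free permutation; restricted/strata permutation
  schemes for repeated measures are out of scope.
* The dyadic LMM treats dyad distances as conditionally independent given
  the two individual intercepts; full dyadic covariance (e.g. MRQAP) is not
  implemented.
* NMDS stress comparability across runs assumes the same tie treatment;
  only stress-1 with primary ties is provided.
* The indicator analysis is restricted to two groups; multi-group
  combinations are not supported.
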