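# sociobiome

Analysis toolkit for a question in host–microbiome ecology: **how do group
living and social relationships structure gut microbiome composition?** In
band-living mammals — harem-forming equids are the motivating system, with
bands of one stallion, several mares, and their immature offspring — the
microbiome may vary at multiple levels at once: within an individual over
time, between individuals, and between social groups, with specific
relationships (mother–offspring, stallion–mare) pulling particular pairs
closer together.

`sociobiome` implements the full analysis chain for this question and a
synthetic-data generator that emulates the hierarchical structure such a
study assumes, so the entire pipeline is testable end to end with no
external data. It is aimed at researchers combining 16S amplicon community
profiles (sample × sequence-variant count tables) with field sighting logs.

## What it computes

* **Proximity-weighted association index** per dyad from daily sightings
  (close → 2, medium → 1, apart → 0):

  E_AB = x_SUM / (2·x_COUNT + y_AB + y_A + y_B)

  where x_SUM sums the dyad's daily scores, x_COUNT counts days sighted
  together, and the y terms count days seen apart or alone.
* **Community divergence**: Bray–Curtis dissimilarity and Jensen–Shannon
  divergence (natural log, JSD ∈ [0, ln 2]); core-microbiome extraction at
  detection/prevalence thresholds.
* **NMDS ordination** (Kruskal stress-1, isotonic regression + SMACOF
  updates, multi-start).
* **PERMANOVA**: sequential (Type-I) partitioning of a Gower-centered
  distance matrix over metadata terms with permutation pseudo-F tests —
  the per-term df / SS / F / R² / p table.
* **Mantel-style Kendall correlation** between the association matrix and
  microbiome distances (node-label permutations).
* **Indicator taxa** (IndVal = √(specificity × fidelity)) between two
  groups, e.g. nursing foals vs weaned sub-adults.
* **Dyadic comparisons**: Gaussian mixed models with crossed random
  intercepts for both dyad members and band (likelihood-ratio χ² tests) for
  within/between-individual, maternal, and stallion–mare contrasts; one-way
  ANOVA + Tukey HSD for within/between-band divergence.
* **Synthetic studies**: Dirichlet baseline × lognormal band/individual/
  sample effects, a shared foal community shift, convex profile mixing
  along bonded dyads, multinomial read sampling, and cohesion-based
  sighting simulation.

## Worked example

Run the demo study (three bands of 9, 13, and 8 ponies, 3–5 faecal samples
each over a field season, 10 sighting days):

```python
import warnings; warnings.filterwarnings("ignore")
from pathlib import Path
from sociobiome import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(out_dir=Path("pony_demo"), sim=SimConfig(), seed=42, n_perm=999)
out = run_pipeline(cfg)

print(out["permanova_total_terms"].table.round(3))
m = out["mantel"]
print(f"\nMantel-Kendall: tau = {m.tau:.3f}, p = {m.p_perm:.3f}")
comp = out["comparison_individual"]
print(f"within-individual JSD  {comp.means['within_individual']:.3f} +/- {comp.ses['within_individual']:.3f}")
print(f"between-individual JSD {comp.means['between_individual_within_band']:.3f} +/- {comp.ses['between_individual_within_band']:.3f}")
print(f"LRT chi2 = {comp.statistic:.1f}, df = {comp.df}, p = {comp.p:.2g}")
```

prints

```
             df      SS       F     R2      p
term
band          2   3.220  11.449  0.156  0.001
life_stage    2   1.197   4.255  0.058  0.001
sex           1   0.276   1.965  0.013  0.003
Residual    113  15.893     NaN  0.772    NaN
Total       118  20.587     NaN  1.000    NaN

Mantel-Kendall: tau = -0.555, p = 0.001
within-individual JSD  0.167 +/- 0.002
between-individual JSD 0.226 +/- 0.001
LRT chi2 = 369.9, df = 1, p = 1.9e-82
```

Reading the output: band membership explains 15.6% of sample-level
compositional variance and life stage 5.8% (both p = 0.001 over 999
permutations); individuals that associate more have more similar
microbiomes (negative tau between association index and NMDS-space
distance); and repeated samples from one individual diverge less (mean JSD
0.167) than samples from different individuals of the same band (0.226),
a strongly supported contrast under the dyadic mixed model. `pony_demo/`
now contains every table (distance matrices, PERMANOVA tables, dyad
comparisons, indicator genera, association and similarity networks, NMDS
coordinates), a `manifest.json` with checksums — reruns with the same seed
are bit-identical — and `report.md` after calling
`sociobiome.make_report(out, "pony_demo/report.md")`.

The same stages are available from the shell:

```sh
sociobiome simulate --out fixture --seed 42
sociobiome run --in fixture --out results --seed 42
sociobiome network --sightings fixture/sightings.csv --out assoc.tsv
sociobiome stats permanova --dist results/distance_bray_samples.tsv \
    --meta fixture/metadata.tsv --terms band,life_stage,sex --perms 999
```

See `docs/methods.md` for the model, its assumptions, the generator's
calibration, and known limitations.

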