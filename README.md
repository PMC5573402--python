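# rarebio

Rare-biosphere partitioning and multivariate community analysis for
OTU-by-sample amplicon tables along environmental gradients.

Microbial and microeukaryotic communities sampled by high-throughput
amplicon sequencing split into an **abundant** biosphere (OTUs holding
more than 1% of a sample's reads), a **rare** biosphere (below 0.01%),
and the often-ignored **intermediate** group between those thresholds.
`rarebio` is a toolkit for asking, on estuarine-style survey designs
(multiple sites along a salinity gradient, repeated sampling through the
year, one to three depth layers), how these three groups are structured,
how OTUs move between them across space and time, how metabolically
active they are (rRNA:rDNA comparison), and which environmental variables
best explain community turnover.

It is aimed at microbial ecologists who start from a processed OTU table
(TSV matrix or BIOM 1.0 JSON) plus sample metadata and environmental
measurements — no raw-read processing is included.

## What it computes

* **Normalization** — fixed-depth rarefaction (multivariate hypergeometric
  subsampling, seeded), rarefaction curves with a closed-form
  hypergeometric oracle `E[S_d] = Σ_i (1 − C(N−n_i, d)/C(N, d))`, relative
  abundance conversion.
* **Biosphere partition** — per-(OTU, sample) classes from per-sample
  relative abundance *r*: abundant (*r* > 1%), intermediate
  (0.01% ≤ *r* ≤ 1%), rare (0 < *r* < 0.01%), absent (*r* = 0);
  per-sample read- and richness-fractions; pooled richness shares;
  transition accounting among classes (occurrence census or
  consecutive-month pairing); per-class subtables; OTU overlap between
  sample groups.
* **Activity** — for OTUs common to paired rRNA/rDNA tables, OLS of
  log₁₀ mean rRNA fraction on log₁₀ mean rDNA fraction, with the signed
  mean vertical deviation from the 1:1 line as the community-level
  activity summary, and a 3×3 (DNA class × RNA class) grid.
* **Multivariate machinery** — Bray-Curtis distances
  (`d = Σ|x−y| / Σ(x+y)`), non-metric MDS (Kruskal stress-1, isotonic
  regression, PCA-rotated axes), ANOSIM
  (`R = (r̄_between − r̄_within) / (n(n−1)/4)` on midranked distances),
  simple and partial Mantel tests (residual-correlation construction),
  BIOENV (exhaustive) and BV-STEP (stepwise) selection of the
  environmental subset whose Euclidean distances best Spearman-correlate
  with community distances, environmental preprocessing (normalizing
  transforms, z-scores, |ρ| > 0.90 collinearity pruning).
* **Indicators** — Dufrêne–Legendre IndVal (`IV = A × B`, specificity ×
  fidelity) with label-permutation p-values and the strict reporting
  filter IV > 0.3 and p < 0.05.
* **Synthetic data** — a seeded generator emulating the full survey
  design (97 samples, 548 OTUs, 14,825 reads/sample, three salinity zones,
  cool/warm seasons, env tables coupled to the planted gradients, paired
  rRNA/rDNA subset), so every stage is testable without any download.
* **Pipeline + CLI** — `run_full` orchestrates the entire battery and
  writes tidy TSVs plus a JSON manifest; the `rarebio` command exposes
  each stage (`synth`, `normalize`, `biosphere`, `ordinate`, `anosim`,
  `mantel`, `bioenv`, `bvstep`, `indicators`, `activity`, `network`,
  `run`).

All permutation tests use the (1 + hits)/(1 + permutations) convention
and explicit seeds.

## Worked example

```python
from rarebio import (SyntheticConfig, generate_community, generate_paired,
                     classify, pooled_richness_fractions, transitions,
                     bray_curtis, anosim, nmds, axis_env_correlation,
                     env_prepare, bvstep, fit_activity, common_otu_means)

cfg = SyntheticConfig(seed=42)                  # 548 OTUs x 97 samples
table, meta, env = generate_community(cfg)

cls = classify(table)
print(pooled_richness_fractions(cls))
# abundant        0.569573
# intermediate    0.985158
# rare            0.862709

print(transitions(cls)[["to_abundant", "to_intermediate", "to_rare"]].round(3))
#               to_abundant  to_intermediate  to_rare
# abundant            0.209            0.710    0.081
# intermediate        0.174            0.731    0.095
# rare                0.167            0.732    0.101

d = bray_curtis(table)
res = anosim(d, meta["zone"], n_permutations=999, seed=42)
print(f"zone ANOSIM R={res.r:.3f} p={res.p_value:.3g}")
# zone ANOSIM R=0.661 p=0.001

ordn = nmds(d, seed=42)
ax = axis_env_correlation(ordn, env, "salinity", axis=1)
print(f"stress={ordn.stress:.3f} dim1~salinity rho={ax['rho']:.3f}")
# stress=0.051 dim1~salinity rho=-0.916

penv, report = env_prepare(env)                 # 65 env-complete samples
bv = bvstep(d.filter(list(penv.index)), penv, seed=42)
print(bv.best_subset, round(bv.best_rho, 3))
# ('salinity', 'temperature', 'nh4_n') 0.912

paired = generate_paired(cfg, table)            # 26 paired rRNA/rDNA samples
fit = fit_activity(common_otu_means(paired))
print(f"activity slope={fit.slope:.3f} deviation={fit.mean_deviation:.3f}")
# activity slope=1.004 deviation=0.196
```

Reading: the intermediate group carries the largest share of total OTU
richness (98.5% of OTUs pass through it somewhere) and is the main pool
OTUs transition through; communities separate sharply by salinity zone
(ANOSIM R = 0.66 at the permutation floor p = 0.001); the first nMDS axis
is a salinity axis (|ρ| = 0.92); stepwise environmental selection
recovers the two planted drivers, salinity and temperature; and the
rRNA:rDNA regression sits above the 1:1 line (mean deviation +0.20 log₁₀
units), i.e. the typical common OTU is metabolically active.

The same analysis from the shell:

```bash
rarebio synth --out demo --seed 42
rarebio run --counts demo/counts.tsv --metadata demo/metadata.tsv \
            --env demo/env.tsv --rna demo/paired_rna.tsv \
            --dna demo/paired_dna.tsv --out demo_report --seed 42
```

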