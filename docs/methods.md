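# Methods

This note documents the models, conventions and numerical choices behind
`rarebio`, in the order the pipeline applies them, together with the
design decisions that were genuinely open and the limitations a user
should know about.

## Data model

The central object is a `CountTable`: OTU × sample non-negative integer
read counts, with unique ids on both axes and no empty samples.  Counts
stay integral until normalization; relative-abundance tables are the same
container with a `relative` flag, so the two states cannot be mixed
silently.  Sample metadata (site, month, depth layer, nucleic-acid type,
salinity in ‰, temperature in °C) and environmental measurements travel
as DataFrames indexed by sample id.  `align_tables` intersects the three
inputs, preserves the count table's sample order, and records every
dropped sample with its cause.  Samples with *missing environmental
values* are kept for community-only analyses and excluded from
env-dependent analyses (the complete-case reduction happens inside
`env_prepare`); with the generator's defaults this reproduces a 97 → 65
sample reduction.

Supported formats: TSV matrices (UTF-8, tab-separated, `#` comments
ignored except a QIIME-style `#OTU_ID` header, optional trailing
`taxonomy` column) and dense BIOM 1.0 JSON, written and read by a small
internal codec.

## Rarefaction

Libraries are subsampled without replacement to a common depth — one
multivariate hypergeometric draw per sample
(`numpy.random.Generator.multivariate_hypergeometric`), seeded and
bit-reproducible.  The default depth is 14,825 reads (the minimum library
size of the emulated design); `subsample_to` is the same operation at 100
reads, kept as a named stage for the robustness experiment at
clone-library sequencing effort.  Samples below the target depth are
dropped with a logged warning; OTU rows that become all-zero are retained
(classification treats them as absent).  The test oracle is the
closed-form expected richness under the hypergeometric model,
`E[S_d] = Σ_i (1 − C(N−n_i, d)/C(N, d))`, evaluated with log-gamma
functions.

## Biosphere partition and transitions

Classes are assigned per (OTU, sample) cell from the within-sample
relative abundance *r*: abundant strictly above 1%, rare strictly below
0.01%, intermediate on the closed interval between them, and absent at
*r* = 0.  The boundary convention follows the strict readings "more than
1%" / "less than 0.01%", which makes the intermediate interval closed.
Zeros are "absent", not "rare": classification presupposes presence, and
absent cells never enter transition denominators.

The transition summary takes, for each source class *c*, the OTUs
assigned *c* in at least one sample (the class-*c* membership table) and
tabulates the class of every present occurrence of those OTUs
(`all_occurrences`, the default occurrence census).  Because published
descriptions of this census are ambiguous about pairing, a second mode
(`consecutive_months`) tabulates ordered class pairs between temporally
adjacent samples of the same site and depth layer, counting occurrences
present at both times.  Both are reported when the design has a time
axis; neither is claimed to be the only defensible reading.

Per-OTU "status" labels within a sample group are the modal present
class, with ties broken toward the class holding more of the OTU's reads.

## rRNA:rDNA activity

"Common OTUs" have nonzero total reads in both the rRNA and rDNA
datasets.  Per-dataset means are taken across *all* samples of that
dataset, zeros included, before the log — common OTUs therefore have
strictly positive means and no pseudocount is needed.  The fit is
ordinary least squares of log₁₀ mean RNA fraction on log₁₀ mean DNA
fraction (log base 10, x = DNA, y = RNA), reported with the signed mean
vertical deviation from the 1:1 line; a positive deviation means the
typical common OTU carries disproportionately many transcripts.  Means
are joint over all paired samples rather than per-season (a per-season
split is a straightforward subset of the paired tables).  The same 1% /
0.01% thresholds applied to the means place each OTU on a 3×3
(DNA class × RNA class) grid.

## Multivariate analyses

**Distances.** Bray-Curtis dissimilarity `Σ|x−y| / Σ(x+y)` via scipy's
`pdist`, held in a validated `skbio.DistanceMatrix` (symmetry, zero
diagonal).

**nMDS.** Non-metric MDS with isotonic regression and Kruskal stress-1,
backed by scikit-learn's SMACOF implementation (`metric_mds=False`,
precomputed dissimilarities), best of 8 random restarts by default,
convergence tolerance 1e-9.  The final configuration is centred and
rotated to its principal axes so dimension 1 carries the most spread
(the convention of the major vegan-style implementations), with a
deterministic sign rule.  Axis *identity* is a property of the data: when
two planted gradients carry comparable variance, which one lands on
dimension 1 can vary between realizations.

**ANOSIM.** Clarke's statistic on midranked distances,
`R = (r̄_between − r̄_within) / (n(n−1)/4)`, label permutation,
p = (1 + hits)/(1 + permutations).  Pairwise ANOSIM optionally applies
Bonferroni (`min(1, m·p)` over the m pairs) — the only multiplicity
correction offered, matching the reporting convention the pipeline
mirrors.

**Mantel.** Correlation (Spearman by default) of the strict upper
triangles; significance by permuting the samples of the first matrix.
The partial Mantel test rank-transforms (for Spearman) the unrolled
triangles of a, b and the control, residualizes a and b on the control by
linear regression, and correlates the residuals; permutations relabel the
samples of a and recompute its residual vector.  This
residual-correlation construction is stated explicitly here because the
packages usually cited for it do not document their internal choices.

**Environmental preprocessing.** Per-variable normalizing transforms —
`auto` picks the member of {identity, √x, log₁₀(x+c)} minimizing
|skewness| for non-negative variables (c is half the smallest positive
value when zeros are present) — then complete-case reduction, z-scores,
and greedy collinearity pruning: from every pair with |Spearman ρ| >
0.90, the variable later in a user-supplied priority list is dropped
(default priority: salinity and temperature first, then column order).
Keeping the cheap, mechanistically primary variables is a deliberate
choice; the alternative (keep the variable more correlated with the
community) would bias later selection steps.

**BIOENV / BV-STEP.** For a candidate variable subset, Euclidean
distances on the standardized columns are Spearman-correlated with the
community distances over the upper triangles.  BIOENV searches all
subsets up to a size cap and is guarded at 15 variables (2¹⁵ subsets);
beyond that, callers must either pass an explicit override with a small
size cap or use BV-STEP.  BV-STEP alternates forward additions and
backward eliminations, each round accepting the single change improving ρ
by more than `rho_tol = 0.001`, from an empty, full or random start; the
search path is recorded.  Plain (unweighted) Spearman is used throughout.

**Axis–environment correlations.** Spearman ρ of an ordination axis
against one variable, with either the asymptotic p (default, flagged) or
a permutation p.

## Indicator species

IndVal per OTU and group: specificity `A_ij` (share of the OTU's
abundance in group j) times fidelity `B_ij` (occurrence fraction within
group j); the OTU's IV is the maximum over groups.  Two specificity
conventions exist in the literature and the cited implementations differ
in their default, so both are provided: the default computes A from group
*total* abundances (size-unequalized); `group_equalized=True` uses group
*means* (size-corrected).  They coincide for balanced designs; the choice
is recorded in the result object.  IV is reported on [0, 1] (×100 is a
display option).  Significance comes from permuting group labels and
recomputing each OTU's maximum IV (+1 convention).  The reporting filter
for "good" indicators is strict: IV > 0.3 and p < 0.05.

Table 2-style reporting in the pipeline runs both searches for all
samples and per salinity zone, once with all OTUs and once restricted to
the good indicators.

## Synthetic data generator

The generator emulates a year-long estuarine survey: 8 sites spanning a
full salinity gradient (three freshwater sites < 0.5‰, two
oligo/mesohaline 0.5–18‰, three poly/euhaline 18–40‰), six bimonthly
cruises, three depth layers at four of the sites plus one extra
mid-water sample — 97 samples; 548 OTUs at 14,825 reads per sample.
Seasons are cool (months 2, 4, 12) and warm (6, 8, 10) with mean
temperatures 16.5 / 26.4 °C.

Each OTU carries three traits: a lognormal base abundance
(log-SD `lognormal_sigma = 1.8`), a salinity-niche optimum on a
log-salinity axis with Gaussian breadth `niche_sigma = 0.30`, and a
seasonal log-response of scale `season_sigma = 1.4`.  A sample's expected
composition multiplies the three terms; a Dirichlet perturbation
(concentration `dirichlet_alpha = 150` × expected fractions) adds
replicate-level overdispersion, and a multinomial draw at the configured
depth yields counts.  Samples of one site and month share one salinity
value across depth layers (a well-mixed water column), so depth carries
no community signal — by design.  Optima and seasonal responses are
assigned by stratified (Latin-hypercube style) sampling within blocks of
12 consecutive abundance ranks: every stratum of the rank-abundance
curve covers the whole gradient and both seasons.  This "species
packing" keeps the planted spatial and seasonal signals present at every
abundance level in each realization; with fully independent traits, the
variance balance between the two gradients fluctuates strongly with
which few OTUs happen to dominate.  The default shape parameters were
chosen so that, at the design depth, all three biosphere classes are
populated and the intermediate class holds the largest richness share —
a generator property, not an empirical claim about any real dataset.

Environmental variables are noisy functions of the same two latent
signals (salinity position, season): temperature, chlorophyll *a*,
bacterial abundance, five nutrients, ten accessory pigments
(diadinoxanthin means 0.41 / 0.59 µg/L by season), and three
phytoplankton size-fraction ratios generated through a softmax so they
lie in [0, 1] and sum to 1.  Salinity and temperature are the planted
drivers (`planted_truth` reports them); setting the coupling
coefficients to zero severs the community–environment link.  A
configurable number of samples (default 32) receives one missing
environmental value, reproducing a 97 → 65 complete-case reduction.

Paired rRNA/rDNA tables cover the first 26 samples of months 2 and 6.
Per-OTU activity factors are lognormal (median 2.0, log-SD 1.0).  Both
tables carry a `NONFOCAL_POOL` row — the share of the sequencing library
(default 90%) held by non-focal eukaryotes, with reference activity 1 —
so relative abundances are measured against the whole library.  This is
what makes the *absolute* activity level observable: in a table
renormalized over focal OTUs alone, a common activity factor cancels
exactly and the planted median would be unidentifiable.  With the pool,
an OTU's expected log₁₀ RNA:DNA offset is `log10(a_i / Z)` with
`Z = bg + (1−bg)·Σ_j p_j a_j`, so a median activity above 1 produces a
positive fitted deviation.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomic structure, spatial autocorrelation beyond the salinity axis,
tidal dynamics, and OTU co-occurrence networks with ecological
interactions.  Passing tests therefore demonstrate that the analysis
stack recovers planted structure of the assumed form — not that any
particular field dataset satisfies those assumptions.

## Pipeline

`run_full` chains: align → rarefy → zone/season labels (F < 0.5‰,
OM 0.5–18‰, PE 18–40‰; months {2,4,12} cool, {6,8,10} warm) → biosphere
partition, fractions, transitions, subtables → Bray-Curtis → nMDS + axis
correlations → global/pairwise ANOSIM on zone, season and depth →
env_prepare → IndVal + filter → BIOENV/BV-STEP battery (all samples and
per zone × all OTUs and indicator OTUs) → simple + partial Mantel
battery (per variable, total/cool/warm scopes, controlling for salinity,
Bonferroni over the variable family) → activity analysis when paired
tables are given → network edge-list export.  Every stage logs inputs,
parameters and wall time; all tables are TSVs; `manifest.json` records
the config, derived stage seeds and input hashes, so a rerun with the
same inputs reproduces every number.  A stage failure aborts with the
stage name and still writes the partial manifest.

Pipeline defaults trade permutation resolution for wall time: 999
permutations per test (the floor p = 0.001 is sufficient for the
design-level contrasts), BIOENV size cap 2 inside the pipeline (the
full-variable exhaustive search is exponential; BV-STEP explores larger
subsets), nMDS with 8 restarts.  Standalone calls default to 9,999
permutations.  The test suite and the acceptance script run the complete
design (548 OTUs × 97 samples, and 600 × 97 for the budget check) in
minutes on one CPU.

## Known limitations

* BIOENV's exhaustive search is infeasible above ~15 variables; the
  pipeline's size-capped search plus BV-STEP is a heuristic and can miss
  the global optimum (the tests bound BV-STEP by the exhaustive maximum
  on small instances).
* A "variability explained" percentage for environmental subsets is not
  computed: no defensible definition exists for rank-correlation-based
  selection, and none is offered.
* Partial Mantel inference is known to be anti-conservative under strong
  spatial autocorrelation; results are reported with the construction
  spelled out rather than reinterpreted.
* nMDS axis numbering is variance-ordered; when two gradients are of
  comparable strength, axis identity can swap between realizations (the
  acceptance script reports best-axis correlations alongside the
  dimension-1 convention for this reason).
* The IndVal permutation p-values are per-OTU and not corrected for the
  number of OTUs; the IV > 0.3 filter is the primary guard, matching the
  reporting convention mirrored here.
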