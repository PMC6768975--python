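# Methods

## Scope and model

`assemblyscope` analyses rarefied amplicon OTU tables (samples × taxa,
integer reads) together with a rooted, branch-length-bearing phylogeny
over the OTUs and per-sample metadata (depth, coordinates, season,
environmental variables). Its core is the two-stage null-model inference
of community assembly processes; around it sit the standard descriptive
layers (alpha diversity, Bray–Curtis/PCoA, permutation group tests,
SIMPER/IndVal) needed to characterize a community dataset before asking
*why* it is structured.

### Stage 1 — phylogenetic turnover (βMNTD → βNTI)

For samples *k* and *m* with relative abundances *f* and cophenetic
(patristic) distances *d<sub>ij</sub>*:

βMNTD = ½ [ Σ<sub>i∈k</sub> f<sub>ik</sub> · min<sub>j∈m</sub> d<sub>ij</sub> +
Σ<sub>j∈m</sub> f<sub>jm</sub> · min<sub>i∈k</sub> d<sub>ij</sub> ]

Taxa shared by both samples match themselves at distance 0 (the standard
weighted convention). The null shuffles taxon labels across **all tips of
the phylogeny** (regional-pool randomization; an option restricts the
shuffle to the union of the pair's taxa), recomputing βMNTD per
randomization (999 by default). The standardized deviate

βNTI = (βMNTD<sub>obs</sub> − mean βMNTD<sub>null</sub>) / sd βMNTD<sub>null</sub>

uses the sample SD (ddof = 1) of the null draws. βNTI > +2 is read as
heterogeneous (variable) selection, βNTI < −2 as homogeneous selection.
Pairs whose null SD is exactly zero (e.g. both communities contain the
same taxon set, or a star phylogeny) are flagged *degenerate*, reported
separately, and excluded from process denominators rather than silently
propagated as NaN.

### Stage 2 — taxonomic turnover (Raup–Crick with Bray–Curtis)

For pairs not resolved by selection (|βNTI| < 2), observed Bray–Curtis
dissimilarity is compared against a null in which each community is
reassembled from the metacommunity (all samples in the run) preserving
its observed richness and read depth: members are drawn without
replacement with probability ∝ occupancy (occurrence frequency across
samples); each member receives one read and the remaining reads are
multinomial with probability ∝ pooled relative abundance among the
members. With *n<sub>lt</sub>* null values below and *n<sub>eq</sub>*
tied with the observed dissimilarity (tie tolerance 10⁻¹⁰),

RC<sub>bray</sub> = 2 · ( (n<sub>lt</sub> + ½ n<sub>eq</sub>) / reps − ½ ) ∈ [−1, 1].

One set of null communities is drawn per **sample** and shared across
that sample's pairs, so the 999 null Bray–Curtis values of a pair are
paired by randomization index; this is what makes the 10,000-pair bounds
check affordable.

### Classification

Strict inequalities, applied in order: βNTI > 2 → heterogeneous
selection; βNTI < −2 → homogeneous selection; else RC > 0.95 → dispersal
limitation; RC < −0.95 → homogenizing dispersal; else the pair is
*undominated* (ecological drift plus weak selection/dispersal). Exactly
|βNTI| = 2 or |RC| = 0.95 therefore falls through to the next rule.
Per-group process fractions count within-group pairs only; *m* members
give m(m−1)/2 pairs.

## Descriptive layers and their conventions

* **Rarefaction** — one seeded draw per sample without replacement
  (`multivariate_hypergeometric`), default depth 7,597 reads; samples
  below depth are dropped with a warning, never padded. A repeated-draw
  mean is available but not default.
* **Depth layers** — [0, 50) m surface (3 m casts), [50, 100) euphotic,
  [100, 200) transitional, [200, 1000] mesopelagic; left-closed intervals
  with 1000 m included. Stations are *nearshore* when the water column is
  < 50 m, otherwise *offshore* (50 m itself is offshore).
* **Alpha diversity** — observed richness; Shannon H′ in nats with
  exp(H′) as the order-1 true diversity (the pairing forces base *e*);
  Faith's PD including the root path, so a single-tip sample has positive
  PD; Chao1 as S_obs + F₁²/(2F₂), bias-corrected form when F₂ = 0.
* **PCoA** — Gower centering of −½D², `eigh`, coordinates =
  eigenvectors × √λ for positive λ. Negative eigenvalues are reported
  untransformed (no Cailliez/Lingoes correction) and excluded from the
  proportion-explained denominator.
* **Permutation tests** — ANOSIM on midranked dissimilarities,
  R = (r̄_between − r̄_within)/(M/2); one-way PERMANOVA from the
  distance formulation with pseudo-F and R²; MRPP with group weights
  n_g/n and A = 1 − δ_obs/mean δ_perm; Mantel as Pearson r on unfolded
  upper triangles with simultaneous row/column permutation of the first
  matrix; partial Mantel by the first-order residual formula with the
  control correlation held fixed. All five use the estimator
  p = (count + 1)/(n_perm + 1) (one-sided; for MRPP the count is of
  δ_perm ≤ δ_obs) and a single seeded generator, so results are
  bit-reproducible. 999 permutations by default; the smallest attainable
  p is then 0.001.
* **SIMPER** — per between-group pair, taxon k contributes
  |x_k − y_k| / Σ(x + y); averages over pairs sum exactly to the mean
  between-group Bray–Curtis. Computed on the same (rarefied count) scale
  as the distance matrix.
* **IndVal** — specificity A (group mean relative abundance over the sum
  of group means, equal-weight groups), fidelity B (occurrence fraction),
  statistic √(A·B) with the OTU assigned to its argmax group; p by
  permuting sample labels. Both √(A·B) and A·B are reported; the 0.3
  indicator threshold is applied on the square-root scale, combined with
  p < 0.05.
* **Group summaries** — pairwise two-sided exact Mann–Whitney tests per
  alpha metric, Benjamini–Hochberg adjusted within metric, rendered as a
  compact letter display (insert-and-absorb).

## Synthetic communities

The generator produces what the pipeline consumes downstream of
clustering: a fixed-depth table, an ultrametric unit-height Yule tree
(pure-birth with a final exponential hold so terminal branches are never
zero-length), and transect-style metadata. Niche optima evolve by
Brownian motion from a root value of 0; an optional early-burst (ACDC)
mode decays the diffusion rate as exp(−g·t) from the root.

Defaults define the study conditions used by the tests: 128 taxa, 12
sites, 2,000 reads per site, 999 randomizations.

* **Heterogeneous selection** — sites evenly spaced on an environmental
  gradient spanning [−2, 2] (≈ ±2 trait SD); expected abundance of taxon
  k at site s ∝ exp(−(opt_k − env_s)²/(2σ²)) with σ = 0.25, multinomial
  reads. Scenarios use early-burst traits (rate 5, conservatism 5, tip
  SD ≈ 1): under pure Brownian motion on a Yule tree most trait variance
  accrues on shallow branches, so environmental bands are not
  clade-compact and nearest-taxon metrics lose power; concentrating
  divergence on deep branches makes niches clade-heritable, which is the
  regime in which βNTI is designed to detect selection.
* **Homogeneous selection** — all sites share one environmental value
  (+1.0). The filter acts at clade level: the clade holding 20–45% of
  taxa whose mean optimum best matches that value is the suitable pool,
  and each site hosts a uniform random half of it with lognormal
  (SD 0.5 log-units) abundances — selection fixes the candidate pool,
  local drift decides who establishes. A soft abundance kernel shared by
  all sites cannot express this process to nearest-taxon metrics: the
  abundant taxa are then identical across sites (contributing zero to
  βMNTD) and turnover is confined to the negligible-weight rarity tail.
* **Dispersal limitation** — taxa partitioned into three disjoint random
  pools; contiguous site clusters draw neutrally (lognormal weights,
  SD 1.5) from their own pool. Between-cluster pairs have Bray–Curtis
  ≈ 1 and RC → +1; within-cluster pairs legitimately read as
  homogenizing exchange.
* **Homogenizing dispersal** — one shared realized pool (a single
  multinomial draw of 10⁵ individuals from a lognormal metacommunity)
  from which every site is a multinomial sample: turnover sits at
  read-noise level, below the Raup–Crick expectation.
* **Drift** — each site independently resamples the shared lognormal
  pool through a small effective population (400 individuals) before
  sequencing-depth sampling. The effective size is chosen so site-level
  compositional variance sits in the middle of the Raup–Crick null —
  which is precisely what "drift alone" means in this framework; read
  depth stays at the fixed 2,000.

### What the generator does and does not emulate

It reproduces the statistical structure the inference relies on —
fixed-depth multinomial sampling, phylogenetically conserved niches, an
environmental/spatial gradient, metacommunity occupancy/abundance
structure. It does not simulate sequencing error, chimeras, clustering
artifacts, temporal dynamics, or spatially explicit dispersal kernels;
passing recovery tests therefore demonstrates that the estimators detect
the processes they target under their own assumptions, not that any real
dataset satisfies those assumptions.

Recovery at the study scale (thresholds chosen loose deliberately):
selection scenarios yield ≥ 60% of pairs correctly labeled; the
dispersal scenarios and drift yield their own label as plurality.
Across ten tree seeds the homogeneous-selection fraction ranged
0.29–1.00 (median ≈ 0.9); the suite runs the recorded seeds.

## Numerical choices

* Permutation p-values never report 0: (count + 1)/(n_perm + 1).
* βNTI null SD uses ddof = 1; a null SD of exactly 0 flags the pair
  degenerate instead of dividing.
* Raup–Crick tie comparisons use an absolute tolerance of 10⁻¹⁰ on
  Bray–Curtis values (rationals with a shared denominator; exact ties are
  real).
* Environmental distances z-standardize with sample SD (ddof = 1);
  zero-variance variables are dropped with a warning.
* Geographic distances are haversine with Earth radius 6,371 km.
* PCoA treats eigenvalues below max(10⁻¹², 10⁻¹⁰·λ₁) as zero.
* All randomness flows through `numpy.random.Generator`; compound
  analyses spawn independent child streams via `SeedSequence` (seeds kept
  below 2³¹), so each stage is reproducible in isolation.

## Problem sizes in the test suite

Unit tests run on toy fixtures (4-tip tree, 6 × 10 deterministic
bundle). The scientific checks run at the study scale — five scenarios
at 128 × 12 × 2,000 with 999 randomizations (~20 s total), a 12-site
neutral calibration at 999 randomizations, and a 10,011-pair Raup–Crick
bounds sweep — sizes chosen to exercise the estimators where they are
actually used while keeping the suite comfortably interactive.
Exhaustive-relabeling oracles for the permutation tests enumerate all
720 orderings at n = 6; cross-language oracles (vegan's ANOSIM/adonis/
MRPP statistics, picante's `comdistnt` for βMNTD) agree to 10⁻¹⁰ on the
fixture.

## Known limitations

* One-way designs only for the group tests; no strata, no PERMDISP
  companion, no multi-factor adonis.
* IndVal uses equal-weight group means (no group-size correction); with
  very unbalanced groups the statistic can drift from the size-corrected
  variant.
* The Raup–Crick metacommunity is the sample set being analysed;
  per-subset runs (e.g. one layer at a time) change the null and are a
  configuration choice, not an implementation detail.
* βNTI seed-to-seed variability on small trees is real; single-seed runs
  near the ±2 threshold should be interpreted with the degenerate-pair
  report and, ideally, replicate seeds.
* The homogeneous-selection fraction recovered from synthetic data
  varies substantially across tree realizations (see above); the
  scenario demonstrates detectability under clade-heritable niches, not
  a universal power guarantee.
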