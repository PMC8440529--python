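# Methods

`mrith` reconstructs the clonal architecture of multi-region
whole-exome tumor data and summarizes it as per-patient heterogeneity
metrics with survival associations. This note documents the models, the
defaults and why they were chosen, the synthetic cohort the tests run
against, and the limits of what those tests show.

## Read-count model and CCF estimation

A somatic mutation with cancer cell fraction `CCF` and multiplicity `m`
(mutated copies per tumor cell) in a region with purity `p`, local
total copy number `q` and normal copy number `q_n = 2` has expected
variant allele frequency

    E[VAF] = p * CCF * m / (p*q + (1 - p)*q_n)

Inverting, the mutation copy number is `mut_cn = VAF * (p*q +
(1-p)*q_n) / p`; the multiplicity estimate is `round(mut_cn)` clamped
to `[1, major_cn]`, and `CCF = mut_cn / multiplicity`. CCF estimates
are capped at 1.5 (with a flag): sampling noise and FFPE artifacts push
raw values above 1, and values beyond the cap carry no extra
information. Mutations falling in a zero-copy segment are excluded with
a warning.

## Mutation clustering (`BinomialMixture`)

Mutations are clustered across regions under a binomial mixture:
mutation `i` of cluster `k` contributes `alt[i,r] ~ Binomial(depth[i,r],
c[i,r] * phi[k,r])`, where `c[i,r] = m*p / (p*q + (1-p)*2)` converts a
cluster prevalence `phi` to an expected VAF and entries with zero depth
are unobserved. The fit is EM with:

- initialization from k-means centers over the naive per-mutation CCF
  rows plus seeded k-means++-style row draws (the extra candidates
  guard against local optima at small k);
- an exact 1-D bisection M-step for each `phi[k,r]` (the weighted
  binomial score is strictly decreasing in `phi`);
- model selection over `k = 1..k_max` (default 8) by BIC with
  `k*R + (k-1)` parameters;
- post-selection consolidation: clusters whose prevalence vectors agree
  within 0.06 (max over regions) are merged. Mixture likelihoods
  overfit a single population near the prevalence boundary (splitting a
  unimodal clonal cluster can beat the BIC penalty at a few hundred
  mutations); merging indistinguishable clusters is the usual remedy in
  CCF clustering tools and 0.06 is well below the separation at which
  two subclones are resolvable at ~250x depth.

All randomness flows from `random_state`; a fixed seed gives a
byte-identical solution. The cluster with the largest mean prevalence
across regions is the clonal cluster (ties to the larger cluster, then
the lower id); SNV ITH is the subclonal fraction of the patient-level
union of nonsilent mutations. TMB is that union divided by the callable
coding footprint (`coding_mb`, default 38 Mb — a typical whole-exome
capture; configurable because the true denominator depends on the
panel), and TMB/cluster divides by the selected cluster count.

## Somatic filters and rescue

A call is retained when alt reads >= 5, normal depth >= 10, tumor depth
> 30, VAF >= 3% and population allele frequency <= 1%. Counts are
assumed to come from high-quality reads only (base and mapping quality
filtering happen upstream). A variant called in at least one but not
all regions of a tumor is rescued into a missing region when the raw
pileup there shows VAF > 1% and the matched normal has fewer than five
mutant reads; rescue runs after all per-region filters, never removes a
call, and never invents a variant absent everywhere.

## Copy-number heterogeneity

Gains and losses are ploidy-relative: with `lr = log2(total_cn /
ploidy)`, a segment is a gain when `lr >= log2(2.5/2)` and a loss when
`lr < log2(1.5/2)`. GII is the fraction of the autosomal genome covered
by either. Because regions are segmented independently, cross-region
comparison projects events onto fixed 10-Mb bins (configurable); a gain
is clonal when all regions carry it, a loss when every region shows the
loss or LOH. CNV ITH is the mean pairwise Jaccard distance between
per-region binned event sets, with empty-union pairs contributing 0.

Whole-genome doubling is tested per region on the length-weighted
fraction of the autosomal genome with major allele count >= 2. The null
permutes the assignment of allele-specific states to segment lengths
(`p = (1 + #{sim >= obs}) / (n_sim + 1)`), and the call threshold
depends on the rounded length-weighted ploidy: 0.001 up to triploid,
0.05 for tetraploid, 0.5 for pentaploid, and always for hexaploid or
higher. A fully doubled genome is degenerate under this null (every
permutation ties the observation, so p = 1); the implementation
short-circuits `statistic = 1.0` with rounded ploidy >= 4 to a WGD
call. Sex chromosomes are excluded from GII and WGD denominators by
default: the cohort mixes sexes and single-copy male X/Y would distort
both statistics.

## Phylogenies and timing

Trees relate a patient's regions to a germline (all-zero) root through
binary presence/absence over the union of nonsilent mutations;
mutations overlapping an LOH segment in any region are excluded because
allelic loss can erase presence signal. For the 3-4 regions typical of
multi-region designs, all rooted multifurcating topologies are scored
exhaustively by small parsimony (two-state dynamic programming, root
fixed absent) and the minimum-score topology wins; among ties the least
resolved topology is preferred — an internal edge is only introduced
when some shared pattern supports it — then the lexicographically
smallest canonical form. Each mutation is placed on its trunk-most
gain edge in an optimal labeling, so branch lengths are mutation counts
and sum to the mutation total on conflict-free matrices.

Timing: an SNV is early when `mut_cn > 1` (it predates a gain), late
otherwise. A gained segment is timed by the mean `mut_cn` of the
mutations inside it, requiring at least five (fewer gives "NA"). A
clonal loss in a genome-doubled tumor is early; any other loss is late.

## Signatures and drivers

SNVs are counted into the standard 96 trinucleotide categories
(pyrimidine-strand convention). Exposures are refit by non-negative
least squares against a catalog on the normalized spectrum, pruning
exposures below 0.06 and renormalizing — the convention of standard
refitting tools. The packaged catalog
(`synthetic_sbs_v2_like_catalog.tsv`) is a deterministic synthetic
stand-in with the COSMIC-v2 shape (96 x 30, column-stochastic,
age-like, tobacco-like, flat HR-deficiency-like and aflatoxin-like
profiles among random sparse ones); all refitting code is
catalog-agnostic, so a real catalog can be dropped in as a TSV with the
same layout. The packaged driver list is likewise a synthetic
census-style subset; driver APIs accept any gene set.

A driver gene's occurrence is `frequency / n` over the cohort. Its
dominant score aggregates co-occurrence:
`score(g) = [sum over tumors with g, sum over co-occurring drivers d,
1/frequency(d)] / frequency(g)`, pooled over tumors by default (a
per-tumor averaging variant is available behind a flag).

## Survival analysis

Heterogeneity metrics are dichotomized at the cutoff maximizing the
two-group log-rank statistic, scanning observed values between the 0.2
and 0.8 quantiles so neither group is degenerate (ties go to the
smaller cutoff); TMB instead uses an upper-quantile split (default
0.75, type-7 linear-interpolation quantile — the convention is pinned
so results are reproducible). The log-rank statistic is computed
in-repo and verified against lifelines; Cox models delegate
partial-likelihood maximization to lifelines, reporting hazard ratios
with 95% CIs and flagging non-convergence instead of raising.
Maximally selected statistics inflate type-I error; no correction is
applied, and downstream users should treat best-cutoff p-values as
exploratory.

## Synthetic cohort generator

The generator emulates a 40-patient, 3-regions-per-patient FFPE exome
cohort at mean depth 252x with purity 0.3-0.9 — the regime the pipeline
is built for. Per patient:

- A clone tree with a founder plus 0-4 subclones, linear or branching
  with equal probability (both occur in real multi-region cohorts).
  Subclones occupy a proper subset of their parent's regions (spatial
  confinement is what makes multi-region sampling informative).
  Sibling CCFs are allocated by stick-breaking on 95% of the parent's
  budget with U(0.2, 0.8) fractions — the Dirichlet-process-style
  prevalence prior assumed by CCF clustering models, giving diverse
  clone sizes while honoring the sum rule in every region. Subclone
  subtrees that stay below CCF 0.1 in every occupied region are not
  instantiated: at ~250x exome depth such clones are invisible to any
  method, and keeping them would make ground truth unrecoverable in
  principle rather than in implementation.
- 50-450 clonal and 15-110 per-subclone mutations (nonsilent fraction
  0.75), placed uniformly on autosomes with trinucleotide contexts
  drawn from a configurable signature mixture (defaults: age-like 0.40,
  tobacco-like 0.30, HR-deficiency-like 0.15, aflatoxin-like 0.15,
  matching the etiologies dominant in smoking-associated
  neuroendocrine lung tumors). Recurrent driver labels (TP53 0.88
  clonal, RB1 0.72 clonal, CREBBP 0.30 clonal; LRP1B/PCLO/KMT2D
  subclonal) are painted onto mutations of the right clonality.
- Shared-breakpoint allele-specific segments per region: 1-3 segments
  per autosome, Poisson(6) clonal events (gain or LOH loss), Poisson(3)
  region-private events, and WGD with probability 0.4 that doubles the
  clonal states. Post-WGD private losses remove single copies (the
  remaining haplotype of an LOH segment is treated as essential), so
  doubled genomes retain major_cn >= 2 genome-wide — the signature the
  WGD test keys on.
- One count record per (mutation, region): depth ~ Poisson(252), alt
  reads ~ Binomial(depth, E[VAF]) with the read-count model above;
  founder mutations in doubled genomes predate the doubling with
  probability 0.75 (multiplicity 2). Matched-normal counts carry a
  5e-4 error rate; 2% of records get a nonzero population allele
  frequency to exercise the germline filter. An optional FFPE knob
  injects private low-VAF C>T artifacts (off by default).
- Survival from an exponential proportional-hazards model: OS log
  hazard +1.5 per unit of true SNV ITH (worse OS), DFS log hazard
  -0.12 per mut/Mb of TMB/cluster (better DFS), baselines with median
  45 and 28 months and uniform censoring on 6-84 months, consistent
  with a surgical cohort followed about two years. TNB is a Poisson
  draw proportional to nonsilent burden with lognormal noise, giving a
  moderate rank correlation with TMB.

Per-patient seeds derive from `SeedSequence(master_seed,
patient_index)`: cohorts are byte-reproducible and patients
independent.

What the generator does **not** model — and what passing recovery tests
therefore cannot show: alignment and calling artifacts beyond the
optional C>T knob, segmentation noise or purity/ploidy estimation error
(segments and purities are passed through exactly), independent
per-region breakpoints, indels, germline variation, kataegis or
regional mutation-rate variation, correlation between DFS and OS within
a patient, and biallelic deletions. Recovery rates on this cohort
measure the pipeline's statistical behavior under its own read-count
model, not robustness to upstream errors.

## Problem sizes used in the checks

The bundled end-to-end checks run a 40 x 3 cohort at depth 250 for
clustering recovery, 100 doubled plus 100 diploid regions at
`n_sim = 1000` for the WGD operating characteristics, 40 linear-tree
patients for topology recovery, 10^5 sampled mutations for signature
refitting, and n = 500 for Cox hazard-ratio recovery. These sizes give
Monte-Carlo error comfortably below the tolerances being checked.

## Known limitations

- The binomial likelihood ignores overdispersion; consolidation
  (above) absorbs the practical consequence, but heavily overdispersed
  real data may still oversplit.
- Exhaustive tree search is implemented for up to five regions; larger
  designs need a heuristic search that is out of scope here.
- The WGD permutation null has no power when the doubled fraction is
  spatially uniform (the degenerate short-circuit covers the fully
  doubled case); genomes doubled and then heavily re-lost below
  rounded ploidy 4 can be missed.
- Best-cutoff dichotomization is selection-biased by construction.
- The packaged signature catalog and driver list are synthetic
  stand-ins; scientific use requires swapping in the real reference
  files.
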