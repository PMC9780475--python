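# Methods

## The activity score

For one sample, genes are ranked by descending expression (rank 1 = most
expressed of the N genes in the matrix). For a gene set S the enrichment
score is the running sum

    ES(S) = sum_{i=1..N} [ P_in^w(i) − P_out(i) ]

walking genes from the top of the ranking, where

    P_in^w(i)  = Σ_{g ∈ S, rank_g ≤ r_i} w_g / Σ_{g ∈ S} w_g ,   w_g = (N − rank_g + 1)^α
    P_out(i)   = #{g ∉ S, rank_g ≤ r_i} / (N − |S|)

The weight exponent α defaults to 0.25; at α = 0 the statistic reduces to
the plain difference of the member and non-member empirical CDFs summed
over all rank positions, which is what the hand-enumerated test cases and
the brute-force oracle evaluate. The TP53 activity score of a sample is
`score = ES(induced) − ES(repressed)` over the packaged 30-gene signature.

**Ties.** Under the default `average_rank` policy tied genes share their
average rank, and the running sum evaluates every member of a tie group at
the cumulative mass through the *end* of the group. This makes the score
invariant to the order in which tied genes are listed; in particular a
matrix in which every induced gene has an identically-valued repressed
partner scores exactly 0. `stable_order` instead breaks ties by input
order, producing integer ranks 1..N (useful for exact reproducibility of
integer-rank oracles).

**Normalization.** `normalize="none"` (default) subtracts raw enrichment
scores. `normalize="range"` divides each direction's score vector by its
(max − min) across samples first; because group assignment is rank-based
(median split), the choice does not affect stratification, and neither
behavior is asserted as canonical. A degenerate zero range leaves the
vector untouched.

**Missing genes.** Scoring proceeds on the intersection of the signature
with the matrix, logging absent symbols; only an entirely absent direction
is an error. Duplicate gene rows in input files are collapsed by mean (the
probe-averaging convention for array data).

**Grouping.** `high` iff score > cut-point, with the cohort median as the
default cut-point; an explicit numeric cut is accepted, and an all-equal
score vector under the median rule is an error rather than an arbitrary
split.

## Survival

Kaplan–Meier product-limit estimation and the two-sided log-rank test
(chi-square with 1 df) are computed via lifelines. Censored observations
at an event time are counted as at-risk through that time — the standard
convention, stated here because the toy product-limit oracles in the test
suite depend on it. No Cox regression or multivariable adjustment is
attempted; p < 0.05 is the significance convention throughout.

## Differential expression

A desk-scale two-group stage: per-gene Welch t-test on log2(x+1) values,
fold change = 2^(mean log difference), Benjamini–Hochberg adjustment, and
the calling rule p_adj < 0.05 and fold change strictly outside
[1/1.5, 1.5]. This deliberately substitutes a simple, assumption-light
test for count-model machinery (dispersion estimation, shrinkage); the
thresholds — the actual decision rule — are exercised exactly, but DEG
lists from count models on real sequencing data would differ. A gene with
zero variance in both groups gets p = 1 when the group means agree and
p = 0 when they differ (the t statistic is infinite); both cases are
logged.

## Variant screening

All three criteria are strict inequalities (depth > 30, VAF > 1 %,
Q > 10), checked in that order; the reported failure reason is the first
violated criterion and a zero-coverage site fails on depth without any
VAF division. VAF is variant depth over total depth — the only ratio the
two depth fields define. Gene-level TP53 status is the default; a
position allowlist emulates hotspot-site restriction but no default site
list is shipped.

## Spatial stage

ROIs are square (side 1000 μm by default) and partitioned into a √n × √n
grid of equal blocks, numbered row-major from the origin corner with
half-open tiles (the outer row/column closed), so every in-ROI point maps
to exactly one block. Region labels (tumor / boundary / stroma) are inputs
per block; cells are assigned by centroid only.

Neighborhood: cells i, j are neighbors iff centroid distance
≤ r_i + r_j + margin (default margin 4 μm). With no segmentation radii the
rule degrades to a pure 4 μm centroid criterion (radius 0); a constant
radius can be supplied instead. The k-d-tree implementation is capped at
the largest possible interaction distance and post-filtered against the
exact rule, and is tested for equality with an all-pairs reference.
Adjacency never crosses ROI boundaries. Region comparisons use a
two-sided Wilcoxon rank-sum on per-ROI proportions; ROIs whose region
holds no cells are excluded and logged.

## Synthetic cohort generator

A two-state latent model stands in for TP53 functional status — the
simplest structure consistent with retention vs inactivation, not a
biological model:

- **Expression.** Per-gene log2 means ~ N(5, 1.5²); within-gene noise SD
  1.0 (log2 scale); 300 background genes plus the 30 signature genes.
  Active samples get +delta·SD on the induced genes, inactive samples
  +delta·SD on the repressed genes; delta defaults to 2.
- **Survival.** Exponential event times, baseline hazard 0.1 for active
  samples and 0.1 × hazard_ratio (default 3) for inactive. Censoring is
  independent exponential with its rate solved per state so the marginal
  censoring probability equals `censoring_rate` (default 0.2); rate 0
  yields all-events data.
- **Variants.** Passing TP53 records planted with probability 0.7 in
  inactive and 0.1 in active samples; three extra records straddle the
  screening thresholds, each failing exactly one criterion (depth 30,
  VAF 1 %, Q 10 — the boundary values, which the strict rule rejects).
- **Spatial.** Each ROI reuses a 20 × 20 mask with a 10 × 10 tumor core,
  a one-block boundary ring and stromal remainder; 600 cells per ROI are
  placed uniformly within their region with region-specific phenotype
  frequencies (8-phenotype palette). In the low group the boundary Treg
  frequency is multiplied by `boundary_enrichment` (default 3) and
  CD47+PD1+ cells are re-placed within the 4 μm membrane margin of a
  random Treg, planting the immunosuppressive niche the spatial stage is
  meant to detect. Cell radii default to 5 μm.

All generators derive their randomness from `(seed, stage-salt)` seed
sequences and are bit-reproducible given the config. Default calibration
(delta 2, hazard ratio 3, enrichment 3, n = 200 cohorts, 50 ROIs/group)
was chosen once as a realistic strong-signal regime that sits comfortably
above the property-test floors (AUC ≈ 1, log-rank power > 95 %); the
null settings (delta 0, hazard ratio 1, enrichment 1) are used for
calibration checks.

**What passing tests show — and don't.** The generator plants clean
additive shifts, exponential hazards and uniform spatial placement. Real
cohorts have correlated genes, platform effects, non-proportional
hazards, segmentation error and irregular tissue geometry; recovery on
synthetic data demonstrates the machinery is correct and calibrated, not
that effect sizes of this magnitude exist in real tissue.

## Numerical choices and degenerate inputs

- Enrichment is undefined when a set is disjoint from, or equal to, the
  gene universe; both raise with the offending symbols listed.
- The brute-force oracle agreement tolerance is 1e-12 (absolute) on
  instances with N ≤ 50 genes.
- Rank-sum and log-rank p-values are asymptotic; the log-rank test is
  cross-checked against an exhaustive permutation reference on a 4-sample
  toy dataset at the permutation resolution.
- Problem sizes in the test and acceptance suites (200-sample cohorts,
  100–200 replicates, 50 ROIs per group, ≤ 250-cell adjacency oracles)
  were chosen as the smallest sizes at which the Monte-Carlo bounds are
  stable.

## Known limitations

- The DEG stage is not a count model; see above.
- Microarray probe collapsing, deconvolution, clustering of cytometry
  data, segmentation and ligand–receptor analysis are upstream/downstream
  of this package and out of scope; the spatial stage consumes cell tables
  and block masks as given.
- The original cohort's block-mask delineation against H&E sections is a
  manual step; masks here are inputs (or synthetic).
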