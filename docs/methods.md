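# Methods

This note records the models, conventions and numerical choices behind
`quartetqc`, and what the synthetic testbed does and does not establish.

## Measurement model and ratio scaling

All quantitative layers are treated on log2 scales (methylation M values,
log2 CPM/FPKM/FOT/intensity).  The working model is log-additive:

    value(f, s) = baseline(f) + donor_effect(f, donor(s))
                + batch_offset(f, batch(s)) + global_shift(batch(s))
                + noise(f, s)

which is a multiplicative sensitivity model I = f(C) on the linear scale.
`ratio_scale` subtracts, per feature and batch, the mean of the reference
donor's replicates.  Under the model above this cancels `batch_offset` and
`global_shift` exactly; replicate noise breaks the exactness, and the tests
quantify by how much.  Conventions:

- The ratio is **study minus reference mean** in log space (so D5/D6 > 0
  means D5 is more abundant).
- Reference replicates are kept in the output as deviations from their own
  mean (their per-batch mean becomes 0), so four-group statistics remain
  computable after scaling.
- Applying `ratio_scale` to already-ratio data is an error (scale tags are
  tracked on the dataset).
- `zscore_by_batch` standardizes each feature within each batch with the
  sample (n−1) standard deviation; a zero-variance feature-batch maps to 0.

## SNR

`snr_from_embedding` implements the pair-count-normalized ratio of average
between-group to average within-group squared distance, in decibels, on the
first two embedding components weighted by their explained-variance
fractions.  `compute_snr` produces the embedding by feature-wise
standardization (unit variance; zero-variance features dropped with a
warning) followed by PCA via SVD.  Exactly two components are used;
requiring equal replicate counts per group keeps the pair-count prefactor
exact.

`snr_from_similarity` treats each sample's similarity-matrix row as its
profile vector and applies the same ratio.  Two orientations of this
statistic circulate; the default here puts the between-group distance in the
numerator so that better-separated clusterings always score higher, and
`as_printed=True` returns the negation (within-group in the numerator) for
compatibility with the inverted convention.

A zero within-group distance yields +infinity with a warning; `cap_snr`
maps it to a 999 dB sentinel for tabular output.  Zero between- and
within-group distance together is an error (degenerate embedding).

## ARI and RMSE

`adjusted_rand_index` is the standard Hubert–Arabie pair-counting
contingency form, which is 1 exactly when the partitions coincide up to
relabeling and 0 in expectation under chance.  When both partitions are
trivial the convention is 1 if they are identical, else 0.  `rmse` is
computed over the feature intersection only, with coverage (shared /
reference count) reported alongside, and an empty intersection is an error
rather than a silent 0.

## Differential features and consensus voting

DEF calling uses a two-sided Welch t-test (unequal variances,
Welch–Satterthwaite degrees of freedom, delegated to
`scipy.stats.ttest_ind`) plus a log2 fold-change cutoff.  Deliberately, no
multiple-testing correction is applied: the non-stringent P cutoff with
fold-change ranking is the reproducibility-oriented convention for
small-replicate reference designs, and the cross-batch consensus vote is
the error-control mechanism.  Features with zero variance in both groups
are flagged degenerate and never become DEFs.

Voting: a feature must be quantifiable (survive intra-batch QC) in more
than the per-omics presence rate of batches; one direction must then win
more than the vote threshold (default 0.7) of the feature's **quantifiable**
batches.  The denominator choice is not dictated by the procedure's
description, so the alternative (all batches) is available via
`denominator="all"`; the quantifiable default avoids punishing features for
batches in which they could not have been observed.  The reference fold
change averages exactly the batches voting the winning direction.  With a
threshold above 0.5, conflicting directions cannot both qualify.

Intra-batch QC drops a feature if, in any donor's replicate group, it is
missing in more than one replicate or its replicate CV exceeds the
per-omics cutoff.  CV is computed on the back-transformed linear scale by
default (the quantity bench scientists report); `on_linear_scale=False`
uses the stored values.

## Cross-omics references

Features of two omics layers are paired through shared gene annotations
(many-to-many; pathway-based metabolite pairing reuses the same mechanism
with pathway members as "genes").  Samples are aligned across layers by
donor, with replicates paired positionally after sorting replicate numbers —
replicates in different batches have no physical correspondence, so any
pairing convention is admissible and this one is deterministic.  Pearson r
and its t-distribution p-value come from `scipy.stats.pearsonr`.

The classification grid (positive: r ≥ 0.5 and P < 0.05; negative: r ≤ −0.5
and P < 0.05) leaves two cells unspecified — significant-but-weak and
strong-but-nonsignificant — and both map to "none".  The presence threshold
for entering the vote is ceil(rate_a·B_a)·ceil(rate_b·B_b) batch
combinations (ceiling by default, floor available), and the category vote
and reference r follow the same more-than-70% rule as DEFs.

## Vertical integration

Feature selection keeps the top-k features by sample standard deviation
(ties broken lexicographically on feature id for determinism) and
standardizes them.  The affinity kernel is a scaled exponential of
Euclidean distances with a local bandwidth from each sample's K nearest
neighbors; the exponent is d²/(α·ε²) with ε in distance units, so affinities
are invariant to a global rescaling of the feature space.  K defaults to
round(sqrt(N)) — 3 for the 12-sample single-batch design; α = 0.5; 10
iterations.  Ties at the K-th neighbor are all kept, so exact duplicate
samples (the twin genotype columns) are treated symmetrically.

`snf_fuse` is a **consensus-preserving cross-diffusion**: each layer's
row-normalized network is nudged, through its own K-NN local kernel, toward
the average of the other layers' networks,

    P_v <- P_v + 0.5 * offdiag( S_v (mean_{u!=v} P_u - P_v) S_v' ),

and the fused result is the average of the final networks.  Two deliberate
properties distinguish this from the classic fusion iteration: (1)
agreement is a fixed point — fusing identical networks returns the
normalized input, since fusion should add nothing when the layers already
agree; and (2) only off-diagonal structure is exchanged, because a sample's
self-similarity says nothing about sample relationships, and letting dense
diagonals enter the block averages makes them masquerade as cluster
cohesion (empirically this inverts the within-donor/cross-twin ordering
when a degenerate layer like identical twin genotypes is present).  The
damping factor 0.5 keeps the two-layer case from oscillating.

PAM is the classic deterministic BUILD + SWAP algorithm on dissimilarity
1 − S/max(S).  `cluster_and_score` reports ARI against both the four-donor
and the three-family labelings plus the similarity SNR;
`twin_block_similarity` is the mean of the cross entries between two
donors' replicates (9 entries in the 3-replicate design).

## Synthetic data generator

The generator emulates the Quartet design: 4 donors (one twin pair), 3
technical replicates per donor per batch, B batches per layer.  Defaults,
chosen once as a moderate-quality multi-batch study and used by every
example: baseline N(8, 2²) log2 units, donor-effect sd 0.5, twin divergence
sd 0.2 per twin (quantitative layers only), per-feature batch offsets sd
1.0, global batch shift sd 0.25, replicate noise sd 0.2.  The acceptance
checks use the condition values each claim states (e.g. offset sd 3 with
zero noise for the cancellation identity; six batches and noise 0.2 for DEF
recovery).

- **Twins.** Quantitative layers share a genetic effect per feature with
  independent per-twin divergence; the DNA layer is identical between twins
  by construction (parents drawn at the configured allele frequency,
  daughters by Mendelian inheritance, one twin copied to the other), encoded
  hom-ref → 0 / alt-containing → 1, constant across replicates and batches.
- **Planted DEFs** replace the background biology of dedicated features
  with a single-donor effect of the configured size, so the realized
  donor-effect matrix (exposed in the ground truth) gives the exact true
  fold change of every feature for any contrast.
- **Planted cross-omics pairs** couple dedicated feature pairs through a
  standardized four-level donor score pattern, permuted over donors per
  pair, with loadings set so the model correlation equals the target.  A
  fixed score pattern rather than Gaussian donor draws keeps the planted
  correlation at its nominal strength; with four Gaussian draws a
  substantial fraction of pairs would realize too little donor spread to be
  detectable at any implementation quality, which would make recovery rates
  a test of luck rather than of the pipeline.
- **Missingness** is off by default; when configured, MNAR masking is
  logistic in the log2 value (low abundance → more missing, the mass-spec
  regime the detection filters address) with optional MCAR on top, and a
  configuration expected to mask over half the matrix is rejected.

What the generator does **not** emulate: heavy-tailed and count-based noise,
feature-feature correlation beyond the planted pairs, per-sample library
effects, probe cross-hybridization, batch effects that change shape rather
than location (variance or nonlinearity drifts).  Passing recovery tests
therefore shows the pipeline is correct under the log-additive model it
targets, not that real data meet that model.

## Numerical choices and degenerate inputs

- Imputation: iterative SVD completion, feature-mean start, rank 2 by
  default, convergence when the largest change on a missing cell is below
  1e-6 (500 iterations max, warning + best iterate on non-convergence).
  `n_components="auto"` picks the rank (1–5) by masking 10% of observed
  cells.  Completion needs the rank to be below what makes the
  reconstruction the identity map (e.g. rank 1 for a 3×3 matrix).
- Detection: "detected" means non-missing after upstream flooring; the rule
  is strictly-greater-than the detection rate; methylation defaults to the
  strict drop-any-missing rule.
- Welch test with zero variance in both groups: p undefined → degenerate
  flag, never a DEF.  Pearson with a constant vector: (nan, nan) →
  category "none".
- Bandwidths in the affinity kernel are floored at 1e-12 when a sample's
  neighborhood is entirely duplicates.
- All simulation randomness flows from a single integer seed through one
  `numpy` Generator; identical configurations are bit-reproducible.

## Problem sizes

Tests and the acceptance script run the simulations at a few hundred
features per layer, 1–6 batches, and 20–50 seeds per stochastic claim —
sizes at which every claimed effect is unambiguous (the ratio-vs-absolute
SNR gap is ~27 dB) while the full suite completes in seconds.
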