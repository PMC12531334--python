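# Methods

## Overview

`lesionrx` implements a semi-synthetic counterfactual simulation framework
for stroke prescriptive inference. Because the package's claims are about
*inference machinery* — which representation/learner combinations recover
planted treatment-response heterogeneity under which allocation and noise
regimes — every input that a full-scale study would take from empirical
sources is generated synthetically with known structure, so recovery can be
verified exactly. This note records the model, the defaults and why they
were chosen, the numerical conventions, and what the synthetic conditions
do and do not show about real data.

## The synthetic world

All volumes share one `GridSpec`; the default grid is 24×24×24 voxels
(16×24³ for the fastest tests), chosen so that a full virtual trial runs in
seconds on one core while leaving each functional network ≥ ~1000 grey
voxels — large enough for the 5 % overlap rule to be a meaningful
designation and for subdivision into two nonempty subterritories.

- **Grey matter** is an axis-aligned ellipsoid with semi-axes 0.42 of each
  grid dimension (~31 % fill), a single connected mask analogous to a
  thresholded tissue-probability map.
- **Planted networks** grow simultaneously from random seed voxels by
  repeated 6-connected dilation, giving a contiguous Voronoi-like partition
  of grey matter. Contiguity matters: the observable-confounding policy and
  the transcriptome subdivision both rely on spatial structure.
- **Vascular atlases** are geometric: anterior/posterior × hemisphere
  (4 coarse labels), 3 slabs × 2 hemispheres (6 fine labels), plus a
  2-label anterior/posterior atlas (hemispheres collapsed) used as the
  conventional low-expressivity trial baseline.
- **Term–voxel association maps** score term t at voxel v as
  `effect·1[network(t) = network(v)] + N(0, noise_sd)`. At zero noise the
  hierarchical clustering must recover the planted partition exactly; this
  is the oracle for the parcellation path.
- **Receptor maps** are Gaussian-smoothed white-noise fields standardized
  to zero mean / unit variance on grey matter. Standardization makes the
  parameter-free z > 0 binarization meaningful when ranking receptor
  preponderance.
- **Transcriptome samples** are drawn within each network, with a planted
  two-way split along the network's widest axis; the two sides carry
  opposite-signed copies of a random gene pattern of magnitude
  `split_effect` (default 5) on unit noise. The pattern (rather than a
  constant shift) is anti-correlated between sides, so correlation-distance
  clustering can recover it; at `split_effect = 0` recovery is at chance.
- **Lesions** grow by stochastic 6-connected region growing inside grey
  matter from seeds drawn uniformly (or from a supplied frequency map),
  with sizes uniform on 20–400 voxels — roughly 0.4–9 % of grey matter,
  mimicking the heavy spread of real infarct volumes from lacunes to large
  territory strokes. One lesion per synthetic patient; the repeat-image
  rule for real cohorts is an ingestion concern handled by the harness.
- **Surrogate tracts** are jittered voxel walks between random grey
  endpoints, shared across subjects up to per-subject endpoint jitter.
  They are not diffusion tractography and make no anatomical claim; only
  the output contract matters — a disconnectome in [0,1] equal to the
  fraction of reference subjects with a bundle through the lesion. By
  convention lesion-core voxels are set to 1 (switchable), which keeps
  designation monotone between the lesion and disconnectome
  representations.

## Parcellation and subdivision

Voxels are clustered agglomeratively on their term-association profiles
with **correlation distance and average linkage** (configurable): the
natural choice when similarity of functional association profiles, not
magnitude, defines a network. Undersized connected components
(< 64 voxels at 26-connectivity, both configurable) are dissolved by a
5-nearest-neighbour majority vote whose donor set excludes all undersized
voxels — islands cannot relabel each other. Term rankings use the mean
in-network association score (cosine available).

Receptome subdivision ranks receptors by Dice between the network mask and
each z-map binarized at z > 0, selects the top two, and assigns each voxel
to the one with the greater local z (ties to the top-ranked). Transcriptome
subdivision clusters in-network samples two ways (correlation/average),
smooths each cluster's site indicator with an isotropic Gaussian, assigns
voxels by argmax, and picks the kernel sd from a grid by minimizing

J(σ) = |n_A − n_B| / (n_A + n_B) + λ·(components_A + components_B − 2),
λ = 0.05.

The balance/compactness trade-off is stated in the design as a bi-objective
without a formula; J is this package's explicit surrogate, with λ small
enough that balance dominates unless a σ fragments a side.

## Ground truth and outcomes

Designation uses strict inequalities at both thresholds: responsiveness
requires overlap strictly above 5 % of a subterritory's volume, and
probabilistic disconnectomes binarize at strictly above 0.5. Boundary
behaviour is unit-tested.

The default outcome model is the **branch** semantics: Y ~ Bernoulli(TE)
if the allocated arm is individually suitable (w = w*, or the patient is a
dual responder), else Bernoulli(RE). This matches TE = P(Y=1 | W=w*)
literally and makes TE=1, RE=0 exactly deterministic. An alternative
OR-composition (an "immune" draw at RE combined with a responder draw at
TE) is available via `semantics="or"`. The default true effect is
effect-scaled, τ = s·(TE − RE), under which a consistent probabilistic
model attains PEHE → 0; τ = s is available via `tau_mode="sign"`.

## Allocation policies

Observable confounding sorts patients by lesion centroid along the axis
that maximally separates the two subterritory centroids and assigns
P(W=B) from an evenly spaced ramp: [0.5−b, 0.5+b] for b ≤ 0.5. Beyond 0.5
the design statement — deterministic extremes relative to the training-set
median — fixes no fraction; this package allocates a per-tail fraction
f = b − 0.5 of ranked patients deterministically (below the training
median → A, at/above → B) with the interior ramp spanning [0,1]. The rule
is continuous in b at 0.5 and fully deterministic at b = 1. The training
median is computed on the training fold and applied to both folds;
allocation is generated per CV iteration. Sorting ties break by patient id.

Unobservable confounding draws W = w* with probability b_unobs for single
responders; dual responders, for whom w* is undefined, get a fair coin.

## Meta-learners

S-learners append the treatment indicator δ (A = 1) to the features of a
single outcome classifier; T-learners fit one classifier per arm. Base
learners use library defaults with seeds threaded to every stochastic
algorithm; "gradient-boosted trees" names the algorithm rather than any
product. Gaussian-process fits are subsampled (seeded) to 2000
observations. Exact prescription ties go to arm A for reproducibility.
Degenerate training data — an empty arm, or a single outcome class overall
(S) or within an arm (T) — is detected by `check_fittable` and the cell is
marked degenerate rather than scored, mirroring the unfittable cells of a
full-scale grid.

## Evaluation

Folds are a random patient-level partition fixed before any model or
embedder is fitted; embedders see only training-fold volumes (the leakage
guard is structural — validation volumes are never passed to `fit`).
Balanced accuracy averages the two single-responder classes' correct
fractions and is *missing* (not zero) when a validation fold lacks a
class; degenerate folds are excluded from fold-averages with their count
retained. PEHE includes dual responders, penalizing models that infer
superiority between equivalent treatments. Group comparisons use the
pooled-variance Student t-test (configurable to Welch) with Cohen's d on
the pooled SD and Benjamini–Hochberg step-up flags at FDR 0.05.

Per-cell seeds derive from the master seed by CRC-32 of the
(condition key, fold, stage) tokens, so any grid cell is replayable in
isolation from the manifest alone.

## Problem sizes

The package's reference experiments run at desk scale by design:

- **Headline contrast**: 24³ world, 4 networks, receptome subdivision of
  the first network, 400 patients per cohort, TE=0.9 / RE=0.1, T-learner
  extremely randomized trees, 10 folds, 5 independent master seeds
  (~150–250 included responders per cohort). Expressive arm: 10-d PCA of
  lesion volumes at b_obs=0.8; baseline arm: 2-territory coding at b=0.
- **Null calibration**: 50 replicates of 200-patient cohorts at TE=RE=0.5.
- **CATE recovery**: 2000 patients with oracle features (r_A, r_B).

The full-scale accounting (22,528 conditions × 460 configurations ×
10 folds) is reported by product arithmetic via `report --full-scale`;
the level counts (16 networks × 2 criteria × 2 representations × 4 TE ×
4 RE × 11 confounding levels × 2 observability regimes) are a
reconstruction that reproduces the published totals, since the individual
level counts are not printed anywhere.

## What passing tests do and do not show

The synthetic world preserves the *structural* features the inference
problem depends on — contiguous networks, anatomically coherent
subterritories, lesions of heterogeneous size whose location carries
treatment-response information, disconnectomes that extend lesions along
shared bundles — but not realistic neuroanatomy, lesion morphology, or
registration error. Passing the headline contrast shows the machinery
ranks representation expressivity against allocation confounding the way
the model predicts; it does not by itself validate the magnitude of that
advantage on real lesion cohorts, which depends on real anatomy and much
larger grids. AE/VAE embedders, full 91×109×91 grids, and real
NeuroQuery/Allen/PET ingestion are deliberately out of the desk-scale
loop; PCA/NMF are the always-on embedding methods.

## Known limitations

- Lesions are confined to the grey-matter mask; white-matter-only lesions
  enter the framework solely through the disconnectome representation.
- Surrogate tracts share one bundle skeleton across subjects (jittered),
  so disconnectome values are more correlated across subjects than real
  tractography would produce.
- The transcriptome subdivision's σ objective is a surrogate for an
  unstated bi-objective; λ is configurable.
- Balanced-accuracy bands in the stochastic tests use empirical standard
  errors across replicates, not exact null distributions.
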