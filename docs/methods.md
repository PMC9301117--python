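# Methods

This note documents the models, conventions, defaults, and numerical
choices behind `gliorad`, and what the synthetic phantoms do and do not
establish about real data.

## Data model and label conventions

All volumes are 3D integer label grids with voxel spacing in mm.
Tumor maps use the BraTS label convention: 0 background, 1
non-enhancing core (NEC), 2 peritumoral edema (PTE), 4 enhancing core
(ENC). The overlapping hierarchy is derived by union — whole tumor
WT = {1,2,4}, tumor core TC = {1,4}, enhancing tumor EC = {4} — and
inverted by set subtraction. Overlapping inputs that violate
EC ⊆ TC ⊆ WT are repaired by intersecting down the chain (with a
warning), the same hierarchy-imposing step cascaded segmentation
networks apply to their own outputs.

Only voxel spacing is honoured from NIfTI headers; affine orientation
is read but ignored (logged). All supported data — synthetic phantoms
and BraTS-style volumes resampled to 1 mm isotropic — is axis-aligned,
so orientation handling would add complexity without changing any
result computed here. Coordinates are 0-based voxel indices times
spacing.

OS classes: short < 10 months, medium 10–15 months, long > 15 months,
with one month = 365.25/12 days and the boundary values (10 and 15
months exactly) assigned to medium.

## Synthetic cohort generator

The generator emulates the inputs of a BraTS-style OS study as label
maps only (no MRI intensities are simulated — the feature set is
purely shape/spatial, so none are needed).

**Phantom.** The brain is a discrete ellipsoid with semi-axes
(0.42, 0.39, 0.36) of the grid shape. The "atlas" is a weighted
Voronoi partition of the brain around 21 seed points; the first 6
seeds get 2.5× reach so a handful of regions dominate in volume, the
way cerebral cortex, white matter, and ventricles dominate a real
subcortical parcellation. One parcellation is shared by all subjects
of a cohort — it plays the role of an atlas registered into subject
space, so region identities must be comparable across subjects
(registration itself is out of scope; the atlas arrives already in
subject space).

**Tumor.** Nested spheres — NEC ball inside an ENC shell inside a PTE
shell — intersected with the brain, with a smooth random radial
perturbation (0.75 voxels) shared by the three surfaces. Per subject,
the outer radius is drawn uniformly from 11–22 % of the grid edge and
the inner radii as fixed fractions with jitter; the center is drawn
from a shrunken ellipsoid so the bulk of the tumor stays in-brain.
Spheres were chosen over lesion-realistic shapes deliberately: they
admit closed-form volume checks (voxel counts match 4/3·πr³ shells
within 15 %) and keep generation fast. One tumor per subject;
multifocal disease is not modelled.

**Outcome.** A cumulative-logit ordinal model on standardized
(log-volume, centroid distance, age): η = β_v·z(log V) + β_d·z(d) +
β_a·z(age), with cutpoints logit(1/3) and logit(2/3) so that all-zero
betas give a uniform class marginal. Positive η pushes toward long
survival; the defaults β = (−2.0, −0.5, −1.0) encode that larger,
more eccentric tumors in older patients shorten survival, with volume
the dominant effect. Standardization constants are derived in closed
form from the tumor-sampling design of the phantom grid (so the class
marginal stays balanced on any grid size); age is Normal(62, 12)
clipped to [18, 90], matching the demographics of public glioma
cohorts. Survival days are drawn uniformly from the emitted class's
day range (12–304 / 305–456 / 457–1767 days), so days always classify
back to the class.

**Segmentation schemes.** Each scheme is a corruption profile applied
to the ground truth: (1) each of the WT/TC/EC surfaces is displaced by
an independent smooth Gaussian random field (white noise smoothed at
2 voxels, unit-normalized, scaled by `boundary_sigma` in mm) added to
the signed Euclidean distance transform, after which the hierarchy is
re-imposed; (2) boundary voxels of the label map swap to a random
6-neighbour label with probability `flip_rate`; (3) small connected
ENC components are "missed" (relabelled NEC) with probability
`dropout_rate`. Six default profiles ship, with boundary sigmas
1.25–1.55 mm chosen so each profile's cohort-mean whole-tumor Dice
falls in 0.88–0.93 — the operating range of published segmentation
CNNs on this task. The corresponding HD-95 values (≈1.7–2.4 mm) sit
below the 4–7 mm such networks report on real data: smooth spheres
have no thin structures or distant false-positive islands, so a Dice
match cannot simultaneously be an HD match. Exact profile parameters
are configuration, not claims. The pipeline uses the first five
profiles as CNN stand-ins and derives the sixth scheme by STAPLE
fusion, mirroring the five-CNNs-plus-consensus design.

**What passing on phantoms shows.** That the implementation is correct
(metrics match brute-force oracles, EM is monotone, planted effects
are recovered at study scale and absent under the null) — not that
any particular AUC level transfers to real MRI, where feature/outcome
links, tumor morphology, and segmentation-failure modes are all
richer.

## Segmentation evaluation

**Dice** is 2|A∩B|/(|A|+|B|), with both-empty defined as 1.

**HD-95** follows the BraTS-community convention: surfaces are mask
voxels with at least one 6-connected background neighbour (the volume
border counts as background); the directed distance set from A to B
holds, for each surface voxel of A, the Euclidean distance in mm to
the nearest surface voxel of B; HD-95 is the max of the two directed
95th percentiles (linear-interpolation percentile). Exactly one empty
mask makes the metric undefined — the metric raises, and pipeline
callers substitute the grid diagonal in mm as a deterministic,
bounded, logged penalty. Both empty gives 0. The implementation
queries a KD-tree of surface-voxel coordinates, which computes the
same nearest-surface-voxel distances as a distance-transform lookup;
it is verified against an O(n²) all-pairs oracle to 1e-9 on random
blob pairs.

**FRS.** For every subject and each of the six metrics (Dice and
HD-95 for WT/TC/EC), schemes receive fractional competition ranks
(Dice descending, HD ascending; ties share the mean rank); ranks are
averaged over metrics, then subjects, and normalized by the number of
schemes so scores are comparable across experiments. Lower is better;
1-based ordinal positions are also emitted, which is the form usually
printed. The rank-average definition is stated openly; agreement with
other FRS variants is ordinal, not numeric.

**Permutation test.** Paired, two-sided sign-flip test on per-subject
mean ranks: each permutation swaps a subject's A/B pair with
probability ½; p = (1 + #{|mean diff| ≥ observed}) / (1 + n_perm).
The +1 smoothing keeps p ≥ 1/(1+n_perm) and the type-I error at
α = 0.05 calibrated (verified at 0.03–0.07 over 1000 null
replicates).

## STAPLE fusion

Full multi-category STAPLE over the 4-symbol alphabet (0, 1, 2, 4) —
one EM for the complete label map rather than per-structure binary
runs, because entire label maps are being fused. E-step:
W_i(s) ∝ prior(s)·Π_j θ_j[s, d_ij]; M-step:
θ_j[s,s′] = Σ_i W_i(s)·1[d_ij = s′] / Σ_i W_i(s). Initialization:
θ diagonals 0.95, off-diagonals uniform; prior = label frequencies of
the voxel-wise majority vote with 1e-6 smoothing. The prior is static
(not re-estimated) for stability on a small alphabet. Convergence:
mean absolute θ change < 1e-6 or 100 iterations; the log-likelihood
trace is checked non-decreasing to 1e-8. Fused label = argmax of W,
ties broken by higher prior frequency then lower numeric label.
Computation is restricted to the union bounding box of nonzero voxels
dilated by 3 voxels, with everything outside fused as unanimous
background — an explicit, logged approximation that changes only the
background-row counts of θ, not the fused map.

## Anatomy-guided partitioning

Tumor-affected volume per atlas region is |WT ∩ region| × voxel
volume; regions are ranked by volume descending (ties to the lower
region id) and the top-K prefix retained, K being the smallest prefix
whose cumulative coverage of |WT| strictly exceeds 85 %. If the atlas
covers less than 85 % of WT, all affected regions are returned with a
logged flag.

Top-K selection exists in two forms: per subject (the literal
procedure) and cohort-level (regions ranked by mean tumor-affected
volume, the coverage rule applied to mean coverage). The *feature*
models need a fixed region list — a per-subject K would change the
feature-vector length — so the 6-subregions model uses a fixed
cohort-level set: the named six structures when a Harvard-Oxford-style
atlas is in play, or the cohort-level top-6 on synthetic atlases.
Features for the anatomical models are computed on WT ∩ region (the
tumor-affected portion), not the whole structure — consistent with
ranking regions by tumor-affected volume — and the choice is
switchable in code.

## Features

Per region: volume (voxel count × voxel volume) and surface area by
exposed-face counting — each mask-voxel face adjacent to background or
the volume border contributes its face area from the spacing. The
face-count estimator is bit-exact, translation invariant, and testable
combinatorially (a solid n-cube gives exactly 6n²); it over-estimates
smooth surfaces relative to mesh-based estimators, a constant-style
bias that cancels in the relative comparisons these models make.
Spatial features: unweighted centroid of WT minus centroid of the
brain mask, in mm, plus the Euclidean norm. Age in years completes the
vector. Empty regions contribute zeros, never missing values, so
vectors are always exactly 7 / 11 / 17 / 47 long.

## Classifier, metrics, stability

Features are z-scored with training-cohort statistics (constant
features map to 0); test cohorts always use the training stats. The
ensemble is N random forests trained on identical data differing only
in RNG stream (member i seeded master+i) — no resampling — with
n_estimators = 200, max_features = "sqrt" (the classification meaning
of the historical "auto"), class_weight = "balanced", Gini. Soft
voting averages member probability vectors uniformly; argmax ties go
to the earlier class in (short, medium, long).

Evaluation: one-vs-rest AUC and AUPRC per class from that class's
probability column; headline values are support-weighted means over
the classes present (a class absent from the truth is flagged
undefined and excluded, logged); accuracy in percent. Overfitting is
monitored by 200× repeated stratified 70/30 splits of the training
cohort, re-fitting normalization and ensemble inside each split.

RSD = 100 × population (1/n) standard deviation / mean of the AUCs
across schemes. Published RSD values in this literature typically come
from unrounded AUCs and fall between the population and sample
conventions applied to rounded table cells; the population convention
is fixed here and stated.

## Failure analysis

For each radiomic model, each subject's misclassification count over
the six schemes is tallied, with bins for "all six", "≥ 5", and the
majority rule "≥ 4 of 6" that defines the model's misclassified set
(a single set per model is what Venn intersections need; ≥ 4 is the
weakest published bin). Pairwise and higher intersections of the
majority sets are reported. The HD-stratified summary averages
HD-95(WT) over schemes per subject and contrasts majority-correct vs
majority-misclassified groups (union over models); empty groups are
flagged, not imputed.

In the synthetic pipeline the boundary corruptions barely move the
volume feature, so misclassification is classifier noise and the HD
contrast between groups is near zero — the directional claim
(misclassified subjects carry larger segmentation errors) is therefore
established by a dedicated injection experiment: per-subject HD values
with misclassification probability increasing in HD, checked by a
sign test over 20 replicates.

## Problem sizes and determinism

Library defaults match the study design (N = 100 forests × 200 trees;
200 split repeats; 85 % coverage; 118/31 cohorts on 64³ 1 mm grids).
The pipeline driver and the acceptance script run a scaled ensemble
(N = 25 × 100 trees — soft-voting forests differing only by RNG are
statistically close to one larger forest) and average the null-model
check over three independent replicates to tame the variance of a
31-subject test cohort; the informative/null recovery bands
(AUC > 0.65 vs 0.4–0.6) are comfortably met at these sizes. Every
source of randomness flows from one master seed via
`numpy.random.SeedSequence` spawning; reruns are bit-identical, and
report bundles carry a checksummed manifest.

## Known limitations

- Phantom tumors are smooth nested spheres: HD-95 magnitudes and
  segmentation-failure modes are milder than on real lesions, and no
  intensity or texture features can be defined.
- The synthetic atlas is a weighted Voronoi partition, not anatomy;
  region identities are meaningful only within a cohort.
- Fusion is hard-label STAPLE; probabilistic inputs and spatially
  varying rater performance are out of scope.
- No feature selection or synthetic oversampling is performed, by
  design of the study being modelled.
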