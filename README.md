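# gliorad

Multiregional shape/spatial radiomics for overall-survival (OS)
classification in brain glioma, with quantification of how robust the
predictions are to the choice of automatic tumor-segmentation method.

## The problem

Radiomic OS models for glioma are trained on features extracted from a
segmentation of the tumor — and that segmentation comes from one of
many competing automatic methods. Two questions follow:

1. **Which tumor partition yields the most predictive features?**
   Four candidates are compared: the whole tumor alone (*WT* model,
   7 features), the physiologic partition into peritumoral edema,
   non-enhancing core, and enhancing core (*3-subregions* model,
   11 features), and anatomy-guided partitions of the whole tumor by a
   21-region subcortical atlas — either the top-6 tumor-affected
   anatomical regions (*6-subregions* model, 17 features) or all 21
   (*21-subregions* model, 47 features). Each model's vector is
   per-region volume (mm³) and surface area (mm²), plus the whole-tumor
   centroid offset from the brain centroid (dx, dy, dz, ‖·‖ in mm) and
   age in years.
2. **How stable are the predictions across segmentation methods?**
   Features are re-extracted from six "segmentation schemes" (five
   CNN-like methods plus their STAPLE consensus), the classifier is
   re-evaluated under each, and stability is summarized as the relative
   standard deviation RSD = 100·σ/μ of the AUC across schemes.

The classifier is an ensemble of N = 100 random forests (200 trees,
√p feature subsampling, balanced class weights, Gini) trained on
z-scored features and combined by uniform soft voting; OS classes are
short (< 10 months), medium (10–15), and long (> 15). Segmentation
quality is measured by the Dice coefficient and the 95th-percentile
symmetric Hausdorff surface distance (HD-95), schemes are ordered by a
rank-aggregation Final Ranking Score (FRS) with sign-flip permutation
tests, and multi-scheme consensus maps are produced by a multi-label
STAPLE expectation–maximization.

Because the BraTS-style MRI data such studies run on cannot ship with a
package, `gliorad` includes a first-class synthetic-cohort generator:
ellipsoidal brain phantoms with a weighted-Voronoi "atlas", nested
spherical tumors, an ordinal-logit survival model driven by tumor
volume/location/age, and calibrated label-corruption profiles that
stand in for the segmentation CNNs. Every pipeline stage is exercised
and tested end to end on these phantoms; real BraTS label maps (NIfTI)
drop in through the same interfaces.

## Worked example

Simulate ten test subjects, corrupt their ground-truth labels with the
five CNN stand-in profiles, add the STAPLE consensus as a sixth scheme,
and rank all six:

```python
from gliorad import (
    CohortRole, generate_cohort, evaluate_scheme, quality_table,
    scheme_summary, frs_rank, RaterSet, staple_fuse,
)
from gliorad.synthetic_cohort import DEFAULT_SCHEME_PROFILES, PhantomSpec

bundle = generate_cohort(
    10, CohortRole.TESTING_A, master_seed=42,
    scheme_profiles=DEFAULT_SCHEME_PROFILES[:5],
    spec=PhantomSpec(grid_shape=(64, 64, 64)),
)
for sb in bundle:
    sb.predictions["staple"] = staple_fuse(
        RaterSet(maps=list(sb.predictions.values()))
    ).fused

qualities = [
    evaluate_scheme(sb.truth, pred, sb.record.subject_id, scheme)
    for sb in bundle
    for scheme, pred in sb.predictions.items()
]
table = quality_table(qualities)
print(scheme_summary(table)[["dsc_wt", "hd_wt"]].round(3))
ranking = frs_rank(table, n_perm=2000, seed=0)
print("FRS ordinal positions:", ranking.ordinal)
print("p (staple vs cnn2d_a): %.4f" % ranking.pairwise_p.loc["staple", "cnn2d_a"])
```

prints

```
          dsc_wt  hd_wt
scheme
cnn25d_b   0.887  2.341
cnn2d_a    0.895  2.314
cnn3d_c    0.925  1.736
cnn3d_d    0.908  2.136
cnn3d_e    0.916  1.950
staple     0.977  1.041
FRS ordinal positions: {'staple': 1, 'cnn3d_c': 2, 'cnn3d_e': 3, 'cnn3d_d': 4, 'cnn25d_b': 5, 'cnn2d_a': 6}
p (staple vs cnn2d_a): 0.0010
```

Reading: the five corruption profiles span whole-tumor Dice 0.89–0.93
(the operating range of modern segmentation CNNs), the STAPLE consensus
beats every individual scheme on both Dice and HD-95 and takes FRS
rank 1, and its advantage over the weakest scheme is significant at the
permutation-test floor (p = 0.001 at 2000 permutations).

The whole experiment — simulation, per-scheme evaluation, fusion,
partitioning, feature extraction, ensemble training, stability and
failure reports — runs as one call (`gliorad.run_pipeline(RunConfig(...))`)
or from the shell:

```bash
gliorad run --seed 2 --n-train 30 --n-test 12 --grid 48 --outdir out/
```

which writes `segmentation_metrics.csv`, `report.json`, a Markdown
summary, and a checksummed manifest. Individual stages are exposed as
`gliorad simulate | seg-eval | fuse | partition | extract-features |
train | predict | evaluate`.

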