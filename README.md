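# tunel3d

Objective quantification of apoptosis in preimplantation embryos from
two-channel 3D confocal z-stacks, with the mixed-effect statistics used in
embryo-toxicology studies.

Blastocysts stained with DAPI (all nuclei) and a TUNEL assay (nuclei with
fragmented DNA, the hallmark of late apoptosis) are imaged as z-stacks with
2 µm optical sections. `tunel3d` segments both channels, counts nuclei and
apoptotic nuclei per embryo, and fits treatment-effect models for
developmental endpoints and apoptosis — the whole chain exercisable without
any microscope through a bundled ground-truthed synthetic-stack generator.

**Who it is for:** image-analysis and reproductive-biology groups who need
per-embryo cell counts and TUNEL-positive proportions from confocal stacks,
plus the replicate-aware statistics that go with a multi-replicate in-vitro
embryo-production experiment.

## The methods at the core

* **TUNEL channel — iterative 3D per-object ellipsoid-fit thresholding
  (POE).** On the max-tree (component tree of upper level sets), each object
  gets its own threshold: the largest component whose smallest/largest
  equivalent axis diameters (d = 4√λ from the second-moment eigenvalues λ)
  satisfy the bounds and whose Jaccard overlap with its equal-moment digitized
  ellipsoid is within tolerance of the best on its branch. Because a dim
  nucleus touching a brighter one is invisible to any single threshold, the
  loop keeps eroded objects as seeds, blacks segmented voxels out and
  re-segments until nothing new appears, then splits the combined mask by a
  seeded watershed on the negated Euclidean distance transform.
* **DAPI channel — SizeIntervalPrecision (SIP) global thresholding.** The
  global grey level is chosen by sweeping every candidate level and scoring
  the components of `{I ≥ T}` against a nucleus-sized volume interval
  (objective: the fraction of foreground voxels in size-conforming
  components, computed incrementally on the max-tree), followed by a
  watershed split seeded at regional maxima of the distance map.
* **Apoptosis calling.** An apoptotic nucleus lies inside the blastocyst
  area (convex hull of nuclei, dilated) and is co-labelled: a TUNEL object
  flags the nucleus it dominantly overlaps; TUNEL signal without DAPI
  beneath is discarded. Dead/degenerating embryos (quality grade 4) are
  excluded before analysis.
* **Statistics.** Mixed-effect logistic regression for binomial
  developmental endpoints (group size as binomial weights, replicate random
  intercept, day-5/6 blastocyst outcomes as repeated measures; estimates
  match `lme4::glmer` with adaptive quadrature), cumulative-link mixed
  models for ordinal stage/grade, and linear mixed models for log cell
  counts and the nucleus-count-adjusted apoptotic proportion. OR < 1 means
  a negative treatment effect; p < 0.05 is significant, 0.05 ≤ p < 0.1 a
  tendency.

## Worked example

```bash
python examples/simulate_and_segment.py
```

prints (seed 3, default study-like conditions):

```
stack shape (z, y, x): (44, 174, 174), voxel size (2.0, 0.5, 0.5) µm
truth: 36 nuclei, 4 apoptotic
segmented: 36 nuclei, 4 apoptotic (TUNEL objects found: 4 in 2 iterations)
apoptotic proportion: 0.111 (truth 0.111)
```

All 36 nuclei and all 4 apoptotic nuclei of the simulated blastocyst are
recovered, so the per-embryo apoptotic proportion — the outcome variable of
the treatment models — matches the ground truth exactly here; across many
stacks the mean absolute error of this proportion stays within a few
hundredths. The other examples show the touching bright/dim rescue
(`touching_nuclei_rescue.py`: a single POE pass finds 1 object, the
iterative loop finds both), the model-fitting layer
(`developmental_models.py`: a simulated day-6 odds ratio of 1.6 is estimated
at 1.57 and labelled significant), and the directory-level pipeline
(`full_pipeline_directory.py`).

A thin CLI wraps the same library functions:

```bash
tunel3d simulate --out stacks/ --n-stacks 5
tunel3d segment stacks/embryo_000.tif --channel DAPI --out out/e0
tunel3d metrics stacks/ --config config.yaml --out results/
tunel3d stats --metrics-csv results/metrics.csv --out report.csv
tunel3d validate            # built-in brute-force oracle checks
```

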