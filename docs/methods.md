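# Methods

`tunel3d` quantifies apoptosis in preimplantation embryos from two-channel
confocal z-stacks (DAPI marks all nuclei; TUNEL marks nuclei with fragmented
DNA) and models treatment effects on development and apoptosis with mixed
models. This note records the models and procedures implemented, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Coordinate and unit conventions

Arrays are `(z, y, x)`, 0-based. All sizes are physical (µm, µm³) and are
converted to voxels with the stack's voxel size, which is anisotropic: the
default z spacing is 2.0 µm (the optical section thickness used for this kind
of imaging), the default lateral size 0.31 µm for real stacks read from disk.
The synthetic generator uses 0.5 µm laterally; neither the lateral pixel size
of the original acquisitions nor their intensity calibration is known, so both
are documented assumptions, not measurements.

## TUNEL segmentation: per-object ellipsoid-fit thresholding (POE)

Apoptotic nuclei are bright, roughly ellipsoidal blobs whose brightness varies
object to object, so a single global threshold cannot be right for all of
them. POE gives each object its own threshold: among the nested connected
components of the upper level sets `{I >= T}` (the max-tree), it selects
components that (a) satisfy diameter criteria and (b) look most like solid
ellipsoids.

**Fit score.** For a candidate voxel set R, the score is the Jaccard overlap
`|R ∩ E| / |R ∪ E|` with the digitized solid ellipsoid E having R's centroid
and second central moments (for a solid ellipsoid the covariance eigenvalues
are `a_i²/5`, so E's semi-axes are `sqrt(5 λ_i)`). The score is 1 for a
perfectly ellipsoidal region; a single voxel scores 1 by convention; moment
eigenvalues are floored at the variance of one voxel so flat regions digitize
to something non-empty. Reported equivalent axis diameters use the
`d_i = 4 sqrt(λ_i)` convention; note this is the ellipse-moment convention, so
a solid sphere of radius a has "diameter" `4a/√5 ≈ 1.79a`, and the diameter
bounds below are calibrated in that metric.

**Diameter criteria.** A component conforms when its *smallest* equivalent
axis diameter is ≥ `min_diameter_um` (default 3.0) and its *largest* is
≤ `max_diameter_um` (default 12.0). Enforcing the minimum on the smallest
axis matters under anisotropic sampling: with 2 µm sections, two vertically
adjacent noise voxels already have a largest-axis "diameter" of 4 µm and a
perfect fit score, so a largest-axis-only minimum admits a flood of noise
doublets.

**Selection.** A conforming component with score ≥ `min_fit_score` (default
0.5) is a candidate. Descending from the root, the selected object on each
branch is the *largest* candidate whose score is within
`fit_score_tolerance` (default 0.05) of the best candidate score in its
subtree; selection blocks the subtree, so objects are pairwise disjoint, and
each object's threshold is its component's level. The tolerance is the key
numerical choice: for any blurred, radially decreasing object every upper
level set is itself nearly a perfect ellipsoid, so the exact score maximum
lands on an arbitrary interior core decided by digitization noise. Taking the
largest near-optimal candidate anchors the object at its full extent, which
both stabilises the threshold and leaves only a thin residue for the
iterative pass below. Candidate thresholds exclude the global minimum (the
background level is never an object threshold), and a flat image yields zero
objects.

The implementation computes all of this on a max-tree built by union-find
(compiled with numba), with per-node moments obtained from prefix sums over
an Euler-tour layout of the tree and 3×3 eigenvalues by the closed-form
trigonometric solution. Its defining semantics is the exhaustive sweep:
threshold at every grey level, enumerate components, apply the same
criteria — and the test suite holds the tree implementation to exact
agreement (supports and thresholds) with that brute-force oracle on random
images, plus a monotone-intensity invariance property.

**Iterative masking.** When a dim nucleus touches a brighter one there is no
global threshold that separates them: every level either merges the pair or
loses the dim object (the bundled fixture generator verifies this property by
an exhaustive sweep at generation time). The iterative variant therefore
runs POE, keeps each object eroded by `erosion_voxels` (default 2 iterations
of the 6-connected unit ball; an object that erodes away keeps its brightest
voxel) as a seed, blacks the segmented voxels out of a working copy,
re-segments, and merges new objects and seeds under fresh labels until a pass
finds nothing or `max_iterations` (default 10, with a recorded warning) is
reached. Earlier objects are never modified. Finally the combined mask is
split among the combined seeds by a seeded watershed whose flooding priority
is the negated physically-scaled Euclidean distance transform (whether the
original procedure flooded intensity or distance is not documented; distance
is the choice here). Seeds outside the mask are discarded with a warning;
a seedless non-empty mask comes back as one fresh object; seedless mask
components receive fresh labels so the output always partitions the mask.

## DAPI segmentation: size-interval thresholding (SIP) + watershed

All nuclei are similar in size, so the global threshold is chosen by how many
nucleus-sized objects it produces. For every candidate grey level T the
components of `{I >= T}` are counted against the volume interval
`[sip_min_volume_um3, sip_max_volume_um3]` (defaults 80–800 µm³), and the
precision — the fraction of foreground voxels lying in size-conforming
components — is computed. The default objective maximises precision, with
count and then lowest-T as tie-breaks; a `count` objective (most conforming
components first) is available via config. Precision is the default because
the count objective is maximised at near-background thresholds on noisy
images, where percolation produces many accidentally nucleus-sized clusters;
measured on a default synthetic stack the count optimum sat just above
background with precision 0.05, against the correct threshold's 0.95.

The sweep is computed incrementally on the max-tree (a component of
`{I >= T}` is exactly the subtree of a node whose level range contains T, so
per-level counts are range updates), which the tests pin to the naive
per-level sweep. Images with more than `sip_max_levels` (default 1024)
distinct grey values are quantile-binned, each bin represented by its lowest
original level; this is exact for 8- and 10-bit data and restricts only the
candidate set above that.

Watershed seeds are regional maxima of the mask's Euclidean distance
transform, Gaussian-smoothed by `seed_smoothing_sigma_um` (default 0.5 µm)
with maxima shallower than `seed_h_maxima_um` (default 0.3 µm) relative to
their separating saddle merged, and each maxima plateau collapsed to the
voxel nearest its centroid. Both parameters balance two failure modes:
boundary roughness splits one nucleus into two seeds (over-segmentation),
while aggressive smoothing erases the shallow maximum of a small pycnotic
nucleus pressed against a large neighbour (under-segmentation). The defaults
were chosen by scanning that trade-off on ground-truthed synthetic stacks.
After the watershed split, components smaller than `debris_floor_um3`
(default 10 µm³) are removed as debris.

## Apoptotic-nucleus calling and per-embryo metrics

An apoptotic nucleus is a nucleus inside the blastocyst area co-labelled by
DAPI and TUNEL. The blastocyst area — undefined in the source protocol — is
the 3D convex hull of all nucleus voxels dilated by one mean nucleus radius
(config: `area_dilation_radii`; the area test can be disabled). Each TUNEL
object is assigned to the nucleus sharing the most voxels with it; the
assignment is valid when the shared volume is at least
`tunel_overlap_fraction` of the TUNEL object's volume *and* the nucleus
centroid lies in the area. TUNEL signal with no nucleus underneath is
discarded with reason `no-DAPI`; weak overlaps and out-of-area assignments
are likewise recorded, never counted. Several TUNEL fragments may flag the
same nucleus; one TUNEL object flags at most one nucleus.

The default `tunel_overlap_fraction` is 0.3. The POE object extends to the
object's full blurred extent while the SIP nucleus mask is a tighter
iso-intensity region, so even a perfectly co-localised TUNEL object shares
only ~0.35–0.45 of its volume with its nucleus; 0.3 keeps the
dominant-assignment semantics without rejecting true co-localisation. The
original criterion is unknown and the parameter is config-exposed.

Per embryo, `n_nuclei` is the nucleus label count, `n_apoptotic` the flagged
count, and the apoptotic proportion their ratio (undefined, and the embryo
excluded, when no nuclei are found). Embryos graded 4 (dead or degenerating,
on the 1–4 quality scale with half grades) are excluded before analysis;
applying this filter to a 146-embryo imaged cohort with 6 such embryos
retains 140.

## Statistical models

All models use a single Gaussian random intercept per replicate (the design's
only clustering factor; no random slopes).

* **Binary developmental endpoints** (cleavage at 48 hpf, cleavage beyond
  2-cell — whose denominator is the cleaved count — and day-5/day-6
  blastocyst rates): binomial logistic regression on replicate × treatment
  counts with group size as binomial trials (the "weighted for size"
  convention; a per-oocyte Bernoulli expansion gives the identical
  likelihood, so no second code path exists) and treatment fixed effects.
  Day-5 and day-6 blastocyst outcomes can be fitted jointly as repeated
  measurements with a day indicator. The marginal likelihood integrates the
  random intercept by 25-node Gauss–Hermite quadrature and is maximised with
  L-BFGS; standard errors come from the numerically differentiated observed
  information. On a simulated table the estimates, standard errors and
  random-effect SD agree with `lme4::glmer` (adaptive quadrature, nAGQ = 25)
  to ~1e-3, which the test suite checks by calling R.
* **Ordinal stage and grade**: cumulative-link (proportional odds) logistic
  models, same random-intercept quadrature. Blastocyst stage is condensed to
  two levels before fitting: {early blastocyst, blastocyst} = 1,
  {expanding, hatching} = 2.
* **Counts and apoptosis**: linear mixed models (REML, via statsmodels
  MixedLM) on log nucleus count ~ treatment; on log(TUNEL count + 1) ~
  treatment + log nucleus count (the nucleus-count adjustment; the +1 keeps
  zero counts finite); and a secondary model of the raw apoptotic proportion
  on treatment and nucleus count, whose `n_nuclei` coefficient is the
  size–apoptosis slope on the proportion scale. Linear-mixed-model Wald
  tests use a t reference with residual degrees of freedom; the GLMMs use
  the normal reference.

Odds ratios are reported so OR < 1 means a negative treatment effect;
p < 0.05 is labelled *significant* and 0.05 ≤ p < 0.1 a *tendency*; no
multiple-testing correction is applied, matching the analysis convention the
package reproduces.

## Synthetic data: what it emulates and what it does not

`generate_stack` renders 20–60 ellipsoidal nuclei (radius 4.0 ± 0.5 µm,
random orientation and 0.85–1.15 axis jitter) on a jittered spherical shell
whose radius scales with nucleus count to keep the nuclear surface density
blastocyst-like (~20% packing; 36 nuclei give a 27 µm shell). A
`round(n × apoptotic_fraction)` subset (default fraction 0.12) is apoptotic:
shrunken by `pycnotic_shrink_factor` (0.65), brighter in DAPI (210 vs 150)
and co-rendered in the TUNEL channel (peak 190). Declared touching pairs are
placed in surface contact and, when apoptotic slots exist, form bright/dim
TUNEL pairs (dim factor 0.45) — the configuration the iterative POE exists
for. Channels are Gaussian-blurred (0.8 µm), offset by a uniform background
(8), Poisson-sampled and perturbed by Gaussian read noise (SD 2), then
clipped to 8 bits. Everything is deterministic per seed, and the ground
truth (pre-blur labels, flags, centroids, radii) is returned alongside.

Not emulated: a real optical PSF (only isotropic-in-µm Gaussian blur),
depth-dependent attenuation, photobleaching, intensity gradients across the
embryo, inner-cell-mass geometry (nuclei sit on one shell), hatching
morphology, or staining artefacts. Recovery results on these stacks
therefore demonstrate the *algorithmic* correctness of the pipeline under
known geometry and noise, not its accuracy on any particular microscope's
images; on real data the size intervals, diameter bounds and intensity-level
count are the parameters to revisit first.

`generate_dev_table` simulates the study design: nine replicates × three
groups of 28–40 oocytes, binomial endpoint draws with logit = baseline +
log(OR) + replicate effect (baselines at the control means: cleaved 0.38,
beyond-2-cell 0.59 of cleaved, blastocyst 0.07 day 5 / 0.15 day 6; replicate
SD 0.3 on the logit scale — a plausible between-run spread, not a reported
value), with endpoint-specific replicate effects, plus per-blastocyst ordinal
stage/grade draws from cumulative-logit models. Endpoints are drawn
independently given the replicate effect (no within-oocyte day-5/day-6
coupling), which is a simplification the repeated-measures fit does not
depend on. `generate_metrics_table` simulates per-embryo log-normal nucleus
counts (mean 35.8, log-SD 0.45) and binomial apoptotic counts whose
proportion can depend linearly on nucleus count and treatment.

## Evaluation conditions

The bundled evaluation runs (shared by the test suite and
`scripts/acceptance.py`) use: 50 random 32³ images with ≤ 16 grey levels for
the POE sweep-oracle comparison; 50 random images for SIP (alternating both
objectives); 100 random mask/seed instances for the watershed partition
invariants; 20 touching fixtures; 20 synthetic stacks with 20–60 nuclei and
apoptotic fraction 0.12 at default noise for recovery (nucleus counts within
5% on ≥ 19/20, mean absolute apoptotic-proportion error ≤ 0.03); and 500
simulated studies per statistical family for type-I error (nominal band
3–7% at α = 0.05), odds-ratio recovery at OR = 1.5 (±10%), and the sign of a
−0.0013 per-nucleus apoptosis slope (≥ 95% negative). These sizes keep a
full run in minutes on one CPU while leaving the Monte-Carlo error well
below the acceptance margins.

## Known limitations

* The ellipse-fit criterion cannot prefer any particular level of a
  noiseless, radially symmetric object (all its level sets are ellipsoids);
  the score tolerance plus realistic noise resolve this, but on very clean
  data the chosen threshold can sit anywhere within the tolerance plateau.
* SIP is a global threshold: a nucleus dimmer than the chosen level is lost
  to the nucleus count, which is intrinsic to the method rather than to this
  implementation.
* In dense stacks an occasional small nucleus deeply pressed into a larger
  neighbour still loses its seed (the residual ~1-nucleus undercount seen in
  the recovery runs), and a TUNEL object whose nucleus mask is unusually
  eroded can fall below the overlap fraction; both are the main contributors
  to the residual proportion error.
* The mixed-model p-values are Wald-type (as is conventional for this kind
  of analysis); likelihood-ratio or parametric-bootstrap tests would be
  preferable at much smaller replicate counts than nine.
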