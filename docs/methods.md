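# Methods

This note records the models, parameter choices, numerical decisions and
known limitations of `langnet`, in the order the pipeline runs.

## Network definition

The canonical 10-node ROI set (`langnet.rois.CANONICAL_ROI_SET`) is the
ICA-derived language-network module table: node name, MNI peak coordinate,
module size in 3 mm voxels, and peak T score.  Sphere ROIs use a 6 mm
physical radius; membership is "voxel position within radius of the peak",
which on a 3 mm grid gives 33 voxels for an interior sphere.  The four
lesion subsystems are LF = {lIFG, lMFG}, LT = {lSTG}, RF = {rIFG, rMFG},
RT = {rSTG}; midline (SFG, precuneus) and cerebellar nodes belong to no
subsystem and therefore can never make an edge "direct".

The default analysis path uses this shipped ROI set.  The group-ICA path
(`langnet.network`) exists for phantom-scale validation: temporal
concatenation, per-subject global variance normalization, PCA reduction,
FastICA with symmetric decorrelation.  Its component maps are standardized
ICA weights (zero mean, unit variance over masked voxels), and the
cluster-forming thresholds — 5.0 cerebral, 3.0 cerebellar — are interpreted
on that standardized scale.  This is a deliberate approximation: a
subject-level GLM T map would require per-subject back-reconstruction,
which is out of scope.  The cerebellar region is supplied as an explicit
mask argument; there is no anatomical lookup.

## Preprocessing

`preprocess_timeseries` implements only the numerically simple steps:
per-node linear detrend, least-squares confound regression (intercept
always included), and a 4th-order Butterworth 0.01–0.08 Hz band-pass
applied forward-backward (zero phase).  Band edges at or above Nyquist are
an error.  Motion correction, registration, and smoothing are out of
scope.  Global-signal regression is deliberately not implemented in the
default path.

## Statistical kernel

All inference is implemented from defining formulas
(`langnet.stats`), with scipy supplying only distribution functions:

* Two-sample t: Student pooled-variance by default (df = n_a + n_b − 2);
  Welch behind `equal_var=False`.  Reduction tests use the one-tailed
  "patient < control" direction; the opposite tail is not tested by
  default.
* One-way ANOVA from raw data or from published mean/SD/n summaries; the
  two agree to 1e-10 when summaries are exact, and F = t² holds for k = 2.
* Tukey HSD via the studentized-range distribution, Tukey–Kramer SE for
  unbalanced groups.  scipy evaluates that CDF by numerical integration,
  so p-values are treated as accurate to about 4 decimals.
* Pearson chi-square without continuity correction — the uncorrected
  statistic reproduces the reference cohort's printed values exactly
  (4.524 / 5.66 / 0.692); Yates' correction would not.
* Two-level mixed-design ANOVA via difference scores, testing the
  unweighted (Type-III-style) grand mean of per-group difference means
  with error df = N − k.  Exact for two within-subject levels; no
  sphericity machinery needed.
* Benjamini–Hochberg step-up FDR (reject iff adjusted p ≤ α);
  Benjamini–Yekutieli behind `method="by"`.

A reproducibility note: the reference cohort's education ANOVA recomputes
to F = 1.769 from the printed 2-decimal summaries against a printed
F = 1.776 (rounding propagation); its age ANOVA does not recompute from
the printed summaries at all (1.04 vs printed 0.84) and is therefore
excluded from validation targets.

## Synthetic cohort: what it emulates

`CohortConfig` defaults define the study conditions.

| parameter | default | rationale |
| --- | --- | --- |
| group sizes | 27/26/29/27 patients + 42 HC | reference cohort |
| time points, TR | 200, 2.0 s | a typical ~7-min resting-state EPI run |
| baseline r: within / homotopic / heterotopic | 0.45 / 0.50 / 0.25 | plausible resting-state magnitudes; homotopic > within > heterotopic |
| a_dir | 1.5e-3 z/cm³ | with mean TV 100 cm³, reproduces the reported patient ipsilesional FCw mean ≈ 0.35 from the 0.45 baseline |
| a_ind | 0.8e-3 z/cm³ | likewise reproduces contralesional FCw ≈ 0.41 |
| b_con | 0.65e-3 z/cm³ | makes the expected right-lesion lFCw–TV correlation ≈ 0.5, the reported magnitude, with reliable sign recovery |
| TV distribution | log-normal, mean 100, SD 60 cm³, truncated 10–300 | reference cohort's group means/SDs |
| noise SD | 0.2 | mild measurement noise; attenuates observed correlations by 1/(1+σ²) ≈ 0.96, which the stored ground truth accounts for |

Lesion effects act on the Fisher-z scale and are mapped back through tanh,
so correlations stay inside (−1, 1) and effects are additive on the scale
the statistics use.  If the additive construction ever breaks positive
definiteness, the matrix is repaired by eigenvalue clipping at 1e-6 and
rescaling to unit diagonal, and every repair is logged (at the default
slopes no repair is needed anywhere in the admissible volume range).

One deliberate model choice: the contralesional compensation for
right-lesion groups is centered at the mean tumor volume,
+b_con·(V − V̄) on the left core triangle, rather than an uncentered
+b_con·V.  The centered form encodes the joint empirical pattern —
right-lesion groups show *no mean difference* in lFCw against controls yet
a *positive* lFCw–TV slope.  An uncentered boost cannot produce both: any
slope large enough for a reliable correlation sign shifts the group mean
detectably.

What the generator does **not** emulate, and what passing tests therefore
do not show about real data: hemodynamic autocorrelation and
low-frequency structure (signals are white before optional band-limiting);
subject-level trait variance in connectivity beyond tumor-volume effects
(within-patient-group variance is sampling noise plus the volume slope, so
synthetic TV correlations in left-lesion groups are stronger, ≈ −0.85,
than the reported ≈ −0.5); spatial heterogeneity of lesions within a
subsystem; and any behavioral covariates.

## Phantoms and lesion mapping

Phantoms embed each node's time course as a Gaussian spatial blob
(SD 6 mm) on a 3 mm grid covering the MNI bounding box of the ROI set,
plus spatially white noise.  Tumor masks are ellipsoids (axis ratios
1.2 : 1 : 0.85) centered on the lesioned subsystem's node centroid; the
semi-axis scale is calibrated by bisection so the voxelized volume matches
the requested cm³, and signal inside the mask is attenuated (×0.2 by
default).  Tumor volume is nonzero-voxel count × voxel volume, reported in
cm³.  Subsystem assignment is by maximal parcel overlap; ties break by
overlap fraction of the parcel then lexicographically (logged), and any
mask whose top-two overlaps differ by less than 10% is flagged ambiguous
rather than silently classified.

## Group inference conventions

* FDR family: the 45 edges of one subgroup-vs-control comparison
  (per-comparison correction, as in a per-figure analysis); a pooled
  4×45 family is available via `PipelineConfig(fdr_family="pooled")` but
  is not the default.
* "Direct" requires ≥ 1 endpoint in the lesioned subsystem; the
  complementary class is edges entirely between non-neoplastic modules.
  Exhaustive enumeration gives 17/9/17/9 direct edges for LF/LT/RF/RT.
* The typology chi-square pools LFG+LTG vs RFG+RTG.
* For right-lesion groups, "ipsilesional attenuation" means the edges
  incident to the lesioned subsystem.  The broader reading (every
  right-hemisphere-incident edge) was rejected: it would make the
  right-lesion pool indirect-heavy and invert the left-vs-right typology
  contrast the model exists to express.

## Validation behaviour and a known marginality

At the default conditions, 50-replicate runs reproduce the
tumor-volume-correlation sign pattern (negative lFCw/FCb/FCg slopes for
left-lesion groups, positive lFCw slope for right-lesion groups) in
50/50 replicates, and the edge-wise procedure's realized false-discovery
rate under a global null is ≈ 0.045.

The full group-contrast pattern (FCb and FCg reduced vs controls in all
four patient groups, lFCw reduced only in left-lesion groups) reproduces
in ≈ 70–80% of replicates (40/50 on the test suite's seed set).  The
binding component is the right-temporal group's FCb/FCg contrast: with
attenuation confined to tumor-incident edges, RT's between-hemisphere
effect is a_dir·V̄/3 ≈ 0.05 z, while the Tukey error term is inflated by
the volume-slope spread of the left-lesion groups (σ ≈ slope·σ_V with
σ_V/V̄ ≈ 0.55 fixed by the cohort's volume distribution).  Sweeping the
admissible calibration space under the ipsi/contra anchors leaves that
contrast's expected t at ≈ 2.5–3.3 against a familywise critical ≈ 2.8,
so no admissible parameter choice makes the joint pattern robust.  Making
it robust would require right-lesion disruption beyond tumor-incident
edges (a side-specific slope), which the minimal three-slope model
deliberately does not include.  This is a property of the model worth
knowing, not a numerical defect.

## Numerical details

* All randomness flows through `numpy` Generators seeded from a single
  configuration seed via `SeedSequence` spawning; outputs are
  byte-identical across runs with the same configuration.
* CSV serialization uses `%.10g` floats.
* Cluster labeling uses 26-connectivity by default (6 behind a flag);
  cluster peaks break ties at the lowest linear index, with a warning.
* Degenerate inputs (zero variance with nonzero effect, zero-margin
  contingency tables, |r| ≥ 1 edges) raise typed errors naming the
  offending quantity rather than returning infinities.

## Limitations

The ICA path is validated on phantoms only and makes no claim of
equivalence with GLM-based T maps.  The mixed-design ANOVA is exact only
for two within-subject levels.  Tukey p-values are approximate beyond four
decimals.  The phantom grid is desk-scale (3 mm, ~85k voxels); it is not a
brain template, and subsystem centroids near the grid edge restrict the
largest representable tumors.
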