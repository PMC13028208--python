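# Methods

## Problem setting

Single-slice CT at the L3 vertebral level is the standard proxy for
whole-body skeletal-muscle mass.  A segmentation model trained on coarse
public annotations systematically over-includes adipose tissue and fascia
(which sit at negative HU, below the muscle band) and, for subjects scanned
with arms alongside the body, segments arm muscles that do not belong to
the trunk-muscle quantity of interest.  The package evaluates the standard
remedy — density-clustering arm exclusion plus HU-threshold refinement —
and the statistics used to validate it, on synthetic phantom cohorts.

## Phantom model

Each subject's slice is a 256×256 grid at 1.5 mm isotropic spacing
(38.4 cm field of view).  Tissue compartments are composed of ellipses:
a body outline filled with adipose tissue; a vertebral body (bone); six
trunk muscle groups — psoas major, quadratus lumborum, erector spinae,
abdominal wall (an elliptical ring), rectus abdominis and diaphragm crura —
whose union is the reference mask; non-muscle soft-tissue organs (a bowel
loop and two kidneys) adjacent to muscle; and, for arms-down subjects, two
lateral arm cylinders with a muscle core.  Geometry is schematic, not
anatomically deformable: the package validates metric and pipeline
behaviour, not anatomical realism.

Each compartment's HU values are drawn uniformly from a configurable band:
muscle [+20, +70], adipose/fascia [−120, −30], bone [+200, +1200], other
organs [+25, +65], background −1000.  The adipose/muscle gap deliberately
straddles the −60…0 HU sweep range so a data-driven threshold is
recoverable.  Muscle-compartment area scales linearly with BMI
(slope 0.02 per kg/m² around BMI 26, areas ∝ scale), and the body outline
scales with slope 0.01; both slopes may be set to zero to decouple
geometry from covariates entirely, which is how null cohorts for
calibration checks are built.  At the default muscle scale the median
reference area is ≈ 126 cm² across a cohort (realistic for a mixed-sex
oncology population).

Trunk compartments are placed so that neighbouring muscle groups lie
within 10 px of each other — the reference forms a single DBSCAN cluster —
while arm-muscle cores sit ≥ 23 px lateral of the outermost trunk muscle,
beyond clustering reach.

### Covariates

Cohorts draw age ~ N(65, 11²) years (clipped at 18), sex male with
probability 0.73, BMI ~ N(26, 5²) kg/m² (clipped to [14, 45]), and cancer
types with weights 69:56:41:23 (melanoma, lung, esophageal, head-and-neck)
— the marginals of the published validation population.  Cancer grade and
comorbidity index (1–4) use mildly peaked weights, arm-down prevalence is
0.25 and IV-contrast prevalence 0.5; these are not reported quantities and
were fixed once at plausible values.

### Simulated model-mask errors

The raw model mask is the reference plus four error mechanisms:

1. **Adipose/fascia fringe** — adipose pixels within `fringe_width`
   (default 2 px) of the reference boundary are added, and their HU
   re-painted from the fringe band (default −80…−30 HU, fascia-like).
   The slice is modified so that mask and image stay consistent for
   thresholding.
2. **Arm inclusion** — arm-muscle pixels are added when present.
3. **Non-muscle anatomy blobs** — a Poisson(1) number of ~3 px-radius
   blobs on organ tissue; organ HU overlaps the muscle band, so these
   survive thresholding, as real non-muscle inclusions do.  Blobs far from
   the trunk cluster are removed by clustering; blobs adjacent to muscle
   survive.
4. **Boundary jitter** — pixels in successive 1-px layers around the
   boundary flip with probability 0.3 (outward, over-inclusion) or 0.15
   (inward), attenuated linearly beyond the jitter width so the expected
   flipped area is continuous in the jitter parameter.  The asymmetry makes
   raw-mask errors predominantly false positives, the error pattern
   reported for models trained on coarse annotations.

Fringe width and jitter are multiplied by
`1 + bmi_coupling · (26 − BMI)/26` (floored at 0), so lower-BMI subjects
get larger errors; with the default coupling of 1 this reproduces the
direction of the published BMI association (worse DSC at low BMI,
underweight subjects worse than non-underweight).  After thresholding the
fringe is gone, so the BMI signal that survives post-processing is carried
by the jitter; this is weaker than the raw-mask signal, as in real data.

What the phantoms do **not** emulate: anatomical shape variation, partial
volume effects, scanner physics (kV, kernels, streak artifacts), PET
channels, 3-D context, and inter-rater variability of the reference
standard.  Passing tests therefore demonstrate correctness of the metrics,
post-processing and statistics — not expected model accuracy on clinical
scans.

## Post-processing

DBSCAN runs on the (row, col) coordinates of foreground pixels with
Euclidean distance in pixel units (ε = 10, min_samples = 5, the published
parameters; spacing anisotropy is ignored because the parameters are
quoted in pixels).  Standard DBSCAN semantics apply; note a cluster can
hold fewer than five pixels when border pixels are claimed by an
earlier-seeded neighbouring cluster.  "Centrally located" is defined as
minimal centroid distance to the geometric image centre, with ties broken
toward the larger cluster, then the lowest label; centroid distances are
rounded to 9 decimals before comparison so exact geometric ties behave
deterministically.  A mask with no cluster at all raises; an empty mask
*after* thresholding is legal output (area 0).

Thresholding retains pixels with HU ≥ t.  The sweep evaluates every
integer t in the closed range (default −60…0; 1 HU is the coarsest grid
consistent with integer-valued published optima), applying the full
two-step pipeline at each t — clustering is computed once per subject
since it does not depend on t — and selects the t maximising the median
DSC across subjects, breaking ties toward the value closest to 0 HU (the
most aggressive adipose exclusion among equals).

## Metrics and statistics

DSC and SSE are computed from pixel confusion counts; the identity
`SSE = (1 − DSC)·(2TP+FP+FN)·A` is asserted in tests.  Both-empty mask
pairs return DSC 1.0 with a warning (vacuous agreement; configurable);
reference-empty with non-empty prediction returns 0.  Bland–Altman
differences are prediction − reference (flippable), with the sample SD
(n − 1) and ±1.96 SD limits.  Cohort summaries use the median and
linear-interpolated 25th/75th percentiles.

GLIM underweight: BMI < 20 kg/m² below age 70, BMI < 22 kg/m² at 70 and
above; age exactly 70 is assigned the elder (more inclusive) cut-off.

The battery covers nine factors for each of DSC and SSE: Spearman (age,
BMI) with the weak/moderate/strong bands, Mann–Whitney U (sex, IV
contrast, arm position, GLIM), Kruskal–Wallis (cancer grade, CCI, cancer
type) with all six pairwise cancer-type Mann–Whitney follow-ups run
regardless of the omnibus result.  Tests are two-sided; SciPy's automatic
exact/asymptotic switching handles small groups.  Levels with fewer than
three subjects flag the row `insufficient`; constant inputs flag
`constant` with p = 1.  Raw p-values are compared to α = 0.05 with no
multiplicity correction by default (a Holm-adjusted column is available
but off by default, mirroring common practice in these studies).

Error review: subjects strictly below the interpolated 25th DSC percentile
are selected (189 subjects → 47 reviewed; 232 → 58).  False-negative
pixels are attributed to their own muscle-group label; false-positive
pixels to the muscle group of the nearest reference pixel, capped at 15 px
(beyond which they are unattributed, so remote blobs are not charged to a
muscle).  A subject is flagged *non-muscle anatomy* if any false positive
lies on organ tissue, and *ill-defined boundary* if at least half of its
error pixels are within 2 px of the reference boundary.  A muscle group
counts as "involved" in a reviewed case when it carries ≥ 5% of the error
pixels.  Fisher exact tests (two-sided) compare the prevalence of each
flag between underweight and non-underweight reviewed subjects; a table
with a zero margin is reported as p = 1 with a `degenerate` flag rather
than an error.

## Determinism and problem sizes

Every stochastic step takes an explicit seed and is bit-reproducible;
pipeline bundles are byte-identical across reruns with the same inputs,
config and seed (CSV floats at 6 significant digits, sorted JSON keys, no
timestamps).  The test suite validates clustering against a quadratic-time
textbook DBSCAN, metrics against naive per-pixel counting, and Fisher
p-values against exhaustive hypergeometric enumeration.  Cohort-scale
checks use sizes chosen to keep the suite quick on a laptop while leaving
clear statistical headroom: 20 replicate cohorts of 50 subjects for
threshold-sweep recovery, 200 subjects for direction recovery, and 200
replicates of 60-subject null cohorts for the ≈5% false-positive
calibration check; the acceptance script runs 189 subjects, the analysis
size of the motivating validation design.

## Known limitations

- The phantom's muscle HU band is disjoint from the fringe band, so the
  swept optimum is a plateau across the gap rather than a sharp interior
  peak; real scans with overlapping tissue distributions produce interior
  optima (e.g. around −29 HU).
- Single-label masks only; per-muscle model outputs are out of scope.
- 2-D only; no volumetric metrics or surface-distance metrics (Hausdorff,
  ASSD).
- Streak artifacts from arms-down positioning are modelled only as extra
  mask components, not as image corruption.
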