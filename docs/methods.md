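# Methods

## The problem

The striatum is built from two interdigitated tissue compartments, the
matrix and the striosome. They are indistinguishable on structural MRI but
receive biased afferents from different sets of brain regions, so a
diffusion-tractography experiment that seeds the striatum and lets
streamlines compete between a matrix-favoring composite target and a
striosome-favoring composite target can assign every striatal voxel a
probability of "matrix-like" connectivity. `striocomp` implements that
connectivity-based parcellation and the inference machinery built on top of
it: compartment volumetry at two probability thresholds, equal-volume
most-discriminating compartment masks, leave-one-out somatotopic zone
mapping, overlap/FA/streamline-count controls, matched-pair cohort
statistics with family-wise false-discovery control — and, at its core, a
synthetic tissue phantom that makes the whole pipeline runnable and
testable at desk scale, without access-restricted subject data.

## Parcellation model

Per voxel, with path-length-corrected streamline counts `c_m` toward the
matrix-favoring target and `c_s` toward the striosome-favoring target,

    p_matrix = c_m / (c_m + c_s),        p_striosome = 1 − p_matrix.

Voxels with `c_m + c_s = 0` carry no evidence; they are flagged undefined
and excluded from every denominator rather than imputed. Classification
uses a bias threshold of 0.55: matrix-like iff `p ≥ 0.55`, striosome-like
iff `p ≤ 0.45`, indeterminate strictly between. The verbal band
"0.45–0.55" overlaps the bias rule at its endpoints; we resolve the
endpoints into the biased classes so the three classes are disjoint and the
bias rule holds verbatim. All comparisons against these thresholds use a
1e-9 epsilon because `1 − 0.55` is not representable exactly in binary
floating point.

Volumetry is reported at thresholds 0.95 (highly biased) and 0.55 (minimum
classification), per nucleus (whole striatum, caudate, putamen), plus the
within-subject difference M−S. Histograms over the biased range
[0.55, 1.00] use 0.01-wide bins — 45 bins, left-closed/right-open except
the last bin, which is closed so that `p = 1.0` is counted. A 100-bin
full-range variant is provided for parity with common command-line
histogram tools.

## Equal-volume masks and voxel geometry

Tractography seeded from masks of unequal size is biased toward the larger
mask. Per subject and hemisphere we therefore build compartment masks of
identical voxel count: voxels qualify at `p ≥ 0.55` toward their own
compartment and are accepted in descending own-compartment probability
until 83 voxels (the configured target, corresponding to the tissue
fraction more than 1.5 SD above the mean of a normal distribution; a helper
exposes the tail-fraction arithmetic but the target is a configuration
constant). If either compartment has fewer than 83 qualifying voxels, both
masks truncate to the smaller count so `|matrix mask| = |striosome mask|`
always holds. Ties in probability break deterministically by lexicographic
voxel index.

Voxel positions are summarized as offsets, in physical millimetres, from
the centroid of the nucleus the voxel occupies (caudate or putamen, per
hemisphere), so inter-nucleus placement cannot leak into compartment
position statistics. The distance between two group-mean locations is the
Euclidean norm of the 3-vector difference of the means (not the per-axis
RMS divided by √3; the two differ by a constant factor and the norm is the
convention used here).

The synthetic anatomical frame is fixed: +x lateral, +y rostral, +z dorsal.
"More medial/rostral/ventral" is therefore a sign test on (−x, +y, −z).

## Somatotopic zones

With a roster of ten bait regions (five per class), the contribution of one
region to the matrix-like probability map is the voxelwise difference
between the full-roster group-average map and the map recomputed with the
region left out: full-minus-reduced for matrix-favoring regions,
reduced-minus-full for striosome-favoring regions. Each region's zone keeps
voxels at or above the 5th percentile of that region's positive
contributions (`zone_percentile` is config-exposed; the literal-percentile
reading is the default, and users who read the text as "top 5%" can set
95). Zones are made pairwise disjoint by assigning each surviving voxel to
the region of maximal contribution, ties broken by roster order. Zone
volumetry extracts matrix-like volume at `p ≥ 0.95` per zone per subject,
normalizes the case cohort to the control mean (control ≡ 100%), and feeds
each zone's paired t-test into test family 4.

## Cohort machinery

Pair matching is greedy and deterministic over cases sorted by age: sex is
obligatory; the admissible age gap is 12 months for cases ≤ 240 months,
24 months for 241–360, 48 months above (boundary ages fall in the younger
band); among admissible controls the matcher prefers same-study candidates,
then minimal age gap, then a race match, then subject-id order. Cross-study
borrowing is balanced by preferring donor studies that currently owe
controls. Optimal bipartite matching was considered and rejected: the
greedy hierarchy is auditable and mirrors the criterion ordering directly.

Hypothesis tests run in four pre-declared families — (1) compartment
volumetry contrasts, (2) the top five histogram bins, (3) per-bait-region
extra-striate bias, (4) per-zone matrix-like volume — each corrected
independently by the Benjamini–Hochberg step-up procedure at q = 0.05. The
reported corrected threshold is `q·k*/m` for the largest passing rank; with
zero rejections the threshold is reported as "none" rather than `q/m`.
Family membership is declared by the caller because the exact contrast
roster per family is an experimental-design choice, not an algorithmic one.
Paired two-tailed t-tests are the default; a one-tailed variant is exposed
per test for nucleus-level follow-ups.

The regression harness models matrix-like volume (`p ≥ 0.95`) on diagnosis,
study, hemisphere, striatal volume, sex and race — age is excluded because
it is collinear with striatal volume — then refits significant covariates
with pairwise interactions, and fits a separate volume-on-CSS model for the
severity sub-cohort. A constant response reports R² = 0 (statsmodels
returns −inf for zero total variance; we clamp it). Rank deficiency is
flagged in the report, never silently dropped.

## The tissue phantom

The striosome is modeled as a branched, labyrinthine network of tubules
with coronal-plane diameters of 0.5–1.25 mm, embedded in matrix inside an
ellipsoidal striatal envelope whose long (rostro-caudal) axis spans 40 mm —
semi-axes (10, 20, 8) mm, giving a tissue volume close to a human
hemistriatum at 2 mm resolution (~850 diffusion voxels). The lattice
resolution is 0.25 mm so the thinnest tubule spans two voxels.

Tubules grow as persistent random walks (velocity momentum 0.7, step
0.25 mm) in clusters of 12 branches of 12 mm length, attracted to their
cluster center (attraction 0.12 per step, seed spread 1.2 mm). Clusters —
labyrinth knots — are what produce voxels whose striosome fraction exceeds
one half: a single tubule of ≤ 1.25 mm diameter can occupy at most ~0.31 of
a 2 mm voxel, so striosome-like classification requires multi-branch knots,
exactly the "direct hit or multiple-branch sampling" reading of the
parcellation. Cluster centers are rejection-sampled from an exponential
density along the medial/rostral/ventral gradient (log-slope 1.0 per
normalized axis unit), reproducing the known spatial enrichment of the
striosome. Clusters are added batch by batch until the striosome reaches
15% of envelope tissue (a mid-range histological figure; the paper states
none) within ±10%.

Voxelization to the 2 mm diffusion grid computes the striosome share `f` of
tissue per voxel; diffusion voxels that are mostly exterior are masked out.
The total striosome volume survives voxelization to well within 1% because
the tubules are confined at least one tubule radius inside the envelope.

The forward model maps fraction to probability by a strictly decreasing
logistic, `p_matrix(f) = expit(s·(f0 − f))` with midpoint `f0 = 0.5` and
steepness `s = 10` (pure matrix then maps to p ≈ 0.993 ≥ 0.95, and the
midpoint voxel is exactly indeterminate). The true fraction-to-bias
relation is unknown; both parameters are config-exposed and swept in tests.
Streamline counts split a 5000-streamline voxel budget by `p`, each class
multiplied by independent mean-one log-normal noise (σ = 0.05), so the
count ratio is a consistent estimator of `p`.

### The three perturbations

* **A — striosome volume loss.** Branches are deleted in random order until
  the striosome volume drops by the requested fraction. Because tubules
  overlap inside knots, the number of deleted branches exceeds the volume
  fraction removed; a single cumulative stamping pass locates the cut
  exactly (kept volume is monotone in the kept prefix). Tubule thickness is
  untouched.
* **B — architecture simplification.** The labyrinth is rebuilt from
  scratch with (1−m) times the branch count organized into (1−m) times the
  cluster count, and all diameters are inflated by a common factor, solved
  iteratively, until striosome volume matches the original within 2%
  ("thicker tubes, fewer branches"). Diameters may exceed the generative
  sampling range but never a hard cap (default 1.9 mm, below the voxel
  size); exceeding the cap raises an error rather than clamping silently.
  A rebuild that merely deletes branches from the existing skeleton was
  tried first and rejected: count × diameter² conservation cancels at every
  fraction level set, leaving no voxel-scale signature at all. Knot-level
  consolidation is the geometry in which "fewer, thicker" becomes
  observable at diffusion resolution.
* **C — matrix expansion.** The envelope dilates so matrix volume grows by
  the requested fraction; the striosome label set is bit-identical to the
  input.

### Histogram signatures and the scenario classifier

Case-minus-control signatures are summarized per replicate by paired
z-scores of: top-tail (uppermost 15 bins) and mid-range volume of each
compartment histogram, total biased volume of each compartment, and the
indeterminate pool. At magnitude 0.2 and 50 pairs the scenarios separate
cleanly:

* A: striosome-like volume falls throughout its distribution, the
  indeterminate pool shrinks, matrix-like volume rises.
* B: both distributions' top tails gain, the mid-range and the
  indeterminate pool lose.
* C: the gain is confined to the top matrix-like bins; striosome-like and
  indeterminate volumes are flat.

The classifier is a two-split decision rule on those z-scores (critical
value 2): a significant striosome-top *gain* is unique to B; otherwise a
significant striosome-total *loss* marks A; otherwise C. On the study
conditions (magnitude 0.2, 50 pairs, ten seeds per scenario) recovery is
100%, comfortably above the 90% design requirement.

One caveat surfaced by the simulator: under exact volume conservation,
scenario B's indeterminate loss and matrix-top gain are second-order
(knot-surface) effects and are far weaker than its striosome-top gain; they
reach significance across ten replicates but not reliably within a single
50-pair cohort.

### Cohort simulation

Each simulated pair shares demographics (sex obligatory, control age drawn
within the case's matching window, race/study/diagnosis drawn at the
cohort frequencies of the source studies: 30% female, 81% White, 77.9%
ADOS-high, CSS ≈ N(7.1, 1.35) clipped to [3, 10] for 72.8% of cases). Cases
receive the scenario perturbation and a global streamline deficit (default
−10% budget); controls are unperturbed. FA maps interpolate between a
striosome mean of 0.213 and a matrix value 4.2% higher according to 1−f,
plus 1% Gaussian noise — so the *recovered* compartment-mask FA gap is
smaller than the injected tissue-level gap, because striosome-like voxels
are partial-volume mixtures. All randomness derives from one run seed
fanned out per subject.

### What the phantom does not emulate

Tractography itself (streamline propagation, path-length correction,
seeding geometry) is not simulated; counts come directly from the forward
model, so systematic tractography artifacts (gyral bias, bottlenecks,
false continuations) are outside what passing tests demonstrate. The
phantom's striosome is statistically, not anatomically, realistic; absolute
offset magnitudes (e.g. how many mm more rostral striosome-like voxels sit)
are properties of the generator's gradient strength, and only their signs
are meaningful checks. Effect magnitudes in the scenario suite are likewise
properties of this simulator, not estimates of any empirical effect size.

## Problem sizes and numerical choices

The scenario suite runs 3 scenarios × 10 seeds × 50 pairs (two phantoms per
pair) at 0.25 mm resolution; a full suite completes in a few minutes on one
CPU. Null calibration of the four test families uses 1000 replicates of
10-pair cohorts on a reduced phantom (12 × 20 × 10 mm envelope) in which
only forward-model count noise varies between subjects — family inputs are
still produced by the package's own parcellation and histogram code. The
any-rejection rate per family stays at or below q up to Monte-Carlo error,
as the Benjamini–Hochberg guarantee requires under a global null.

Degenerate inputs are handled explicitly: empty compartments produce empty
equal-volume masks with a warning; an all-nonpositive contribution map
produces an empty zone with a warning; a Dice comparison in which both
thresholded volumes are empty reports NaN ("no signal"), distinct from 0
("no overlap"); zero-count voxels are undefined, not 0.5.

## Known limitations

* The forward model is local (voxelwise): spatial streamline interactions
  between neighboring voxels are not represented.
* The synthetic caudate/putamen split is a rostral/caudal bisection of the
  striatal mask — a labeling convenience for nucleus-wise accounting, not a
  segmentation.
* The matcher is greedy; it can miss globally optimal pairings in dense
  cohorts (an optimal assignment variant would change at most the
  cross-study bookkeeping).
* Scenario B's conservation solver can fail loudly for magnitudes beyond
  ~0.4 with the default diameter cap; that is a modeling limit of
  "thicker tubes" inside 2 mm voxels, not a numerical bug.
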