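# Methods

`vesselfrac` measures the structural complexity of the circle of Willis
and its tributaries as seen in a 2D projection of a bright-blood
angiographic volume, and reproduces the cohort statistics used to compare
such measurements between subject groups. This note documents the model,
the numerical choices, and what the synthetic validation does and does
not establish.

## The measurement

**Projection.** Time-of-flight MRA renders flowing blood bright, so a
maximum-intensity projection (per-ray maximum along one voxel axis)
collapses the vascular tree into a 2D image while suppressing parenchyma.
The default projection axis is the axial (superior–inferior) one, giving
the transverse view in which the arterial ring is conventionally read;
the axis is configurable. Projections stay floating point; quantization
to 8 bits happens only inside the thresholding histogram, avoiding
double-quantization bias.

**Segmentation.** The default route is automatic intensity thresholding
by iterative intermeans (Ridler–Calvard): on a 256-bin histogram over
[min, max], iterate `T ← (mean below T + mean above T)/2` to its fixed
point and keep pixels strictly above T. An alternative supervised route
trains a random-forest pixel classifier on sparse user labels over a
fixed feature bank (raw intensity, Gaussian smoothings at σ ∈ {1,2,4,8}
px and gradient magnitudes at the same scales); it is deterministic
under a stated seed. Interactive artefact erasure is replaced by a
deterministic cleanup that removes 8-connected components smaller than
`min_component_px` (default 50 px at 0.5 mm/px, scaled by
`(0.5/pixel_mm)²` so the physical size of removed speckle is constant).
Foreground connectivity is 8-neighbour throughout; indices are 0-based
row-major.

**Skeletonization.** Topology-preserving Zhang–Suen-class thinning
(scikit-image) reduces the mask to a one-pixel-wide centerline: the
skeleton is a subset of the mask, preserves the number of 8-connected
components, and thinning is idempotent.

**Box counting.** The skeleton is covered with square grids of side ε
for a linearly increasing series of sizes, starting at ε_min = 2 px and
capped at 45% of the smaller image side; the step is chosen as
`max(1, (ε_max − ε_min) // 25)` so 10–30 scales exist. At each scale the
number N of boxes containing at least one foreground pixel is counted
for 12 grid offsets — the first fixed at (0, 0), the rest drawn
uniformly from [0, ε)² by a seeded generator — and averaged. Boxes that
extend past the border count if their in-image part contains foreground.
Ordinary least squares of log N̄ on log ε over *all* scales (none are
ever dropped) gives the estimate

    D_f = −slope,   with R² ≥ 0.995 required for QC acceptance.

The negative sign is the standard box-counting estimator (N̄ shrinks as
ε grows); it produces the positive dimensions in the ~1.5 range expected
for planar vascular skeletons. A QC failure still returns the estimate
with `qc_pass = False`; the pipeline's strict mode refuses to average
non-QC estimates, warn-only mode averages anyway.

**Two-rater design.** Human raters are emulated by running the
segmentation stage twice with two declared parameter sets; the two
estimates are averaged arithmetically and their agreement is quantified
with the intraclass correlation below.

### Known finite-range bias

Counting partially covered boxes up to ε = 0.45 × image side biases the
estimate downward for smooth and space-filling sets. For a 1-px line of
length L the offset-averaged count is exactly E[N] = L/ε + 1; the `+1`
border term flattens the log–log plot at large ε, and the OLS slope
magnitude over any linear series reaching the 45% cap is at most ≈0.94
(measured: ≈0.91 at 512 px). A filled rectangle squares the same term
(measured: ≈1.82 instead of 2). A mid-range self-similar set is much
less affected: the order-7 Sierpinski gasket is recovered at 1.55–1.56
against log 3/log 2 ≈ 1.585, with R² ≈ 0.998. The bias is scale
invariant — enlarging the canvas does not remove it — and is a property
of the protocol, not of this implementation; R² does not flag it (the
contaminated plots still fit well above 0.995). Because every image in a
cohort is measured under the same protocol, group *differences* remain
meaningful; absolute values carry the documented offset. Tests assert
truthful bands around the biased values plus the strict dimension
ordering line < gasket < rectangle.

## Cohort statistics

* **Welch's t** (default) for the group comparison of the averaged
  dimension, accepting raw vectors or `(n, mean, sd)` summaries so
  published group tables can be re-analysed directly; Satterthwaite
  degrees of freedom, 95% CI = diff ± t₀.₉₇₅,df·SE. The unequal-variance
  form is the default because fractional published df identify it; a
  pooled-variance flag exists for completeness. From the summaries
  (8, 1.5172, 0.0248) vs (14, 1.5653, 0.0304) the package computes
  t = 4.024, df = 17.31, CI (0.0229, 0.0733) — the slight difference
  from t = 4.018 / df = 17.282 obtained on the unrounded per-subject
  data is the precision lost in the printed summaries.
* **Spearman's ρ** as the Pearson correlation of mid-ranks; the
  two-sided p is an exact permutation enumeration for n ≤ 10 and the
  usual t-approximation above that (a study-sized n = 22 falls in the
  approximation regime). A sensitivity re-run drops the single most
  extreme point in rank space (largest median/MAD-standardized rank
  distance) — a deterministic stand-in for visual outlier removal, and
  labelled as such in every report.
* **ICC(A,1)** — two-way mixed-effects, absolute agreement, single
  measurement — from the two-way ANOVA mean squares, with the
  McGraw–Wong F-based 95% interval. Identical rater columns return
  exactly 1. Cross-checked against pingouin in the test suite.
* **Fisher's exact test** (scipy) for the sex proportion, two-sided by
  the probability-mass rule; verified against exhaustive hypergeometric
  enumeration for every 2×2 table with total ≤ 12.
* **Shapiro–Wilk** routes the analysis: the dimension (normal) goes to
  the t-test, the right-skewed risk score to the rank correlation.

## Synthetic data

The study's raw angiograms are not public, so validation rests on three
phantom families whose ground truth is known:

* **Analytic fractals** — line (D = 1), filled square (D = 2),
  Sierpinski gasket (log 3/log 2, rendered by quadrant subdivision with
  3^order elementary triangles), Koch curve (log 4/log 3), and a seeded
  random branching tree. Deterministic kinds ignore the seed entirely.
* **Vessel volumes** — a recursive bifurcating tree grown in the
  projection plane: fixed branching half-angle 0.6 rad with seeded
  azimuth, per-sub-segment angular jitter of SD `tortuosity` (default
  0.15 rad), geometric radius decay (default 0.8/generation from a 4-px
  root) and length decay 0.75/generation with the trunk scaled so the
  tree spans the volume at any depth. Tubes are rasterized by marking
  voxels within the branch radius of the centerline, with distances
  taken in millimetres so anisotropic voxels are handled; the exact
  centerline voxels are returned as ground truth. `rarefaction` r prunes
  exactly `floor(r × n_terminal)` terminal branches (seeded choice,
  independent of the tree-shape stream, so the same seed gives the same
  tree at every r). Contrast is bright-vessel on additive Gaussian
  background noise clipped at zero (default SD 5 against vessel
  intensity 100) — adequate for exercising thresholding; Rician noise
  and MRI physics (flow saturation, coil inhomogeneity) are not
  modelled. Default volumes are 128³ voxels at 0.5 mm — a deliberately
  compact problem size that keeps a 20-run sweep to seconds while
  leaving ~26 box-count scales.
* **Cohorts** — group sizes 8 vs 14 with dimension distributions
  1.5172 ± 0.0248 vs 1.5653 ± 0.0304 (truncated normal on (1, 2)),
  covariate marginals (age, BMI, systolic BP, TC/HDL, sex proportion)
  matching the published group table, and a QRISK2 score drawn from a
  pooled lognormal (mean 3.11, SD 4.22, right-skewed by construction)
  coupled to the *pooled* dimension ranks through a Gaussian copula with
  r = 2 sin(πρ_s/6), so the realized rank correlation converges to the
  requested ρ_s (default −0.656). Anchoring the copula to pooled ranks
  rather than a shared latent variable is what makes the pooled rank
  correlation hit its target despite the two groups having different
  marginal transforms; the per-group QRISK2 means are then emergent
  (higher in the lesion group via the negative coupling), not pinned.
  Rater columns add independent Gaussian noise (default SD 0.003,
  chosen to reproduce an inter-rater ICC of ≈0.99); zero noise gives
  exact agreement. Only group-level moments are emulated — per-subject
  values were never published — so recovery claims are distributional:
  power ≈ 1 at 50× the study size, null rejection ≈ 5%, realized ρ_s
  within sampling error of the target.

Passing these tests shows the estimator and statistics behave correctly
on objects with known truth and TOF-like contrast; it does not certify
segmentation accuracy on real MRA, where motion, vessel overlap and
intensity inhomogeneity are the dominant difficulties.

## Degenerate inputs and tie-breaks

Constant images raise (degenerate histogram); empty masks raise at
skeletonization and box counting; scans need ≥ 3 scales to fit; both
group SDs zero make t undefined and raise; zero rank variance raises for
the correlation; ICC requires ≥ 5 subjects, ≥ 2 raters, no missing
cells. Ties in either correlation variable get mid-ranks. The
intermeans iteration nudges toward the data if a split ever becomes
one-sided. Batch cohort runs log and skip failing subjects (strict mode
aborts); every output JSON embeds the config hash and package version.
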