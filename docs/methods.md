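# Methods

This note documents the models, estimators, parameter choices and numerical
details behind `ebmorph`, and what the synthetic data do and do not emulate.

## Volumetric morphometry

EBs are treated as spheres. An EB measured in k ∈ [2, 8] directions gets a
mean diameter first and then the volume V = πd̄³/6 — not the mean of
per-direction volumes — because averaging diameters before cubing is the
convention the measurement protocol implies, and the two differ at order
CV² anyway. Growth ratios compare stage mean volumes and are unit-free;
ratios quoted as integers are rounded half-up, matching how such fold
values are reported by hand.

Shape descriptors operate on a single-component binary mask:
circularity = 4πA/P², roundness = 4A/(π·major²), aspect = major/minor from
the ellipse fit. The perimeter uses the Crofton estimator with diagonal
correction; a naive pixel-edge perimeter overestimates P by up to ~27% on
smooth shapes and would bias circularity far below its true value, so
circularity is computed with Crofton and clipped at 1.0 (rasterised ideal
circles can land marginally above 1). Closed-form oracles (circle, 2:1
ellipse) agree within 2% at ≥ 200 px major axis. Skewness and density are
sometimes listed among particle descriptors but have no agreed mask-level
definition, so they are deliberately out of scope.

Pattern proportions assume concentric spherical shells (the archetype is
radially symmetric): cavity = (d_cav/d)³, ExEn = 1 − ((d − 2t)/d)³, Epi-l
the remainder. The volume ledger enforces conservation exactly:
cellular = total − cavity, labelled = EdU-fraction × cellular.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions; their defaults are fixed and
are not tuning knobs.

**Diameter cohorts.** 24 EBs per stage by default. Per-EB true diameters
are truncated normal (mean, CV·mean, cut at ±3 sd, which keeps diameters
positive for any CV ≤ 1/3); day-1–3 cohorts use CV ≈ 3% and day-5–10
cohorts ≈ 6%, inside the reported 2.6–4.0% / 4.9–7.2% bands. Each EB is
then "measured" in 2–8 directions with per-direction jitter
sd = 0.3·CV·d_true. The 0.3 factor is a modelling choice (the measurement
protocol reports no direction-level spread): it makes a zero-CV cohort
measure exactly and adds only CV²·0.09/k to the variance of the per-EB mean,
so the cohort CV of mean diameters remains ≈ the planted CV.

**Nuclei stacks.** Planes are independent 2D sections (matching per-plane
counting); there is no 3D rendering, optical PSF, or z-correlation. Nuclei
are disks with areas uniform in a configured range (default 40–120 µm²,
well inside the 15–350 µm² counting filter), placed by dart throwing with a
1 px clearance so they never touch (an `allow_touching` switch removes the
clearance to exercise the watershed). The EdU-labelled subset is the first
round(f·n) entries of a seeded shuffle, so planted fractions are exact
rather than binomial — essential for bias tests of the estimator. Surface
mode places centres uniformly (by area) in the outer 20% of the radius; the
true depth distribution of labelled cells is unknown, so the 20% figure is
a free choice that merely has to produce a detectable uniform→surface
contrast. Gaussian pixel noise (sd 0.03 against disk intensity 0.85)
roughens edges without affecting the Otsu split.

**Marker sections.** Concentric zones with Gata4 bright only in the outer
shell, Oct4 only in the Epi-l shell, near-zero in the cavity. Each zone
boundary is perturbed by a smooth angular field (6 Fourier modes, pointwise
sd = the configured jitter in px), mimicking biological boundary
irregularity while keeping the mean radius unbiased. Zone areas match
analytic annuli within 2% at ≥ 500 px diameter.

**qPCR tables.** Ct = gene baseline − log2(planted fold) + N(0, sd),
triplicate by default, with Hprt as the always-included reference gene at
its own baseline. Amplification-efficiency deviations from 2.0 are not
modelled (efficiency correction is out of scope).

Passing tests on these data demonstrate correctness of the estimators
under the stated geometry and noise, not robustness to out-of-focus light,
uneven illumination, clumped chromatin, or failed wells in real data.

## Image quantification

Segmentation: global Otsu threshold (deterministic; the original protocol
names no method), Euclidean distance transform, watershed seeded from
distance maxima, then the inclusive [15, 350] µm² area filter. The minimum
seed separation is the radius of the smallest admissible nucleus
(√(15 µm²/π) at the working pixel size). This choice matters: two
just-touching equal nuclei have their distance maxima one diameter apart,
so any larger exclusion zone (e.g. a mean-nucleus diameter) suppresses one
seed and silently merges neighbours — with a filter-midpoint-radius rule we
measured 143/150 nuclei recovered on a dense plane versus 150/150 with the
minimum-radius rule. The manual-correction step of interactive counting is
replaced by fully automatic processing; the accepted accuracy loss is
bounded by the test invariants (exact counts on ≥ 95% of seeds for
non-overlapping in-range nuclei; EdU estimator bias ≤ 2 points).

EdU/nucleus matching is nearest-centroid within one nucleus radius, greedy
by distance with each nucleus matched at most once — exact on disk
phantoms and cheaper than mask-overlap logic. Planes with zero segmented
nuclei are excluded from the stack mean (avoids 0/0); an entirely blank
stack is an error. All planes of a stack are used.

Diametral profiles sample bilinearly at 1 px steps along a line through
the mask centroid, clipped to the filled EB mask (holes, i.e. the cavity,
are filled for masking). Pattern radii come from the angular-averaged
radial profile: the cavity edge is the inner half-maximum rise of Oct4
(cavity = 0 if the centre is already above half-max), the Epi-l/ExEn
boundary the inner half-maximum rise of Gata4 (absent ring ⇒ boundary at
the outer edge), and the total radius the half-coverage falloff of the
mask, each with linear interpolation between integer radii. On noiseless
sections the planted radii are recovered within ~1 px; with 2 px boundary
jitter the angular average keeps the bias far below the percent level.

## Expression analysis

Replicate Ct values are averaged before ΔCt (equivalent at replicate level
to averaging ΔCt, since the same replicates enter both terms). The
reference sample's fold is exactly 1 by construction. Profile scaling is
per gene (z-score with sample sd; zero-sd rows map to 0), with a flag for
per-condition scaling since the original heatmap convention is ambiguous.
Clustering uses Euclidean distances with complete linkage by default — a
common default in the R environment such heatmaps come from — and the
linkage method is configurable; clustering is fully deterministic.

## Statistics

One-way fixed-effects ANOVA from explicit sums of squares, with p from the
F distribution; zero within-group variance is rejected explicitly rather
than returning an infinite F. The t-test is the pooled-variance (Student's)
two-tailed form, matching the "unpaired Student's t" convention, not
Welch. Both Tukey(-Kramer) and SNK post hoc procedures are provided (both
appear in this analysis tradition; Tukey is the default):
q = |Δmean|/√(MSW(1/nᵢ + 1/nⱼ)/2), with a single q(α, k, df) critical value
for Tukey and stepwise q(α, span, df) over ordered means for SNK, including
the standard protection that pairs inside a non-significant range are not
declared significant. Under the null (3 normal groups, n = 24), the ANOVA
rejection rate at α = 0.05 is calibrated to 0.05 ± 0.015 over 2000
replicates in the test suite.

## Morphogen-threshold (French-flag) model

The patterning observations are conceptual — no equations are given for
them — so the model here is the simplest one consistent with "free
diffusion from the external environment" plus interior consumption:
steady-state diffusion with first-order uptake in a sphere, giving
c(r) = c_s (R/r) sinh(r/λ)/sinh(R/λ). It is an interpretation, documented
as such, not established mechanism. Numerics: the profile is evaluated in
the overflow-safe form (R/r)·e^((r−R)/λ)(1−e^(−2r/λ))/(1−e^(−2R/λ)) with
the analytic centre limit c(0) = c_s(R/λ)/sinh(R/λ), so R/λ up to 10³
poses no difficulty; fate boundaries are found by bracketed root-finding
(Brent, xtol 10⁻¹² R) on the monotone profile, and proportions then follow
from the concentric-shell formulas. Agreement with a volume-weighted
quadrature oracle is within 10⁻⁴.

Three thresholds are named in the conceptual scheme but only three zones
are described; two boundaries (T1, T2) suffice, so T3 is retained as a
validated label (T3 ≤ T2) for the sub-T2 cavitation regime rather than a
fourth-zone boundary. Diffusion-restriction events (tight junctions,
basement membrane) are represented only as changes in λ, not as explicit
internal barriers. Scaling experiments compare `lambda_proportional`
(λ/R fixed, default 1/3 — proportions exactly size-invariant, by
nondimensionalisation) with `lambda_fixed` (absolute λ — proportions drift
with size). The default thresholds T1 = 0.84·c_s, T2 = 0.53·c_s at R/λ = 3
were chosen once so the model reproduces archetype-like proportions
(≈ 25% ExEn, ≈ 27% cavity); any λ change at late stages would be an
illustrative choice, as the diffusion restriction is not quantified.

## Pipeline and problem sizes

The default `report` run uses compact problem sizes chosen so a full run
completes in seconds while every stage remains statistically meaningful:
24 EBs per stage per cohort (the study's cohort size), 5-plane stacks of
80 nuclei at 0.8 µm/px (the late-stage stack radius is 1.5× the early one
so surface-confined nuclei remain placeable without overlap), one 600 µm
section per medium, and triplicate qPCR for six lineage markers. The
acceptance script uses the larger planted geometries it states (72-EB
cohorts; 20-plane, 150-nuclei stacks at 0.5 µm/px). All randomness flows
from a single seed; outputs carry the seed and a hash of the analysis
parameters, and re-running a config reproduces `summary.json` bit for bit.

## Known limitations

- Spherical-volume bookkeeping ignores the asymmetric ExEn outgrowths of
  late EBs; the concentric decomposition assumes a centred cavity.
- Segmentation is per-plane 2D; nothing links nuclei across planes, so
  stack-level percentages count nucleus sections, not cells.
- The synthetic noise model is Gaussian and spatially white; real confocal
  noise is neither.
- The morphogen model is steady-state and single-species; time-dependent
  PDEs and activator–inhibitor (Turing) initiation of the ExEn pattern are
  out of scope.
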