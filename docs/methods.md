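# Methods

This note documents the models, numerical choices and limitations of
`opmlesion`. Headings follow the pipeline: geometry and synthetic
cohorts, sensor arrays and error models, forward models, trial
simulation, Bayesian inversion, and evaluation.

## Geometry and the synthetic cohort

**Surfaces.** Cortex and scalp are closed triangulated 2-manifolds in a
common head frame (mm). The synthetic cortex is an icosphere
(subdivision order 4 by default, 2,562 vertices) radially modulated by
a seeded band-limited spherical-harmonic field (degrees 1–4) scaled by
a `bumpiness` fraction, default 0.1. The non-sphericity is load-bearing,
not cosmetic: dipoles are oriented along outward surface normals, and
on an exactly spherical cortex every such dipole would be radial and
therefore magnetically silent in a spherical-ish conductor. With
bumpiness 0.1 the max/min radius ratio stays below 1.25 and every
source retains a tangential component. The scalp is a sphere of radius
92 mm; cortex–scalp clearance must exceed 5 mm.

**Decimation.** Quadric edge collapse with a lazy heap, link-condition
manifold guards and a normal-flip check; collapse targets are the
quadric-optimal point with a midpoint fallback. Parity with other
decimators is statistical (vertex count within a few percent of
`n/factor`; closedness, orientation and Euler characteristic 2
preserved), not bit-exact.

**Lesions.** A candidate lesion is a geodesic disk: vertices accreted
in graph-geodesic order from a seed until the cumulative one-third
face-area share reaches a target area. Default areas are uniform in
200–1,000 mm², spanning roughly 8–40 vertices at the default mesh
resolution — the same patch-to-mesh regime as a ~3,300-vertex
whole-cortex source space. The lesion "COM vertex" is the member vertex
nearest the arithmetic mean of member coordinates (the mean itself lies
off the surface; restricting to members keeps dipoles on the source
space). The loose-prior region volume is reported as the convex-hull
volume of the region's vertices; volume is not asserted against any
external figure since the metric (hull vs voxelisation vs
area×thickness) is a convention.

**Cohorts.** Per-patient lesion counts follow a shifted geometric
distribution P(k) ∝ p(1−p)^(k−2) truncated to {2,…,14} with p = 0.6,
giving median 2 and mean ≈ 2.7 — matching the reported count statistics
of multi-lesion patients in machine-read lesion maps. Lesion placement
is uniform over the cortex subject to separation constraints; no
lobe-level spatial bias is emulated (the synthetic cortex has no lobes,
and separation, not lobe, is the performance-relevant variable).
Separation semantics: the *minimum* separation applies to every pair of
COMs; the optional *maximum* applies to each lesion's nearest
alternative. An all-pairs maximum would be geometrically infeasible on
a surface for k = 4 with tight windows (no four points on a 2-manifold
can be pairwise within [16, 20] mm while patches stay disjoint), and
the nearest-alternative distance is the quantity the distance-binned
analyses use. For near-separation cohorts (nearest alternative < 2 cm)
the area range is reduced to 150–400 mm² so that disjoint patches
remain packable; all other studies use the default range. Packing is
rejection-sampled with distance-windowed candidate sets and bounded
retries. Everything is reproducible from one master seed via
`SeedSequence` spawning.

## Sensor arrays and error models

Dual-axis OPMs are packed on the scalp by seeded farthest-point
sampling; points are added while the largest coverage gap exceeds
0.75 × spacing, which puts the mean nearest-neighbour distance near the
nominal spacing and, on an adult-sized scalp, yields sensor counts
close to published dense/sparse OPM layouts (114/26 sensors at
32/64 mm here vs 95/25 on a real adult scalp). Each sensor sits
8.7 mm above the scalp along the local normal — the scalp-to-vapour-cell
distance of a typical commercial OPM — and records a radial channel
plus one tangential channel at a seeded random angle.

Four error classes, all zero-mean and exactly identity at magnitude 0:

* **position** — i.i.d. N(0, sd²) per Cartesian component per sensor
  (the printed SD is the per-axis SD, the simplest reading of a
  "zero-mean Gaussian position error");
* **orientation** — each triad rotated about an independent uniform
  random axis by |N(0, sd²)| degrees;
* **gain** — per-channel multiplicative factors 1 + ε, ε ~ N(0, sd²).
  A literal "multiply the data by a zero-mean number" would annihilate
  the signal and contradict gain errors being the *least* harmful
  error source, so the zero-mean draw is interpreted as a perturbation
  about unity gain. The "% of signal maximum" phrasing is likewise
  ambiguous (per-channel vs global maximum vs gain fraction); it is
  implemented as a gain fraction;
* **rigid rotation** — the whole array rotated about a seeded random
  axis through the head origin (the pivot is a choice; nothing in the
  error model fixes it).

Sharing protocol: one position/orientation/rotation realisation per
error level is shared by all lesions (the distorted forward model is
computed once); gain realisations are drawn per lesion and applied to
the data. The rotation axis is redrawn per error level.

## Forward models

Units are fT per nA·m throughout; μ0/4π and the unit changes are folded
into one scale so lead-field entries are O(0.1–10) for superficial
sources, which keeps the covariance algebra well conditioned.

**Sphere.** The closed-form field of a current dipole in a homogeneous
conducting sphere, projected on each channel axis. Only the fitted
sphere centre matters (the field is radius-independent); radial dipoles
and dipoles at the centre are silent. The implementation is validated
against two independent oracles: numerical differentiation of the
analytic magnetic scalar potential, and the identity that the radial
field component equals that of the infinite-medium primary field.

**Corrected single shell.** For a homogeneous conductor bounded by an
arbitrary closed surface, the magnetic lead field equals the
infinite-medium (Biot–Savart) kernel plus the gradient of a function
harmonic inside the conductor, fixed by the boundary condition that no
current crosses the surface — equivalently, the total lead field has
zero normal component on the boundary. The harmonic correction is
expanded in exterior point-source potentials 1/|r − pⱼ| with poles on
three nested layers (1.3/2.2/4.0 × the maximal surface radius,
(order+1)² − 1 quasi-uniform directions per layer, order 10 by
default) and fitted by area-weighted least squares at face centroids.
This basis was chosen over solid spherical harmonics because it is
pole-free, numerically robust, and nested — enlarging the order can
only decrease the boundary residual, which the tests assert. On an
exactly spherical shell the corrected model reproduces the analytic
sphere solution to ~0.1% (relative Frobenius norm) at order 10. The
global relative boundary residual is attached to every lead field and
a warning is raised above 0.3. Note that per-channel residuals are
uninformative for radial channels on near-spherical shells: their
boundary data are already ≈ 0 because volume currents contribute no
radial field there.

The shell for a synthetic head follows the cortex's large-scale shape:
for each direction of an order-3 icosphere the radius is the largest
cortex-vertex radius within a 20° cone plus a 6 mm margin, keeping all
sources strictly inside. Dipole moments are unit by convention — the
fixed-SNR protocol (below) makes absolute moment irrelevant.

## Trial simulation

One 1 s trial per dataset at 1,000 Hz (the rate is a choice; it must
exceed 512 Hz so the 0–256 Hz analysis band is representable). The
source waveform is a single 200 ms cosine cycle centred in the trial
(peak 1 at t = 0.5 s, hard-truncated at the support edges; the phase
convention is a documented choice). Four scenarios place identical
unit dipoles at: the COM vertex, all lesion vertices, all boundary
vertices, or one seeded boundary vertex. White Gaussian channel noise
is scaled so that 20·log10(rms(noiseless)/σ) equals the target sensor
SNR, default −20 dB, with the rms over all channels and samples.
Fixing sensor SNR deliberately decouples detectability from lesion
size and depth (it inflates the effective strength of deep or small
sources); the simulation asserts that independence rather than
modelling it away.

## Bayesian inversion

**Pre-processing.** Hanning window, DCT band-pass 0–256 Hz, then a
temporal SVD keeping the smallest number of modes capturing ≥ 99% of
variance, capped at 16. With −20 dB white noise the cap always binds
(r = 16), inside which the signal mode dominates — the effective SNR
after reduction is of order 0 dB. There is deliberately *no* spatial
(channel) reduction: inversions with distorted sensor models must stay
comparable in the same channel space.

**ReML.** The sensor covariance model is Σ(h) = h₀I + Σᵢ hᵢ L Qᵢ Lᵀ
fitted to C = YYᵀ/r with r temporal modes as degrees of freedom. Data
covariance and components are trace-normalised; hyperparameters are
optimised on a log scale by Fisher scoring with Gaussian hyperpriors
(mean −4, variance 16 per component — standard parametric-empirical-
Bayes practice), a noise floor of e⁻⁸ relative to data power, a step
cap of 4 log units, and a step-halving line search so the objective
ascends at every accepted iteration. Convergence is declared when the
free-energy gain falls below 10⁻³ (or when no gain is found along an
ascent direction at ~10⁻⁶ step scale, i.e. numerical stationarity);
the iteration cap is 256 and non-convergence returns best-so-far with
a warning. The reported F is the Gaussian log evidence of the reduced
data minus the hyperprior KL, plus the Laplace Occam term −½ log det H
for the hyperparameter posterior, and is corrected back to the
original data scale. Sparse (ARD-style) optimisation emerges from the
per-component hyperpriors; this differs from greedy-search MSP
variants, and equivalence is expected at the level of F-based
decisions, not hyperparameter values.

**Schemes.** EBB builds one empirical prior with source variances
proportional to unit-gain beamformer power 1/(lᵢᵀC⁻¹lᵢ) (C regularised
by 10⁻¹⁰ × trace-scaled identity), normalised to max 1, and runs
two-component ReML over the whole source space. Loose MSP truncates
the lead field to the 100 vertices nearest the lesion's mean position
and uses one single-dipole component per vertex ("100 neighbouring
dipole sources as priors" admits a patch reading; the dipole reading
is implemented). Restricted MSP uses exactly two components: sensor
noise and a single dipole at the COM vertex. Posterior means are
evaluated analytically from the optimised covariance; the peak is the
source with the largest L2 norm across temporal modes (lowest index on
ties).

**Model comparison.** One inversion per candidate lesion; the winner is
the highest F, with exact ties marked indeterminate (scored incorrect —
conservative). When the truth is known, ΔF = F(true) − max F(others),
and exp(ΔF) is the evidence ratio (ΔF = 3 ⇒ ≈ 20:1).

## Evaluation

Peak-distance rule (EBB and loose): correct iff the peak is strictly
closer to the true lesion's mean vertex position than to every
alternative's. Model-comparison rule (restricted): correct iff ΔF > 0.
Ties are incorrect by construction. Percent correct is summarised with
percentile-bootstrap 95% CIs resampling lesions (within bins for the
distance-binned analysis). Chance level is the closed form
n_patients/n_lesions × 100 (a k-candidate patient contributes k lesions
each guessed at 1/k), with a Monte-Carlo guessing CI; the CI method is
a choice, as no standard one exists for this statistic. Distance
binning uses equal-occupancy quantile bins of the nearest-alternative
COM distance (bin sizes differ by at most one), with bin centres at the
midpoint of each bin's range. ΔF distributions are summarised by
histogram mode (Freedman–Diaconis width unless given) and 5th/95th
percentiles.

## Study presets and problem sizes

The orchestrator runs cohort × scenario × method × error-condition
factorials with per-cell seeds derived from the master seed, so the
zero-error column of any grid is bit-identical to a standalone
zero-error run and every row is regenerable in isolation. The default
error grids are: position SD {0,2,4,5,6,8,10} mm, orientation SD
{0,5,10,15,20}°, gain SD {0,…,5}%, rigid rotation {0,5,10,15,20}°, one
error source at a time, plus a combined flexible preset
(5 mm/10°/5%). The sparse 64 mm array is a config value, not separate
code.

The two headline presets use 40-patient cohorts with 2–4 lesions each
(~95–105 lesions): well-separated (all pairwise COM distances
> 42 mm) with combined flexible errors, and near-separation (nearest
alternative within 14–19 mm) with a 20° rigid rotation. These sizes
keep a full preset under about a minute on one CPU while leaving
binomial standard errors of a few percent; the test suite's
robustness-ordering checks use ~210 lesions. With a single shared
rotation axis per level (the sharing protocol), the near-separation
percentage varies by roughly ±5 points across master seeds — the axis,
not the lesion sample, dominates the uncertainty.

## What the synthetic world does and does not show

The generator reproduces the statistical structure that drives the
discrimination problem — candidate counts, patch areas, controllable
separations, fixed sensor SNR — but not: folded cortical geometry
(nearby synthetic lesions have nearly parallel source orientations,
making them *harder* to separate than nearby lesions on opposite sulcal
banks), lobe-level lesion bias, coloured brain noise, cross-talk
between sensors, gain errors correlated through background-field
gradients, or interactions between error sources. Passing tests
therefore demonstrate correctness and robustness of the method under
the stated generative model, not clinical-grade performance estimates;
the true success rate of lesion arbitration can only be assessed
against post-operative outcomes.
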