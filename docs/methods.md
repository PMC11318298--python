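# Methods

## Signal model and units

The package models the normalized diffusion-weighted signal of perfused
tissue as a two-compartment bi-exponential,

    S(b)/S0 = f · exp(−b·D*) + (1 − f) · exp(−b·D),

where `f` is the fraction of voxel signal arising from the intravascular
space, `D*` the pseudo-diffusion coefficient of blood traversing randomly
oriented capillaries, and `D` the molecular diffusion coefficient of tissue
water. The model assumes a single tissue compartment (no fat or
tri-exponential terms), no relaxation-time weighting differences between
compartments, and isotropic diffusion at the fitted (direction-averaged)
level. Diffusion coefficients are carried internally in mm²/s (e.g.
`1.36e-3`) and converted to the conventional ×10⁻³ mm²/s only in reports —
a deliberate guard against silent scale errors.

All fitters share one set of box constraints: f ∈ [0, 0.5],
D* ∈ [1.5, 500]×10⁻³ mm²/s, D ∈ [0, 2.5]×10⁻³ mm²/s. The D* floor is set
just above the typical muscle D (~1.4×10⁻³ mm²/s) to discourage the two decay
regimes from exchanging roles; the admissible ranges still overlap at their
edges. The segmented fits define the diffusion-only regime strictly as
b > 200 s/mm², so the 220 s/mm² shell of the reference protocol
(b = 0, 10, 20, 40, 70, 110, 160, 220, 300, 400, 500, 600, 700 s/mm²,
3 encoding directions, 4 repeats) belongs to the high-b set. The recorded
goodness-of-fit figure is the *squared* L2 norm of the residual between
measured and fitted normalized signal.

## Fitting strategies

* **One-step NLLS** (`nlls1`): bounded trust-region least squares over
  (f, D*, D) jointly, started deterministically at the box midpoint.
* **Two-step NLLS** (`nlls2`): step A fits `A·exp(−b·D)` to the high-b shells
  by NLLS with a free offset A (stored, but only D is carried forward); step
  B fixes D and fits (f, D*) to every shell.
* **Three-step NLLS** (`nlls3`): ordinary least squares through ln S at high
  b gives D (−slope) and the intercept; extrapolating the diffusion-only
  line to b = 0 gives the tissue fraction, hence f = 1 − exp(intercept); a
  final bounded 1-D fit over all shells gives D*. An intercept above 1 (which
  would imply f < 0) clamps f to its bound with a flag.
* **Bayesian** (`bayes`): uniform priors on the constraint box, Gaussian
  likelihood whose noise scale is marginalized under a Jeffreys prior — the
  log marginal posterior is −(n/2)·ln SSR(f, D*, D). The point estimate is the
  marginal posterior mean. Two engines compute it: affine-invariant ensemble
  MCMC (seeded, 24 walkers, 400 burn-in + 200 kept steps by default, with an
  effective-sample-size convergence flag) and a dense-grid integration
  (default 40×48×40 nodes over f × D* × D) that evaluates thousands of curves
  per second via one matrix product per batch. Grid and MCMC agree within a
  posterior SD on noisy curves; the grid is the default wherever many voxels
  or simulated curves are processed. Posterior mean, median or MAP are
  switchable in the sampler settings; the mean is the default and the one
  used throughout.

Segmented-step NLLS initialization is deterministic (f = 0.1,
D* = 20×10⁻³ mm²/s); convergence tolerances are 1e-10 on the objective with
at most 1,000 model evaluations. A parameter is flagged "at boundary" when
the solution equals a bound within 1e-12 after projection.

### Known estimator properties

* The segmented fits carry a small systematic truncation error because the
  pseudo-diffusion tail is not exactly zero above the cutoff; for typical
  muscle values it is ≲0.3% and it grows as D* approaches the cutoff scale
  (1/220 s·mm⁻² ≈ 4.5×10⁻³ mm²/s), where the segmentation assumption itself
  breaks down.
* In the near-mono-exponential regime (f < 0.05) the one-step D estimate is
  biased slightly low at finite SNR: the f ≥ 0 constraint lets noise leak
  decay into the perfusion term. The three-step D, read off the high-b shells
  alone, is unbiased there.
* The marginalized posterior SSR^(−n/2) has heavier-than-Gaussian tails:
  across noise replicates at SNR 50 the truth lies within ±3 posterior SDs of
  the posterior mean about 95% of the time, not the ~99.7% a Gaussian
  approximation would suggest.

## Image-processing chain

Order of operations (fixed): 2D 3×3 median filter → arithmetic average over
encoding directions → average over repeats (skipped for temporal analyses) →
per-voxel normalization by the voxel's own averaged b = 0 signal → fitting.
The median filter uses reduced neighborhoods at slice borders rather than
inventing padded values. Preprocessing that requires external tools on real
acquisitions (distortion correction, PCA denoising, motion correction) is out
of scope and assumed done upstream.

SNR is estimated from a single b = 0 acquisition as mean(muscle ROI) /
SD(equally sized background ROI outside the body), with no Rayleigh
correction by default (a ×0.655 correction of the background SD is available
but off, since the plain ratio is the reported convention).

Voxels are excluded from final maps when (a) the first diffusion-weighted
shell (b = 10 s/mm² after averaging) exceeds the b = 0 shell — a physicality
violation caused by noise or motion — or (b) any fitted parameter equals a
bound for the method in question, which signals an unreliable fit. Exclusion
reasons are stored per voxel and inclusion fractions reported per method.

## Repeatability statistics

The within-subject coefficient of variation is the root-mean-square of
per-subject CVs, `WS-CV = 100·sqrt(mean_i(s_i²/m_i²))`, with the sample SD
(ddof = 1) over each subject's replicates; a pooled variant
(`100·sqrt(mean s_i²)/mean m_i`) is available behind a flag. Replicates are
the 4 temporal repeats of the whole-ROI curve (assuming perfusion and
diffusion are constant over the few-minute acquisition), the 4 slices of one
spinal segment (assuming spatial uniformity within a segment, not across the
whole spine), or the 2 scan sessions (voxelwise maps averaged over the ROI,
with the mean voxelwise SD per visit reported as a dispersion measure).
Subjects with fewer than two valid replicates are dropped and logged. The
composite f·D* is summarized from per-replicate products, never from the
product of summaries.

## Monte Carlo simulation

Ground-truth triplets are drawn uniformly within the constraint box, clean
curves are synthesized on the 13-shell protocol, and zero-mean Gaussian noise
with σ = 1/SNR is added to the normalized signal (S0 = 1). Gaussian rather
than Rician noise is the deliberate default (a Rician option exists for
sensitivity work); noise is added after normalization because the simulation
has no images to normalize. Random streams split deterministically per
(draw, SNR level) from the master seed, so any single experiment can be
regenerated in isolation. Every method fits every curve; failures (e.g. a
log step on a non-positive noisy signal) are excluded from that cell's score
with counts reported, and at-boundary fits are included but their rate is
reported per cell.

Truth-versus-estimate agreement is summarized by ICC(2,1) — the two-way
random-effects, absolute-agreement, single-measure intraclass correlation of
the n×2 (truth, estimate) table — computed from the explicit ANOVA mean
squares. The composite f·D* is not scored separately, since its accuracy is
determined by its two factors. The full design defaults to 7,875 draws × 14
SNR levels (15–80 in steps of 5), ≈110k experiments; tests and the
acceptance script run a scaled-down 2,000 draws at SNR 40, where all four
methods already show ICC > 0.9 for f and D while D* remains clearly the
hardest parameter — the same qualitative picture as the full design.

## Synthetic phantom and cohorts

The phantom emulates the acquisition geometry: rectangular tissue regions
(two paraspinal muscle blocks inside a generic-tissue body block, air
around), each with its own (f, D*, D) and S0, imaged over the full
b × direction × repeat grid with Gaussian noise of σ = S0_muscle/SNR. The
default muscle template (f = 0.11, D* = 28.4×10⁻³, D = 1.36×10⁻³ mm²/s) and
cohort between-subject SDs (0.02, 6.8×10⁻³, 0.08×10⁻³) are typical
resting-muscle values. Directions are generated i.i.d. (no anisotropy),
matching a pipeline that averages directions before fitting. Cohorts draw
per-subject truths from truncated Gaussians around the template; visits share
the truth and differ only in noise seed.

What the phantom deliberately does **not** emulate: anatomical geometry,
diffusion anisotropy, fat contamination, EPI distortion, motion, coil
sensitivity profiles, and Rician magnitude statistics (unless enabled). Tests
passing on phantom data therefore demonstrate correctness of the estimators
and pipeline mechanics under the stated noise model — not robustness to all
in-vivo artifacts. Cohort-level results on real subjects depend on
physiology the generator cannot know, so in-vivo summary values are treated
as qualitative patterns (orderings) rather than numerical targets.

## Problem sizes used in tests

Unit tests run in seconds on toy grids. The acceptance-style checks use:
2,000 simulated curves at SNR 40 (all four fitters, grid posterior); 100
noiseless interior round-trips; 500 curves at SNR 45 for the residual-norm
ordering; a 40×40×6 two-region phantom (1,680 voxels per region) at SNR 60;
and a 15-subject, two-visit cohort on 20×20×8 grids with two 4-slice
segments at SNR 45. "Interior" truths for round-trip checks sit at least 5%
of each range inside the bounds and satisfy f ≥ 0.02 and D* ≥ 10·D, which
guarantees the time-scale separation the segmented estimators assume.

## Known limitations

* The high-b cutoff (200 s/mm²) is fixed, not evaluated as a design variable.
* The Bayesian prior/estimator choices are declared in configuration;
  alternative published Bayesian IVIM implementations may differ in prior
  structure and point-estimate convention.
* WS-CV has two legitimate formulations; the RMS-of-CVs form is the default
  and the pooled form a documented alternative.
* ICC is undefined for zero-variance tables and returned as a flagged NaN.
* The slice-to-segment assignment is user-supplied anatomy; it cannot be
  derived from the data.
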