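# ivimfit

Quantification of perfusion and diffusion in skeletal muscle from
intravoxel incoherent motion (IVIM) diffusion-weighted MRI.

Resting muscle perfuses slowly, so its IVIM signal is dominated by tissue
diffusion with a small, fast-decaying vascular component. How that signal is
fitted — jointly, in segmented stages, or by Bayesian inference — changes the
parameter values and their test–retest stability. `ivimfit` implements the
full analysis chain needed to study this: the signal model, four fitting
strategies, a voxelwise image-processing pipeline with physically motivated
exclusion rules, within-subject repeatability statistics, a Monte Carlo
simulation that scores each fitter against known ground truth across SNR, and
a synthetic phantom generator so everything can be exercised without scanner
data. It is aimed at researchers analyzing muscle (e.g. lumbar paraspinal)
diffusion protocols and at methodologists comparing IVIM fitting strategies.

## Model

The normalized diffusion-weighted signal at weighting *b* (s/mm²) follows the
bi-exponential IVIM equation

```
S(b) / S0 = f · exp(−b·D*) + (1 − f) · exp(−b·D)
```

with perfusion fraction *f*, pseudo-diffusion coefficient *D\** (blood moving
through randomly oriented capillaries) and diffusion coefficient *D*; the
composite *f·D\** is carried as a derived perfusion index. Fits share box
constraints f ∈ [0, 0.5], D\* ∈ [1.5, 500]×10⁻³ mm²/s, D ∈ [0, 2.5]×10⁻³
mm²/s, and the segmented fits treat b > 200 s/mm² as the diffusion-only
regime.

Four estimators are provided:

| tag     | strategy |
|---------|----------|
| `nlls1` | one-step bounded NLLS, (f, D\*, D) jointly |
| `nlls2` | D from an NLLS mono-exponential fit (free offset A) to high-b shells, then f, D\* from all shells |
| `nlls3` | D and intercept from a log-linear high-b fit, f = 1 − exp(intercept), then D\* alone |
| `bayes` | posterior mean under uniform box priors, Gaussian likelihood with the noise scale marginalized (MCMC or dense-grid engine) |

Agreement between truth and estimate in simulations is scored by the
two-way random-effects, absolute-agreement, single-measure intraclass
correlation ICC(2,1); repeatability of in-vivo-style analyses by the
within-subject coefficient of variation (WS-CV, root-mean-square of
per-subject CVs).

## Worked example

Fit one noisy decay curve (typical resting paraspinal parameters, SNR 50)
with all four methods:

```python
import numpy as np
from ivimfit import (DecayCurve, PROTOCOL_B_VALUES, IVIMParams,
                     ivim_signal, fit_all_methods)

rng = np.random.default_rng(0)
truth = IVIMParams(f=0.11, Dstar=28.4e-3, D=1.36e-3)
signal = ivim_signal(truth, PROTOCOL_B_VALUES) + rng.normal(0, 1/50, 13)
curve = DecayCurve(PROTOCOL_B_VALUES, signal)

for tag, r in fit_all_methods(curve).items():
    p = r.params
    print(f"{tag:6s} f={p.f:.3f}  D*={p.Dstar*1e3:5.1f}e-3  D={p.D*1e3:.2f}e-3  "
          f"fD*={p.fDstar*1e3:.2f}e-3  resid={r.resid_sq_norm:.1e}")
```

```
nlls1  f=0.076  D*= 42.7e-3  D=1.52e-3  fD*=3.25e-3  resid=2.5e-03
nlls2  f=0.065  D*= 52.0e-3  D=1.57e-3  fD*=3.38e-3  resid=2.8e-03
nlls3  f=0.049  D*= 76.4e-3  D=1.58e-3  fD*=3.78e-3  resid=3.6e-03
bayes  f=0.068  D*=112.7e-3  D=1.54e-3  fD*=7.72e-3  resid=3.6e-03
```

One noisy single-voxel curve scatters every estimator well away from the
truth — exactly why D\* is the hardest parameter to pin down and why the
one-step fit, with the most freedom, always attains the smallest residual.
Averaging over an ROI, or over the thousands of draws in the simulation,
recovers the parameters tightly.

The same machinery is scriptable from the shell:

```
ivimfit phantom  --seed 5 --shape 48 48 22 --snr 46.6 --out runs/phantom
ivimfit fit      --series runs/phantom/series --mask runs/phantom/mask --out runs/fit
ivimfit simulate --n 500 --snr 40 --seed 7 --out runs/sim
ivimfit repeatability --fits runs/fits.csv --grouping temporal --out runs/rep
```

Every output directory contains the exact `config.yaml` that produced it.

## Layout

- `ivimfit.model` — signal equation, parameter container, fit bounds
- `ivimfit.fitters` — the four estimators
- `ivimfit.simulate` — Monte Carlo design, noise model, ICC(2,1)
- `ivimfit.pipeline` — median filtering, direction/repeat averaging, SNR
  estimation, voxelwise fitting, exclusion masking
- `ivimfit.repeatability` — WS-CV and the temporal / spatial / inter-session
  analyses
- `ivimfit.phantom` — synthetic acquisitions and cohorts
- `ivimfit.io`, `ivimfit.config`, `ivimfit.cli` — NIfTI/bval/bvec round-trips,
  YAML run configs, command-line drivers

See `docs/methods.md` for the modeling assumptions, numerical choices and
known limitations.
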