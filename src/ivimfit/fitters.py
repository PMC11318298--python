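"""Parameter-estimation strategies for the bi-exponential IVIM model.

Four fitters operate on a :class:`~ivimfit.model.DecayCurve` under shared
:class:`~ivimfit.model.FitBounds`:

``nlls1``
    One-step bounded non-linear least squares: (f, D*, D) jointly.
``nlls2``
    Two-step segmented fit: D from an NLLS mono-exponential fit (with free
    offset A) to the high-b shells, then f and D* from all shells with D fixed.
``nlls3``
    Three-step segmented fit: D and the intercept from an ordinary
    least-squares line through log-signal at high b; f = 1 - exp(intercept)
    (the diffusion-only line extrapolated to b = 0 carries the tissue fraction
    1 - f); finally D* alone by bounded NLLS over all shells.
``bayes``
    Bayesian estimation under uniform box priors and a Gaussian likelihood
    whose noise scale is marginalized with a Jeffreys prior, which reduces the
    log marginal posterior to -(n/2) * ln SSR(f, D*, D).  The point estimate
    is the marginal posterior mean, computed either by affine-invariant MCMC
    or on a dense grid (fast, vectorizable across many curves).

NLLS fits start deterministically (box midpoint for the one-step fit; f = 0.1
and D* = 20e-3 mm^2/s for the segmented steps), so repeated runs are
bit-identical.  A solution sitting exactly on a bound is flagged per
parameter, which downstream masking uses as an exclusion reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import (
    PARAM_NAMES,
    DecayCurve,
    FitBounds,
    IVIMParams,
    _ivim_model,
    residual_norm,
)

__all__ = [
    "METHOD_TAGS",
    "NLLSSettings",
    "BayesSettings",
    "FitResult",
    "fit_1step",
    "fit_2step",
    "fit_3step",
    "fit_bayesian",
    "fit_all_methods",
    "bayes_grid_batch",
]

METHOD_TAGS = ("nlls1", "nlls2", "nlls3", "bayes")

# Equality to a bound is decided after optimizer projection, to this tolerance.
_BOUNDARY_ATOL = 1e-12


@dataclass(frozen=True)
class NLLSSettings:
    """Deterministic NLLS configuration (documented so runs are reproducible).

    ``ftol`` is the relative tolerance on the objective, ``max_iter`` bounds
    the number of model evaluations.  ``f_init``/``Dstar_init`` seed the
    segmented steps.
    """

    ftol: float = 1e-10
    xtol: float = 1e-12
    max_iter: int = 1000
    f_init: float = 0.1
    Dstar_init: float = 20e-3


@dataclass(frozen=True)
class BayesSettings:
    """Sampler configuration for the Bayesian fitter.

    engine : "mcmc" (affine-invariant ensemble sampler) or "grid" (dense
    evaluation of the marginal posterior; the batched workhorse for large
    simulations).  ``n_walkers * n_keep`` post-burn-in samples feed the
    posterior mean (default 24 * 200 = 4800).  ``min_ess`` is the effective
    sample size below which ``converged`` is declared False.
    """

    engine: str = "mcmc"
    n_walkers: int = 24
    n_burn: int = 400
    n_keep: int = 200
    seed: int = 0
    grid_shape: tuple = (40, 48, 40)
    min_ess: float = 50.0


@dataclass
class FitResult:
    """One fitter's answer for one curve.

    ``params`` is None when the fit failed outright (``error`` then carries
    the reason).  ``at_boundary`` flags, per parameter, solutions equal to a
    box constraint.  ``intercept_A`` is the high-b offset of the segmented
    fits; ``posterior_sd`` the marginal posterior SDs of the Bayesian fit.
    """

    method: str
    params: IVIMParams | None
    resid_sq_norm: float
    at_boundary: dict = field(default_factory=dict)
    converged: bool = True
    intercept_A: float | None = None
    posterior_sd: dict | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.params is not None and self.converged

    @property
    def any_at_boundary(self) -> bool:
        return any(self.at_boundary.values())


def _boundary_flags(x: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> dict:
    return {
        name: bool(
            abs(x[i] - lower[i]) <= _BOUNDARY_ATOL or abs(x[i] - upper[i]) <= _BOUNDARY_ATOL
        )
        for i, name in enumerate(PARAM_NAMES)
    }


def _least_squares(fun, x0, lo, hi, settings: NLLSSettings):
    return optimize.least_squares(
        fun,
        np.clip(x0, lo, hi),
        bounds=(lo, hi),
        method="trf",
        ftol=settings.ftol,
        xtol=settings.xtol,
        gtol=1e-12,
        max_nfev=settings.max_iter,
    )


def fit_1step(
    curve: DecayCurve, bounds: FitBounds | None = None, settings: NLLSSettings | None = None
) -> FitResult:
    """Joint bounded NLLS over (f, D*, D), started at the box midpoint."""
    bounds = bounds or FitBounds()
    settings = settings or NLLSSettings()
    if curve.n_points < 4:
        raise ValueError("one-step fit needs at least 4 points")
    b, y = curve.b_values, curve.signal
    lo, hi = bounds.lower, bounds.upper

    res = _least_squares(lambda x: _ivim_model(*x, b) - y, bounds.midpoint, lo, hi, settings)
    x = np.clip(res.x, lo, hi)
    params = IVIMParams.from_array(x)
    return FitResult(
        method="nlls1",
        params=params,
        resid_sq_norm=residual_norm(curve, params),
        at_boundary=_boundary_flags(x, lo, hi),
        converged=bool(res.success),
    )


def _high_b_subset(curve: DecayCurve, bounds: FitBounds):
    mask = bounds.high_b_mask(curve.b_values)
    if mask.sum() < 2:
        raise ValueError(
            f"segmented fitting needs >= 2 b-values above the cutoff {bounds.high_b_cutoff}"
        )
    return curve.b_values[mask], curve.signal[mask]


def fit_2step(
    curve: DecayCurve, bounds: FitBounds | None = None, settings: NLLSSettings | None = None
) -> FitResult:
    """Segmented fit: D (with offset A) from high b, then f and D* from all b."""
    bounds = bounds or FitBounds()
    settings = settings or NLLSSettings()
    b, y = curve.b_values, curve.signal
    b_hi, y_hi = _high_b_subset(curve, bounds)
    d_lo, d_hi = bounds.D_range

    # Step A: A*exp(-b*D) on the diffusion-only shells.  A is stored but not
    # reused downstream; only D is carried into step B.
    res_a = _least_squares(
        lambda x: x[0] * np.exp(-b_hi * x[1]) - y_hi,
        np.array([1.0, 0.5 * (d_lo + d_hi)]),
        np.array([1e-8, d_lo]),
        np.array([2.0, d_hi]),
        settings,
    )
    A, D = res_a.x

    # Step B: with D fixed, fit (f, D*) to every shell.
    lo2 = np.array([bounds.f_range[0], bounds.Dstar_range[0]])
    hi2 = np.array([bounds.f_range[1], bounds.Dstar_range[1]])
    res_b = _least_squares(
        lambda x: _ivim_model(x[0], x[1], D, b) - y,
        np.array([settings.f_init, settings.Dstar_init]),
        lo2,
        hi2,
        settings,
    )
    f, Dstar = np.clip(res_b.x, lo2, hi2)
    x = np.array([f, Dstar, np.clip(D, d_lo, d_hi)])
    params = IVIMParams.from_array(x)
    return FitResult(
        method="nlls2",
        params=params,
        resid_sq_norm=residual_norm(curve, params),
        at_boundary=_boundary_flags(x, bounds.lower, bounds.upper),
        converged=bool(res_a.success and res_b.success),
        intercept_A=float(A),
    )


def fit_3step(
    curve: DecayCurve, bounds: FitBounds | None = None, settings: NLLSSettings | None = None
) -> FitResult:
    """Segmented fit: log-linear D and intercept, f from the intercept, then D*.

    The ordinary least-squares line through ln S at high b estimates the
    diffusion-only decay ln[(1-f) * exp(-b*D)]; its slope is -D and its b = 0
    extrapolation exp(intercept) = 1 - f.  An intercept above 1 (f < 0) or a
    positive slope is clamped to the nearest bound and flagged.
    """
    bounds = bounds or FitBounds()
    settings = settings or NLLSSettings()
    b, y = curve.b_values, curve.signal
    b_hi, y_hi = _high_b_subset(curve, bounds)
    if np.any(y_hi <= 0):
        raise ValueError("three-step fit requires positive high-b signal (log undefined)")

    slope, intercept = np.polyfit(b_hi, np.log(y_hi), 1)
    A = float(np.exp(intercept))
    d_lo, d_hi = bounds.D_range
    f_lo, f_hi = bounds.f_range
    D = float(np.clip(-slope, d_lo, d_hi))
    f = float(np.clip(1.0 - A, f_lo, f_hi))

    # Step C: with f and D fixed, bounded 1-D NLLS for D* over every shell.
    ds_lo, ds_hi = bounds.Dstar_range
    res_c = _least_squares(
        lambda x: _ivim_model(f, x[0], D, b) - y,
        np.array([settings.Dstar_init]),
        np.array([ds_lo]),
        np.array([ds_hi]),
        settings,
    )
    Dstar = float(np.clip(res_c.x[0], ds_lo, ds_hi))
    x = np.array([f, Dstar, D])
    params = IVIMParams.from_array(x)
    return FitResult(
        method="nlls3",
        params=params,
        resid_sq_norm=residual_norm(curve, params),
        at_boundary=_boundary_flags(x, bounds.lower, bounds.upper),
        converged=bool(res_c.success),
        intercept_A=A,
    )


# ---------------------------------------------------------------------------
# Bayesian fitter
# ---------------------------------------------------------------------------

def _log_marginal_post(theta, b, y, lo, hi):
    if np.any(theta < lo) or np.any(theta > hi):
        return -np.inf
    r = _ivim_model(theta[0], theta[1], theta[2], b) - y
    ssr = float(r @ r)
    return -0.5 * b.size * np.log(ssr + 1e-300)


def _grid_axes(bounds: FitBounds, shape):
    nf, ns, nd = shape
    return (
        np.linspace(*bounds.f_range, nf),
        np.linspace(*bounds.Dstar_range, ns),
        np.linspace(*bounds.D_range, nd),
    )


def bayes_grid_batch(
    signals: np.ndarray,
    b_values: np.ndarray,
    bounds: FitBounds | None = None,
    shape: tuple = (40, 48, 40),
    chunk: int = 128,
):
    """Marginal posterior means and SDs for many curves on a dense grid.

    Parameters
    ----------
    signals : (m, n_b) array of normalized signals.
    b_values : (n_b,) array.
    shape : grid resolution along (f, D*, D).

    Returns
    -------
    means, sds : (m, 3) arrays ordered (f, D*, D).

    The marginal posterior over the box is proportional to SSR^(-n/2)
    (Gaussian likelihood, Jeffreys prior on the noise scale, flat box prior);
    posterior moments are grid-weighted averages.  Cross terms are computed by
    one matrix product per chunk, so thousands of curves take seconds.
    """
    bounds = bounds or FitBounds()
    b = np.asarray(b_values, dtype=float)
    Y = np.atleast_2d(np.asarray(signals, dtype=float))
    n = b.size
    f_ax, ds_ax, d_ax = _grid_axes(bounds, shape)

    e_s = np.exp(-np.outer(ds_ax, b))        # (ns, n)
    e_d = np.exp(-np.outer(d_ax, b))         # (nd, n)
    F = f_ax[:, None, None, None]
    G = F * e_s[None, :, None, :] + (1.0 - F) * e_d[None, None, :, :]
    G = G.reshape(-1, n)                      # (n_grid, n)
    gg = np.einsum("ij,ij->i", G, G)          # ||model||^2 per grid point
    coords = np.stack(
        [a.reshape(-1) for a in np.meshgrid(f_ax, ds_ax, d_ax, indexing="ij")], axis=1
    )                                          # (n_grid, 3)

    m = Y.shape[0]
    means = np.empty((m, 3))
    sds = np.empty((m, 3))
    for start in range(0, m, chunk):
        Yc = Y[start : start + chunk]                    # (c, n)
        ssr = gg[:, None] - 2.0 * (G @ Yc.T) + np.einsum("ij,ij->i", Yc, Yc)[None, :]
        np.clip(ssr, 1e-30, None, out=ssr)
        logw = -0.5 * n * np.log(ssr)
        logw -= logw.max(axis=0, keepdims=True)
        w = np.exp(logw)
        w /= w.sum(axis=0, keepdims=True)                # (n_grid, c)
        mu = w.T @ coords                                 # (c, 3)
        second = w.T @ (coords**2)
        means[start : start + chunk] = mu
        sds[start : start + chunk] = np.sqrt(np.maximum(second - mu**2, 0.0))
    return means, sds


def _fit_bayes_grid(curve, bounds, settings) -> FitResult:
    means, sds = bayes_grid_batch(
        curve.signal[None, :], curve.b_values, bounds, shape=settings.grid_shape
    )
    params = IVIMParams.from_array(np.clip(means[0], bounds.lower, bounds.upper))
    return FitResult(
        method="bayes",
        params=params,
        resid_sq_norm=residual_norm(curve, params),
        at_boundary=_boundary_flags(means[0], bounds.lower, bounds.upper),
        converged=True,
        posterior_sd=dict(zip(PARAM_NAMES, sds[0])),
    )


def _fit_bayes_mcmc(curve, bounds, settings) -> FitResult:
    import logging

    import emcee

    logging.getLogger("emcee.autocorr").setLevel(logging.ERROR)

    b, y = curve.b_values, curve.signal
    lo, hi = bounds.lower, bounds.upper
    rng = np.random.default_rng(settings.seed)

    # Walkers start in a small ball around a quick NLLS point estimate (falling
    # back to the box midpoint), a standard initialization for ensemble MCMC.
    try:
        center = fit_1step(curve, bounds).params.as_array()
    except Exception:
        center = bounds.midpoint
    span = hi - lo
    p0 = center[None, :] + 0.01 * span[None, :] * rng.standard_normal((settings.n_walkers, 3))
    p0 = np.clip(p0, lo + 1e-9 * span, hi - 1e-9 * span)

    sampler = emcee.EnsembleSampler(
        settings.n_walkers, 3, _log_marginal_post, args=(b, y, lo, hi)
    )
    sampler.random_state = np.random.RandomState(settings.seed).get_state()
    sampler.run_mcmc(p0, settings.n_burn + settings.n_keep, progress=False)
    chain = sampler.get_chain(discard=settings.n_burn, flat=True)

    mean = chain.mean(axis=0)
    sd = chain.std(axis=0)
    n_samples = chain.shape[0]
    try:
        tau = sampler.get_autocorr_time(discard=settings.n_burn, quiet=True)
        ess = n_samples / max(float(np.nanmax(2.0 * tau)), 1.0)
    except Exception:
        ess = float(n_samples)
    params = IVIMParams.from_array(np.clip(mean, lo, hi))
    return FitResult(
        method="bayes",
        params=params,
        resid_sq_norm=residual_norm(curve, params),
        at_boundary=_boundary_flags(mean, lo, hi),
        converged=bool(np.isfinite(ess) and ess >= settings.min_ess),
        posterior_sd=dict(zip(PARAM_NAMES, sd)),
    )


def fit_bayesian(
    curve: DecayCurve, bounds: FitBounds | None = None, settings: BayesSettings | None = None
) -> FitResult:
    """Posterior-mean estimate of (f, D*, D) under uniform box priors.

    The Gaussian noise scale is marginalized under a Jeffreys prior, so no
    noise estimate is required.  ``settings.engine`` selects affine-invariant
    MCMC (default) or dense-grid integration; both are deterministic given the
    configured seed (the grid exactly so).
    """
    bounds = bounds or FitBounds()
    settings = settings or BayesSettings()
    if settings.engine == "grid":
        return _fit_bayes_grid(curve, bounds, settings)
    if settings.engine == "mcmc":
        return _fit_bayes_mcmc(curve, bounds, settings)
    raise ValueError(f"unknown Bayesian engine {settings.engine!r}")


def fit_all_methods(
    curve: DecayCurve,
    bounds: FitBounds | None = None,
    nlls_settings: NLLSSettings | None = None,
    bayes_settings: BayesSettings | None = None,
    methods=METHOD_TAGS,
) -> dict:
    """Run every requested fitter; per-method failures never abort the batch."""
    bounds = bounds or FitBounds()
    dispatch = {
        "nlls1": lambda: fit_1step(curve, bounds, nlls_settings),
        "nlls2": lambda: fit_2step(curve, bounds, nlls_settings),
        "nlls3": lambda: fit_3step(curve, bounds, nlls_settings),
        "bayes": lambda: fit_bayesian(curve, bounds, bayes_settings),
    }
    out = {}
    for tag in methods:
        try:
            out[tag] = dispatch[tag]()
        except KeyError:
            raise ValueError(f"unknown method tag {tag!r}") from None
        except Exception as exc:  # recorded, not propagated
            out[tag] = FitResult(
                method=tag,
                params=None,
                resid_sq_norm=float("nan"),
                converged=False,
                error=str(exc),
            )
    return out
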