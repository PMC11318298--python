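"""Bi-exponential signal model for intravoxel incoherent motion (IVIM) MRI.

Diffusion-weighted signal in perfused tissue decays with two apparent
compartments: molecular diffusion of tissue water (coefficient ``D``) and
pseudo-diffusion of blood moving through randomly oriented capillaries
(coefficient ``D*``, typically 10-100x faster than ``D``).  The normalized
signal as a function of diffusion weighting ``b`` (s/mm^2) is

    S(b) / S0 = f * exp(-b * D*) + (1 - f) * exp(-b * D)

where ``f`` is the perfusion fraction, the share of voxel signal arising from
the intravascular compartment.  The composite ``f*D*`` is carried as a derived
quantity.

All diffusion coefficients are handled internally in mm^2/s (e.g. ``1.36e-3``);
conversion to the conventional reporting unit of 1e-3 mm^2/s happens only at
the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PROTOCOL_B_VALUES",
    "IVIMParams",
    "FitBounds",
    "DecayCurve",
    "ivim_signal",
    "mono_exp_signal",
    "residual_norm",
]

#: Diffusion weightings (s/mm^2) of the reference lumbar-spine acquisition.
PROTOCOL_B_VALUES = np.array(
    [0.0, 10.0, 20.0, 40.0, 70.0, 110.0, 160.0, 220.0, 300.0, 400.0, 500.0, 600.0, 700.0]
)

PARAM_NAMES = ("f", "Dstar", "D")


def _ivim_model(f, Dstar, D, b):
    """Vectorized model evaluation without container overhead (internal)."""
    return f * np.exp(-np.asarray(b) * Dstar) + (1.0 - f) * np.exp(-np.asarray(b) * D)


@dataclass(frozen=True)
class IVIMParams:
    """The IVIM unknowns: perfusion fraction and the two diffusion coefficients.

    Parameters
    ----------
    f : float
        Perfusion fraction, dimensionless, in [0, 1].
    Dstar : float
        Pseudo-diffusion coefficient, mm^2/s.
    D : float
        Diffusion coefficient, mm^2/s.

    The product ``fDstar`` is always recomputed from ``f`` and ``Dstar``; it is
    never stored independently, so the identity ``fDstar == f * Dstar`` holds
    under every construction path.
    """

    f: float
    Dstar: float
    D: float

    def __post_init__(self):
        vals = (self.f, self.Dstar, self.D)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"IVIM parameters must be finite, got {vals}")
        if any(v < 0 for v in vals):
            raise ValueError(f"IVIM parameters must be non-negative, got {vals}")

    @property
    def fDstar(self) -> float:
        """Perfusion-related composite f*D*, mm^2/s (derived, never stored)."""
        return self.f * self.Dstar

    def as_array(self) -> np.ndarray:
        """Return (f, D*, D) as a float array."""
        return np.array([self.f, self.Dstar, self.D], dtype=float)

    @classmethod
    def from_array(cls, x) -> "IVIMParams":
        f, Dstar, D = np.asarray(x, dtype=float)
        return cls(float(f), float(Dstar), float(D))


@dataclass(frozen=True)
class FitBounds:
    """Box constraints shared by every fitting strategy.

    Defaults follow the convention for resting skeletal muscle: f in [0, 0.5],
    D* in [1.5e-3, 500e-3] mm^2/s, D in [0, 2.5e-3] mm^2/s.  The D* floor is
    set just above the typical muscle D (~1.4e-3 mm^2/s) to discourage the two
    decay regimes from swapping roles; the admissible ranges still overlap at
    their edges.  ``high_b_cutoff`` separates the diffusion-only regime
    used by the segmented fits; the cutoff is strict (b > cutoff), so with the
    default 200 s/mm^2 the b = 220 s/mm^2 shell is part of the high-b set.
    """

    f_range: tuple = (0.0, 0.5)
    Dstar_range: tuple = (1.5e-3, 500e-3)
    D_range: tuple = (0.0, 2.5e-3)
    high_b_cutoff: float = 200.0

    def __post_init__(self):
        for name in ("f_range", "Dstar_range", "D_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} must be a finite interval with lo < hi, got ({lo}, {hi})")
        if self.high_b_cutoff < 0:
            raise ValueError("high_b_cutoff must be non-negative")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.f_range[0], self.Dstar_range[0], self.D_range[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.f_range[1], self.Dstar_range[1], self.D_range[1]])

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def contains(self, params: "IVIMParams") -> bool:
        x = params.as_array()
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))

    def high_b_mask(self, b_values) -> np.ndarray:
        """Boolean mask of the diffusion-only (high-b) shells."""
        return np.asarray(b_values) > self.high_b_cutoff


@dataclass
class DecayCurve:
    """Paired b-values and normalized signal S(b)/S0 — the input of every fit.

    ``b_values`` must be strictly increasing with the first element 0 so the
    normalization reference is part of the curve.  Use :meth:`from_raw` to
    build a curve from unnormalized intensities (divides by the b = 0 value,
    making ``signal[0] == 1`` exactly); curves carrying measurement noise on
    every point, including b = 0, may be constructed directly.
    """

    b_values: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.b_values.ndim != 1 or self.signal.ndim != 1:
            raise ValueError("b_values and signal must be 1-D")
        if self.b_values.shape != self.signal.shape:
            raise ValueError(
                f"length mismatch: {self.b_values.size} b-values vs {self.signal.size} signal points"
            )
        if self.b_values.size < 2:
            raise ValueError("a decay curve needs at least 2 points")
        if self.b_values[0] != 0.0:
            raise ValueError("first b-value must be 0 (normalization reference)")
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")

    @classmethod
    def from_raw(cls, b_values, raw_signal) -> "DecayCurve":
        """Normalize raw intensities by their b = 0 value."""
        raw = np.asarray(raw_signal, dtype=float)
        if raw[0] <= 0:
            raise ValueError("b=0 intensity must be positive for normalization")
        return cls(b_values, raw / raw[0])

    @property
    def n_points(self) -> int:
        return int(self.b_values.size)


def ivim_signal(params: IVIMParams, b) -> np.ndarray | float:
    """Evaluate the bi-exponential IVIM model at diffusion weighting(s) ``b``.

    Returns ``f*exp(-b*D*) + (1-f)*exp(-b*D)`` elementwise; a scalar ``b``
    yields a scalar.  Negative ``b`` is rejected.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    out = _ivim_model(params.f, params.Dstar, params.D, b)
    return float(out) if out.ndim == 0 else out


def mono_exp_signal(A: float, D: float, b) -> np.ndarray | float:
    """Single-compartment decay ``A*exp(-b*D)`` with intercept ``A``.

    This is the model of the high-b regime where pseudo-diffusion has decayed
    to nothing; ``A`` absorbs the tissue fraction (ideally ``1 - f``).
    """
    if A <= 0:
        raise ValueError("offset A must be positive")
    if D < 0:
        raise ValueError("D must be non-negative")
    out = A * np.exp(-np.asarray(b, dtype=float) * D)
    return float(out) if out.ndim == 0 else out


def residual_norm(curve: DecayCurve, params: IVIMParams) -> float:
    """Squared Euclidean norm of (measured - modeled) signal.

    Zero iff the model passes through every point of the curve.  This squared
    quantity (not its root) is the per-fit figure recorded alongside every
    parameter estimate.
    """
    r = curve.signal - ivim_signal(params, curve.b_values)
    return float(r @ r)
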