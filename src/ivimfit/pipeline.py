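"""Voxel-level processing of 4D diffusion-weighted series.

The chain mirrors the analysis of a multi-b-value, multi-direction,
multi-repeat acquisition of the lumbar paraspinal muscles:

    2D 3x3 median filter -> average over diffusion directions
    -> (average over repeats) -> normalize by the voxel's own b=0 signal
    -> fit voxelwise / ROI-wise -> exclusion masking

Voxels are excluded from final maps when (a) noise or motion pushes the first
diffusion-weighted shell above the b = 0 shell, or (b) a fitted parameter sits
exactly on a box constraint (per method).  Both reasons are recorded per
voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitters import (
    METHOD_TAGS,
    BayesSettings,
    FitResult,
    NLLSSettings,
    bayes_grid_batch,
    fit_1step,
    fit_2step,
    fit_3step,
    fit_bayesian,
)
from .model import PARAM_NAMES, DecayCurve, FitBounds, IVIMParams

__all__ = [
    "IVIMSeries",
    "ROIMask",
    "ParameterMaps",
    "REASON_CODES",
    "median_filter_2d",
    "average_directions_and_repeats",
    "estimate_snr",
    "roi_mean_curve",
    "fit_voxelwise",
    "build_inclusion_mask",
    "process_series",
]

#: Inclusion-mask reason codes.
REASON_CODES = {
    "included": 0,
    "outside_roi": 1,
    "physicality": 2,
    "boundary": 3,
    "fit_failed": 4,
}

MAP_PARAMS = ("f", "Dstar", "D", "fDstar")


@dataclass
class IVIMSeries:
    """4D voxel array plus per-volume acquisition metadata.

    ``data`` is indexed (x, y, slice, volume); ``bvals``, ``dirs`` and
    ``reps`` give each volume's diffusion weighting (s/mm^2), direction index
    (1-based; 0 marks direction-averaged volumes) and repeat index (1-based;
    0 marks repeat-averaged volumes).  Every (b, direction, repeat) triple
    must be unique.
    """

    data: np.ndarray
    bvals: np.ndarray
    dirs: np.ndarray
    reps: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("series data must be 4-D (x, y, slice, volume)")
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.dirs = np.asarray(self.dirs, dtype=int)
        self.reps = np.asarray(self.reps, dtype=int)
        nvol = self.data.shape[3]
        for name in ("bvals", "dirs", "reps"):
            if getattr(self, name).shape != (nvol,):
                raise ValueError(
                    f"{name} must have one entry per volume ({nvol}), got {getattr(self, name).shape}"
                )
        triples = list(zip(self.bvals, self.dirs, self.reps))
        if len(set(triples)) != len(triples):
            raise ValueError("duplicate (b, direction, repeat) volume in series metadata")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape3d(self) -> tuple:
        return self.data.shape[:3]

    @property
    def unique_bvals(self) -> np.ndarray:
        return np.unique(self.bvals)

    def volume(self, b: float, direction: int = 0, repeat: int = 0) -> np.ndarray:
        """Return the 3D volume with the given metadata triple."""
        sel = (self.bvals == b) & (self.dirs == direction) & (self.reps == repeat)
        idx = np.flatnonzero(sel)
        if idx.size != 1:
            raise KeyError(f"no unique volume with (b={b}, dir={direction}, rep={repeat})")
        return self.data[..., idx[0]]


@dataclass
class ROIMask:
    """Labeled voxel mask with an optional slice-to-spinal-segment map.

    ``labels`` is an integer array on the series grid; ``label_map`` names the
    integer codes (``background`` must map to 0).  The synthetic label
    ``paraspinal`` denotes the union of the muscle labels (any label other
    than background/body).  ``segment_map`` assigns slice indices (0-based) to
    segment names such as "L1".."L5"; when provided, each segment must own
    exactly 4 slices, matching slabs spanning one vertebral body.
    """

    labels: np.ndarray
    label_map: dict
    segment_map: dict | None = None

    NON_MUSCLE = ("background", "body")

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.label_map.get("background", 0) != 0:
            raise ValueError("label_map must map 'background' to 0")
        if self.segment_map is not None:
            counts = {}
            for _sl, seg in self.segment_map.items():
                counts[seg] = counts.get(seg, 0) + 1
            bad = {seg: c for seg, c in counts.items() if c != 4}
            if bad:
                raise ValueError(f"each spinal segment needs exactly 4 slices, got {bad}")

    @property
    def muscle_labels(self) -> list:
        return [name for name in self.label_map if name not in self.NON_MUSCLE]

    def mask_for(self, label: str) -> np.ndarray:
        """Boolean mask for one label, or for the 'paraspinal' union."""
        if label == "paraspinal":
            out = np.zeros(self.labels.shape, dtype=bool)
            for name in self.muscle_labels:
                out |= self.labels == self.label_map[name]
            return out
        if label not in self.label_map:
            raise KeyError(f"unknown ROI label {label!r}")
        return self.labels == self.label_map[label]

    def slices_of(self, segment: str) -> list:
        if self.segment_map is None:
            raise ValueError("no segment map supplied")
        return sorted(sl for sl, seg in self.segment_map.items() if seg == segment)


@dataclass
class ParameterMaps:
    """Per-method voxel maps of f, D*, D, fD* and the squared residual norm.

    ``values[method][param]`` are float maps (NaN where not computed);
    ``at_boundary`` / ``failed`` are boolean maps; ``inclusion[method]`` holds
    the per-voxel reason code once :func:`build_inclusion_mask` has run.
    """

    shape: tuple
    affine: np.ndarray
    values: dict = field(default_factory=dict)
    resid: dict = field(default_factory=dict)
    at_boundary: dict = field(default_factory=dict)
    failed: dict = field(default_factory=dict)
    inclusion: dict = field(default_factory=dict)

    def add_method(self, method: str):
        self.values[method] = {p: np.full(self.shape, np.nan) for p in MAP_PARAMS}
        self.resid[method] = np.full(self.shape, np.nan)
        self.at_boundary[method] = np.zeros(self.shape, dtype=bool)
        self.failed[method] = np.zeros(self.shape, dtype=bool)

    def set_voxel(self, method: str, idx: tuple, result: FitResult):
        if result.params is None:
            self.failed[method][idx] = True
            return
        p = result.params
        vals = self.values[method]
        vals["f"][idx] = p.f
        vals["Dstar"][idx] = p.Dstar
        vals["D"][idx] = p.D
        vals["fDstar"][idx] = p.fDstar
        self.resid[method][idx] = result.resid_sq_norm
        self.at_boundary[method][idx] = result.any_at_boundary

    def included_mask(self, method: str) -> np.ndarray:
        if method not in self.inclusion:
            raise KeyError(f"inclusion mask not built for {method!r}")
        return self.inclusion[method] == REASON_CODES["included"]

    def summary(self, roi: ROIMask, included_only: bool = True) -> pd.DataFrame:
        """Mean/SD per (ROI label, method, parameter) over (included) voxels."""
        rows = []
        roi_labels = ["paraspinal"] + roi.muscle_labels
        for method in self.values:
            base = (
                self.included_mask(method)
                if (included_only and method in self.inclusion)
                else ~self.failed[method]
            )
            for label in roi_labels:
                sel = base & roi.mask_for(label)
                for pname in MAP_PARAMS:
                    vox = self.values[method][pname][sel]
                    vox = vox[np.isfinite(vox)]
                    rows.append(
                        {
                            "roi": label,
                            "method": method,
                            "parameter": pname,
                            "mean": float(np.mean(vox)) if vox.size else float("nan"),
                            "sd": float(np.std(vox, ddof=1)) if vox.size > 1 else float("nan"),
                            "n_voxels": int(vox.size),
                        }
                    )
                res = self.resid[method][sel]
                res = res[np.isfinite(res)]
                rows.append(
                    {
                        "roi": label,
                        "method": method,
                        "parameter": "resid_sq_norm",
                        "mean": float(np.mean(res)) if res.size else float("nan"),
                        "sd": float(np.std(res, ddof=1)) if res.size > 1 else float("nan"),
                        "n_voxels": int(res.size),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Processing operations
# ---------------------------------------------------------------------------

def median_filter_2d(series: IVIMSeries) -> IVIMSeries:
    """In-plane 3x3 median filter applied to every slice of every volume.

    Border voxels use the reduced neighborhood actually inside the slice
    (no padding values are invented); with an even neighbor count the median
    is the midpoint of the two central order statistics.
    """
    nx, ny = series.data.shape[:2]
    if nx < 3 or ny < 3:
        raise ValueError("median filter needs an in-plane grid of at least 3x3")
    padded = np.pad(
        series.data.astype(float), ((1, 1), (1, 1), (0, 0), (0, 0)), constant_values=np.nan
    )
    windows = np.lib.stride_tricks.sliding_window_view(padded, (3, 3), axis=(0, 1))
    filtered = np.nanmedian(windows, axis=(-2, -1))
    return IVIMSeries(filtered, series.bvals, series.dirs, series.reps, series.affine)


def average_directions_and_repeats(series: IVIMSeries, collapse_repeats: bool = True) -> IVIMSeries:
    """Arithmetic mean over encoding directions, optionally over repeats.

    Directions are always collapsed; repeats only when ``collapse_repeats``
    (temporal-stability analyses keep the four repeats separate).  The full
    (b, direction, repeat) grid must be present; a gap raises an error naming
    the missing triple.
    """
    bvals = np.unique(series.bvals)
    dirs = np.unique(series.dirs)
    reps = np.unique(series.reps)
    index = {(b, d, r): i for i, (b, d, r) in enumerate(zip(series.bvals, series.dirs, series.reps))}
    for b in bvals:
        for d in dirs:
            for r in reps:
                if (b, d, r) not in index:
                    raise ValueError(f"missing volume (b={b}, direction={d}, repeat={r})")

    out_vols, out_b, out_r = [], [], []
    rep_groups = [0] if collapse_repeats else list(reps)
    for r in rep_groups:
        for b in bvals:
            if collapse_repeats:
                idx = [index[(b, d, rr)] for d in dirs for rr in reps]
            else:
                idx = [index[(b, d, r)] for d in dirs]
            out_vols.append(series.data[..., idx].mean(axis=-1))
            out_b.append(b)
            out_r.append(r)
    data = np.stack(out_vols, axis=-1)
    return IVIMSeries(
        data,
        np.array(out_b),
        np.zeros(len(out_b), dtype=int),
        np.array(out_r, dtype=int),
        series.affine,
    )


def estimate_snr(b0_volume: np.ndarray, muscle_roi: np.ndarray, background_roi: np.ndarray) -> float:
    """SNR of a b = 0 image: mean(muscle ROI) / SD(background ROI).

    The two ROIs must be non-empty and of equal voxel count (the background
    one sits outside the body).  The plain ratio is reported; no Rayleigh
    correction of the background SD is applied by default, matching the
    convention of reporting SNR directly from magnitude images.
    """
    b0 = np.asarray(b0_volume, dtype=float)
    m = np.asarray(muscle_roi, dtype=bool)
    bg = np.asarray(background_roi, dtype=bool)
    n_m, n_bg = int(m.sum()), int(bg.sum())
    if n_m == 0 or n_bg == 0:
        raise ValueError("both ROIs must be non-empty")
    if n_m != n_bg:
        raise ValueError(f"ROIs must have equal voxel counts, got {n_m} vs {n_bg}")
    sd = float(np.std(b0[bg], ddof=1))
    if sd == 0:
        raise ValueError("background SD is zero; SNR undefined")
    return float(np.mean(b0[m])) / sd


def _curve_from_mean(bvals: np.ndarray, mean_signal: np.ndarray) -> DecayCurve | None:
    order = np.argsort(bvals)
    b = bvals[order]
    s = mean_signal[order]
    if s[0] <= 0:
        return None
    return DecayCurve(b, s / s[0])


def roi_mean_curve(
    series: IVIMSeries,
    roi: ROIMask,
    label: str = "paraspinal",
    scope: str = "whole",
    per_repeat: bool = False,
):
    """ROI-averaged decay curve(s), normalized by the ROI-mean b = 0 signal.

    ``scope='whole'`` averages over the full ROI; ``scope='per_slice'`` yields
    one curve per slice (None where the slice holds no ROI voxels).  With
    ``per_repeat`` the series must still carry separate repeats and one curve
    per repeat is returned (dict keyed by repeat index, or nested dict for
    per-slice scope).
    """
    mask = roi.mask_for(label)
    if not mask.any():
        raise ValueError(f"ROI {label!r} is empty")
    reps = sorted(np.unique(series.reps)) if per_repeat else [None]

    def mean_curve(vmask, rep):
        sel = np.ones(series.bvals.size, dtype=bool) if rep is None else series.reps == rep
        bvals = np.unique(series.bvals[sel])
        means = np.array(
            [series.data[..., (series.bvals == b) & sel][vmask].mean() for b in bvals]
        )
        return _curve_from_mean(bvals, means)

    if scope == "whole":
        out = {rep: mean_curve(mask, rep) for rep in reps}
        return out if per_repeat else out[None]
    if scope == "per_slice":
        n_slices = series.shape3d[2]
        out = {}
        for sl in range(n_slices):
            smask = np.zeros_like(mask)
            smask[:, :, sl] = mask[:, :, sl]
            if not smask.any():
                out[sl] = {rep: None for rep in reps} if per_repeat else None
                continue
            curves = {rep: mean_curve(smask, rep) for rep in reps}
            out[sl] = curves if per_repeat else curves[None]
        return out
    raise ValueError(f"unknown scope {scope!r}")


def _check_collapsed(series: IVIMSeries) -> np.ndarray:
    """Require one volume per b-value; return the volume order sorted by b."""
    if series.unique_bvals.size != series.bvals.size:
        raise ValueError(
            "fit_voxelwise expects a series collapsed to one volume per b-value; "
            "run average_directions_and_repeats first"
        )
    return np.argsort(series.bvals)


def fit_voxelwise(
    series: IVIMSeries,
    roi: ROIMask,
    bounds: FitBounds | None = None,
    methods=("nlls1", "nlls2", "nlls3", "bayes"),
    nlls_settings: NLLSSettings | None = None,
    bayes_settings: BayesSettings | None = None,
) -> ParameterMaps:
    """Fit every ROI voxel's normalized decay with each requested method.

    The series must be preprocessed (filtered, averaged to one volume per
    b-value).  Each voxel is normalized by its own b = 0 signal.  Per-voxel
    failures are recorded with a reason, never aborting the run.  The
    Bayesian method defaults to the batched grid posterior for tractability
    across thousands of voxels.
    """
    bounds = bounds or FitBounds()
    nlls_settings = nlls_settings or NLLSSettings()
    bayes_settings = bayes_settings or BayesSettings(engine="grid")
    order = _check_collapsed(series)
    b = series.bvals[order]
    maps = ParameterMaps(shape=series.shape3d, affine=series.affine)

    vox_idx = np.argwhere(roi.mask_for("paraspinal"))
    signals = np.array([series.data[x, y, z, :][order] for x, y, z in vox_idx], dtype=float)
    b0 = signals[:, 0] if signals.size else np.empty(0)
    valid = b0 > 0
    norm = np.where(valid[:, None], signals / np.where(valid, b0, 1.0)[:, None], np.nan)

    nlls_dispatch = {"nlls1": fit_1step, "nlls2": fit_2step, "nlls3": fit_3step}
    for tag in methods:
        maps.add_method(tag)
        if tag == "bayes" and bayes_settings.engine == "grid" and valid.any():
            means, _ = bayes_grid_batch(norm[valid], b, bounds, shape=bayes_settings.grid_shape)
            j = 0
            for i, (x, y, z) in enumerate(vox_idx):
                if not valid[i]:
                    maps.failed[tag][x, y, z] = True
                    continue
                params = IVIMParams.from_array(np.clip(means[j], bounds.lower, bounds.upper))
                r = norm[i] - (
                    params.f * np.exp(-b * params.Dstar) + (1 - params.f) * np.exp(-b * params.D)
                )
                fr = FitResult(
                    method=tag,
                    params=params,
                    resid_sq_norm=float(r @ r),
                    at_boundary={
                        name: bool(
                            abs(means[j][k] - bounds.lower[k]) <= 1e-12
                            or abs(means[j][k] - bounds.upper[k]) <= 1e-12
                        )
                        for k, name in enumerate(PARAM_NAMES)
                    },
                )
                maps.set_voxel(tag, (x, y, z), fr)
                j += 1
            continue
        for i, (x, y, z) in enumerate(vox_idx):
            if not valid[i]:
                maps.failed[tag][x, y, z] = True
                continue
            try:
                curve = DecayCurve(b, norm[i])
                if tag == "bayes":
                    fr = fit_bayesian(curve, bounds, bayes_settings)
                else:
                    fr = nlls_dispatch[tag](curve, bounds, nlls_settings)
            except Exception:
                maps.failed[tag][x, y, z] = True
                continue
            maps.set_voxel(tag, (x, y, z), fr)
    return maps


def build_inclusion_mask(
    series: IVIMSeries, roi: ROIMask, fits: ParameterMaps, bounds: FitBounds | None = None
):
    """Apply the voxel exclusion rules; store reason codes into ``fits``.

    A voxel is excluded when the first diffusion-weighted shell (the smallest
    non-zero b after averaging) exceeds the b = 0 shell (``physicality``), or
    when any of its fitted parameters for the given method equals a bound
    (``boundary``); failed fits carry ``fit_failed``.  Returns the per-method
    reason arrays and inclusion fractions (over ROI voxels).
    """
    _check_collapsed(series)
    bvals = np.sort(series.unique_bvals)
    if bvals[0] != 0 or bvals.size < 2:
        raise ValueError("series must contain a b=0 shell and at least one DW shell")
    s0 = series.volume(bvals[0])
    s_first = series.volume(bvals[1])
    unphysical = s_first > s0

    roi_mask = roi.mask_for("paraspinal")
    fractions = {}
    for method in fits.values:
        reason = np.full(fits.shape, REASON_CODES["outside_roi"], dtype=np.int8)
        reason[roi_mask] = REASON_CODES["included"]
        reason[roi_mask & unphysical] = REASON_CODES["physicality"]
        bnd = roi_mask & ~unphysical & fits.at_boundary[method]
        reason[bnd] = REASON_CODES["boundary"]
        fail = roi_mask & ~unphysical & fits.failed[method]
        reason[fail] = REASON_CODES["fit_failed"]
        fits.inclusion[method] = reason
        n_roi = int(roi_mask.sum())
        fractions[method] = (
            float((reason[roi_mask] == REASON_CODES["included"]).sum() / n_roi) if n_roi else np.nan
        )
    return fits.inclusion, fractions


def process_series(
    series: IVIMSeries,
    roi: ROIMask,
    bounds: FitBounds | None = None,
    methods=("nlls1", "nlls2", "nlls3", "bayes"),
    nlls_settings: NLLSSettings | None = None,
    bayes_settings: BayesSettings | None = None,
):
    """Full chain: median filter -> average -> voxelwise fit -> exclusions.

    Returns ``(maps, summary, inclusion_fractions)`` where ``summary`` is the
    mean/SD table over included voxels per ROI label.
    """
    bounds = bounds or FitBounds()
    filtered = median_filter_2d(series)
    collapsed = average_directions_and_repeats(filtered, collapse_repeats=True)
    maps = fit_voxelwise(collapsed, roi, bounds, methods, nlls_settings, bayes_settings)
    _, fractions = build_inclusion_mask(collapsed, roi, maps, bounds)
    summary = maps.summary(roi, included_only=True)
    return maps, summary, fractions
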