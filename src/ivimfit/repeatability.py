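"""Test-retest variability metrics for IVIM parameters.

The central statistic is the within-subject coefficient of variation (WS-CV):
each subject contributes a replicate vector (4 temporal repeats, the 4 slices
of one spinal segment, or 2 scan sessions), and the cohort WS-CV is the
root-mean-square of the per-subject CVs,

    WS-CV = 100 * sqrt( mean_i( s_i^2 / m_i^2 ) )

with s_i, m_i the sample SD (ddof = 1) and mean of subject i's replicates.
An alternative pooled formulation (sqrt of the mean within-subject variance
divided by the grand mean) is available via ``variant='pooled'``.

Three analyses use it:

* temporal stability — whole-ROI decay curves fitted per repeat;
* spatial consistency — per-slice curves, WS-CV across the 4 slices of each
  spinal segment (subjects as replicate rows), summarized across segments;
* inter-session repeatability — ROI-mean voxelwise parameters of two visits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitters import BayesSettings, NLLSSettings, fit_all_methods
from .model import FitBounds
from .pipeline import ParameterMaps, ROIMask

__all__ = [
    "ws_cv",
    "fit_replicate_curves",
    "temporal_stability",
    "spatial_consistency",
    "intersession_repeatability",
    "VariabilityReport",
]

REPORT_PARAMS = ("f", "Dstar", "D", "fDstar")


@dataclass
class VariabilityReport:
    """Tidy WS-CV table plus any per-segment breakdown and exclusion log."""

    table: pd.DataFrame
    per_segment: pd.DataFrame | None = None
    log: list | None = None


def ws_cv(replicates_by_subject, variant: str = "rms") -> float:
    """Within-subject CV (%) across subjects' replicate vectors.

    ``replicates_by_subject`` is a sequence (or dict) of 1-D arrays, one per
    subject, each with >= 2 strictly positive replicates.  Scale-invariant per
    subject; reduces to the ordinary CV for a single subject.
    """
    if isinstance(replicates_by_subject, dict):
        items = list(replicates_by_subject.items())
    else:
        items = list(enumerate(replicates_by_subject))
    if not items:
        raise ValueError("no subjects supplied")
    cvs2, variances, means = [], [], []
    for subject, values in items:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"subject {subject!r} has fewer than 2 replicates")
        m = v.mean()
        if m <= 0:
            raise ValueError(f"subject {subject!r} has non-positive mean {m}")
        s2 = v.var(ddof=1)
        cvs2.append(s2 / m**2)
        variances.append(s2)
        means.append(m)
    if variant == "rms":
        return float(100.0 * np.sqrt(np.mean(cvs2)))
    if variant == "pooled":
        return float(100.0 * np.sqrt(np.mean(variances)) / np.mean(means))
    raise ValueError(f"unknown WS-CV variant {variant!r}")


def fit_replicate_curves(
    curves_by_subject: dict,
    bounds: FitBounds | None = None,
    methods=("nlls1", "nlls2", "nlls3", "bayes"),
    nlls_settings: NLLSSettings | None = None,
    bayes_settings: BayesSettings | None = None,
) -> pd.DataFrame:
    """Fit each subject's replicate curves; tidy rows of parameter values.

    ``curves_by_subject`` maps subject -> {replicate -> DecayCurve or None}.
    Failed or absent fits are omitted (downstream WS-CV drops subjects left
    with < 2 replicates, logging them).
    """
    bounds = bounds or FitBounds()
    bayes_settings = bayes_settings or BayesSettings(engine="grid")
    rows = []
    for subject, curves in curves_by_subject.items():
        items = curves.items() if isinstance(curves, dict) else enumerate(curves)
        for rep, curve in items:
            if curve is None:
                continue
            results = fit_all_methods(curve, bounds, nlls_settings, bayes_settings, methods)
            for tag, fr in results.items():
                if fr.params is None:
                    continue
                rows.append(
                    {
                        "subject": subject,
                        "replicate": rep,
                        "method": tag,
                        "f": fr.params.f,
                        "Dstar": fr.params.Dstar,
                        "D": fr.params.D,
                        "fDstar": fr.params.fDstar,
                        "resid_sq_norm": fr.resid_sq_norm,
                    }
                )
    return pd.DataFrame(rows)


def _wscv_table(df: pd.DataFrame, grouping: str, variant: str):
    """WS-CV per (method, parameter) from a tidy replicate table."""
    rows, log = [], []
    for method, grp in df.groupby("method", sort=False):
        for pname in REPORT_PARAMS:
            vecs = {}
            for subject, sub in grp.groupby("subject"):
                vals = sub[pname].to_numpy()
                if vals.size >= 2:
                    vecs[subject] = vals
                else:
                    log.append(f"{grouping}/{method}/{pname}: subject {subject} dropped (<2 replicates)")
            if not vecs:
                continue
            subj_means = np.array([v.mean() for v in vecs.values()])
            rows.append(
                {
                    "grouping": grouping,
                    "method": method,
                    "parameter": pname,
                    "ws_cv_pct": ws_cv(vecs, variant=variant),
                    "mean": float(subj_means.mean()),
                    "sd": float(subj_means.std(ddof=1)) if subj_means.size > 1 else float("nan"),
                    "n_subjects": len(vecs),
                }
            )
        rows.append(
            {
                "grouping": grouping,
                "method": method,
                "parameter": "resid_sq_norm",
                "ws_cv_pct": float("nan"),
                "mean": float(grp["resid_sq_norm"].mean()),
                "sd": float(grp["resid_sq_norm"].std(ddof=1)),
                "n_subjects": grp["subject"].nunique(),
            }
        )
    return pd.DataFrame(rows), log


def temporal_stability(
    curves_by_subject: dict,
    bounds: FitBounds | None = None,
    methods=("nlls1", "nlls2", "nlls3", "bayes"),
    nlls_settings: NLLSSettings | None = None,
    bayes_settings: BayesSettings | None = None,
    variant: str = "rms",
) -> VariabilityReport:
    """WS-CV across the temporally resolved repeats of the whole-ROI curve.

    ``curves_by_subject`` maps subject -> the per-repeat ROI-mean curves (as
    produced by ``roi_mean_curve(..., per_repeat=True)``).  Parameters are
    assumed physiologically constant over the acquisition, so all replicate
    spread is measurement variability.
    """
    df = fit_replicate_curves(curves_by_subject, bounds, methods, nlls_settings, bayes_settings)
    if df.empty:
        raise ValueError("no successful fits")
    table, log = _wscv_table(df, "temporal", variant)
    return VariabilityReport(table=table, log=log)


def spatial_consistency(
    slice_values: pd.DataFrame,
    segment_map: dict,
    variant: str = "rms",
) -> VariabilityReport:
    """WS-CV across the slices within each spinal segment.

    ``slice_values`` is a tidy table with columns ``subject``, ``method``,
    ``slice`` and the parameter columns (one fitted value per slice, repeats
    already averaged); ``segment_map`` maps slice index -> segment name with
    4 slices per segment.  For each segment the WS-CV treats subjects as rows
    and that segment's slices as replicates; the report gives the mean (SD)
    across segments, mirroring how spatial consistency is summarized over the
    lumbar levels.
    """
    seg_of = dict(segment_map)
    segments = sorted(set(seg_of.values()))
    per_seg_rows, log = [], []
    for method, grp in slice_values.groupby("method", sort=False):
        for seg in segments:
            seg_slices = [sl for sl, s in seg_of.items() if s == seg]
            sub = grp[grp["slice"].isin(seg_slices)]
            for pname in REPORT_PARAMS:
                vecs = {}
                for subject, ssub in sub.groupby("subject"):
                    vals = ssub[pname].dropna().to_numpy()
                    if vals.size >= 2:
                        vecs[subject] = vals
                    else:
                        log.append(
                            f"spatial/{method}/{seg}/{pname}: subject {subject} dropped (<2 valid slices)"
                        )
                if not vecs:
                    continue
                per_seg_rows.append(
                    {
                        "method": method,
                        "segment": seg,
                        "parameter": pname,
                        "ws_cv_pct": ws_cv(vecs, variant=variant),
                        "n_subjects": len(vecs),
                    }
                )
    per_segment = pd.DataFrame(per_seg_rows)
    if per_segment.empty:
        raise ValueError("no segment had enough valid slices")
    rows = []
    for (method, pname), grp in per_segment.groupby(["method", "parameter"], sort=False):
        rows.append(
            {
                "grouping": "spatial",
                "method": method,
                "parameter": pname,
                "ws_cv_pct": float(grp["ws_cv_pct"].mean()),
                "ws_cv_sd_pct": (
                    float(grp["ws_cv_pct"].std(ddof=1)) if len(grp) > 1 else float("nan")
                ),
                "n_segments": len(grp),
            }
        )
    return VariabilityReport(table=pd.DataFrame(rows), per_segment=per_segment, log=log)


def intersession_repeatability(
    maps_by_subject: dict,
    roi_by_subject,
    methods=None,
    roi_label: str = "paraspinal",
    variant: str = "rms",
) -> VariabilityReport:
    """WS-CV of ROI-averaged voxelwise parameters across two scan sessions.

    ``maps_by_subject`` maps subject -> (ParameterMaps visit 1, ParameterMaps
    visit 2); either may be None, which excludes the subject (logged).
    ``roi_by_subject`` is one shared :class:`ROIMask` or a dict per subject.
    Besides the WS-CV over the per-subject two-session replicate pairs, the
    report carries the dispersion statistic: the mean across subjects of the
    voxelwise SD within the ROI, per visit.
    """
    log = []
    values = {}      # (method, param) -> {subject: [v1, v2]}
    dispersion = {}  # (method, param, visit) -> [per-subject voxelwise SDs]
    for subject, pair in maps_by_subject.items():
        if pair is None or any(m is None for m in pair):
            log.append(f"intersession: subject {subject} excluded (missing visit)")
            continue
        roi = roi_by_subject[subject] if isinstance(roi_by_subject, dict) else roi_by_subject
        mask = roi.mask_for(roi_label)
        for visit, maps in enumerate(pair):
            for method in maps.values:
                if methods is not None and method not in methods:
                    continue
                include = (
                    maps.included_mask(method) if method in maps.inclusion else ~maps.failed[method]
                )
                sel = mask & include
                for pname in REPORT_PARAMS:
                    vox = maps.values[method][pname][sel]
                    vox = vox[np.isfinite(vox)]
                    if vox.size == 0:
                        continue
                    values.setdefault((method, pname), {}).setdefault(subject, [np.nan, np.nan])[
                        visit
                    ] = float(vox.mean())
                    dispersion.setdefault((method, pname, visit), []).append(
                        float(vox.std(ddof=1)) if vox.size > 1 else float("nan")
                    )

    rows = []
    for (method, pname), per_subject in values.items():
        vecs = {
            s: np.asarray(v)
            for s, v in per_subject.items()
            if np.all(np.isfinite(v))
        }
        if not vecs:
            continue
        disp = [
            float(np.nanmean(dispersion.get((method, pname, visit), [np.nan])))
            for visit in (0, 1)
        ]
        subj_means = np.array([v.mean() for v in vecs.values()])
        rows.append(
            {
                "grouping": "intersession",
                "method": method,
                "parameter": pname,
                "ws_cv_pct": ws_cv(vecs, variant=variant),
                "mean": float(subj_means.mean()),
                "sd": float(subj_means.std(ddof=1)) if subj_means.size > 1 else float("nan"),
                "dispersion_visit1": disp[0],
                "dispersion_visit2": disp[1],
                "n_subjects": len(vecs),
            }
        )
    if not rows:
        raise ValueError("no subject had both visits")
    return VariabilityReport(table=pd.DataFrame(rows), log=log)
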