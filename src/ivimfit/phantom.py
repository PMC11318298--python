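"""Synthetic IVIM acquisitions with the full protocol structure.

The phantom emulates an axial lumbar-spine diffusion acquisition: a voxel
grid with rectangular tissue regions (each carrying its own ground-truth
(f, D*, D) and proton-density-like S0), imaged at 13 b-values x 3 encoding
directions x 4 repeats, with zero-mean Gaussian noise at a configurable SNR
(sigma = S0_reference / SNR).  Directions are generated i.i.d. — muscle
diffusion anisotropy is not simulated, consistent with a pipeline that
averages directions before fitting.  Air voxels carry zero mean signal and
the same noise, so the SNR estimator's background ROI works as on real data.

Default template parameters (f = 0.11, D* = 28.4e-3 mm^2/s, D = 1.36e-3
mm^2/s) are typical of resting paraspinal muscle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import PROTOCOL_B_VALUES, FitBounds, IVIMParams, _ivim_model
from .pipeline import IVIMSeries, ParameterMaps, ROIMask

__all__ = [
    "TissueRegion",
    "PhantomSpec",
    "default_phantom_spec",
    "generate_phantom",
    "make_cohort",
    "snr_rois",
]

MUSCLE_TEMPLATE = IVIMParams(f=0.11, Dstar=28.4e-3, D=1.36e-3)
#: Plausible between-subject SDs for cohort generation.
DEFAULT_BETWEEN_SUBJECT_SD = {"f": 0.02, "Dstar": 6.8e-3, "D": 0.08e-3}


@dataclass(frozen=True)
class TissueRegion:
    """A rectangular tissue block: label, ground truth, S0, and its box.

    ``box`` is ((x0, x1), (y0, y1), (z0, z1)) with half-open index ranges.
    """

    label: str
    params: IVIMParams
    s0: float
    box: tuple

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.box
        m[x0:x1, y0:y1, z0:z1] = True
        return m


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue truths, protocol and noise level of one phantom.

    The default protocol matches the reference acquisition (13 b-values, 3
    directions, 4 repeats); the grid defaults to 22 slices covering L1-S1.
    ``segment_scales`` optionally scales region parameters per spinal segment
    (e.g. {"L5": {"D": 1.1}}) to emulate cranio-caudal gradients; it requires
    ``segment_map`` (slice index -> segment name).
    """

    seed: int
    shape: tuple = (48, 48, 22)
    regions: tuple = ()
    snr: float = 46.6
    b_values: tuple = tuple(PROTOCOL_B_VALUES)
    n_directions: int = 3
    n_repeats: int = 4
    voxel_size: tuple = (1.5, 1.5, 8.0)
    segment_map: dict | None = None
    segment_scales: dict | None = None
    bounds: FitBounds = field(default_factory=FitBounds)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("PhantomSpec requires an explicit seed")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        for region in self.regions:
            if not self.bounds.contains(region.params):
                raise ValueError(f"region {region.label!r} parameters outside the fit bounds")

    @property
    def s0_reference(self) -> float:
        """Noise reference: the largest S0 among tissue regions."""
        return max((r.s0 for r in self.regions), default=1.0)


def default_phantom_spec(
    seed: int, shape=(48, 48, 22), snr: float = 46.6, **kwargs
) -> PhantomSpec:
    """A body block containing erector spinae and multifidus boxes, in air.

    Muscle boxes sit inside a generic-tissue body so their borders see
    tissue, not air, as in vivo; the surrounding air provides background
    voxels for SNR estimation.
    """
    nx, ny, nz = shape
    bx0, bx1 = nx // 8, nx - nx // 8
    by0, by1 = ny // 8, ny - ny // 8
    mw = max((bx1 - bx0) // 3, 2)
    regions = (
        TissueRegion(
            "body",
            IVIMParams(f=0.08, Dstar=20e-3, D=1.2e-3),
            s0=80.0,
            box=((bx0, bx1), (by0, by1), (0, nz)),
        ),
        TissueRegion(
            "erector_spinae",
            MUSCLE_TEMPLATE,
            s0=100.0,
            box=((bx0 + 1, bx0 + 1 + mw), (by0 + 1, by1 - 1), (0, nz)),
        ),
        TissueRegion(
            "multifidus",
            IVIMParams(f=0.12, Dstar=22.7e-3, D=1.30e-3),
            s0=100.0,
            box=((bx1 - 1 - mw, bx1 - 1), (by0 + 1, by1 - 1), (0, nz)),
        ),
    )
    return PhantomSpec(seed=seed, shape=shape, regions=regions, snr=snr, **kwargs)


def _region_params(spec: PhantomSpec, region: TissueRegion, z: int) -> IVIMParams:
    if not spec.segment_scales or spec.segment_map is None:
        return region.params
    seg = spec.segment_map.get(z)
    scales = spec.segment_scales.get(seg, {}) if seg else {}
    return IVIMParams(
        f=region.params.f * scales.get("f", 1.0),
        Dstar=region.params.Dstar * scales.get("Dstar", 1.0),
        D=region.params.D * scales.get("D", 1.0),
    )


def generate_phantom(spec: PhantomSpec):
    """Synthesize one acquisition; returns (series, roi, truth_maps).

    Regions may not overlap.  Deterministic under the spec seed (same seed,
    bit-identical series).  Truth maps are stored under the method tag
    ``truth`` on the same grid.
    """
    shape = spec.shape
    labels = np.zeros(shape, dtype=int)
    label_map = {"background": 0}
    covered = np.zeros(shape, dtype=bool)
    # Later regions may nest inside earlier ones (muscles inside the body
    # block); true overlap between same-precedence boxes is rejected by
    # checking muscle boxes against each other.
    muscle_masks = []
    for code, region in enumerate(spec.regions, start=1):
        label_map[region.label] = code
        m = region.mask(shape)
        if region.label not in ("body",):
            for other in muscle_masks:
                if (m & other).any():
                    raise ValueError("tissue regions overlap")
            muscle_masks.append(m)
        labels[m] = code
        covered |= m

    b = np.asarray(spec.b_values, dtype=float)
    nb, nd, nr = b.size, spec.n_directions, spec.n_repeats
    nvol = nb * nd * nr
    bvals = np.empty(nvol)
    dirs = np.empty(nvol, dtype=int)
    reps = np.empty(nvol, dtype=int)
    clean = np.zeros(shape + (nb,), dtype=float)

    truth = ParameterMaps(shape=shape, affine=_affine(spec))
    truth.add_method("truth")
    for region in spec.regions:
        m3 = region.mask(shape) & (labels == label_map[region.label])
        for z in range(shape[2]):
            mz = m3[:, :, z]
            if not mz.any():
                continue
            p = _region_params(spec, region, z)
            decay = region.s0 * _ivim_model(p.f, p.Dstar, p.D, b)
            clean[:, :, z, :][mz] = decay
            truth.values["truth"]["f"][:, :, z][mz] = p.f
            truth.values["truth"]["Dstar"][:, :, z][mz] = p.Dstar
            truth.values["truth"]["D"][:, :, z][mz] = p.D
            truth.values["truth"]["fDstar"][:, :, z][mz] = p.fDstar
    truth.resid["truth"][:] = 0.0

    sigma = spec.s0_reference / spec.snr
    rng = np.random.default_rng(spec.seed)
    data = np.empty(shape + (nvol,), dtype=float)
    v = 0
    for r in range(1, nr + 1):
        for d in range(1, nd + 1):
            for i in range(nb):
                noise = rng.normal(0.0, sigma, shape) if sigma > 0 else 0.0
                data[..., v] = clean[..., i] + noise
                bvals[v], dirs[v], reps[v] = b[i], d, r
                v += 1

    series = IVIMSeries(data, bvals, dirs, reps, _affine(spec))
    roi = ROIMask(labels, label_map, spec.segment_map)
    return series, roi, truth


def _affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spec.voxel_size
    return aff


def snr_rois(roi: ROIMask, n_voxels: int = 500):
    """Equal-sized muscle and air (background) boolean ROIs for SNR estimation."""
    muscle = np.flatnonzero(roi.mask_for("paraspinal").ravel())
    air = np.flatnonzero(roi.mask_for("background").ravel())
    n = min(n_voxels, muscle.size, air.size)
    if n < 2:
        raise ValueError("not enough voxels for SNR ROIs")
    m = np.zeros(roi.labels.size, dtype=bool)
    bg = np.zeros(roi.labels.size, dtype=bool)
    m[muscle[:n]] = True
    bg[air[:n]] = True
    return m.reshape(roi.labels.shape), bg.reshape(roi.labels.shape)


def make_cohort(
    n_subjects: int,
    seed: int,
    template: PhantomSpec | None = None,
    between_subject_sd: dict | None = None,
    n_visits: int = 2,
):
    """Per-subject phantom specs with Gaussian between-subject truths.

    Muscle-region parameters are drawn from truncated Gaussians centered on
    the template values (truncation to the fit bounds), identically for every
    visit of a subject; each visit gets a fresh noise seed.  Returns
    ``(cohort, truth_table)`` where ``cohort[subject]`` is the list of
    per-visit :class:`PhantomSpec` and the table records each subject's truth
    per region.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    template = template or default_phantom_spec(seed=0)
    sd = DEFAULT_BETWEEN_SUBJECT_SD if between_subject_sd is None else between_subject_sd
    rng = np.random.default_rng([seed, 0])
    lo, hi = template.bounds.lower, template.bounds.upper

    cohort = {}
    rows = []
    for subj in range(n_subjects):
        regions = []
        for region in template.regions:
            center = region.params.as_array()
            scale = np.array([sd.get("f", 0.0), sd.get("Dstar", 0.0), sd.get("D", 0.0)])
            draw = center + scale * rng.standard_normal(3)
            # truncate to the sampling box (redraw-free clipping keeps streams aligned)
            draw = np.clip(draw, lo, hi)
            params = IVIMParams.from_array(draw)
            regions.append(replace(region, params=params))
            rows.append(
                {
                    "subject": subj,
                    "region": region.label,
                    "f": params.f,
                    "Dstar": params.Dstar,
                    "D": params.D,
                    "fDstar": params.fDstar,
                }
            )
        cohort[subj] = [
            replace(template, regions=tuple(regions), seed=int(1 + seed + 1000 * subj + visit))
            for visit in range(n_visits)
        ]
    return cohort, pd.DataFrame(rows)
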