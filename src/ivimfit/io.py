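"""NIfTI / bval / bvec / JSON round-tripping for series, masks and maps.

A series is stored as ``<prefix>.nii.gz`` plus FSL-style ``<prefix>.bval``
(one row of b-values) and ``<prefix>.bvec`` (three rows of unit vectors), and
a JSON sidecar ``<prefix>.json`` carrying the repeat index of each volume and
the direction indices (the bvec alone cannot encode repeats).  Masks are
uint8 NIfTI files with their label map and segment map in a JSON sidecar.
Parameter maps are written one float32 NIfTI per parameter per method, with
the source affine preserved.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .pipeline import IVIMSeries, ParameterMaps, ROIMask

__all__ = [
    "save_series",
    "load_series",
    "save_mask",
    "load_mask",
    "save_parameter_maps",
]

# Axis-aligned encoding directions used when only a direction index is known.
_UNIT_DIRS = {0: (0.0, 0.0, 0.0), 1: (1.0, 0.0, 0.0), 2: (0.0, 1.0, 0.0), 3: (0.0, 0.0, 1.0)}


def save_series(series: IVIMSeries, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(series.data.astype(np.float32), series.affine), str(prefix) + ".nii.gz"
    )
    np.savetxt(str(prefix) + ".bval", series.bvals[None, :], fmt="%g")
    bvecs = np.array([_UNIT_DIRS.get(int(d), (0.0, 0.0, 0.0)) for d in series.dirs]).T
    np.savetxt(str(prefix) + ".bvec", bvecs, fmt="%g")
    sidecar = {
        "RepeatIndex": [int(r) for r in series.reps],
        "DirectionIndex": [int(d) for d in series.dirs],
    }
    Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_series(prefix) -> IVIMSeries:
    prefix = str(prefix)
    img = nib.load(prefix + ".nii.gz")
    bvals = np.loadtxt(prefix + ".bval").reshape(-1)
    sidecar = json.loads(Path(prefix + ".json").read_text())
    return IVIMSeries(
        np.asarray(img.dataobj, dtype=np.float32),
        bvals,
        np.array(sidecar["DirectionIndex"], dtype=int),
        np.array(sidecar["RepeatIndex"], dtype=int),
        img.affine,
    )


def save_mask(roi: ROIMask, prefix, affine=None) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(roi.labels.astype(np.uint8), affine), str(prefix) + ".nii.gz")
    sidecar = {
        "LabelMap": {k: int(v) for k, v in roi.label_map.items()},
        "SegmentMap": (
            {str(k): v for k, v in roi.segment_map.items()} if roi.segment_map else None
        ),
    }
    Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_mask(prefix) -> ROIMask:
    prefix = str(prefix)
    img = nib.load(prefix + ".nii.gz")
    sidecar = json.loads(Path(prefix + ".json").read_text())
    seg = sidecar.get("SegmentMap")
    return ROIMask(
        np.asarray(img.dataobj).astype(int),
        sidecar["LabelMap"],
        {int(k): v for k, v in seg.items()} if seg else None,
    )


def save_parameter_maps(maps: ParameterMaps, out_dir) -> list:
    """One float32 NIfTI per parameter per method (plus residual and reasons)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for method, params in maps.values.items():
        for pname, vol in params.items():
            path = out_dir / f"{method}_{pname}.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), maps.affine), path)
            written.append(path)
        path = out_dir / f"{method}_resid_sq_norm.nii.gz"
        nib.save(nib.Nifti1Image(maps.resid[method].astype(np.float32), maps.affine), path)
        written.append(path)
        if method in maps.inclusion:
            path = out_dir / f"{method}_inclusion_reason.nii.gz"
            nib.save(nib.Nifti1Image(maps.inclusion[method].astype(np.uint8), maps.affine), path)
            written.append(path)
    return written
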