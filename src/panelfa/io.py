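"""File formats: panel CSV, NIfTI volume stacks, result JSON.

Conventions: NIfTI-1 with float32 data for FA maps and int8 masks;
panel CSV is UTF-8, comma-separated with a header row and reserved
columns ``subject_id, group, timepoint``.  Subject alignment between the
panel and the volume stack is an explicit join on ``subject_id`` that
errors on any mismatch.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .panel import PanelTable
from .voxelwise import VolumeStack


def read_panel(path) -> PanelTable:
    """Read a panel CSV (validates non-negativity; NaN is rejected)."""
    return PanelTable.from_csv(path)


def write_panel(panel: PanelTable, path) -> None:
    panel.to_csv(path)


def write_nifti(data: np.ndarray, affine: np.ndarray, path,
                dtype=np.float32) -> None:
    nib.Nifti1Image(np.asarray(data).astype(dtype), affine).to_filename(
        str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def read_volumes(volume_paths, mask_path, subject_ids=None) -> VolumeStack:
    """Stack per-subject 3D NIfTI volumes (or one 4D NIfTI) with a mask.

    ``volume_paths`` is a list of 3D files (subject ids default to file
    stems, ``_fa`` suffix stripped) or a single 4D file (then
    ``subject_ids`` is required).
    """
    mask, mask_aff = read_nifti(mask_path)
    mask = mask > 0
    if isinstance(volume_paths, (str, Path)):
        data, aff = read_nifti(volume_paths)
        if data.ndim != 4:
            raise ValueError("single volume file must be 4D")
        data = np.moveaxis(data, -1, 0)
        if subject_ids is None:
            raise ValueError("subject_ids required with a 4D input")
    else:
        vols, aff = [], None
        ids = []
        for p in volume_paths:
            d, a = read_nifti(p)
            if d.ndim != 3:
                raise ValueError(f"{p} is not a 3D volume")
            if aff is None:
                aff = a
            elif not np.allclose(aff, a, atol=1e-5):
                raise ValueError(f"{p}: affine differs from the first volume")
            vols.append(d)
            stem = Path(p).name.split(".nii")[0]
            ids.append(stem[:-3] if stem.endswith("_fa") else stem)
        data = np.stack(vols)
        if subject_ids is None:
            subject_ids = ids
    if data.shape[1:] != mask.shape:
        raise ValueError("mask grid does not match the volumes")
    if not np.allclose(aff, mask_aff, atol=1e-5):
        raise ValueError("mask affine does not match the volumes")
    return VolumeStack(data=data, mask=mask, affine=aff,
                       subject_ids=np.asarray(subject_ids))


def align_panel_to_volumes(panel: PanelTable,
                           volumes: VolumeStack) -> PanelTable:
    """Reorder panel rows to the volume stack's subject order (strict join)."""
    if volumes.subject_ids is None:
        raise ValueError("volume stack has no subject ids to join on")
    panel_ids = list(dict.fromkeys(panel.subject_id.tolist()))
    vol_ids = [str(s) for s in volumes.subject_ids]
    missing_vol = sorted(set(panel_ids) - set(vol_ids))
    missing_pan = sorted(set(vol_ids) - set(panel_ids))
    if missing_vol or missing_pan:
        raise ValueError(
            "subject mismatch between panel and volumes; "
            f"panel-only: {missing_vol}, volumes-only: {missing_pan}")
    order = []
    ids = panel.subject_id.tolist()
    for sid in vol_ids:
        order.append(ids.index(sid))
    idx = np.asarray(order)
    return PanelTable(panel.values[idx], panel.subject_id[idx],
                      panel.group[idx], panel.timepoint[idx],
                      list(panel.markers))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
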