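"""NIfTI and manifest I/O for serial studies and phantom datasets.

Volumes are exchanged exclusively as NIfTI; a YAML manifest names one file
per (parameter, timepoint) plus the mask, hemisphere-label and ROI volumes.
Integer-coded label volumes always get a sidecar JSON code table.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .preprocess import PARAMETERS, QuantMap, SerialStudy
from .tissue_classes import LesionROISet


def _affine(voxel_size_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_volume(values: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(values), _affine(voxel_size_mm))
    nib.save(img, str(path))
    return path


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_code_table(codes: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(codes, indent=2, sort_keys=True) + "\n")
    return path


def _hours_tag(t: float) -> str:
    return f"{t:g}h"


def save_study(study: SerialStudy, out_dir, voxel_size_mm=(1.0, 1.0, 1.0)) -> Path:
    """Write a study to a directory and return the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"voxel_size_mm": list(voxel_size_mm), "maps": [], "rois": {}}
    for (param, t), qmap in sorted(study.maps.items()):
        if qmap.is_relative:
            continue  # relative maps are derived, not stored
        name = f"{param}_{_hours_tag(t)}.nii.gz"
        save_volume(qmap.values, out_dir / name, voxel_size_mm)
        manifest["maps"].append({"parameter": param, "timepoint_h": t, "file": name})
    save_volume(study.brain_mask.astype(np.uint8), out_dir / "mask.nii.gz", voxel_size_mm)
    manifest["brain_mask"] = "mask.nii.gz"
    save_volume(study.hemisphere.astype(np.int16), out_dir / "hemisphere.nii.gz", voxel_size_mm)
    manifest["hemisphere"] = "hemisphere.nii.gz"
    for name, roi in study.ref_rois.items():
        fname = f"roi_{name}.nii.gz"
        save_volume(np.asarray(roi).astype(np.uint8), out_dir / fname, voxel_size_mm)
        manifest["rois"][name] = fname
    if study.lesion_rois is not None:
        rois = study.lesion_rois
        for key in ("acute", "maximal", "chronic"):
            fname = f"lesion_{key}.nii.gz"
            save_volume(getattr(rois, key).astype(np.uint8), out_dir / fname, voxel_size_mm)
            manifest.setdefault("lesion_rois", {})[key] = fname
        manifest["lesion_rois"]["maximal_timepoint_h"] = rois.maximal_timepoint_h
        manifest["lesion_rois"]["chronic_timepoint_h"] = rois.chronic_timepoint_h
    manifest_path = out_dir / "study.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path


def load_study(manifest_path) -> SerialStudy:
    """Load a study from a YAML manifest written by :func:`save_study`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())

    maps = {}
    for entry in manifest["maps"]:
        param = entry["parameter"]
        if param not in PARAMETERS:
            raise ValueError(f"manifest lists unknown parameter {param!r}")
        t = float(entry["timepoint_h"])
        maps[(param, t)] = QuantMap(load_volume(base / entry["file"]), param, t)

    brain_mask = load_volume(base / manifest["brain_mask"]) > 0.5
    hemisphere = load_volume(base / manifest["hemisphere"]).astype(np.int16)
    ref_rois = {
        name: load_volume(base / fname) > 0.5
        for name, fname in manifest.get("rois", {}).items()
    }
    lesion_rois = None
    lr = manifest.get("lesion_rois")
    if lr:
        lesion_rois = LesionROISet(
            acute=load_volume(base / lr["acute"]) > 0.5,
            maximal=load_volume(base / lr["maximal"]) > 0.5,
            chronic=load_volume(base / lr["chronic"]) > 0.5,
            maximal_timepoint_h=lr.get("maximal_timepoint_h"),
            chronic_timepoint_h=lr.get("chronic_timepoint_h"),
        )
    return SerialStudy(
        maps=maps,
        brain_mask=brain_mask,
        hemisphere=hemisphere,
        ref_rois=ref_rois,
        lesion_rois=lesion_rois,
    )


def save_phantom(dataset, out_dir) -> Path:
    """Write a phantom dataset (study + ground truth) to a directory."""
    from .phantom import SIGNATURE_CODES  # local import to avoid a cycle
    from .tissue_classes import CLASS_CODES

    out_dir = Path(out_dir)
    vox = dataset.config.voxel_size_mm
    manifest_path = save_study(dataset.study, out_dir, vox)
    save_volume(dataset.truth_labels, out_dir / "truth_labels.nii.gz", vox)
    save_code_table(SIGNATURE_CODES, out_dir / "truth_labels.codes.json")
    save_volume(dataset.truth_classes, out_dir / "truth_classes.nii.gz", vox)
    save_code_table(CLASS_CODES, out_dir / "truth_classes.codes.json")
    save_volume(dataset.generative_labels, out_dir / "generative_labels.nii.gz", vox)
    return manifest_path
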