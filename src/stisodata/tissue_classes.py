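"""Operational tissue classification from acute, maximal and chronic lesion ROIs.

Serial stroke MRI defines three manually (or, for the phantom, synthetically)
delineated lesion extents: the acute ADC lesion at ~1 h, the T2 lesion at the
timepoint of maximal volume ("Maximal Lesion"), and the chronic T2 lesion at
follow-up. Set relations among the three partition the brain into operational
classes:

- ``Core``      = acute AND chronic       (abnormal early, still abnormal late)
- ``Growth``    = chronic AND NOT acute   (recruited into the lesion over time)
- ``Recovery``  = acute AND NOT chronic   (early abnormality that normalized)
- ``Edema``     = maximal AND NOT (acute OR chronic)  (transient swelling only)
- ``Normal``    = everything else in the brain mask

Before classification the ROIs are conventionally enlarged by three 3D binary
dilation steps to absorb delineation uncertainty at lesion borders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Integer codes for the tissue-class volume.
CLASS_CODES = {"Normal": 0, "Core": 1, "Growth": 2, "Recovery": 3, "Edema": 4}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class LesionROISet:
    """Acute / maximal / chronic lesion masks on a shared grid."""

    acute: np.ndarray
    maximal: np.ndarray
    chronic: np.ndarray
    maximal_timepoint_h: float | None = None
    chronic_timepoint_h: float | None = None

    def __post_init__(self) -> None:
        self.acute = np.asarray(self.acute, dtype=bool)
        self.maximal = np.asarray(self.maximal, dtype=bool)
        self.chronic = np.asarray(self.chronic, dtype=bool)
        if not (self.acute.shape == self.maximal.shape == self.chronic.shape):
            raise ValueError("acute/maximal/chronic masks must share one grid")

    @property
    def shape(self) -> tuple:
        return self.acute.shape


def _structuring_element(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 (faces) or 26 (full cube)")


def dilate_roi(
    mask: np.ndarray,
    steps: int = 3,
    connectivity: int = 6,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Binary-dilate a ROI ``steps`` times, then clip to the brain mask.

    With the default 6-connected (face-adjacent) element, n steps grow a
    single voxel into the octahedral ball |dx|+|dy|+|dz| <= n.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    if steps > 0:
        out = ndimage.binary_dilation(
            out, structure=_structuring_element(connectivity), iterations=steps
        )
    if brain_mask is not None:
        brain_mask = np.asarray(brain_mask, dtype=bool)
        if brain_mask.shape != out.shape:
            raise ValueError("brain mask shape differs from ROI shape")
        out &= brain_mask
    return out


def dilate_roi_set(
    rois: LesionROISet,
    steps: int = 3,
    connectivity: int = 6,
    brain_mask: np.ndarray | None = None,
) -> LesionROISet:
    """Apply :func:`dilate_roi` uniformly to all three lesion masks."""
    return LesionROISet(
        acute=dilate_roi(rois.acute, steps, connectivity, brain_mask),
        maximal=dilate_roi(rois.maximal, steps, connectivity, brain_mask),
        chronic=dilate_roi(rois.chronic, steps, connectivity, brain_mask),
        maximal_timepoint_h=rois.maximal_timepoint_h,
        chronic_timepoint_h=rois.chronic_timepoint_h,
    )


def classify_tissue(rois: LesionROISet, brain_mask: np.ndarray) -> np.ndarray:
    """Partition the brain mask into Core/Growth/Recovery/Edema/Normal.

    Expects ROIs that have already been dilated (callers opting out of
    dilation do so knowingly). Returns an integer volume coded per
    ``CLASS_CODES``; voxels outside the brain mask are Normal (0).
    Acute membership takes precedence over Edema: a voxel in
    maximal AND acute but not chronic is Recovery, not Edema.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if rois.shape != brain_mask.shape:
        raise ValueError("ROI grid does not match the brain mask")
    acute = rois.acute & brain_mask
    maximal = rois.maximal & brain_mask
    chronic = rois.chronic & brain_mask

    out = np.zeros(brain_mask.shape, dtype=np.int16)
    out[chronic & ~acute] = CLASS_CODES["Growth"]
    out[acute & ~chronic] = CLASS_CODES["Recovery"]
    out[maximal & ~acute & ~chronic] = CLASS_CODES["Edema"]
    out[acute & chronic] = CLASS_CODES["Core"]
    return out


def crosstab_signatures_classes(
    signature_bins: np.ndarray,
    class_map: np.ndarray,
    region: np.ndarray | None = None,
    signature_names: dict | None = None,
) -> pd.DataFrame:
    """Cross-tabulate signature bins against tissue classes.

    Counts voxels per (signature, class) within ``region`` (default: voxels
    with a nonzero signature bin), and adds row percentages that sum to 100
    per signature. ``signature_names`` maps integer bin codes to labels.
    """
    signature_bins = np.asarray(signature_bins)
    class_map = np.asarray(class_map)
    if signature_bins.shape != class_map.shape:
        raise ValueError("signature bins and class map shapes differ")
    if region is None:
        region = np.ones(signature_bins.shape, dtype=bool)
    else:
        region = np.asarray(region, dtype=bool)
        if region.shape != signature_bins.shape:
            raise ValueError("region shape differs")

    sig = signature_bins[region].ravel()
    cls = class_map[region].ravel()
    rows = []
    for s in np.unique(sig):
        s_sel = sig == s
        total = int(s_sel.sum())
        for c in np.unique(cls[s_sel]):
            count = int((s_sel & (cls == c)).sum())
            rows.append(
                {
                    "signature": signature_names.get(int(s), int(s))
                    if signature_names
                    else int(s),
                    "tissue_class": CLASS_NAMES.get(int(c), int(c)),
                    "count": count,
                    "row_percent": 100.0 * count / total,
                }
            )
    return pd.DataFrame(rows, columns=["signature", "tissue_class", "count", "row_percent"])
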