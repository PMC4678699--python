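"""Preprocessing of serial quantitative MRI studies.

Turns a :class:`SerialStudy` (co-registered, skull-stripped ADC/FA/T2 volumes
acquired at several timepoints after stroke onset, plus a brain mask,
hemisphere labels and reference ROIs) into the masked, relative-valued,
spatially weighted voxel-by-feature matrix that the ISODATA clustering stage
consumes.

The stages, in the order the pipeline runs them:

1. :func:`exclude_csf_vessels` — drop voxels whose first-timepoint ADC exceeds
   1.2e-3 mm^2/s (CSF and large vessels) from the analysis mask.
2. :func:`compute_relative_maps` — divide each map by its mean value over the
   contralateral (unaffected) hemisphere, yielding rADC/rFA/rT2 with normal
   tissue close to 1.
3. :func:`spatial_contiguity_weight` — replace each in-mask voxel by a
   Gaussian distance-weighted mean of its in-mask neighbourhood, suppressing
   voxel-level noise before clustering.
4. :func:`build_feature_matrix` — concatenate the relative maps across
   timepoints into one row per voxel (timepoint-major column order) and
   optionally z-score each column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

# Hemisphere label codes used throughout the package.
HEMI_NONE = 0
HEMI_IPSI = 1
HEMI_CONTRA = 2

#: Quantitative parameters and their relative (contralateral-normalized) forms.
PARAMETERS = ("ADC", "FA", "T2")
RELATIVE_OF = {"ADC": "rADC", "FA": "rFA", "T2": "rT2"}
RELATIVE_PARAMETERS = tuple(RELATIVE_OF.values())

#: First-timepoint ADC above this value (mm^2/s) marks CSF / large vessels.
ADC_CSF_THRESHOLD = 1.2e-3


@dataclass
class QuantMap:
    """A single quantitative 3D map at one timepoint.

    Parameters are identified by name: ``ADC`` (mm^2/s), ``FA`` (unitless,
    in [0, 1]), ``T2`` (ms), or their relative forms ``rADC``/``rFA``/``rT2``.
    """

    values: np.ndarray
    parameter: str
    timepoint_h: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"QuantMap values must be 3D, got {self.values.ndim}D")
        valid = set(PARAMETERS) | set(RELATIVE_PARAMETERS)
        if self.parameter not in valid:
            raise ValueError(
                f"unknown parameter {self.parameter!r}; expected one of {sorted(valid)}"
            )

    @property
    def is_relative(self) -> bool:
        return self.parameter in RELATIVE_PARAMETERS


@dataclass
class SerialStudy:
    """One subject's aligned serial study: maps, masks and reference ROIs.

    ``maps`` is keyed by ``(parameter, timepoint_h)``. ``hemisphere`` labels
    every voxel ipsilateral (lesioned side), contralateral or background.
    ``ref_rois`` holds boolean masks for contralateral white matter (``WM``),
    contralateral grey matter (``GM``) and ``CSF``. ``analysis_mask`` is the
    brain mask after CSF/vessel exclusion; until :func:`exclude_csf_vessels`
    has run it defaults to the brain mask itself.
    """

    maps: dict
    brain_mask: np.ndarray
    hemisphere: np.ndarray
    ref_rois: Mapping[str, np.ndarray] = field(default_factory=dict)
    lesion_rois: object | None = None
    analysis_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.hemisphere = np.asarray(self.hemisphere)
        shape = self.brain_mask.shape
        if self.hemisphere.shape != shape:
            raise ValueError("hemisphere labels and brain mask shapes differ")
        for key, qmap in self.maps.items():
            if qmap.values.shape != shape:
                raise ValueError(f"map {key} shape {qmap.values.shape} != mask {shape}")
        for name, roi in self.ref_rois.items():
            roi = np.asarray(roi, dtype=bool)
            if roi.shape != shape:
                raise ValueError(f"ref ROI {name!r} shape mismatch")
            if not (roi <= self.brain_mask).all():
                raise ValueError(f"ref ROI {name!r} extends outside the brain mask")
        for name in ("WM", "GM"):
            if name in self.ref_rois:
                roi = np.asarray(self.ref_rois[name], dtype=bool)
                if (roi & (self.hemisphere != HEMI_CONTRA)).any():
                    raise ValueError(f"{name} reference ROI must be contralateral")
        if self.analysis_mask is None:
            self.analysis_mask = self.brain_mask.copy()
        else:
            self.analysis_mask = np.asarray(self.analysis_mask, dtype=bool)
            if self.analysis_mask.shape != shape:
                raise ValueError("analysis mask shape mismatch")

    @property
    def shape(self) -> tuple:
        return self.brain_mask.shape

    @property
    def timepoints_h(self) -> tuple:
        return tuple(sorted({t for (_, t) in self.maps.keys()}))

    def parameters_present(self, relative: bool = False) -> tuple:
        pool = RELATIVE_PARAMETERS if relative else PARAMETERS
        return tuple(p for p in pool if any(k[0] == p for k in self.maps))

    def get_map(self, parameter: str, timepoint_h: float) -> QuantMap:
        try:
            return self.maps[(parameter, timepoint_h)]
        except KeyError:
            raise KeyError(
                f"study has no ({parameter}, {timepoint_h} h) map; "
                f"available: {sorted(self.maps.keys())}"
            ) from None

    def contralateral_region(self) -> np.ndarray:
        """Contralateral hemisphere voxels inside the analysis mask."""
        return (self.hemisphere == HEMI_CONTRA) & self.analysis_mask

    def ipsilateral_region(self) -> np.ndarray:
        """Ipsilateral hemisphere voxels inside the analysis mask."""
        return (self.hemisphere == HEMI_IPSI) & self.analysis_mask


@dataclass
class FeatureMatrix:
    """Per-voxel feature block flattened for clustering.

    ``data`` has one row per analysis-mask voxel and one column per
    (timepoint, parameter) pair in timepoint-major order. ``voxel_index``
    maps row -> (x, y, z); ``feature_index`` maps column ->
    (timepoint_h, parameter). If the columns were z-scored, ``column_means``
    and ``column_sds`` record the transform so centroids can be mapped back
    to relative units.
    """

    data: np.ndarray
    voxel_index: np.ndarray
    feature_index: tuple
    shape: tuple
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def standardized(self) -> bool:
        return self.column_means is not None

    def destandardize(self, vectors: np.ndarray) -> np.ndarray:
        """Map feature-space vectors back to relative (physical) units."""
        vectors = np.asarray(vectors, dtype=float)
        if not self.standardized:
            return vectors.copy()
        return vectors * self.column_sds + self.column_means

    def standardize_vector(self, vector: np.ndarray) -> np.ndarray:
        """Map a relative-unit vector into the (possibly z-scored) space."""
        vector = np.asarray(vector, dtype=float)
        if not self.standardized:
            return vector.copy()
        return (vector - self.column_means) / self.column_sds

    def rows_for_mask(self, mask: np.ndarray) -> np.ndarray:
        """Row indices whose voxels fall inside a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.shape:
            raise ValueError("mask shape does not match the feature grid")
        x, y, z = self.voxel_index.T
        return np.nonzero(mask[x, y, z])[0]

    def volume_from_rows(self, row_values: np.ndarray, fill=0) -> np.ndarray:
        """Scatter one value per row back onto the 3D grid."""
        row_values = np.asarray(row_values)
        out = np.full(self.shape, fill, dtype=row_values.dtype)
        x, y, z = self.voxel_index.T
        out[x, y, z] = row_values
        return out


def exclude_csf_vessels(
    adc_first_timepoint: QuantMap,
    brain_mask: np.ndarray,
    threshold: float = ADC_CSF_THRESHOLD,
) -> np.ndarray:
    """Remove CSF/vessel voxels (first-timepoint ADC > threshold) from the mask.

    The comparison is strict: a voxel exactly at the threshold is retained.
    """
    if threshold <= 0:
        raise ValueError("ADC exclusion threshold must be positive")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if adc_first_timepoint.values.shape != brain_mask.shape:
        raise ValueError("ADC map and brain mask shapes differ")
    if adc_first_timepoint.parameter != "ADC":
        raise ValueError("CSF/vessel exclusion requires an absolute ADC map")
    return brain_mask & ~(adc_first_timepoint.values > threshold)


def apply_analysis_mask(study: SerialStudy, analysis_mask: np.ndarray) -> SerialStudy:
    """Return a copy of the study carrying the given analysis mask."""
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    if not (analysis_mask <= study.brain_mask).all():
        raise ValueError("analysis mask must be a subset of the brain mask")
    return replace(study, analysis_mask=analysis_mask.copy())


def compute_relative_maps(study: SerialStudy) -> SerialStudy:
    """Divide each map by its mean contralateral-hemisphere value.

    Adds an ``rADC``/``rFA``/``rT2`` map for every absolute map present. The
    mean is taken over contralateral voxels inside the analysis mask, so CSF
    and vessels excluded by :func:`exclude_csf_vessels` do not inflate it.
    By construction the contralateral analysis-mask mean of each relative map
    is 1. Refuses to run twice: maps that are already relative are rejected.
    """
    contra = study.contralateral_region()
    if not contra.any():
        raise ValueError("contralateral hemisphere is empty within the analysis mask")
    new_maps = dict(study.maps)
    for (param, t), qmap in study.maps.items():
        if qmap.is_relative:
            raise ValueError(
                f"map ({param}, {t} h) is already relative; "
                "compute_relative_maps must not be applied twice"
            )
        mean = float(qmap.values[contra].mean())
        if mean == 0:
            raise ValueError(f"zero contralateral mean for ({param}, {t} h)")
        rel = QuantMap(qmap.values / mean, RELATIVE_OF[param], t)
        new_maps[(rel.parameter, t)] = rel
    return replace(study, maps=new_maps)


def _neighbourhood_kernel(radius: int, decay: float) -> np.ndarray:
    """Gaussian distance weights on the (2r+1)^3 cube, w(d) = exp(-d^2/2*decay^2)."""
    ax = np.arange(-radius, radius + 1, dtype=float)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    d2 = dx**2 + dy**2 + dz**2
    return np.exp(-d2 / (2.0 * decay**2))


def spatial_contiguity_weight(
    study: SerialStudy, neighborhood_radius: int = 1, decay: float = 1.0
) -> SerialStudy:
    """Replace each relative-map voxel by its Gaussian-weighted local mean.

    Weights fall off with Euclidean distance to the centre voxel,
    ``w(d) = exp(-d^2 / (2 decay^2))``; out-of-mask neighbours get zero weight
    and the weights are renormalized to sum to 1 over the in-mask
    neighbourhood (which always includes the centre voxel itself, so an
    isolated voxel keeps its value). Applied only to relative maps — run
    :func:`compute_relative_maps` first.
    """
    if neighborhood_radius < 1:
        raise ValueError("neighborhood_radius must be >= 1")
    if decay <= 0:
        raise ValueError("decay must be positive")
    rel_keys = [k for k, m in study.maps.items() if m.is_relative]
    if not rel_keys:
        raise ValueError("no relative maps present; run compute_relative_maps first")

    kernel = _neighbourhood_kernel(neighborhood_radius, decay)
    mask = study.analysis_mask.astype(float)
    weight_sum = ndimage.correlate(mask, kernel, mode="constant", cval=0.0)

    centre = kernel[neighborhood_radius, neighborhood_radius, neighborhood_radius]
    n_isolated = int(
        ((np.abs(weight_sum - centre) < 1e-12) & study.analysis_mask).sum()
    )
    if n_isolated:
        logger.warning(
            "%d isolated voxel(s) have no in-mask neighbours; values kept unchanged",
            n_isolated,
        )

    new_maps = dict(study.maps)
    for key in rel_keys:
        qmap = study.maps[key]
        num = ndimage.correlate(
            qmap.values * mask, kernel, mode="constant", cval=0.0
        )
        smoothed = qmap.values.copy()
        inside = study.analysis_mask
        smoothed[inside] = num[inside] / weight_sum[inside]
        new_maps[key] = QuantMap(smoothed, qmap.parameter, qmap.timepoint_h)
    return replace(study, maps=new_maps)


def build_feature_matrix(
    study: SerialStudy,
    parameters: Sequence[str] = PARAMETERS,
    standardize: bool = True,
) -> FeatureMatrix:
    """Assemble the voxel-by-(timepoint x parameter) feature matrix.

    ``parameters`` names absolute parameters (``ADC``/``FA``/``T2``); their
    relative maps are the actual features. Columns are ordered timepoint-major
    (all parameters at t1, then all at t2, ...). With ``standardize`` each
    column is z-scored over the rows and the (mean, sd) pair recorded.
    """
    parameters = tuple(parameters)
    for p in parameters:
        if p not in PARAMETERS:
            raise ValueError(f"unknown parameter {p!r}; expected subset of {PARAMETERS}")
    timepoints = study.timepoints_h
    if not timepoints:
        raise ValueError("study has no maps")

    feature_index = []
    columns = []
    for t in timepoints:
        for p in parameters:
            rel = RELATIVE_OF[p]
            if (rel, t) not in study.maps:
                raise KeyError(
                    f"missing relative map ({rel}, {t} h); "
                    "run compute_relative_maps or check the study manifest"
                )
            feature_index.append((t, rel))
            columns.append(study.maps[(rel, t)].values)

    voxel_index = np.argwhere(study.analysis_mask)
    x, y, z = voxel_index.T
    data = np.stack([c[x, y, z] for c in columns], axis=1)
    if not np.isfinite(data).all():
        raise ValueError("non-finite feature values inside the analysis mask")

    means = sds = None
    if standardize:
        means = data.mean(axis=0)
        sds = data.std(axis=0)
        sds = np.where(sds == 0, 1.0, sds)
        data = (data - means) / sds

    return FeatureMatrix(
        data=data,
        voxel_index=voxel_index,
        feature_index=tuple(feature_index),
        shape=study.shape,
        column_means=means,
        column_sds=sds,
    )
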