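"""Post-cluster processing: CoV pruning, 1-100 normalization, signature bins.

ISODATA typically over-segments serial stroke data: many clusters are
temporally flat (normal tissue, mild artifacts) and only the temporally
dynamic ones carry lesion information. Three steps turn a raw cluster model
into named tissue signatures:

1. **CoV pruning** — a cluster whose centroid trajectory over time has a
   coefficient of variation (sd/mean, per parameter, pooled as the maximum
   over parameters) at or below a threshold is merged into a single "normal"
   cluster; clusters above the threshold are retained as abnormal.
2. **Normalization** — because cluster ids are arbitrary and run-dependent,
   clusters are placed on a reproducible 1-100 scale anchored at tissue
   references: the cluster matching contralateral white matter maps to 1 and
   the cluster matching CSF maps to 100, with the rest positioned by their
   relative proximity to the two anchors in feature space.
3. **Binning** — normalized values are grouped in tens into named signatures
   (N for values <= 5, then I, II, ... with generic B-labels for bins the
   study never observed), making signatures comparable across subjects.

Per-signature temporal profiles (mean/sd/count of rADC, rFA, rT2 at each
timepoint) summarize what each signature's tissue actually did over time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isodata import ClusterModel
from .preprocess import RELATIVE_PARAMETERS, SerialStudy

logger = logging.getLogger(__name__)

#: Default temporal-dispersion threshold below which a cluster is "normal".
DEFAULT_COV_THRESHOLD = 0.05

#: Signature bin upper edges on the 1-100 scale and their labels. A value v
#: falls in the first bin whose upper edge is >= v (edges are closed on the
#: right: 15 -> I, 16 -> B2). Labels B2, B7..B10 are generic names for tens
#: bins with no named signature.
BIN_EDGES = (
    (5, "N"),
    (15, "I"),
    (25, "B2"),
    (35, "II"),
    (45, "III"),
    (55, "IV"),
    (65, "V"),
    (75, "B7"),
    (85, "B8"),
    (95, "B9"),
    (100, "B10"),
)

#: Integer codes for the binned-signature volume (0 is also "outside mask"
#: in exported label volumes; inside the mask 0 means Signature N).
BIN_CODES = {label: i for i, (_, label) in enumerate(BIN_EDGES)}
BIN_NAMES = {v: k for k, v in BIN_CODES.items()}


@dataclass
class PrunedModel:
    """Cluster model after CoV pruning.

    Cluster 0 is the merged normal cluster (possibly empty); clusters
    1..n_abnormal are the retained abnormal clusters. ``provenance`` maps
    each pruned cluster id to the list of original cluster ids it absorbed,
    and ``cluster_cov`` records every original cluster's pooled CoV.
    """

    centroids: np.ndarray
    assignments: np.ndarray
    voxel_index: np.ndarray
    feature_index: tuple
    grid_shape: tuple
    column_means: np.ndarray | None
    column_sds: np.ndarray | None
    covariance: np.ndarray
    threshold: float
    provenance: dict = field(default_factory=dict)
    cluster_cov: dict = field(default_factory=dict)

    @property
    def n_abnormal(self) -> int:
        return len(self.centroids) - 1

    def abnormal_mask(self) -> np.ndarray:
        """Boolean volume of all voxels in abnormal (non-normal) clusters."""
        out = np.zeros(self.grid_shape, dtype=bool)
        x, y, z = self.voxel_index.T
        out[x, y, z] = self.assignments > 0
        return out

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=len(self.centroids))


@dataclass
class SignatureMap:
    """Per-voxel normalized cluster value (1-100) and binned signature label."""

    normalized: np.ndarray  # float volume, 0 outside the analysis mask
    bins: np.ndarray  # int volume per BIN_CODES, -1 outside the analysis mask
    cluster_values: dict  # pruned cluster id -> normalized value
    provenance: np.ndarray  # pruned cluster id per voxel, -1 outside mask


def temporal_cov(
    centroid: np.ndarray,
    feature_index: tuple,
    column_means: np.ndarray | None = None,
    column_sds: np.ndarray | None = None,
) -> dict:
    """Coefficient of variation of a centroid's temporal trajectory.

    The centroid is first mapped back to relative units (if the features were
    z-scored), then for each parameter CoV = population sd over timepoints /
    mean over timepoints. The pooled value under key ``"pooled"`` is the
    maximum over parameters: a cluster temporally dynamic in any parameter
    counts as dynamic.
    """
    centroid = np.asarray(centroid, dtype=float)
    if column_means is not None:
        centroid = centroid * column_sds + column_means
    params = sorted({p for (_, p) in feature_index})
    out = {}
    for p in params:
        cols = [i for i, (_, fp) in enumerate(feature_index) if fp == p]
        if len(cols) < 2:
            raise ValueError(f"parameter {p!r} has fewer than 2 timepoints")
        traj = centroid[cols]
        mean = float(traj.mean())
        if mean == 0:
            raise ValueError(f"zero-mean trajectory for parameter {p!r}: CoV undefined")
        out[p] = float(traj.std() / abs(mean))
    out["pooled"] = max(out[p] for p in params)
    return out


def prune_by_cov(
    model: ClusterModel, threshold: float = DEFAULT_COV_THRESHOLD
) -> PrunedModel:
    """Merge temporally flat clusters (pooled CoV <= threshold) into "normal".

    Retained abnormal clusters keep their relative order; the normal cluster
    takes id 0 with a size-weighted mean centroid (zero vector if every
    cluster is abnormal and no normal voxels exist). Voxel counts are
    conserved: abnormal + normal = pre-pruning total.
    """
    if model.n_clusters < 1:
        raise ValueError("model has no clusters")
    covs = {
        j: temporal_cov(
            model.centroids[j], model.feature_index,
            model.column_means, model.column_sds,
        )["pooled"]
        for j in range(model.n_clusters)
    }
    normal_ids = [j for j in range(model.n_clusters) if covs[j] <= threshold]
    abnormal_ids = [j for j in range(model.n_clusters) if covs[j] > threshold]

    sizes = model.cluster_sizes()
    d = model.centroids.shape[1]
    if normal_ids:
        w = sizes[normal_ids].astype(float)
        normal_centroid = (w[:, None] * model.centroids[normal_ids]).sum(0) / w.sum()
    else:
        normal_centroid = np.zeros(d)
    centroids = np.vstack([normal_centroid[None, :], model.centroids[abnormal_ids]])

    remap = np.zeros(model.n_clusters, dtype=int)
    for new_id, j in enumerate(abnormal_ids, start=1):
        remap[j] = new_id
    assignments = remap[model.assignments]

    provenance = {0: normal_ids}
    for new_id, j in enumerate(abnormal_ids, start=1):
        provenance[new_id] = [j]
    return PrunedModel(
        centroids=centroids,
        assignments=assignments,
        voxel_index=model.voxel_index,
        feature_index=model.feature_index,
        grid_shape=model.grid_shape,
        column_means=model.column_means,
        column_sds=model.column_sds,
        covariance=model.covariance,
        threshold=threshold,
        provenance=provenance,
        cluster_cov=covs,
    )


def reference_feature_vectors(study: SerialStudy, feature_index: tuple) -> dict:
    """Mean relative-map feature vector of each reference ROI (WM, GM, CSF).

    Vectors are assembled in the same (timepoint, parameter) column order as
    the feature matrix, in relative units (not z-scored); CSF voxels sit
    outside the analysis mask but the relative maps are defined on the full
    grid, so the CSF anchor can still be synthesized.
    """
    out = {}
    for name, roi in study.ref_rois.items():
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            raise ValueError(f"reference ROI {name!r} is empty")
        vec = []
        for t, param in feature_index:
            if param not in RELATIVE_PARAMETERS:
                raise ValueError("feature index must reference relative parameters")
            vec.append(float(study.get_map(param, t).values[roi].mean()))
        out[name] = np.asarray(vec)
    return out


def normalize_clusters(
    model: PrunedModel, csf_ref: np.ndarray, wm_ref: np.ndarray
) -> SignatureMap:
    """Place clusters on the anchored 1-100 scale and bin them.

    Each cluster's raw position is s = |mu - wm| / (|mu - wm| + |mu - csf|)
    (Mahalanobis norms under the model covariance), monotone in relative
    proximity to the CSF anchor. Positions are affinely rescaled over the
    clusters so the WM-nearest cluster lands exactly at 1 and the
    CSF-nearest at 100 (value = 1 + 99 * s after rescaling). Reference
    vectors are given in relative units and are mapped into the model's
    feature space here.
    """
    csf_ref = np.asarray(csf_ref, dtype=float)
    wm_ref = np.asarray(wm_ref, dtype=float)
    if np.allclose(csf_ref, wm_ref):
        raise ValueError("CSF and WM reference vectors coincide")
    if model.column_means is not None:
        wm = (wm_ref - model.column_means) / model.column_sds
        csf = (csf_ref - model.column_means) / model.column_sds
    else:
        wm, csf = wm_ref, csf_ref

    scale = np.sqrt(model.covariance)
    C = model.centroids / scale
    d_wm = np.linalg.norm(C - wm / scale, axis=1)
    d_csf = np.linalg.norm(C - csf / scale, axis=1)
    s = d_wm / (d_wm + d_csf)
    if len(s) > 1 and s.max() > s.min():
        s = (s - s.min()) / (s.max() - s.min())
    else:
        s = np.zeros_like(s)
    values = 1.0 + 99.0 * np.clip(s, 0.0, 1.0)

    cluster_values = {j: float(values[j]) for j in range(len(values))}
    per_row = values[model.assignments]
    normalized = np.zeros(model.grid_shape, dtype=float)
    provenance = np.full(model.grid_shape, -1, dtype=np.int32)
    x, y, z = model.voxel_index.T
    normalized[x, y, z] = per_row
    provenance[x, y, z] = model.assignments

    bins = np.full(model.grid_shape, -1, dtype=np.int16)
    bins[x, y, z] = bin_signatures(per_row)
    return SignatureMap(
        normalized=normalized, bins=bins, cluster_values=cluster_values,
        provenance=provenance,
    )


def bin_signatures(values: np.ndarray) -> np.ndarray:
    """Map normalized values in [1, 100] to integer signature-bin codes.

    Bin ranges are closed on the right: values <= 5 are Signature N, 5-15 is
    I, 15-25 is B2, 25-35 is II, and so on in tens up to 100.
    """
    values = np.asarray(values, dtype=float)
    if values.size and (values.min() < 1.0 or values.max() > 100.0):
        raise ValueError("normalized values must lie in [1, 100]")
    edges = np.array([edge for edge, _ in BIN_EDGES], dtype=float)
    return np.searchsorted(edges, values, side="left").astype(np.int16)


def signature_time_profiles(
    signature_bins: np.ndarray,
    study: SerialStudy,
    region: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-signature temporal profiles of the relative maps.

    For every signature bin present in ``region`` (default: the ipsilateral
    analysis mask) and every (timepoint, relative parameter), reports the
    mean, population sd and voxel count over that signature's voxels. Empty
    signatures are simply absent from the output.
    """
    signature_bins = np.asarray(signature_bins)
    if signature_bins.shape != study.shape:
        raise ValueError("signature bins and study grid differ")
    if region is None:
        region = study.ipsilateral_region()
    else:
        region = np.asarray(region, dtype=bool)

    rows = []
    present = [int(c) for c in np.unique(signature_bins[region]) if c >= 0]
    for code in present:
        sel = region & (signature_bins == code)
        n = int(sel.sum())
        if n == 0:
            logger.info("signature %s empty within region; omitted", BIN_NAMES.get(code))
            continue
        for t in study.timepoints_h:
            for param in study.parameters_present(relative=True):
                vals = study.get_map(param, t).values[sel]
                rows.append(
                    {
                        "signature": BIN_NAMES.get(code, str(code)),
                        "timepoint_h": t,
                        "parameter": param,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std()),
                        "n": n,
                    }
                )
    return pd.DataFrame(
        rows, columns=["signature", "timepoint_h", "parameter", "mean", "sd", "n"]
    )
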