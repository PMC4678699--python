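"""Overlap scoring and the input-combination x CoV-threshold sweep.

The pipeline's segmentation quality is judged by the Dice similarity index
(DSI = 2 TP / (2 TP + FP + FN)) between the pruned abnormal region and the
reference "Maximal Lesion" ROI, evaluated within the ipsilateral analysis
mask. The sweep reruns the full chain (relative maps -> contiguity
weighting -> features -> ISODATA -> CoV pruning -> abnormal-region
extraction -> Dice) over every requested MRI-parameter combination and CoV
threshold; clustering does not depend on the CoV threshold, so each
combination is clustered once and pruned at every threshold.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .isodata import IsodataParams, derive_dispersion_params, run_isodata
from .preprocess import (
    SerialStudy,
    build_feature_matrix,
    compute_relative_maps,
    exclude_csf_vessels,
    spatial_contiguity_weight,
)
from .signatures import prune_by_cov

logger = logging.getLogger(__name__)

#: The six MRI input combinations evaluated in the sweep.
DEFAULT_COMBINATIONS = (
    ("ADC",),
    ("FA",),
    ("T2",),
    ("ADC", "FA"),
    ("ADC", "T2"),
    ("ADC", "FA", "T2"),
)

#: Default CoV threshold grid, descending 0.1 -> 0.01 in steps of 0.01.
DEFAULT_COV_THRESHOLDS = tuple(np.round(np.arange(0.10, 0.0099, -0.01), 2))


def combo_name(parameters: Sequence[str]) -> str:
    return "+".join(parameters)


@dataclass
class OverlapResult:
    """Confusion counts and Dice index of a predicted vs reference mask."""

    tp: int
    fp: int
    fn: int
    tn: int
    dsi: float

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class SweepResult:
    """Per-configuration DSI table and the best configuration found."""

    table: pd.DataFrame
    best_combination: str
    best_threshold: float
    best_mean_dsi: float
    errors: list = field(default_factory=list)

    def mean_dsi(self) -> pd.DataFrame:
        """Mean +/- sd DSI per (combination, threshold) over datasets."""
        g = self.table.groupby(["combination", "cov_threshold"])["dsi"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"mean": "mean_dsi", "std": "sd_dsi", "count": "n"})


def dice(
    predicted: np.ndarray,
    reference: np.ndarray,
    region: np.ndarray | None = None,
) -> OverlapResult:
    """Dice overlap of two boolean masks within an evaluation region.

    Both masks empty within the region scores DSI = 1 (perfect agreement on
    "nothing there"); a nonempty prediction against an empty reference
    scores 0.
    """
    predicted = np.asarray(predicted, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference mask shapes differ")
    if region is None:
        region = np.ones(predicted.shape, dtype=bool)
    else:
        region = np.asarray(region, dtype=bool)
        if region.shape != predicted.shape:
            raise ValueError("evaluation region shape differs")
    if not region.any():
        raise ValueError("evaluation region is empty")

    p = predicted[region]
    r = reference[region]
    tp = int((p & r).sum())
    fp = int((p & ~r).sum())
    fn = int((~p & r).sum())
    tn = int((~p & ~r).sum())
    denom = 2 * tp + fp + fn
    if denom == 0:
        logger.info("both masks empty in evaluation region; DSI defined as 1")
        dsi = 1.0
    else:
        dsi = 2.0 * tp / denom
    return OverlapResult(tp=tp, fp=fp, fn=fn, tn=tn, dsi=dsi)


def config_seed(master_seed: int, dataset_name: str, combination: str) -> int:
    """Stable per-(dataset, combination) seed below 2**31.

    Derived by hashing the configuration name, so the seed of a given run
    does not depend on the order in which the grid is traversed.
    """
    tag = f"{dataset_name}|{combination}".encode()
    return (int(master_seed) * 1_000_003 + zlib.crc32(tag)) % (2**31)


def masked_relative_study(study: SerialStudy) -> SerialStudy:
    """CSF/vessel exclusion plus relative-map computation (no smoothing).

    This is the study the per-signature temporal profiles are read from:
    contiguity weighting exists only to stabilize clustering and would bias
    profile means at lesion borders.
    """
    t0 = study.timepoints_h[0]
    analysis = exclude_csf_vessels(study.get_map("ADC", t0), study.brain_mask)
    study = SerialStudy(
        maps=dict(study.maps),
        brain_mask=study.brain_mask,
        hemisphere=study.hemisphere,
        ref_rois=study.ref_rois,
        lesion_rois=study.lesion_rois,
        analysis_mask=analysis,
    )
    return compute_relative_maps(study)


def preprocess_study(
    study: SerialStudy,
    parameters: Sequence[str] = ("ADC", "FA", "T2"),
    neighborhood_radius: int = 1,
    decay: float = 1.0,
    standardize: bool = True,
):
    """Run the standard preprocessing chain and return (study, features).

    Chain: CSF/vessel exclusion on the first-timepoint ADC map, relative-map
    computation, spatial contiguity weighting, feature-matrix assembly.
    """
    study = masked_relative_study(study)
    study = spatial_contiguity_weight(study, neighborhood_radius, decay)
    features = build_feature_matrix(study, parameters, standardize=standardize)
    return study, features


def segment_abnormal(
    study: SerialStudy,
    parameters: Sequence[str],
    params: IsodataParams,
    cov_threshold: float,
    seed: int,
):
    """Full chain from raw study to the pruned abnormal mask.

    Returns (abnormal mask restricted to the ipsilateral analysis mask,
    pruned model, raw cluster model, preprocessed study, features).
    phi_c/phi_s are derived from the study's WM/GM reference ROIs when the
    supplied params leave them unset.
    """
    prep, features = preprocess_study(study, parameters)
    if params.phi_c is None or params.phi_s is None:
        phi_c, phi_s = derive_dispersion_params(
            features, prep.ref_rois["WM"], prep.ref_rois["GM"]
        )
        params = IsodataParams(
            phi_n=params.phi_n,
            phi_c=params.phi_c if params.phi_c is not None else phi_c,
            phi_s=params.phi_s if params.phi_s is not None else phi_s,
            k_init=params.k_init,
            k_anchor=params.k_anchor,
            max_iter=params.max_iter,
            eps_r=params.eps_r,
            max_merges=params.max_merges,
        )
    model = run_isodata(features, params, seed=seed)
    pruned = prune_by_cov(model, cov_threshold)
    abnormal = pruned.abnormal_mask() & prep.ipsilateral_region()
    return abnormal, pruned, model, prep, features


def sweep(
    studies: dict,
    combinations: Sequence[Sequence[str]] = DEFAULT_COMBINATIONS,
    cov_thresholds: Sequence[float] = DEFAULT_COV_THRESHOLDS,
    params: IsodataParams | None = None,
    seed: int = 0,
) -> SweepResult:
    """Evaluate every (combination, CoV threshold) against the Maximal Lesion.

    ``studies`` maps dataset name -> SerialStudy carrying ``lesion_rois``
    with a maximal mask. For each dataset and combination the study is
    preprocessed and clustered once (with a seed derived from the master
    seed and the configuration name), then pruned at each threshold; the
    abnormal region is scored with :func:`dice` against the maximal ROI
    within the ipsilateral analysis mask. Failures are recorded per
    configuration and the sweep continues. The best configuration is the
    (combination, threshold) with highest mean DSI over datasets (ties:
    first in grid order).
    """
    if params is None:
        params = IsodataParams()
    rows = []
    errors = []
    for name, study in studies.items():
        if study.lesion_rois is None:
            raise ValueError(f"dataset {name!r} has no reference lesion ROIs")
        for combo in combinations:
            cname = combo_name(combo)
            run_seed = config_seed(seed, name, cname)
            try:
                prep, features = preprocess_study(study, combo)
                phi_c, phi_s = derive_dispersion_params(
                    features, prep.ref_rois["WM"], prep.ref_rois["GM"]
                )
                run_params = IsodataParams(
                    phi_n=params.phi_n,
                    phi_c=params.phi_c if params.phi_c is not None else phi_c,
                    phi_s=params.phi_s if params.phi_s is not None else phi_s,
                    k_init=params.k_init,
                    k_anchor=params.k_anchor,
                    max_iter=params.max_iter,
                    eps_r=params.eps_r,
                    max_merges=params.max_merges,
                )
                model = run_isodata(features, run_params, seed=run_seed)
            except Exception as exc:  # recorded, sweep continues
                errors.append({"dataset": name, "combination": cname, "error": str(exc)})
                logger.warning("sweep failure for %s/%s: %s", name, cname, exc)
                continue
            ipsi = prep.ipsilateral_region()
            reference = study.lesion_rois.maximal
            for thr in cov_thresholds:
                try:
                    pruned = prune_by_cov(model, float(thr))
                    abnormal = pruned.abnormal_mask() & ipsi
                    result = dice(abnormal, reference, region=ipsi)
                except Exception as exc:
                    errors.append(
                        {"dataset": name, "combination": cname,
                         "cov_threshold": float(thr), "error": str(exc)}
                    )
                    continue
                rows.append(
                    {
                        "dataset": name,
                        "combination": cname,
                        "cov_threshold": float(thr),
                        "seed": run_seed,
                        "n_clusters": model.n_clusters,
                        "n_abnormal": pruned.n_abnormal,
                        "tp": result.tp,
                        "fp": result.fp,
                        "fn": result.fn,
                        "tn": result.tn,
                        "dsi": result.dsi,
                    }
                )

    table = pd.DataFrame(
        rows,
        columns=["dataset", "combination", "cov_threshold", "seed", "n_clusters",
                 "n_abnormal", "tp", "fp", "fn", "tn", "dsi"],
    )
    if len(table):
        means = table.groupby(["combination", "cov_threshold"], sort=False)["dsi"].mean()
        best_key = means.idxmax()
        best = SweepResult(
            table=table,
            best_combination=best_key[0],
            best_threshold=float(best_key[1]),
            best_mean_dsi=float(means.loc[best_key]),
            errors=errors,
        )
    else:
        best = SweepResult(
            table=table, best_combination="", best_threshold=float("nan"),
            best_mean_dsi=float("nan"), errors=errors,
        )
    return best
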