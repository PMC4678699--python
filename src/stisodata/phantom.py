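"""Synthetic serial stroke-MRI phantom with ground-truth labels.

Generates an aligned, skull-stripped serial study (quantitative ADC, FA and
T2 volumes at seven post-stroke timepoints) in which ischemic lesion regions
follow configurable relative-value time-courses, so every downstream stage —
preprocessing, ISODATA clustering, CoV pruning, signature binning, tissue
classification and Dice evaluation — can be exercised end to end with a
known answer.

Anatomy is deliberately simple: an ellipsoidal brain split at the
mid-sagittal plane (left hemisphere ipsilateral by convention), a grey-matter
shell over a white-matter interior, and a central CSF compartment whose high
ADC places it above the CSF/vessel exclusion threshold. Abnormal "signature"
regions are ellipsoids planted in the ipsilateral hemisphere; each follows a
named temporal profile of relative-ADC/FA/T2 multipliers.

Lesion voxels are anchored to the contralateral analysis-mask mean of each
parameter rather than to the local compartment baseline: the profiles are
*relative* time-courses, so generating the lesion as (hemispheric reference
mean x multiplier) guarantees that contralateral normalization recovers the
configured multipliers exactly on a noiseless phantom, independent of the
WM/GM composition of the normal hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .preprocess import (
    ADC_CSF_THRESHOLD,
    HEMI_CONTRA,
    HEMI_IPSI,
    HEMI_NONE,
    PARAMETERS,
    QuantMap,
    SerialStudy,
    exclude_csf_vessels,
)
from .tissue_classes import LesionROISet, classify_tissue

#: Abnormal signature names, plus N for normal tissue.
SIGNATURE_IDS = ("N", "I", "II", "III", "IV", "V")

#: Integer codes for truth label volumes (0 = normal tissue).
SIGNATURE_CODES = {"N": 0, "I": 1, "II": 2, "III": 3, "IV": 4, "V": 5}

#: Generative-label codes for normal-tissue compartments (truth partition of
#: the analysis mask: each compartment and each planted signature is one class).
COMPARTMENT_CODES = {"WM": 101, "GM": 102, "CSF": 103}

DEFAULT_TIMEPOINTS_H = (1.0, 2.0, 3.0, 24.0, 72.0, 144.0, 240.0)

#: Physiologically typical compartment baselines (ADC mm^2/s, FA, T2 ms).
#: CSF ADC sits above the 1.2e-3 exclusion threshold by construction.
DEFAULT_BASELINES = {
    "WM": (0.70e-3, 0.45, 80.0),
    "GM": (0.80e-3, 0.15, 95.0),
    "CSF": (3.0e-3, 0.05, 2000.0),
}

# Default per-signature relative multipliers at the seven default timepoints.
# Anchors are chosen to satisfy the qualitative temporal orderings that
# distinguish the signatures; each row notes the constraints it encodes.
DEFAULT_PROFILES = {
    # Normal tissue is the unit profile at every timepoint.
    "N": {
        "rADC": (1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
        "rFA": (1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
        "rT2": (1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
    },
    # I: acute rADC not depressed; slow chronic rADC decline. rFA declines to
    # 144 h then renormalizes. rT2 rises to 144 h then falls back.
    "I": {
        "rADC": (1.00, 1.00, 1.00, 1.02, 1.00, 0.95, 0.90),
        "rFA": (1.00, 0.99, 0.98, 0.92, 0.85, 0.80, 0.90),
        "rT2": (1.00, 1.02, 1.05, 1.30, 1.50, 1.60, 1.45),
    },
    # II: strong acute rADC drop (second-deepest), deepening through 24 h,
    # then slow renormalization. rFA declines through 144 h. rT2 rises
    # monotonically across all timepoints.
    "II": {
        "rADC": (0.65, 0.63, 0.60, 0.55, 0.60, 0.70, 0.80),
        "rFA": (1.00, 0.98, 0.96, 0.85, 0.75, 0.65, 0.62),
        "rT2": (1.02, 1.05, 1.08, 1.40, 1.60, 1.75, 1.85),
    },
    # III: rADC normal acutely, depressed from 24 h then recovering. rT2
    # rises progressively and stabilizes from 72 h on.
    "III": {
        "rADC": (1.00, 0.98, 0.95, 0.75, 0.78, 0.85, 0.92),
        "rFA": (1.00, 0.99, 0.97, 0.88, 0.80, 0.72, 0.70),
        "rT2": (1.00, 1.03, 1.06, 1.35, 1.55, 1.56, 1.56),
    },
    # IV: moderate acute rADC drop with a sharp rise in the first 24 h, then
    # a slow chronic decline. rFA declines to 144 h then renormalizes. rT2
    # rises fastest between 3 and 24 h (bar signature V), peaks at 144 h.
    "IV": {
        "rADC": (0.75, 0.75, 0.78, 1.05, 1.00, 0.95, 0.88),
        "rFA": (1.00, 0.98, 0.96, 0.86, 0.78, 0.72, 0.85),
        "rT2": (1.00, 1.02, 1.05, 1.60, 1.75, 1.85, 1.70),
    },
    # V: deepest acute rADC drop, then progressive increase through 240 h.
    # Only signature with acutely depressed rFA, declining further. rT2
    # rises monotonically and fastest of all.
    "V": {
        "rADC": (0.50, 0.50, 0.52, 0.70, 0.85, 1.00, 1.15),
        "rFA": (0.80, 0.78, 0.75, 0.65, 0.55, 0.50, 0.48),
        "rT2": (1.05, 1.10, 1.15, 1.75, 1.95, 2.10, 2.25),
    },
}

#: Additive Gaussian noise sd per parameter, 5% of the WM baseline.
DEFAULT_NOISE_SD = {"ADC": 0.035e-3, "FA": 0.0225, "T2": 4.0}

_REL_OF_PARAM = {"ADC": "rADC", "FA": "rFA", "T2": "rT2"}


@dataclass
class SignatureRegion:
    """An ellipsoidal lesion region carrying one signature profile."""

    signature: str
    center: tuple
    radii: tuple

    def __post_init__(self) -> None:
        if self.signature not in SIGNATURE_IDS or self.signature == "N":
            raise ValueError(
                f"unknown signature {self.signature!r}; "
                f"valid abnormal ids: {SIGNATURE_IDS[1:]}"
            )
        if len(self.center) != 3 or len(self.radii) != 3:
            raise ValueError("center and radii must be 3-vectors (voxels)")
        if any(r <= 0 for r in self.radii):
            raise ValueError("ellipsoid radii must be positive")

    def mask(self, shape: tuple) -> np.ndarray:
        idx = np.indices(shape, dtype=float)
        r2 = sum(
            ((idx[a] - self.center[a]) / self.radii[a]) ** 2 for a in range(3)
        )
        return r2 <= 1.0


# Default lesion load: three ellipsoids carrying the signatures with
# acutely depressed ADC (II, IV, V), planted in the left (ipsilateral)
# hemisphere of the default 64 x 64 x 24 grid.
DEFAULT_REGIONS = (
    SignatureRegion("II", center=(18, 24, 12), radii=(7.0, 7.0, 5.0)),
    SignatureRegion("IV", center=(14, 40, 11), radii=(6.0, 6.0, 4.0)),
    SignatureRegion("V", center=(24, 48, 12), radii=(5.0, 5.0, 4.0)),
)


@dataclass
class PhantomConfig:
    """Full description of a synthetic serial stroke study."""

    grid_shape: tuple = (64, 64, 24)
    voxel_size_mm: tuple = (1.5, 1.5, 2.5)
    timepoints_h: tuple = DEFAULT_TIMEPOINTS_H
    compartment_baselines: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    signature_regions: Sequence[SignatureRegion] = DEFAULT_REGIONS
    signature_profiles: Mapping[str, Mapping[str, tuple]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROFILES.items()}
    )
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    seed: int = 0
    #: Relative-value thresholds defining "abnormal" for truth ROIs: a voxel
    #: is acutely abnormal if its noiseless 1-h rADC < adc_abnormal_rel, and
    #: T2-abnormal if its noiseless rT2 > t2_abnormal_rel. Chosen to separate
    #: normal-tissue relative values (WM ~0.95-1.0, GM ~1.1-1.15) from the
    #: planted lesion profiles.
    adc_abnormal_rel: float = 0.85
    t2_abnormal_rel: float = 1.25

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.timepoints_h = tuple(float(t) for t in self.timepoints_h)
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if list(self.timepoints_h) != sorted(set(self.timepoints_h)):
            raise ValueError("timepoints_h must be strictly increasing")
        for name, (adc, fa, t2) in self.compartment_baselines.items():
            if adc <= 0 or t2 <= 0 or fa <= 0:
                raise ValueError(f"compartment {name!r} baselines must be positive")
            if not 0 <= fa <= 1:
                raise ValueError(f"compartment {name!r} FA baseline outside [0, 1]")
        for sd in self.noise_sd.values():
            if sd < 0:
                raise ValueError("noise_sd must be >= 0")
        for sig, table in self.signature_profiles.items():
            for param, mults in table.items():
                mults = tuple(mults)
                if len(mults) != len(self.timepoints_h):
                    raise ValueError(
                        f"profile {sig}/{param} has {len(mults)} anchors for "
                        f"{len(self.timepoints_h)} timepoints"
                    )
                if any(m <= 0 for m in mults):
                    raise ValueError(f"profile {sig}/{param} multipliers must be positive")
        nx = self.grid_shape[0]
        for region in self.signature_regions:
            if region.center[0] + region.radii[0] >= nx / 2.0:
                raise ValueError(
                    f"signature region {region.signature} extends beyond the "
                    "ipsilateral (left, x < nx/2) hemisphere"
                )


@dataclass
class PhantomDataset:
    """A generated phantom: the study plus every piece of ground truth."""

    study: SerialStudy
    truth_labels: np.ndarray  # signature code per voxel, 0 = normal
    truth_rois: LesionROISet
    truth_classes: np.ndarray  # tissue-class code per voxel
    generative_labels: np.ndarray  # compartment or signature code per voxel
    config: PhantomConfig


def signature_profile(
    signature_id: str,
    timepoint_h: float,
    profiles: Mapping | None = None,
    timepoints_h: Sequence[float] = DEFAULT_TIMEPOINTS_H,
) -> tuple:
    """Relative (rADC, rFA, rT2) multipliers of a signature at a timepoint.

    At configured timepoints the anchor values are returned exactly; between
    them the profile is interpolated piecewise-linearly in log-time (the
    anchors are roughly geometrically spaced, so log-time interpolation keeps
    the early time-course from being dominated by the chronic anchors).
    """
    profiles = DEFAULT_PROFILES if profiles is None else profiles
    if signature_id not in profiles:
        raise KeyError(
            f"unknown signature {signature_id!r}; valid ids: {sorted(profiles)}"
        )
    if timepoint_h <= 0:
        raise ValueError("timepoint_h must be positive")
    table = profiles[signature_id]
    log_t = np.log(np.asarray(timepoints_h, dtype=float))
    out = []
    for param in ("rADC", "rFA", "rT2"):
        anchors = np.asarray(table[param], dtype=float)
        out.append(float(np.interp(np.log(timepoint_h), log_t, anchors)))
    return tuple(out)


def _build_anatomy(config: PhantomConfig):
    """Compartment labels, brain mask and hemisphere labels for the grid."""
    shape = config.grid_shape
    idx = np.indices(shape, dtype=float)
    center = [(n - 1) / 2.0 for n in shape]
    radii = [0.45 * n for n in shape]
    rho = np.sqrt(sum(((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3)))
    brain = rho <= 1.0

    compartments = np.zeros(shape, dtype=np.int16)
    compartments[brain] = COMPARTMENT_CODES["WM"]
    compartments[brain & (rho > 0.72)] = COMPARTMENT_CODES["GM"]

    # Central ventricle-like CSF compartment straddling the midline.
    csf_radii = (max(3.0, 0.08 * shape[0]), max(5.0, 0.14 * shape[1]), max(2.0, 0.10 * shape[2]))
    csf_r2 = sum(((idx[a] - center[a]) / csf_radii[a]) ** 2 for a in range(3))
    csf = (csf_r2 <= 1.0) & brain
    compartments[csf] = COMPARTMENT_CODES["CSF"]

    hemisphere = np.full(shape, HEMI_NONE, dtype=np.int16)
    x = idx[0]
    hemisphere[brain & (x < shape[0] / 2.0)] = HEMI_IPSI
    hemisphere[brain & (x >= shape[0] / 2.0)] = HEMI_CONTRA
    return compartments, brain, hemisphere


def _reference_rois(config, compartments, brain, hemisphere):
    """Contralateral WM / contralateral GM / CSF reference masks."""
    contra = hemisphere == HEMI_CONTRA
    wm = (compartments == COMPARTMENT_CODES["WM"]) & contra
    gm = (compartments == COMPARTMENT_CODES["GM"]) & contra
    csf = compartments == COMPARTMENT_CODES["CSF"]

    # Trim WM/GM reference ROIs to compact cores so they resemble manually
    # placed reference regions rather than whole-compartment masks.
    nx, ny, nz = config.grid_shape
    box = np.zeros(config.grid_shape, dtype=bool)
    box[int(0.60 * nx) : int(0.85 * nx), int(0.30 * ny) : int(0.70 * ny), :] = True
    wm_roi = wm & box
    gm_roi = gm & box
    if not wm_roi.any():
        wm_roi = wm
    if not gm_roi.any():
        gm_roi = gm
    return {"WM": wm_roi, "GM": gm_roi, "CSF": csf}


def generate_phantom(config: PhantomConfig | None = None) -> PhantomDataset:
    """Generate a seed-deterministic synthetic serial stroke study.

    Normal-tissue voxels take their compartment baseline at every timepoint;
    lesion voxels take (contralateral reference mean x profile multiplier);
    independent Gaussian noise is added per voxel/timepoint/parameter, with
    FA clipped to [0, 1] and ADC/T2 clipped at 0. Truth ROIs are derived from
    the noiseless relative maps (acute: 1-h rADC below threshold; chronic:
    final-timepoint rT2 above threshold; maximal: the abnormal extent at the
    timepoint where it is largest), and truth tissue classes follow from the
    ROIs by their defining set relations.
    """
    if config is None:
        config = PhantomConfig()
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape

    compartments, brain, hemisphere = _build_anatomy(config)
    ref_rois = _reference_rois(config, compartments, brain, hemisphere)

    # Truth signature labels; overlapping regions with different ids are an error.
    truth_labels = np.zeros(shape, dtype=np.int16)
    for region in config.signature_regions:
        m = region.mask(shape) & brain & (hemisphere == HEMI_IPSI)
        code = SIGNATURE_CODES[region.signature]
        clash = m & (truth_labels != 0) & (truth_labels != code)
        if clash.any():
            raise ValueError(
                f"signature region {region.signature} overlaps a region with a "
                "different signature id"
            )
        truth_labels[m] = code

    # Noiseless per-parameter baseline volumes.
    base = {}
    for ip, param in enumerate(PARAMETERS):
        vol = np.zeros(shape, dtype=float)
        for name, values in config.compartment_baselines.items():
            vol[compartments == COMPARTMENT_CODES[name]] = values[ip]
        base[param] = vol

    # Contralateral analysis-mask reference means (time-constant, noiseless).
    adc_map = QuantMap(base["ADC"], "ADC", config.timepoints_h[0])
    analysis = exclude_csf_vessels(adc_map, brain)
    contra_ref = (hemisphere == HEMI_CONTRA) & analysis
    if not contra_ref.any():
        raise ValueError("phantom has no contralateral analysis voxels")
    ref_mean = {p: float(base[p][contra_ref].mean()) for p in PARAMETERS}

    code_to_sig = {v: k for k, v in SIGNATURE_CODES.items()}
    lesion_codes = [c for c in np.unique(truth_labels) if c != 0]

    def noiseless_volume(param: str, t: float) -> np.ndarray:
        vol = base[param].copy()
        for code in lesion_codes:
            sig = code_to_sig[int(code)]
            mult = signature_profile(
                sig, t, config.signature_profiles, config.timepoints_h
            )[PARAMETERS.index(param)]
            vol[truth_labels == code] = ref_mean[param] * mult
        return vol

    maps = {}
    for t in config.timepoints_h:
        for param in PARAMETERS:
            vol = noiseless_volume(param, t)
            sd = float(config.noise_sd.get(param, 0.0))
            if sd > 0:
                vol = vol + rng.normal(0.0, sd, size=shape)
            vol[~brain] = 0.0
            if param == "FA":
                vol = np.clip(vol, 0.0, 1.0)
            else:
                vol = np.clip(vol, 0.0, None)
            maps[(param, t)] = QuantMap(vol, param, t)

    # Truth ROIs from the noiseless relative maps.
    t_first, t_last = config.timepoints_h[0], config.timepoints_h[-1]
    acute = (noiseless_volume("ADC", t_first) / ref_mean["ADC"] < config.adc_abnormal_rel) & analysis
    chronic = (noiseless_volume("T2", t_last) / ref_mean["T2"] > config.t2_abnormal_rel) & analysis

    best_t, best_extent, best_count = t_first, acute, -1
    for t in config.timepoints_h:
        extent = (
            (noiseless_volume("ADC", t) / ref_mean["ADC"] < config.adc_abnormal_rel)
            | (noiseless_volume("T2", t) / ref_mean["T2"] > config.t2_abnormal_rel)
        ) & analysis
        count = int(extent.sum())
        if count > best_count:
            best_t, best_extent, best_count = t, extent, count
    truth_rois = LesionROISet(
        acute=acute,
        maximal=best_extent,
        chronic=chronic,
        maximal_timepoint_h=best_t,
        chronic_timepoint_h=t_last,
    )
    truth_classes = classify_tissue(truth_rois, brain)

    generative_labels = np.where(truth_labels > 0, truth_labels, compartments)
    generative_labels[~brain] = 0

    study = SerialStudy(
        maps=maps,
        brain_mask=brain,
        hemisphere=hemisphere,
        ref_rois=ref_rois,
        lesion_rois=truth_rois,
    )
    return PhantomDataset(
        study=study,
        truth_labels=truth_labels,
        truth_rois=truth_rois,
        truth_classes=truth_classes,
        generative_labels=generative_labels,
        config=config,
    )
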