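"""In-memory pipeline stages: simulate → preprocess → relaxometry → MT fit →
CEST/rNOE isolation → segmentation → report.

Each stage is a plain function over the previous stage's dataclasses, so the
CLI, the tests and cohort studies share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cest, preprocessing, relaxometry, segmentation, stats
from .phantom import (PhantomSpec, Protocol, REGION_LABELS, SyntheticStudy,
                      default_phantom_spec, make_phantom, simulate_study)
from .qmt import TwoPoolMTModel

HIGH_B1_UT = (3.0, 6.0)
LOW_B1_UT = (0.5, 2.0)
WASSR_B1 = 0.1


@dataclass
class PreprocessedStudy:
    study: SyntheticStudy
    z: dict                    # b1 -> (offsets_ppm, corrected stack)
    drift: dict                # b1 -> DriftModel
    b0_shift_ppm: np.ndarray   # WASSR-derived per-voxel shift
    b0_valid: np.ndarray
    mask: np.ndarray           # eroded foreground ∧ B0-valid
    report: dict = field(default_factory=dict)


def preprocess_study(study: SyntheticStudy,
                     b0_threshold_ppm: float = preprocessing.B0_EXCLUSION_PPM,
                     lowb1_b0: bool = True,
                     lowb1_b0_mode: str = "wassr") -> PreprocessedStudy:
    """Drift-correct every stack, map B0 from WASSR, re-centre the WASSR and
    low-B1 spectra voxelwise, and build the analysis mask.

    ``lowb1_b0_mode``: "wassr" re-centres the 0.5/2 µT spectra with the
    CEST-free WASSR shift map (the B0 field is common to all spectra and the
    two-Lorentzian fit is biased by the CEST/rNOE peaks it does not model);
    "lorentzian" uses each spectrum's own two-Lorentzian fit.
    """
    fg = study.geometry.mask
    eroded = preprocessing.erode_mask(fg)
    z, drift = {}, {}
    for b1, stack in study.zspec.items():
        corrected, model = preprocessing.drift_correct(
            stack.frames, stack.reference_indices)
        z[b1] = (stack.measurement_offsets,
                 corrected[~stack.is_reference])
        drift[b1] = model

    offs_w, wassr = z[WASSR_B1]
    shift, shift_ok = preprocessing.fit_b0_map(offs_w, wassr, eroded,
                                               mode="wassr")
    b0_valid = preprocessing.exclude_b0_outliers(shift, b0_threshold_ppm)
    mask = eroded & b0_valid & shift_ok

    z[WASSR_B1] = (offs_w, preprocessing.recenter_stack(offs_w, wassr,
                                                        shift, mask))
    for b1 in LOW_B1_UT:
        if b1 not in z or not lowb1_b0:
            continue
        offs, stack = z[b1]
        if lowb1_b0_mode == "lorentzian":
            lshift, lok = preprocessing.fit_b0_map(offs, stack, mask,
                                                   mode="lowb1")
            lshift = np.where(lok, lshift, shift)  # fall back to WASSR map
        else:
            lshift = shift
        z[b1] = (offs, preprocessing.recenter_stack(offs, stack, lshift,
                                                    mask))

    mean_slope = float(np.nanmean([np.nanmean(np.asarray(m.slope)[fg])
                                   for m in drift.values()]))
    report = {
        "mean_drift_slope_per_index": mean_slope,
        "excluded_b0_voxels": int((eroded & ~b0_valid).sum()),
        "n_voxels": int(mask.sum()),
    }
    return PreprocessedStudy(study=study, z=z, drift=drift,
                             b0_shift_ppm=shift, b0_valid=b0_valid,
                             mask=mask, report=report)


@dataclass
class RelaxometryMaps:
    t1_ms: np.ndarray
    t2_ms: np.ndarray
    s0: np.ndarray
    valid: np.ndarray


def relaxometry_stage(pre: PreprocessedStudy) -> RelaxometryMaps:
    """Per-voxel T1 from the IR series and T2 from the corrected WASSR."""
    study = pre.study
    t1, s0, ok1 = relaxometry.fit_t1_map(
        study.ir_frames, study.protocol.tis_ms, study.protocol.tr_ms,
        mask=pre.mask)
    offs, wassr = pre.z[WASSR_B1]
    t2, ok2 = relaxometry.fit_t2_map(offs, wassr, t1, b1_ut=WASSR_B1,
                                     f0_mhz=study.protocol.f0_mhz,
                                     mask=pre.mask & ok1)
    return RelaxometryMaps(t1_ms=t1, t2_ms=t2, s0=s0, valid=ok1 & ok2)


def roi_mean_spectra(pre: PreprocessedStudy, roi_mask,
                     b1_levels=( WASSR_B1, ) + HIGH_B1_UT) -> dict:
    """ROI-mean Z-spectra for the requested B1 levels."""
    out = {}
    for b1 in b1_levels:
        offs, stack = pre.z[b1]
        mean, _ = stats.roi_zspectrum(stack, roi_mask)
        out[b1] = (offs, mean)
    return out


def qmt_stage(pre: PreprocessedStudy, relax: RelaxometryMaps,
              region_masks: dict, seed: int = 0) -> dict:
    """Two-pool MT fit of ROI-mean spectra for each region (ROI mode).

    Fits the high-B1 (3, 6 µT) spectra; the WASSR spectrum's direct-
    saturation information enters through the T1/T2 maps instead, because
    the phantom simulates it from the observed-relaxation single-pool model
    rather than the two-pool model.  Returns ``{region: TwoPoolMTResults}``.
    """
    out = {}
    for region, roi in region_masks.items():
        roi = roi & pre.mask & np.isfinite(relax.t1_ms)
        if roi.sum() == 0:
            continue
        spectra = roi_mean_spectra(pre, roi, b1_levels=HIGH_B1_UT)
        t1 = float(np.nanmean(relax.t1_ms[roi]))
        out[region] = TwoPoolMTModel(
            spectra, t1, f0_mhz=pre.study.protocol.f0_mhz).fit(seed=seed)
    return out


def broadcast_mt_params(mt_results: dict, label_image,
                        region_masks: dict):
    """Voxel lookup of region-wise MT fits for per-voxel CEST maps."""
    param_image = {}
    for region, res in mt_results.items():
        for i, j in zip(*np.nonzero(region_masks[region])):
            param_image[(i, j)] = res.params
    return lambda i, j: param_image.get((i, j))


def cest_stage(pre: PreprocessedStudy, relax: RelaxometryMaps,
               mt_results: dict, region_masks: dict,
               pool_offsets=cest.DEFAULT_POOL_OFFSETS_PPM) -> dict:
    """MTR_REX and AREX maps at each pool offset for both low-B1 levels."""
    lowb1 = {b1: pre.z[b1] for b1 in LOW_B1_UT if b1 in pre.z}
    params_fn = broadcast_mt_params(mt_results, pre.study.label_image,
                                    region_masks)
    roi_union = np.zeros_like(pre.mask)
    for roi in region_masks.values():
        roi_union |= roi
    return cest.cest_maps(lowb1, params_fn, relax.t1_ms,
                          pre.mask & roi_union, pool_offsets,
                          f0_mhz=pre.study.protocol.f0_mhz)


def segmentation_stage(pre: PreprocessedStudy, relax: RelaxometryMaps,
                       tumour_type: str, seed: int = 0
                       ) -> segmentation.SegmentationResult:
    """Observation matrix → ICA → GMM → labelled clusters."""
    t1n, t2n = preprocessing.normalize_maps(relax.t1_ms, relax.t2_ms)
    stacks = [pre.z[b1][1] for b1 in HIGH_B1_UT]
    mask = pre.mask & np.isfinite(t1n) & np.isfinite(t2n)
    matrix = segmentation.build_observation_matrix(t1n, t2n, stacks, mask)
    return segmentation.SegmentationModel(matrix, tumour_type).fit(seed=seed)


def truth_region_masks(study: SyntheticStudy,
                       regions=("tumour", "necrosis")) -> dict:
    return {r: study.label_image == REGION_LABELS[r] for r in regions}


@dataclass
class StudyRun:
    study: SyntheticStudy
    pre: PreprocessedStudy
    relax: RelaxometryMaps
    mt: dict
    cest_maps: dict
    seg: segmentation.SegmentationResult | None


def run_study(spec: PhantomSpec | None = None,
              protocol: Protocol | None = None,
              tumour_type: str = "22Rv1", seed: int = 0,
              segment: bool = True) -> StudyRun:
    """Simulate one animal and run every stage on it."""
    spec = spec or default_phantom_spec(tumour_type, seed=seed)
    protocol = protocol or Protocol()
    study = simulate_study(make_phantom(spec), protocol, seed=seed)
    pre = preprocess_study(study)
    relax = relaxometry_stage(pre)
    rois = truth_region_masks(study)
    mt = qmt_stage(pre, relax, rois, seed=seed)
    cmaps = cest_stage(pre, relax, mt, rois)
    seg = (segmentation_stage(pre, relax, tumour_type, seed=seed)
           if segment else None)
    return StudyRun(study=study, pre=pre, relax=relax, mt=mt,
                    cest_maps=cmaps, seg=seg)


def per_animal_table(runs: dict) -> pd.DataFrame:
    """Per-animal ROI-mean metrics table for the report stage.

    `runs`: ``{tumour_type: [StudyRun, ...]}``.
    """
    rows = []
    for ttype, run_list in runs.items():
        for animal, run in enumerate(run_list):
            rois = truth_region_masks(run.study)
            for region, roi in rois.items():
                roi = roi & run.pre.mask

                def add(metric, value):
                    rows.append({"tumour_type": ttype, "region": region,
                                 "animal": animal, "metric": metric,
                                 "value": float(value)})

                if roi.any():
                    add("t1_obs_ms", np.nanmean(run.relax.t1_ms[roi]))
                    add("t2_obs_ms", np.nanmean(run.relax.t2_ms[roi]))
                if region in run.mt:
                    res = run.mt[region]
                    add("t2_f_ms", res.params.t2_f_ms)
                    add("mt_effect_hz", res.mt_effect_hz)
                    add("t2_mt_us", res.params.t2_mt_us)
                for (metric, b1, off), m in run.cest_maps.items():
                    if metric == "arex" and roi.any():
                        add(f"arex_{off}ppm_{b1}uT", np.nanmean(m[roi]))
    return pd.DataFrame(rows)
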