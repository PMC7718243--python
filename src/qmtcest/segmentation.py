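"""Intratumoural segmentation: ICA feature reduction + Gaussian-mixture
clustering + rule-based tissue labelling.

Normalized T1 and T2 maps and the high-B1 (3 and 6 µT) Z-spectrum images of
all non-background voxels are concatenated into an observation matrix
(one row per voxel).  FastICA reduces it to three independent components,
which are sorted by increasing normalized mutual information against the
mean of all input images and then weighted per tumour type (IC1:IC2:IC3 =
2:3:1 for 22Rv1, 1:3:2 for DU145).  A five-component full-covariance
Gaussian mixture is fitted in the weighted IC space and each cluster is
assigned a tissue class by fixed rules:

1. the cluster with the largest |mean IC1| is blood/edema;
2. the IC axes are reflected as needed so that cluster's mean lies in the
   first octant (ICA does not fix source signs);
3. the remaining four clusters, ranked by ascending mean IC2, are labelled
   muscle, muscle/connective, necrosis/apoptosis, active tumour (DU145) or
   active tumour, muscle/connective, necrosis/apoptosis, muscle (22Rv1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.metrics import normalized_mutual_info_score
from sklearn.mixture import GaussianMixture

N_COMPONENTS = 3
N_CLUSTERS = 5
NMI_BINS = 32

IC_WEIGHTS = {"22Rv1": (2.0, 3.0, 1.0), "DU145": (1.0, 3.0, 2.0)}

#: ascending-IC2 label order of the four non-blood clusters, per tumour type
IC2_LABEL_ORDER = {
    "DU145": ("muscle", "muscle_connective", "necrosis", "tumour"),
    "22Rv1": ("tumour", "muscle_connective", "necrosis", "muscle"),
}

SEGMENTATION_CLASSES = ("tumour", "necrosis", "muscle", "muscle_connective",
                       "blood_edema")


@dataclass
class ObservationMatrix:
    """Voxel-by-feature matrix with the index map back onto the grid."""

    data: np.ndarray                 # (n_voxels, n_features)
    voxel_index: np.ndarray          # (n_voxels, 2) row/col of each row
    grid_shape: tuple

    def to_image(self, values) -> np.ndarray:
        img = np.full(self.grid_shape, np.nan)
        img[self.voxel_index[:, 0], self.voxel_index[:, 1]] = values
        return img


@dataclass
class ICResult:
    scores: np.ndarray               # (n_voxels, 3), sorted and weighted
    mixing: np.ndarray
    unmixing: np.ndarray
    nmi_scores: np.ndarray           # ascending, one per IC
    weights: np.ndarray


@dataclass
class SegmentationResult:
    cluster_means: np.ndarray        # (5, 3) in weighted IC space
    cluster_covariances: np.ndarray
    cluster_weights: np.ndarray
    cluster_labels: dict | None      # cluster index -> class name
    voxel_clusters: np.ndarray       # (n_voxels,)
    posteriors: np.ndarray           # (n_voxels, 5)
    observation: ObservationMatrix

    def label_image(self) -> np.ndarray:
        """Class-name label map (object array, NaN-free masked by None)."""
        from .phantom import REGION_LABELS
        img = np.zeros(self.observation.grid_shape, dtype=np.int16)
        if self.cluster_labels is None:
            raise ValueError("clusters are unlabelled; run assign_labels first")
        codes = np.array([REGION_LABELS[self.cluster_labels[c]]
                          for c in range(len(self.cluster_weights))])
        img[self.observation.voxel_index[:, 0],
            self.observation.voxel_index[:, 1]] = codes[self.voxel_clusters]
        return img


def build_observation_matrix(t1_norm, t2_norm, highb1_images,
                             background_mask) -> ObservationMatrix:
    """Stack normalized maps and high-B1 frames into (voxels × features).

    Parameters
    ----------
    t1_norm, t2_norm : 2-D maps already scaled by 4000/300 ms.
    highb1_images : sequence of (n_frames, H, W) stacks (3 then 6 µT).
    background_mask : True where voxels are retained (after erosion and
        B0 exclusion).  Row order is the row-major grid scan.
    """
    mask = np.asarray(background_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no voxels to segment")
    idx = np.argwhere(mask)
    cols = [np.asarray(t1_norm, dtype=float)[mask],
            np.asarray(t2_norm, dtype=float)[mask]]
    for stack in highb1_images:
        stack = np.asarray(stack, dtype=float)
        cols.extend(stack[k][mask] for k in range(stack.shape[0]))
    data = np.column_stack(cols)
    good = np.all(np.isfinite(data), axis=1)
    return ObservationMatrix(data=data[good], voxel_index=idx[good],
                             grid_shape=mask.shape)


def run_ica(matrix: ObservationMatrix, n_components: int = N_COMPONENTS,
            seed: int = 0) -> ICResult:
    """FastICA reduction of the observation matrix (unsorted components)."""
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=2000, tol=1e-6)
    try:
        scores = ica.fit_transform(matrix.data)
    except ValueError as err:
        raise RuntimeError(f"ICA failed: {err}") from err
    if ica.n_iter_ >= 2000:
        raise RuntimeError("FastICA did not converge "
                           f"({ica.n_iter_} iterations)")
    return ICResult(scores=scores, mixing=ica.mixing_,
                    unmixing=ica.components_,
                    nmi_scores=np.full(n_components, np.nan),
                    weights=np.ones(n_components))


def quantize(values, bins: int = NMI_BINS) -> np.ndarray:
    """Uniform quantization of a continuous image into integer levels."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros(v.shape, dtype=int)
    edges = np.linspace(lo, hi, bins + 1)
    return np.clip(np.digitize(v, edges[1:-1]), 0, bins - 1)


def nmi_to_reference(component, reference, bins: int = NMI_BINS) -> float:
    """Arithmetic-mean-normalized mutual information on quantized values."""
    q1 = quantize(component, bins)
    q2 = quantize(reference, bins)
    if q1.max() == 0 or q2.max() == 0:   # constant input: NMI defined as 0
        return 0.0
    return float(normalized_mutual_info_score(q1, q2,
                                              average_method="arithmetic"))


def sort_and_weight_ics(ics: ICResult, protocol_mean, tumour_type: str,
                        bins: int = NMI_BINS) -> ICResult:
    """Sort ICs by ascending NMI against the mean image, then weight them."""
    weights = np.asarray(IC_WEIGHTS[tumour_type], dtype=float)
    ref = np.asarray(protocol_mean, dtype=float).ravel()
    nmi = np.array([nmi_to_reference(ics.scores[:, k], ref, bins)
                    for k in range(ics.scores.shape[1])])
    order = np.argsort(nmi, kind="stable")
    return ICResult(scores=ics.scores[:, order] * weights,
                    mixing=ics.mixing[:, order],
                    unmixing=ics.unmixing[order],
                    nmi_scores=nmi[order], weights=weights)


def fit_gmm(matrix: ObservationMatrix, weighted_scores, k: int = N_CLUSTERS,
            seed: int = 0, max_attempts: int = 5) -> SegmentationResult:
    """Five-component full-covariance EM fit with hard max-posterior labels."""
    x = np.asarray(weighted_scores, dtype=float)
    if x.shape[0] < 50:
        raise ValueError("need at least 50 voxels for the mixture fit")
    last_err = None
    for attempt in range(max_attempts):
        gmm = GaussianMixture(n_components=k, covariance_type="full",
                              random_state=seed + attempt, n_init=3,
                              reg_covar=1e-8, max_iter=500)
        try:
            gmm.fit(x)
        except ValueError as err:
            last_err = err
            continue
        if gmm.converged_:
            post = gmm.predict_proba(x)
            return SegmentationResult(
                cluster_means=gmm.means_,
                cluster_covariances=gmm.covariances_,
                cluster_weights=gmm.weights_,
                cluster_labels=None,
                voxel_clusters=np.argmax(post, axis=1),
                posteriors=post, observation=matrix)
    raise RuntimeError(f"GMM failed after {max_attempts} attempts: {last_err}")


def assign_labels(result: SegmentationResult,
                  tumour_type: str) -> SegmentationResult:
    """Apply the fixed cluster-to-tissue assignment rules (in place-ish)."""
    if tumour_type not in IC2_LABEL_ORDER:
        raise ValueError("tumour_type must be '22Rv1' or 'DU145'")
    means = result.cluster_means.copy()
    weights = result.cluster_weights
    # step 1: blood/edema = largest |mean IC1|; ties broken by cluster weight
    order = np.lexsort((weights, np.abs(means[:, 0])))
    blood = int(order[-1])
    # step 2: reflect axes so the blood/edema mean is in the first octant
    flips = np.where(means[blood] < 0, -1.0, 1.0)
    means = means * flips
    # step 3: remaining clusters by ascending (reflected) mean IC2
    rest = [c for c in range(means.shape[0]) if c != blood]
    rest.sort(key=lambda c: (means[c, 1], -weights[c]))
    labels = {blood: "blood_edema"}
    for cls, c in zip(IC2_LABEL_ORDER[tumour_type], rest):
        labels[c] = cls
    return SegmentationResult(
        cluster_means=result.cluster_means,
        cluster_covariances=result.cluster_covariances,
        cluster_weights=result.cluster_weights,
        cluster_labels=labels,
        voxel_clusters=result.voxel_clusters,
        posteriors=result.posteriors,
        observation=result.observation)


class SegmentationModel:
    """End-to-end ICA + GMM segmentation of one observation matrix."""

    def __init__(self, matrix: ObservationMatrix, tumour_type: str,
                 protocol_mean=None):
        self.matrix = matrix
        self.tumour_type = tumour_type
        # default reference: mean over all features, mirrored onto voxels
        self.protocol_mean = (np.asarray(protocol_mean).ravel()
                              if protocol_mean is not None
                              else matrix.data.mean(axis=1))

    def fit(self, seed: int = 0) -> SegmentationResult:
        ics = run_ica(self.matrix, seed=seed)
        ics = sort_and_weight_ics(ics, self.protocol_mean, self.tumour_type)
        result = fit_gmm(self.matrix, ics.scores, seed=seed)
        return assign_labels(result, self.tumour_type)


def dice_coefficient(pred_mask, true_mask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 0 when both masks are empty."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(true_mask, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * np.logical_and(a, b).sum() / denom
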