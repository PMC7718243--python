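"""Z-spectrum conditioning: drift correction, B0 mapping and re-centring,
mask erosion, B0-outlier exclusion and map normalization.

Scanner drift is estimated from reference frames (saturation parked at
667 ppm) interleaved through the acquisition, by a straight-line fit of
reference signal against acquisition index; every frame is divided by the
line's prediction at its own index, which simultaneously normalizes the
spectra to Z = S/S_ref.

Per-voxel B0 offsets are estimated by fitting a Lorentzian dip to the WASSR
spectrum inside ±0.5 ppm (direct saturation only), or a sum of two
Lorentzians with a shared centre (direct saturation + broad MT background)
to the 0.5/2 µT spectra; the spectra are then re-centred onto the nominal
offset grid by linear interpolation.  Voxels whose |B0 shift| exceeds
0.5 ppm are excluded (strict inequality: exactly 0.5 ppm is retained).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.optimize import least_squares

B0_EXCLUSION_PPM = 0.5
WASSR_B0_WINDOW_PPM = 0.5
#: points with Z below this are dropped from B0 fits (degenerate near-null dip)
LOW_SNR_Z_CUTOFF = 0.05

T1_NORM_MS = 4000.0
T2_NORM_MS = 300.0


@dataclass
class DriftModel:
    """Straight-line drift fitted to interleaved reference frames."""

    intercept: np.ndarray | float
    slope: np.ndarray | float
    reference_indices: np.ndarray

    def predict(self, index):
        idx = np.asarray(index, dtype=float)
        return self.intercept + np.multiply.outer(idx, self.slope)


@dataclass
class B0Shift:
    shift_ppm: float
    model: str            # "one-lorentzian" | "two-lorentzian"
    fit_window_ppm: float
    valid: bool = True


def drift_correct(frames, reference_indices):
    """Divide an ordered frame series by a reference-fitted drift line.

    Parameters
    ----------
    frames : array (n_frames, ...) in acquisition order, references included.
    reference_indices : indices of the 667-ppm reference frames (>= 2).

    Returns
    -------
    (z, model) : normalized series Z = S / S_ref_predicted, and the fitted
    :class:`DriftModel`.  Voxels whose predicted reference is not positive
    come back NaN.
    """
    frames = np.asarray(frames, dtype=float)
    ref_idx = np.asarray(reference_indices, dtype=int)
    if ref_idx.size < 2:
        raise ValueError("drift correction needs at least 2 reference frames")
    refs = frames[ref_idx]                       # (n_ref, ...)
    x = ref_idx.astype(float)
    xm = x.mean()
    denom = ((x - xm) ** 2).sum()
    slope = np.tensordot(x - xm, refs - refs.mean(axis=0), axes=(0, 0)) / denom
    intercept = refs.mean(axis=0) - slope * xm
    model = DriftModel(intercept=intercept, slope=slope,
                       reference_indices=ref_idx)
    pred = model.predict(np.arange(frames.shape[0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(pred > 0, frames / pred, np.nan)
    return z, model


def _lorentzian(offset, amp, fwhm, centre):
    """L(Δ) = a·w² / (w² + 4(Δ−c)²) — amplitude/FWHM/centre parameterization."""
    return amp * fwhm**2 / (fwhm**2 + 4.0 * (offset - centre) ** 2)


def fit_b0_wassr(offsets_ppm, z, window_ppm: float = WASSR_B0_WINDOW_PPM) -> B0Shift:
    """B0 shift from a WASSR spectrum: one Lorentzian dip inside ±window."""
    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    z = np.asarray(z, dtype=float)
    keep = (np.isfinite(z) & (np.abs(offsets_ppm) <= window_ppm)
            & (z >= LOW_SNR_Z_CUTOFF))
    offs, zz = offsets_ppm[keep], z[keep]
    if offs.size < 5:
        raise ValueError("need >= 5 WASSR points inside the B0 window")
    a0 = float(np.clip(1.0 - zz.min(), 0.05, 1.2))
    c0 = float(offs[np.argmin(zz)])

    def resid(x):
        return 1.0 - _lorentzian(offs, x[0], x[1], x[2]) - zz

    sol = least_squares(resid, x0=[a0, 1.0, c0],
                        bounds=([0.0, 1e-3, offs.min()],
                                [1.2, 100.0, offs.max()]),
                        xtol=1e-12, ftol=1e-12)
    return B0Shift(shift_ppm=float(sol.x[2]), model="one-lorentzian",
                   fit_window_ppm=window_ppm, valid=bool(sol.success))


def fit_b0_lowb1(offsets_ppm, z) -> B0Shift:
    """B0 shift from a 0.5/2 µT spectrum: two shared-centre Lorentzians.

    The narrow component is direct saturation, the broad one the MT
    background; the shift is their common centre.
    """
    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    z = np.asarray(z, dtype=float)
    keep = np.isfinite(z) & (z >= LOW_SNR_Z_CUTOFF)
    offs, zz = offsets_ppm[keep], z[keep]
    if offs.size < 7 or offs.max() < 4.0 or offs.min() > -4.0:
        raise ValueError("low-B1 B0 fit needs a spectrum covering >= +-4 ppm")
    a0 = float(np.clip(1.0 - zz.min(), 0.05, 1.2))
    c0 = float(offs[np.argmin(zz)])

    def resid(x):
        a_de, w_de, a_mt, w_mt, c = x
        return (1.0 - _lorentzian(offs, a_de, w_de, c)
                - _lorentzian(offs, a_mt, w_mt, c) - zz)

    sol = least_squares(resid, x0=[a0, 1.0, 0.1, 50.0, c0],
                        bounds=([0.0, 1e-3, 0.0, 5.0, offs.min()],
                                [1.2, 5.0, 1.2, 1e4, offs.max()]),
                        xtol=1e-12, ftol=1e-12)
    return B0Shift(shift_ppm=float(sol.x[4]), model="two-lorentzian",
                   fit_window_ppm=float(offs.max()), valid=bool(sol.success))


def recenter(offsets_ppm, z, shift_ppm: float):
    """Re-centre a spectrum by its fitted water position.

    The corrected spectrum on the nominal grid is the measured one read at
    (Δ + shift) by linear interpolation; points falling outside the sampled
    range become NaN (excluded from later fits, never extrapolated).
    """
    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    z = np.asarray(z, dtype=float)
    query = offsets_ppm + shift_ppm
    out = np.interp(query, offsets_ppm, z, left=np.nan, right=np.nan)
    return out


def erode_mask(mask):
    """Binary erosion with the full 3×3 (8-connected) structuring element."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))


def exclude_b0_outliers(shift_map, threshold_ppm: float = B0_EXCLUSION_PPM):
    """Validity mask keeping |shift| <= threshold (strictly greater excluded)."""
    shift = np.asarray(shift_map, dtype=float)
    return np.isfinite(shift) & (np.abs(shift) <= threshold_ppm)


def normalize_maps(t1_map_ms, t2_map_ms):
    """Scale T1 and T2 maps (ms) into the Z-image range: /4000 and /300."""
    return (np.asarray(t1_map_ms, dtype=float) / T1_NORM_MS,
            np.asarray(t2_map_ms, dtype=float) / T2_NORM_MS)


def fit_b0_map(offsets_ppm, stack, mask, mode: str = "wassr"):
    """Per-voxel B0 shift map from a spectrum stack (n_off, H, W).

    Returns (shift_map, valid); failed voxels are NaN/invalid.
    """
    fit = fit_b0_wassr if mode == "wassr" else fit_b0_lowb1
    stack = np.asarray(stack, dtype=float)
    _, h, w = stack.shape
    shift = np.full((h, w), np.nan)
    ok = np.zeros((h, w), dtype=bool)
    for i, j in zip(*np.nonzero(np.asarray(mask, dtype=bool))):
        try:
            res = fit(offsets_ppm, stack[:, i, j])
        except ValueError:
            continue
        if res.valid:
            shift[i, j], ok[i, j] = res.shift_ppm, True
    return shift, ok


def recenter_stack(offsets_ppm, stack, shift_map, mask):
    """Re-centre every masked voxel spectrum of a stack by its own shift."""
    stack = np.asarray(stack, dtype=float)
    out = np.full_like(stack, np.nan)
    for i, j in zip(*np.nonzero(np.asarray(mask, dtype=bool))):
        s = shift_map[i, j]
        if np.isfinite(s):
            out[:, i, j] = recenter(offsets_ppm, stack[:, i, j], s)
    return out
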