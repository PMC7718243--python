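"""Isolation of CEST and rNOE contributions via the extrapolated MT reference.

The fitted two-pool model, evaluated at a low saturation amplitude, predicts
the Z-spectrum that direct saturation and semisolid MT alone would produce
(the extrapolated MT reference, Z_EMR).  Exchange-mediated contributions of
the amide (3.5 ppm), guanidinium (2.0 ppm) and aliphatic/rNOE (−3.3 ppm)
pools are then isolated with the inverse-difference metrics

    MTR_REX = 1/Z_lab − 1/Z_EMR
    AREX    = MTR_REX / T1          (T1 in seconds; units Hz)

MTR_REX removes the multiplicative "dilution" of the CEST signal by direct
saturation and MT; AREX additionally compensates T1 differences between
tissues.  By default T1 is the observed T1 from inversion recovery; the
constrained free-pool 1/R1,F can be selected instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_F0_MHZ
from .qmt import MTParams, constrain_r1f, two_pool_z

DEFAULT_POOL_OFFSETS_PPM = (3.5, 2.0, -3.3)
DEFAULT_CEST_B1_UT = (0.5, 2.0)


@dataclass
class CESTContrast:
    """One voxel's isolated exchange contrast at one offset and B1."""

    offset_ppm: float
    b1_ut: float
    z_lab: float
    z_emr: float

    @property
    def mtr_rex(self) -> float:
        return mtr_rex(self.z_lab, self.z_emr)

    def arex_hz(self, t1_ms: float) -> float:
        return arex(self.mtr_rex, t1_ms)


def mtr_rex(z_lab, z_emr):
    """Inverse-difference exchange contrast 1/Z_lab − 1/Z_EMR (dimensionless).

    Negative values (Z_lab above the reference) are retained, not clipped.
    """
    z_lab = np.asarray(z_lab, dtype=float)
    z_emr = np.asarray(z_emr, dtype=float)
    if np.any(z_lab[np.isfinite(z_lab)] <= 0) or np.any(z_emr[np.isfinite(z_emr)] <= 0):
        raise ValueError("Z values must be positive")
    return 1.0 / z_lab - 1.0 / z_emr


def arex(mtr_rex_value, t1_ms):
    """Apparent exchange-dependent relaxation: MTR_REX / T1, in Hz."""
    t1_s = np.asarray(t1_ms, dtype=float) * 1e-3
    if np.any(t1_s[np.isfinite(t1_s)] <= 0):
        raise ValueError("T1 must be positive")
    return np.asarray(mtr_rex_value, dtype=float) / t1_s


def compute_emr(params: MTParams, t1_obs_ms: float, b1_ut: float,
                offsets_ppm, f0_mhz: float = DEFAULT_F0_MHZ):
    """Extrapolated MT reference Z_EMR: the two-pool model at low B1."""
    return two_pool_z(offsets_ppm, b1_ut, params, t1_obs_ms, f0_mhz)


def _interp_z(offsets_ppm, z, query_ppm: float) -> float:
    """Z_lab at an exact pool offset by linear interpolation, NaN-aware."""
    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    z = np.asarray(z, dtype=float)
    keep = np.isfinite(z)
    if keep.sum() < 2:
        return np.nan
    order = np.argsort(offsets_ppm[keep])
    xs = offsets_ppm[keep][order]
    ys = z[keep][order]
    if not (xs[0] <= query_ppm <= xs[-1]):
        return np.nan
    return float(np.interp(query_ppm, xs, ys))


def cest_contrast(offsets_ppm, z_lab, params: MTParams, t1_obs_ms: float,
                  b1_ut: float, pool_offset_ppm: float,
                  f0_mhz: float = DEFAULT_F0_MHZ) -> CESTContrast:
    """Isolate one pool's contrast from one measured low-B1 spectrum."""
    zl = _interp_z(offsets_ppm, z_lab, pool_offset_ppm)
    ze = float(compute_emr(params, t1_obs_ms, b1_ut, pool_offset_ppm, f0_mhz))
    return CESTContrast(offset_ppm=pool_offset_ppm, b1_ut=b1_ut,
                        z_lab=zl, z_emr=ze)


def cest_maps(lowb1_stacks: dict, mt_params_map, t1_map_ms, mask,
              pool_offsets_ppm=DEFAULT_POOL_OFFSETS_PPM,
              f0_mhz: float = DEFAULT_F0_MHZ,
              t1_source: str = "observed"):
    """Per-voxel MTR_REX and AREX maps at each pool offset and B1.

    Parameters
    ----------
    lowb1_stacks : dict
        ``{b1_ut: (offsets_ppm, stack)}`` with B0-corrected stacks
        (n_off, H, W).
    mt_params_map : callable or 2-D object array
        ``mt_params_map(i, j) -> MTParams`` (e.g. region-wise broadcast of a
        per-ROI fit) or an array of MTParams per voxel.
    t1_map_ms : per-voxel observed T1 map (ms).
    t1_source : "observed" uses T1,obs in the AREX denominator; "free" uses
        the constrained free-pool 1/R1,F.

    Returns
    -------
    dict ``{(metric, b1_ut, offset_ppm): 2-D map}`` for metric in
    {"mtr_rex", "arex"}.
    """
    t1_map_ms = np.asarray(t1_map_ms, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    get_params = (mt_params_map if callable(mt_params_map)
                  else (lambda i, j: mt_params_map[i, j]))
    out = {}
    for b1, (offsets_ppm, stack) in lowb1_stacks.items():
        stack = np.asarray(stack, dtype=float)
        for off in pool_offsets_ppm:
            m_rex = np.full((h, w), np.nan)
            m_arex = np.full((h, w), np.nan)
            for i, j in zip(*np.nonzero(mask)):
                params = get_params(i, j)
                if params is None or not np.isfinite(t1_map_ms[i, j]):
                    continue
                c = cest_contrast(offsets_ppm, stack[:, i, j], params,
                                  t1_map_ms[i, j], b1, off, f0_mhz)
                if not (np.isfinite(c.z_lab) and c.z_lab > 0):
                    continue
                m_rex[i, j] = c.mtr_rex
                if t1_source == "free":
                    r1f = constrain_r1f(t1_map_ms[i, j], params.r_mt_hz,
                                        params.m0_mt, params.r1_mt_hz)
                    m_arex[i, j] = c.mtr_rex * r1f
                else:
                    m_arex[i, j] = c.arex_hz(t1_map_ms[i, j])
            out[("mtr_rex", b1, off)] = m_rex
            out[("arex", b1, off)] = m_arex
    return out


def subtraction_contrast(offsets_ppm, z_lab, params: MTParams,
                         t1_obs_ms: float, b1_ut: float,
                         pool_offset_ppm: float,
                         f0_mhz: float = DEFAULT_F0_MHZ) -> float:
    """Conventional subtraction metric Z_ref − Z_lab (optional comparator)."""
    c = cest_contrast(offsets_ppm, z_lab, params, t1_obs_ms, b1_ut,
                      pool_offset_ppm, f0_mhz)
    return c.z_emr - c.z_lab
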