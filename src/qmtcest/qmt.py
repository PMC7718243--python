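"""Two-pool quantitative magnetization-transfer model (free water + semisolid).

The steady-state Z-value under continuous-wave off-resonance irradiation is
the solution of the coupled longitudinal equations of a free water pool F and
a semisolid pool MT exchanging magnetization at rate R_MT (MT→F; the reverse
rate is R_MT·M0,MT by detailed balance):

    Z = [R1F·R1MT + R1F·Rrf,MT + R1F·R_MT + R1MT·R_MT·M0,MT] /
        [(R1F + Rrf,F + R_MT·M0,MT)(R1MT + Rrf,MT + R_MT) − R_MT²·M0,MT]

with the RF saturation rates

    Rrf,F  = ω1² T2,F / (1 + (Δω T2,F)²)        (Lorentzian, free pool)
    Rrf,MT = π ω1² g(Δ)                          (super-Lorentzian, semisolid)

The four free parameters are T2,F, R_MT, M0,MT and T2,MT; R_MT and M0,MT are
strongly coupled and their product R_MT·M0,MT (the "MT effect") is the robust
scalar.  R1,MT is fixed at 1 s⁻¹ by convention, and R1,F is constrained so
that the slow longitudinal eigenvalue of the exchange system equals the
observed R1 from inversion recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .constants import DEFAULT_F0_MHZ, omega1_rad_s, ppm_to_rad_s
from .lineshape import superlorentzian_g_vec
from .relaxometry import _bse_from_solution, _summary_table

DEFAULT_R1_MT_HZ = 1.0

#: (lower, upper) fit bounds: T2,F ms, R_MT Hz, M0,MT, T2,MT µs
FIT_BOUNDS = ((5.0, 1.0, 0.0, 1.0), (500.0, 100.0, 0.5, 30.0))
FIT_INITIAL = (40.0, 20.0, 0.05, 8.0)

#: B1 levels at or below this (µT) contribute only their |Δ| <= 1 ppm points
#: to the two-pool fit (their information is direct saturation).
WASSR_B1_UT = 0.2
WASSR_FIT_WINDOW_PPM = 1.0


@dataclass
class MTParams:
    """Two-pool MT parameter set."""

    t2_f_ms: float
    r_mt_hz: float
    m0_mt: float
    t2_mt_us: float
    r1_mt_hz: float = DEFAULT_R1_MT_HZ

    def __post_init__(self):
        if min(self.t2_f_ms, self.t2_mt_us, self.r1_mt_hz) <= 0:
            raise ValueError("relaxation times and R1,MT must be positive")
        if self.r_mt_hz < 0 or not (0.0 <= self.m0_mt <= 1.0):
            raise ValueError("need r_mt >= 0 and m0_mt in [0, 1]")

    @property
    def mt_effect_hz(self) -> float:
        """The coupled MT-effect scalar R_MT · M0,MT."""
        return self.r_mt_hz * self.m0_mt

    @classmethod
    def from_mt_effect(cls, t2_f_ms, mt_effect_hz, t2_mt_us,
                       r_mt_hz: float = 25.0, **kw) -> "MTParams":
        """Build a parameter set from the product, splitting at a nominal R_MT."""
        return cls(t2_f_ms=t2_f_ms, r_mt_hz=r_mt_hz,
                   m0_mt=mt_effect_hz / r_mt_hz, t2_mt_us=t2_mt_us, **kw)


def constrain_r1f(t1_obs_ms: float, r_mt_hz: float, m0_mt: float,
                  r1_mt_hz: float = DEFAULT_R1_MT_HZ) -> float:
    """R1 of the free pool given the observed mono-exponential R1.

    R1,F = R1,obs − R_MT·M0,MT·(R1,MT − R1,obs) / (R1,MT − R1,obs + R_MT);
    equivalently, R1,obs is the slow eigenvalue of the longitudinal
    exchange matrix built from (R1,F, R1,MT, R_MT, M0,MT).
    """
    r1_obs = 1000.0 / t1_obs_ms
    denom = r1_mt_hz - r1_obs + r_mt_hz
    if denom == 0.0:
        raise ZeroDivisionError("degenerate R1 constraint (R1,MT - R1,obs + R_MT = 0)")
    return r1_obs - r_mt_hz * m0_mt * (r1_mt_hz - r1_obs) / denom


def _two_pool_z_core(offset_ppm, b1_ut, t2_f_ms, r_mt_hz, m0_mt, t2_mt_us,
                     t1_obs_ms, f0_mhz: float = DEFAULT_F0_MHZ,
                     r1_mt_hz: float = DEFAULT_R1_MT_HZ):
    """Broadcasting two-pool steady state; all parameters may be arrays."""
    r1_obs = 1000.0 / np.asarray(t1_obs_ms, dtype=float)
    r_mt = np.asarray(r_mt_hz, dtype=float)
    m0_mt = np.asarray(m0_mt, dtype=float)
    r1_f = r1_obs - r_mt * m0_mt * (r1_mt_hz - r1_obs) / (r1_mt_hz - r1_obs + r_mt)
    t2_f_s = np.asarray(t2_f_ms, dtype=float) * 1e-3
    dw = ppm_to_rad_s(offset_ppm, f0_mhz)
    w1 = omega1_rad_s(b1_ut)
    rrf_f = w1**2 * t2_f_s / (1.0 + (dw * t2_f_s) ** 2)
    g = superlorentzian_g_vec(offset_ppm, t2_mt_us, f0_mhz)
    rrf_mt = np.pi * w1**2 * g
    num = (r1_f * r1_mt_hz + r1_f * rrf_mt + r1_f * r_mt
           + r1_mt_hz * r_mt * m0_mt)
    den = ((r1_f + rrf_f + r_mt * m0_mt) * (r1_mt_hz + rrf_mt + r_mt)
           - r_mt**2 * m0_mt)
    return num / den


def two_pool_z(offset_ppm, b1_ut, params: MTParams, t1_obs_ms: float,
               f0_mhz: float = DEFAULT_F0_MHZ):
    """Steady-state two-pool Z at the given offsets (ppm) and B1 (µT)."""
    # validate the R1,F constraint up front (raises on the degenerate case)
    constrain_r1f(t1_obs_ms, params.r_mt_hz, params.m0_mt, params.r1_mt_hz)
    return _two_pool_z_core(offset_ppm, b1_ut, params.t2_f_ms,
                            params.r_mt_hz, params.m0_mt, params.t2_mt_us,
                            t1_obs_ms, f0_mhz, params.r1_mt_hz)


class TwoPoolMTModel:
    """Bounded NLS fit of the two-pool MT model to multi-B1 Z-spectra.

    Parameters
    ----------
    spectra : dict
        ``{b1_ut: (offsets_ppm, z)}``; the paper's protocol uses 0.1, 3 and
        6 µT.  B1 levels at the WASSR amplitude contribute only their
        |Δ| <= 1 ppm points.
    t1_obs_ms : float
        Observed T1 of the voxel/ROI (fixed; constrains R1,F).
    """

    def __init__(self, spectra: dict, t1_obs_ms: float,
                 f0_mhz: float = DEFAULT_F0_MHZ,
                 r1_mt_hz: float = DEFAULT_R1_MT_HZ):
        self.t1_obs_ms = float(t1_obs_ms)
        self.f0_mhz = f0_mhz
        self.r1_mt_hz = r1_mt_hz
        self._blocks = []
        n = 0
        for b1, (offs, z) in sorted(spectra.items()):
            offs = np.asarray(offs, dtype=float)
            z = np.asarray(z, dtype=float)
            keep = np.isfinite(z) & np.isfinite(offs)
            if b1 <= WASSR_B1_UT:
                keep &= np.abs(offs) <= WASSR_FIT_WINDOW_PPM
            if keep.sum() == 0:
                continue
            self._blocks.append((float(b1), offs[keep], z[keep]))
            n += int(keep.sum())
        if n < 20:
            raise ValueError(f"need >= 20 spectral points for the 4-parameter fit, got {n}")
        self.n_obs = n

    def _residuals(self, x):
        params = MTParams(t2_f_ms=x[0], r_mt_hz=x[1], m0_mt=x[2],
                          t2_mt_us=x[3], r1_mt_hz=self.r1_mt_hz)
        out = []
        for b1, offs, z in self._blocks:
            out.append(two_pool_z(offs, b1, params, self.t1_obs_ms,
                                  self.f0_mhz) - z)
        return np.concatenate(out)

    def fit(self, n_restarts: int = 3, seed: int = 0,
            initial=FIT_INITIAL) -> "TwoPoolMTResults":
        rng = np.random.default_rng(seed)
        lo = np.array(FIT_BOUNDS[0])
        hi = np.array(FIT_BOUNDS[1])
        best = None
        x0 = np.asarray(initial, dtype=float)
        for attempt in range(max(1, n_restarts)):
            if attempt > 0:
                x0_try = np.clip(x0 * np.exp(rng.normal(0.0, 0.2, 4)), lo, hi)
                # keep M0,MT off its zero bound
                x0_try[2] = max(x0_try[2], 1e-3)
            else:
                x0_try = np.clip(x0, lo + 1e-9, hi - 1e-9)
            sol = least_squares(self._residuals, x0=x0_try, bounds=(lo, hi),
                                method="trf", x_scale=[40.0, 20.0, 0.05, 8.0],
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if best is None or sol.cost < best.cost:
                best = sol
        x = best.x
        at_bound = bool(np.any(np.isclose(x, lo)) or np.any(np.isclose(x, hi)))
        params = MTParams(t2_f_ms=x[0], r_mt_hz=x[1], m0_mt=x[2],
                          t2_mt_us=x[3], r1_mt_hz=self.r1_mt_hz)
        return TwoPoolMTResults(
            model=self, params=params,
            bse=_bse_from_solution(best),
            resid_norm=float(np.sqrt(2.0 * best.cost)),
            converged=bool(best.success), boundary_pinned=at_bound)


@dataclass
class TwoPoolMTResults:
    model: TwoPoolMTModel
    params: MTParams
    bse: np.ndarray
    resid_norm: float
    converged: bool
    boundary_pinned: bool
    param_names: tuple = ("t2_f_ms", "r_mt_hz", "m0_mt", "t2_mt_us")

    @property
    def mt_effect_hz(self) -> float:
        return self.params.mt_effect_hz

    @property
    def r1_f_hz(self) -> float:
        return constrain_r1f(self.model.t1_obs_ms, self.params.r_mt_hz,
                             self.params.m0_mt, self.params.r1_mt_hz)

    def predict(self, offsets_ppm, b1_ut):
        return two_pool_z(offsets_ppm, b1_ut, self.params,
                          self.model.t1_obs_ms, self.model.f0_mhz)

    def summary(self) -> str:
        p = self.params
        return _summary_table(
            "Two-pool MT model fit",
            self.param_names,
            (p.t2_f_ms, p.r_mt_hz, p.m0_mt, p.t2_mt_us), self.bse,
            extra={"mt_effect_hz (R_MT*M0,MT)": round(self.mt_effect_hz, 6),
                   "r1_f_hz (constrained)": round(self.r1_f_hz, 6),
                   "t1_obs_ms (fixed)": self.model.t1_obs_ms,
                   "n_obs": self.model.n_obs,
                   "resid_norm": self.resid_norm,
                   "converged": self.converged,
                   "boundary_pinned": self.boundary_pinned})


def fit_two_pool(spectra: dict, t1_obs_ms: float,
                 f0_mhz: float = DEFAULT_F0_MHZ, seed: int = 0,
                 n_restarts: int = 3) -> TwoPoolMTResults:
    """Functional wrapper around :class:`TwoPoolMTModel`."""
    return TwoPoolMTModel(spectra, t1_obs_ms, f0_mhz).fit(
        n_restarts=n_restarts, seed=seed)
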