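"""Time-domain Bloch / Bloch–McConnell oracles.

These integrators serve as independent cross-checks of the closed-form
steady-state expressions (`relaxometry.eq1_signal`, `qmt.two_pool_z`) and of
the inversion-recovery signal equation.  They propagate the magnetization in
the time domain — via the matrix exponential of the (affine) Bloch generator
or via an ODE solver — and share no algebra with the closed forms beyond the
physical rate definitions.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .constants import DEFAULT_F0_MHZ, omega1_rad_s, ppm_to_rad_s
from .lineshape import superlorentzian_g
from .qmt import MTParams, constrain_r1f


def _propagate_affine(a: np.ndarray, b: np.ndarray, y0: np.ndarray,
                      t_end: float) -> np.ndarray:
    """Propagate dy/dt = A y + b from y0 over t_end via one matrix exponential."""
    n = a.shape[0]
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = a
    aug[:n, n] = b
    y = np.append(y0, 1.0)
    return (expm(aug * t_end) @ y)[:n]


def bloch_steady_state_z(offset_ppm: float, b1_ut: float, t1_ms: float,
                         t2_ms: float, f0_mhz: float = DEFAULT_F0_MHZ,
                         t_end_s: float = 200.0) -> float:
    """Steady-state Mz/M0 of one water pool under CW irradiation (full Bloch).

    Rotating frame with the RF along x: state (Mx, My, Mz).
    """
    r1 = 1000.0 / t1_ms
    r2 = 1000.0 / t2_ms
    dw = float(ppm_to_rad_s(offset_ppm, f0_mhz))
    w1 = float(omega1_rad_s(b1_ut))
    a = np.array([[-r2, dw, 0.0],
                  [-dw, -r2, w1],
                  [0.0, -w1, -r1]])
    b = np.array([0.0, 0.0, r1])
    y = _propagate_affine(a, b, np.array([0.0, 0.0, 1.0]), t_end_s)
    return float(y[2])


def bmc_steady_state_z(offset_ppm: float, b1_ut: float, params: MTParams,
                       t1_obs_ms: float, f0_mhz: float = DEFAULT_F0_MHZ,
                       t_end_s: float = 200.0) -> float:
    """Two-pool Bloch–McConnell steady-state Z (time-domain propagation).

    The free pool keeps its full transverse dynamics; the semisolid pool is
    longitudinal-only with RF saturation rate π ω1² g(Δ) from the
    super-Lorentzian lineshape (adaptive-quadrature path).  Longitudinal
    exchange F↔MT at rates R_MT·M0,MT (F→MT) and R_MT (MT→F).
    """
    r1_f = constrain_r1f(t1_obs_ms, params.r_mt_hz, params.m0_mt,
                         params.r1_mt_hz)
    r2_f = 1000.0 / params.t2_f_ms
    dw = float(ppm_to_rad_s(offset_ppm, f0_mhz))
    w1 = float(omega1_rad_s(b1_ut))
    g = superlorentzian_g(offset_ppm, params.t2_mt_us, f0_mhz)
    rrf_mt = np.pi * w1**2 * g
    kf = params.r_mt_hz * params.m0_mt     # F -> MT
    kb = params.r_mt_hz                    # MT -> F
    r1_mt, m0_mt = params.r1_mt_hz, params.m0_mt
    # state: (MxF, MyF, MzF, MzMT), M0F = 1
    a = np.array([
        [-r2_f, dw, 0.0, 0.0],
        [-dw, -r2_f, w1, 0.0],
        [0.0, -w1, -(r1_f + kf), kb],
        [0.0, 0.0, kf, -(r1_mt + rrf_mt + kb)],
    ])
    b = np.array([0.0, 0.0, r1_f, r1_mt * m0_mt])
    y0 = np.array([0.0, 0.0, 1.0, m0_mt])
    y = _propagate_affine(a, b, y0, t_end_s)
    return float(y[2])


def ir_signal_ode(t1_ms: float, ti_ms: float, tr_ms: float,
                  n_cycles: int = 30, rtol: float = 1e-12) -> float:
    """Magnitude IR signal from a cycled longitudinal-relaxation ODE.

    Each repetition: 90° readout (Mz -> 0), free recovery for TR − TI,
    inversion (Mz -> −Mz), recovery for TI, then readout of |Mz|.  Iterated
    until the cycle is periodic; the returned value is the steady-cycle
    magnitude signal (s0 = 1).
    """
    r1 = 1.0 / (t1_ms * 1e-3)

    def relax(mz0: float, dur_s: float) -> float:
        sol = solve_ivp(lambda t, m: r1 * (1.0 - m[0]), (0.0, dur_s), [mz0],
                        rtol=rtol, atol=1e-14, method="RK45")
        return float(sol.y[0, -1])

    mz = 1.0
    for _ in range(n_cycles):
        mz = relax(0.0, (tr_ms - ti_ms) * 1e-3)   # after previous readout
        mz = relax(-mz, ti_ms * 1e-3)             # inversion then TI recovery
    return abs(mz)


def riemann_superlorentzian_g(offset_hz: float, t2_s: float,
                              n: int = 1_000_000) -> float:
    """Brute-force midpoint Riemann sum of the super-Lorentzian integral."""
    u = (np.arange(n) + 0.5) / n
    s = 3.0 * u * u - 1.0
    integrand = np.exp(-2.0 * (2.0 * np.pi * offset_hz * t2_s / s) ** 2) / np.abs(s)
    return float(np.sqrt(2.0 / np.pi) * t2_s * integrand.mean())


def longitudinal_exchange_eigenvalues(r1_f_hz: float, r1_mt_hz: float,
                                      r_mt_hz: float, m0_mt: float):
    """Eigenvalues (recovery rates, positive) of the 2×2 longitudinal system."""
    kf = r_mt_hz * m0_mt
    a = np.array([[-(r1_f_hz + kf), r_mt_hz],
                  [kf, -(r1_mt_hz + r_mt_hz)]])
    return np.sort(-np.linalg.eigvals(a).real)
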