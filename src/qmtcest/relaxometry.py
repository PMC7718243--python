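"""Observed relaxometry: T1 from inversion recovery, T2 from the WASSR spectrum.

T1,obs comes from a five-point magnitude inversion-recovery series; T2,obs is
then obtained from the very-low-B1 (WASSR) Z-spectrum through the steady-state
direct-saturation signal of a single water pool under continuous-wave
irradiation,

    Z(Δω) = R1 (R2² + Δω²) / (R1 (R2² + Δω²) + ω1² R2),

with R1 = 1/T1,obs, R2 = 1/T2,obs and ω1 = γB1.  This expression is the exact
steady state of the Bloch equations and is tested against a time-domain
integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .constants import DEFAULT_F0_MHZ, omega1_rad_s, ppm_to_rad_s

DEFAULT_TR_MS = 10000.0
DEFAULT_TIS_MS = (30.0, 110.0, 390.0, 1400.0, 5000.0)

T1_BOUNDS_MS = (10.0, 10000.0)
T2_BOUNDS_MS = (1.0, 1000.0)


@dataclass
class RelaxationState:
    """Observed single-pool relaxation parameters of one voxel or ROI."""

    t1_obs_ms: float
    t2_obs_ms: float
    s0: float = 1.0

    def __post_init__(self):
        if self.t1_obs_ms <= 0 or self.t2_obs_ms <= 0:
            raise ValueError("relaxation times must be positive")
        if self.t2_obs_ms > self.t1_obs_ms:
            raise ValueError("t2_obs must not exceed t1_obs")


def ir_signal(t1_ms, s0, ti_ms, tr_ms: float = DEFAULT_TR_MS):
    """Magnitude inversion-recovery signal with finite-TR correction.

    S(TI) = s0 · |1 − 2 e^(−TI/T1) + e^(−TR/T1)|
    """
    t1 = np.asarray(t1_ms, dtype=float)
    ti = np.asarray(ti_ms, dtype=float)
    if np.any(t1 <= 0) or np.any(ti <= 0) or tr_ms <= 0:
        raise ValueError("t1, TI and TR must be positive")
    return s0 * np.abs(1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr_ms / t1))


def eq1_signal(offset_ppm, b1_ut, t1_ms, t2_ms,
               f0_mhz: float = DEFAULT_F0_MHZ):
    """Steady-state direct-saturation Z of a single water pool (s0 = 1)."""
    r1 = 1000.0 / np.asarray(t1_ms, dtype=float)
    r2 = 1000.0 / np.asarray(t2_ms, dtype=float)
    dw = ppm_to_rad_s(offset_ppm, f0_mhz)
    w1 = omega1_rad_s(b1_ut)
    num = r1 * (r2**2 + dw**2)
    return num / (num + w1**2 * r2)


class InversionRecoveryT1:
    """Nonlinear least-squares T1 model for a magnitude IR series.

    Parameters
    ----------
    signals : array
        Measured magnitude signals, one per inversion time.
    ti_ms : array
        Inversion times in ms (>= 3 values spanning the recovery).
    tr_ms : float
        Repetition time in ms (enters the finite-TR recovery term).
    """

    def __init__(self, signals, ti_ms=DEFAULT_TIS_MS, tr_ms: float = DEFAULT_TR_MS):
        self.signals = np.asarray(signals, dtype=float)
        self.ti_ms = np.asarray(ti_ms, dtype=float)
        self.tr_ms = float(tr_ms)
        if self.signals.shape != self.ti_ms.shape:
            raise ValueError("signals and ti_ms must have equal length")
        if self.ti_ms.size < 3:
            raise ValueError("need at least 3 inversion times")

    def fit(self) -> "InversionRecoveryT1Results":
        s0_init = max(self.signals.max(), 1e-12)
        # Polarity restoration: the magnitude data lose the sign of the
        # recovery curve, and fitting |model| directly has local minima at
        # the null-point kink.  The points before the (unknown) null are
        # negative, so try every candidate null position, fit the smooth
        # signed model, and keep the best fit.
        order = np.argsort(self.ti_ms)
        best = None
        # the null lies next to the smallest magnitude sample
        j = int(np.argmin(self.signals[order]))
        for k in (j, j + 1):
            sign = np.ones(self.ti_ms.size)
            sign[order[:k]] = -1.0
            signed = sign * self.signals

            def resid(x, signed=signed):
                t1, s0 = x
                return (s0 * (1.0 - 2.0 * np.exp(-self.ti_ms / t1)
                              + np.exp(-self.tr_ms / t1)) - signed)

            t1_init = float(np.clip(
                self.ti_ms[order][min(k, self.ti_ms.size - 1)] / np.log(2.0),
                T1_BOUNDS_MS[0] * 1.01, T1_BOUNDS_MS[1] * 0.99))
            sol_k = least_squares(resid, x0=[t1_init, s0_init],
                                  bounds=([T1_BOUNDS_MS[0], 0.0],
                                          [T1_BOUNDS_MS[1],
                                           10.0 * s0_init + 1.0]),
                                  xtol=1e-10, ftol=1e-12, gtol=1e-10)
            if best is None or sol_k.cost < best.cost:
                best = sol_k
        sol = best
        t1, s0 = sol.x
        valid = bool(sol.success and T1_BOUNDS_MS[0] < t1 < T1_BOUNDS_MS[1])
        bse = _bse_from_solution(sol)
        return InversionRecoveryT1Results(
            model=self, t1_ms=float(t1), s0=float(s0), bse=bse,
            resid_norm=float(np.linalg.norm(sol.fun)), valid=valid)


@dataclass
class InversionRecoveryT1Results:
    model: InversionRecoveryT1
    t1_ms: float
    s0: float
    bse: np.ndarray
    resid_norm: float
    valid: bool
    param_names: tuple = ("t1_ms", "s0")

    def summary(self) -> str:
        return _summary_table(
            "Inversion-recovery T1 fit",
            self.param_names, (self.t1_ms, self.s0), self.bse,
            extra={"n_obs": self.model.ti_ms.size,
                   "resid_norm": self.resid_norm, "valid": self.valid})


class WassrT2:
    """One-parameter T2 model fitted to a B0-corrected WASSR Z-spectrum.

    T1,obs is supplied (from the IR fit) and held fixed; the only free
    parameter is T2,obs in the direct-saturation steady state.
    """

    def __init__(self, offsets_ppm, z, t1_obs_ms: float, b1_ut: float = 0.1,
                 f0_mhz: float = DEFAULT_F0_MHZ, window_ppm: float = 1.0):
        offsets_ppm = np.asarray(offsets_ppm, dtype=float)
        z = np.asarray(z, dtype=float)
        keep = np.isfinite(z) & (np.abs(offsets_ppm) <= window_ppm)
        self.offsets_ppm = offsets_ppm[keep]
        self.z = z[keep]
        self.t1_obs_ms = float(t1_obs_ms)
        self.b1_ut = float(b1_ut)
        self.f0_mhz = f0_mhz
        if self.offsets_ppm.size < 3:
            raise ValueError("need at least 3 WASSR points inside the window")

    def fit(self, t2_init_ms: float = 50.0) -> "WassrT2Results":
        def resid(x):
            return eq1_signal(self.offsets_ppm, self.b1_ut, self.t1_obs_ms,
                              x[0], self.f0_mhz) - self.z

        sol = least_squares(resid, x0=[t2_init_ms],
                            bounds=([T2_BOUNDS_MS[0]], [T2_BOUNDS_MS[1]]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        t2 = float(sol.x[0])
        valid = bool(sol.success and T2_BOUNDS_MS[0] < t2 < T2_BOUNDS_MS[1])
        return WassrT2Results(model=self, t2_ms=t2,
                              bse=_bse_from_solution(sol),
                              resid_norm=float(np.linalg.norm(sol.fun)),
                              valid=valid)


@dataclass
class WassrT2Results:
    model: WassrT2
    t2_ms: float
    bse: np.ndarray
    resid_norm: float
    valid: bool

    def summary(self) -> str:
        return _summary_table(
            "WASSR direct-saturation T2 fit",
            ("t2_ms",), (self.t2_ms,), self.bse,
            extra={"t1_obs_ms (fixed)": self.model.t1_obs_ms,
                   "b1_ut": self.model.b1_ut,
                   "n_obs": self.model.offsets_ppm.size,
                   "resid_norm": self.resid_norm, "valid": self.valid})


def fit_t1(signals, ti_ms=DEFAULT_TIS_MS, tr_ms: float = DEFAULT_TR_MS):
    """Functional wrapper: fit one voxel's IR series, return (t1_ms, s0)."""
    res = InversionRecoveryT1(signals, ti_ms, tr_ms).fit()
    return res.t1_ms, res.s0


def fit_t2_wassr(offsets_ppm, z, t1_obs_ms, b1_ut=0.1,
                 f0_mhz: float = DEFAULT_F0_MHZ) -> float:
    """Functional wrapper: fit T2,obs from a WASSR spectrum."""
    return WassrT2(offsets_ppm, z, t1_obs_ms, b1_ut, f0_mhz).fit().t2_ms


def fit_t1_map(ir_stack, ti_ms=DEFAULT_TIS_MS, tr_ms: float = DEFAULT_TR_MS,
               mask=None):
    """Per-voxel T1 fit of an IR image stack (n_ti, H, W).

    Returns (t1_map, s0_map, valid) with NaN outside the mask / failed voxels.
    """
    stack = np.asarray(ir_stack, dtype=float)
    n_ti, h, w = stack.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    t1 = np.full((h, w), np.nan)
    s0 = np.full((h, w), np.nan)
    ok = np.zeros((h, w), dtype=bool)
    for i, j in zip(*np.nonzero(mask)):
        try:
            res = InversionRecoveryT1(stack[:, i, j], ti_ms, tr_ms).fit()
        except ValueError:
            continue
        if res.valid:
            t1[i, j], s0[i, j], ok[i, j] = res.t1_ms, res.s0, True
    return t1, s0, ok


def fit_t2_map(offsets_ppm, wassr_stack, t1_map, b1_ut=0.1,
               f0_mhz: float = DEFAULT_F0_MHZ, mask=None):
    """Per-voxel T2 fit from a B0-corrected WASSR stack (n_off, H, W)."""
    stack = np.asarray(wassr_stack, dtype=float)
    _, h, w = stack.shape
    if mask is None:
        mask = np.isfinite(np.asarray(t1_map, dtype=float))
    t2 = np.full((h, w), np.nan)
    ok = np.zeros((h, w), dtype=bool)
    for i, j in zip(*np.nonzero(mask)):
        if not np.isfinite(t1_map[i, j]):
            continue
        try:
            res = WassrT2(offsets_ppm, stack[:, i, j], t1_map[i, j], b1_ut,
                          f0_mhz).fit()
        except ValueError:
            continue
        if res.valid:
            t2[i, j], ok[i, j] = res.t2_ms, True
    return t2, ok


def _bse_from_solution(sol) -> np.ndarray:
    """Asymptotic standard errors from a least_squares solution."""
    m, n = sol.jac.shape
    if m <= n:
        return np.full(n, np.nan)
    dof = m - n
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def _summary_table(title, names, values, bse, extra=None) -> str:
    lines = [title, "=" * len(title)]
    lines.append(f"{'param':>14} {'estimate':>12} {'std err':>12}")
    for k, (name, val) in enumerate(zip(names, values)):
        se = bse[k] if bse is not None and k < len(bse) else np.nan
        lines.append(f"{name:>14} {val:12.6g} {se:12.4g}")
    for key, val in (extra or {}).items():
        lines.append(f"{key}: {val}")
    return "\n".join(lines)
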