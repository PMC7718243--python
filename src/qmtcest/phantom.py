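"""Digital tumour phantoms and forward simulation of the full acquisition.

A phantom is a 2-D single-slice grid whose voxels belong to one of five
tissue classes (active tumour, necrosis/apoptosis, muscle, muscle/connective
tissue, blood/edema) or background, laid out as a xenograft cross-section:
a muscle rim, a connective-tissue ring, a tumour interior with an offset
necrotic core, and sparse blood/edema specks.  Every voxel carries
ground-truth generative parameters drawn from its region's Gaussian
(truncated at zero), and the full protocol is forward-simulated from them:

* Z-spectra at each saturation amplitude, with reference frames
  (Δ = 667 ppm) interleaved every five measurements in acquisition order;
* the WASSR spectrum (0.1 µT) from the single-pool direct-saturation
  steady state;
* high-B1 spectra (3, 6 µT) from the two-pool MT steady state;
* low-B1 spectra (0.5, 2 µT) from the two-pool model with CEST/rNOE pools
  injected inverse-additively, 1/Z_lab = 1/Z_2pool + T1·ΣR_ex,i(Δ), each
  R_ex,i a Lorentzian of the pool's amplitude and width — by this
  construction the ground-truth AREX at a pool offset is exactly the sum of
  the generating R_ex values there;
* a five-TI inversion-recovery series.

Scanner imperfections: a smooth polynomial per-voxel B0 offset map, a
multiplicative linear drift S·(1 + slope·k) over acquisition index k, and
additive Gaussian noise on magnitude (Rician optionally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .constants import DEFAULT_F0_MHZ
from .qmt import _two_pool_z_core
from .relaxometry import DEFAULT_TIS_MS, DEFAULT_TR_MS, eq1_signal, ir_signal

REGION_LABELS = {
    "background": 0,
    "muscle": 1,
    "muscle_connective": 2,
    "tumour": 3,
    "necrosis": 4,
    "blood_edema": 5,
}
LABEL_NAMES = {v: k for k, v in REGION_LABELS.items()}

#: truth-map keys produced by :func:`make_phantom`
TRUTH_KEYS = ("t1_obs_ms", "t2_obs_ms", "t2_f_ms", "mt_effect_hz",
              "r_mt_hz", "m0_mt", "t2_mt_us")


@dataclass(frozen=True)
class CESTPool:
    """One exchange-mediated pool: a Lorentzian R_ex contribution."""

    offset_ppm: float
    amplitude_hz: float   # peak exchange-mediated relaxation rate R_ex,max
    width_ppm: float      # Lorentzian FWHM

    def __post_init__(self):
        if self.amplitude_hz < 0 or self.width_ppm <= 0:
            raise ValueError("need amplitude >= 0 and width > 0")

    def r_ex(self, offset_ppm):
        d = np.asarray(offset_ppm, dtype=float) - self.offset_ppm
        return (self.amplitude_hz * self.width_ppm**2
                / (self.width_ppm**2 + 4.0 * d**2))


@dataclass
class RegionSpec:
    """Generative parameters of one tissue class; (mean, sd) pairs."""

    label: str
    t1_obs_ms: tuple
    t2_obs_ms: tuple
    t2_f_ms: tuple
    mt_effect_hz: tuple
    t2_mt_us: tuple
    cest_pools: tuple = ()
    r_mt_hz: float = 25.0   # nominal split of the coupled product

    def __post_init__(self):
        if self.label not in REGION_LABELS or self.label == "background":
            raise ValueError(f"unknown region label {self.label!r}")
        for name in ("t1_obs_ms", "t2_obs_ms", "t2_f_ms", "mt_effect_hz",
                     "t2_mt_us"):
            mean, sd = getattr(self, name)
            if mean <= 0 and not (name == "mt_effect_hz" and mean == 0):
                raise ValueError(f"{name} mean must be positive")
            if sd < 0:
                raise ValueError(f"{name} SD must be >= 0")
        if self.t2_obs_ms[0] >= self.t1_obs_ms[0]:
            raise ValueError("t2_obs mean must be below t1_obs mean")


@dataclass
class PhantomSpec:
    """Phantom geometry + per-region generative parameters + B0 field.

    Per-voxel parameters are drawn from each region's Gaussian (truncated
    away from zero) but are spatially smooth and cross-correlated through a
    latent "tissue state" field: relaxation times rise and the MT effect
    falls where the latent state is high, mimicking how cellularity drives
    all of these properties together in real tissue.  ``smoothness_vox`` is
    the Gaussian correlation length of the fields; ``latent_correlation``
    is the share of each parameter's variance carried by the shared state
    (0 recovers independent white draws).
    """

    regions: tuple
    grid_shape: tuple = (64, 64)
    b0_amplitude_ppm: float = 0.1
    b0_order: int = 2
    n_blood_specks: int = 6
    smoothness_vox: float = 3.0
    latent_correlation: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if min(self.grid_shape) < 16:
            raise ValueError("grid must be at least 16x16")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate region labels (regions must be disjoint)")

    def region(self, label: str) -> RegionSpec:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)


@dataclass
class Protocol:
    """Acquisition protocol: B1 levels, offset grids, references, IR, noise."""

    b1_levels_ut: tuple = (0.1, 0.5, 2.0, 3.0, 6.0)
    offsets_ppm: dict = field(default_factory=lambda: default_offset_grids())
    reference_offset_ppm: float = 667.0
    reference_every: int = 5
    f0_mhz: float = DEFAULT_F0_MHZ
    field_t: float = 7.0
    tis_ms: tuple = DEFAULT_TIS_MS
    tr_ms: float = DEFAULT_TR_MS
    noise_sd: float = 0.005
    drift_slope: float = 1e-4
    rician: bool = False

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for b1 in self.b1_levels_ut:
            offs = np.asarray(self.offsets_ppm[b1], dtype=float)
            if not np.all(np.isfinite(offs)):
                raise ValueError("offsets must be finite")
            if self.reference_offset_ppm <= 1.5 * np.abs(offs).max():
                raise ValueError("reference offset must sit far outside the "
                                 "fitted windows")


def high_b1_offsets(n: int = 30, lo_ppm: float = 3.0,
                    hi_ppm: float = 300.0) -> np.ndarray:
    """±log-spaced high-B1 grid: n/2 points per sign, 3–300 ppm."""
    half = np.geomspace(lo_ppm, hi_ppm, n // 2)
    return np.concatenate([-half[::-1], half])


def default_offset_grids() -> dict:
    """WASSR ±1 ppm step 0.1; low B1 ±6 ppm step 0.2 plus the exact pool
    offsets (amide 3.5, guanidinium 2.0, aliphatic −3.3 ppm, as acquired);
    high B1 ±log-spaced 3–300 ppm."""
    wassr = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)
    low = np.round(np.arange(-6.0, 6.0 + 1e-9, 0.2), 10)
    low = np.unique(np.concatenate([low, [3.5, 2.0, -3.3]]))
    high = high_b1_offsets()
    return {0.1: wassr, 0.5: low, 2.0: low, 3.0: high, 6.0: high}


@dataclass
class PhantomGeometry:
    """Rasterized labels plus per-voxel ground truth."""

    label_image: np.ndarray          # int codes per REGION_LABELS
    truth_maps: dict                 # name -> 2-D float map (NaN background)
    pool_maps: dict                  # offset_ppm -> (amplitude map, width map)
    b0_map_ppm: np.ndarray
    spec: PhantomSpec

    @property
    def mask(self) -> np.ndarray:
        return self.label_image != REGION_LABELS["background"]

    def region_mask(self, label: str) -> np.ndarray:
        return self.label_image == REGION_LABELS[label]


@dataclass
class ZStack:
    """One B1 level's frames in acquisition order, references included."""

    b1_ut: float
    frames: np.ndarray               # (n_frames, H, W)
    offsets_ppm: np.ndarray          # per frame; reference offset for refs
    is_reference: np.ndarray         # bool per frame

    @property
    def reference_indices(self) -> np.ndarray:
        return np.nonzero(self.is_reference)[0]

    @property
    def measurement_offsets(self) -> np.ndarray:
        return self.offsets_ppm[~self.is_reference]


@dataclass
class SyntheticStudy:
    """A complete simulated acquisition with retained ground truth."""

    geometry: PhantomGeometry
    protocol: Protocol
    zspec: dict                      # b1_ut -> ZStack
    ir_frames: np.ndarray            # (n_ti, H, W)
    seed: int

    @property
    def label_image(self):
        return self.geometry.label_image

    @property
    def truth_maps(self):
        return self.geometry.truth_maps


def necrotic_core_ellipse(grid_shape) -> tuple:
    """(row_centre, col_centre, row_semi_axis, col_semi_axis) of the core."""
    h, w = grid_shape
    s = min(h, w)
    return (h / 2.0 + 0.05 * s, w / 2.0 + 0.02 * s, 0.125 * s, 0.095 * s)


def _ellipse_mask(shape, cy, cx, ay, ax) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _layout(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.grid_shape
    s = min(h, w)
    cy, cx = h / 2.0, w / 2.0
    labels = np.zeros((h, w), dtype=np.int16)
    outer = _ellipse_mask((h, w), cy, cx, 0.44 * s, 0.42 * s)
    ring = _ellipse_mask((h, w), cy, cx, 0.38 * s, 0.36 * s)
    tum = _ellipse_mask((h, w), cy, cx, 0.32 * s, 0.30 * s)
    labels[outer] = REGION_LABELS["muscle"]
    labels[ring] = REGION_LABELS["muscle_connective"]
    labels[tum] = REGION_LABELS["tumour"]
    ncy, ncx, nay, nax = necrotic_core_ellipse((h, w))
    core = _ellipse_mask((h, w), ncy, ncx, nay, nax)
    labels[core] = REGION_LABELS["necrosis"]
    # sparse blood/edema specks inside the viable tumour
    host = np.argwhere((labels == REGION_LABELS["tumour"]))
    if spec.n_blood_specks > 0 and host.size:
        picks = rng.choice(host.shape[0], size=min(spec.n_blood_specks,
                                                   host.shape[0]),
                           replace=False)
        for k in picks:
            i, j = host[k]
            labels[i:i + 2, j:j + 2][labels[i:i + 2, j:j + 2]
                                     == REGION_LABELS["tumour"]] = \
                REGION_LABELS["blood_edema"]
    return labels


def _smooth_unit_field(shape, rng, sigma: float):
    """Zero-mean, unit-variance Gaussian random field, smoothed over sigma."""
    f = rng.normal(size=shape)
    if sigma > 0:
        f = ndimage.gaussian_filter(f, sigma, mode="nearest")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f


def _b0_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.grid_shape
    if spec.b0_amplitude_ppm == 0:
        return np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    x = 2.0 * xx / (w - 1) - 1.0
    y = 2.0 * yy / (h - 1) - 1.0
    terms = [np.ones_like(x)]
    if spec.b0_order >= 1:
        terms += [x, y]
    if spec.b0_order >= 2:
        terms += [x * y, x**2, y**2]
    coeffs = rng.uniform(-1.0, 1.0, len(terms))
    raw = sum(c * t for c, t in zip(coeffs, terms))
    peak = np.abs(raw).max()
    if peak == 0:
        return np.zeros((h, w))
    return spec.b0_amplitude_ppm * raw / peak


def make_phantom(spec: PhantomSpec) -> PhantomGeometry:
    """Rasterize the phantom and draw per-voxel ground-truth parameters."""
    rng = np.random.default_rng(spec.seed)
    labels = _layout(spec, rng)
    present = {name for name in REGION_LABELS
               if name != "background" and
               np.any(labels == REGION_LABELS[name])}
    missing = present - {r.label for r in spec.regions}
    if missing:
        raise ValueError(f"spec lacks parameters for regions {sorted(missing)}")

    h, w = spec.grid_shape
    truth = {k: np.full((h, w), np.nan) for k in TRUTH_KEYS}
    pool_offsets = sorted({p.offset_ppm for r in spec.regions
                           for p in r.cest_pools})
    pools = {off: (np.zeros((h, w)), np.full((h, w), np.nan))
             for off in pool_offsets}

    # latent tissue-state field shared by all parameters (fluid-like where
    # positive: longer relaxation times, weaker MT)
    latent = _smooth_unit_field((h, w), rng, spec.smoothness_vox)
    rho = spec.latent_correlation
    signs = {"t1_obs_ms": 1.0, "t2_obs_ms": 1.0, "t2_f_ms": 1.0,
             "mt_effect_hz": -1.0, "t2_mt_us": 1.0}
    draws = {"t1_obs_ms": "t1_obs_ms", "t2_obs_ms": "t2_obs_ms",
             "t2_f_ms": "t2_f_ms", "mt_effect_hz": "mt_effect_hz",
             "t2_mt_us": "t2_mt_us"}
    for region in spec.regions:
        m = labels == REGION_LABELS[region.label]
        if not m.any():
            continue
        for key in draws:
            mean, sd = getattr(region, key)
            indep = _smooth_unit_field((h, w), rng, spec.smoothness_vox)
            val = mean + sd * (rho * signs[key] * latent
                               + np.sqrt(1.0 - rho**2) * indep)
            # truncate away from zero (5 % of the mean floor)
            truth[key][m] = np.clip(val[m], 0.05 * mean if mean > 0 else 0.0,
                                    None)
        # keep t2_obs < t1_obs voxelwise
        truth["t2_obs_ms"][m] = np.minimum(truth["t2_obs_ms"][m],
                                           0.95 * truth["t1_obs_ms"][m])
        truth["r_mt_hz"][m] = region.r_mt_hz
        truth["m0_mt"][m] = truth["mt_effect_hz"][m] / region.r_mt_hz
        for pool in region.cest_pools:
            amp, wid = pools[pool.offset_ppm]
            amp[m] = pool.amplitude_hz
            wid[m] = pool.width_ppm

    return PhantomGeometry(label_image=labels, truth_maps=truth,
                           pool_maps=pools, b0_map_ppm=_b0_field(spec, rng),
                           spec=spec)


def build_acquisition(offsets_ppm, reference_offset_ppm: float,
                      every: int = 5):
    """Frame order with references before/after and every `every` scans."""
    offs, is_ref = [], []
    for k, off in enumerate(np.asarray(offsets_ppm, dtype=float)):
        if k % every == 0:
            offs.append(reference_offset_ppm)
            is_ref.append(True)
        offs.append(off)
        is_ref.append(False)
    offs.append(reference_offset_ppm)
    is_ref.append(True)
    return np.asarray(offs), np.asarray(is_ref)


#: B1 levels whose spectra carry the injected CEST/rNOE pools
CEST_B1_LEVELS_UT = (0.5, 2.0)


def _voxel_z(geometry: PhantomGeometry, protocol: Protocol, b1: float,
             offsets_ppm: np.ndarray) -> np.ndarray:
    """Noise/drift-free Z for all foreground voxels: (n_vox, n_off)."""
    m = geometry.mask
    t = geometry.truth_maps
    b0 = geometry.b0_map_ppm[m][:, None]
    eff = np.asarray(offsets_ppm, dtype=float)[None, :] - b0
    t1 = t["t1_obs_ms"][m][:, None]
    if b1 <= 0.2:   # WASSR: direct saturation of the observed water pool
        return eq1_signal(eff, b1, t1, t["t2_obs_ms"][m][:, None],
                          protocol.f0_mhz)
    z = _two_pool_z_core(eff, b1, t["t2_f_ms"][m][:, None],
                         t["r_mt_hz"][m][:, None], t["m0_mt"][m][:, None],
                         t["t2_mt_us"][m][:, None], t1, protocol.f0_mhz)
    if b1 in CEST_B1_LEVELS_UT and geometry.pool_maps:
        r_ex = np.zeros_like(z)
        for off, (amp, wid) in geometry.pool_maps.items():
            a = amp[m][:, None]
            wdt = np.where(np.isfinite(wid[m]), wid[m], 1.0)[:, None]
            d = eff - off
            r_ex += a * wdt**2 / (wdt**2 + 4.0 * d**2)
        z = 1.0 / (1.0 / z + (t1 * 1e-3) * r_ex)
    return z


def _add_noise(frames: np.ndarray, protocol: Protocol,
               rng: np.random.Generator) -> np.ndarray:
    if protocol.noise_sd == 0:
        return frames
    if protocol.rician:
        re = frames + rng.normal(0.0, protocol.noise_sd, frames.shape)
        im = rng.normal(0.0, protocol.noise_sd, frames.shape)
        return np.hypot(re, im)
    return frames + rng.normal(0.0, protocol.noise_sd, frames.shape)


def simulate_study(geometry: PhantomGeometry, protocol: Protocol,
                   seed: int = 0) -> SyntheticStudy:
    """Forward-simulate every acquisition of the protocol from the phantom."""
    rng = np.random.default_rng(seed)
    h, w = geometry.label_image.shape
    m = geometry.mask
    zspec = {}
    for b1 in protocol.b1_levels_ut:
        offs, is_ref = build_acquisition(protocol.offsets_ppm[b1],
                                         protocol.reference_offset_ppm,
                                         protocol.reference_every)
        z = _voxel_z(geometry, protocol, b1, offs)      # (n_vox, n_frames)
        drift = 1.0 + protocol.drift_slope * np.arange(offs.size)
        frames = np.zeros((offs.size, h, w))
        frames[:, m] = (z * drift[None, :]).T
        frames = _add_noise(frames, protocol, rng)
        zspec[b1] = ZStack(b1_ut=b1, frames=frames, offsets_ppm=offs,
                           is_reference=is_ref)
    tis = np.asarray(protocol.tis_ms, dtype=float)
    ir = np.zeros((tis.size, h, w))
    t1 = geometry.truth_maps["t1_obs_ms"][m]
    ir[:, m] = ir_signal(t1[None, :], 1.0, tis[:, None], protocol.tr_ms)
    ir = _add_noise(ir, protocol, rng)
    return SyntheticStudy(geometry=geometry, protocol=protocol, zspec=zspec,
                          ir_frames=ir, seed=seed)


# --- default generative parameter sets -----------------------------------
#
# Region means for tumour and necrosis carry the group means reported for the
# two xenograft lines (T1/T2 observed, T2,F, R_MT·M0,MT, T2,MT).  Values the
# study never printed (tumour-region T1/T2,obs, DU145 tumour T2,F, all CEST
# pool amplitudes, and everything for muscle, connective tissue and
# blood/edema) are package choices documented in docs/methods.md.

_COMMON_REGIONS = dict(
    muscle=RegionSpec(
        label="muscle", t1_obs_ms=(1800, 80), t2_obs_ms=(35, 3),
        t2_f_ms=(30, 4), mt_effect_hz=(3.5, 0.3), t2_mt_us=(8.0, 0.2),
        cest_pools=(CESTPool(3.5, 0.05, 1.2), CESTPool(2.0, 0.05, 1.5),
                    CESTPool(-3.3, 0.05, 3.0))),
    muscle_connective=RegionSpec(
        label="muscle_connective", t1_obs_ms=(1900, 80), t2_obs_ms=(42, 4),
        t2_f_ms=(36, 4), mt_effect_hz=(2.9, 0.3), t2_mt_us=(8.6, 0.3),
        cest_pools=(CESTPool(3.5, 0.15, 1.2), CESTPool(2.0, 0.15, 1.5),
                    CESTPool(-3.3, 0.12, 3.0))),
    blood_edema=RegionSpec(
        label="blood_edema", t1_obs_ms=(3000, 150), t2_obs_ms=(180, 20),
        t2_f_ms=(180, 20), mt_effect_hz=(0.3, 0.1), t2_mt_us=(8.0, 0.5),
        cest_pools=(CESTPool(3.5, 0.05, 1.2), CESTPool(2.0, 0.05, 1.5),
                    CESTPool(-3.3, 0.05, 3.0))),
)

DEFAULT_REGIONS = {
    "22Rv1": (
        RegionSpec(label="tumour", t1_obs_ms=(2200, 100), t2_obs_ms=(55, 5),
                   t2_f_ms=(47, 6), mt_effect_hz=(1.8, 0.2),
                   t2_mt_us=(7.8, 0.1),
                   cest_pools=(CESTPool(3.5, 1.2, 1.2), CESTPool(2.0, 1.5, 1.5),
                               CESTPool(-3.3, 0.9, 3.0))),
        RegionSpec(label="necrosis", t1_obs_ms=(2000, 50), t2_obs_ms=(44, 4),
                   t2_f_ms=(39, 5), mt_effect_hz=(2.3, 0.6),
                   t2_mt_us=(7.4, 0.1),
                   cest_pools=(CESTPool(3.5, 0.5, 1.2), CESTPool(2.0, 0.6, 1.5),
                               CESTPool(-3.3, 0.5, 3.0))),
        _COMMON_REGIONS["muscle"], _COMMON_REGIONS["muscle_connective"],
        _COMMON_REGIONS["blood_edema"],
    ),
    "DU145": (
        RegionSpec(label="tumour", t1_obs_ms=(2400, 150), t2_obs_ms=(60, 6),
                   t2_f_ms=(58, 8), mt_effect_hz=(1.2, 0.1),
                   t2_mt_us=(8.2, 0.2),
                   cest_pools=(CESTPool(3.5, 0.8, 1.2), CESTPool(2.0, 0.9, 1.5),
                               CESTPool(-3.3, 0.6, 3.0))),
        RegionSpec(label="necrosis", t1_obs_ms=(2500, 200), t2_obs_ms=(70, 20),
                   t2_f_ms=(69, 15), mt_effect_hz=(1.1, 0.4),
                   t2_mt_us=(7.9, 0.4),
                   cest_pools=(CESTPool(3.5, 0.35, 1.2), CESTPool(2.0, 0.4, 1.5),
                               CESTPool(-3.3, 0.35, 3.0))),
        _COMMON_REGIONS["muscle"], _COMMON_REGIONS["muscle_connective"],
        _COMMON_REGIONS["blood_edema"],
    ),
}


def default_phantom_spec(tumour_type: str = "22Rv1", grid_shape=(64, 64),
                         seed: int = 0,
                         b0_amplitude_ppm: float = 0.1) -> PhantomSpec:
    """The study-condition phantom for one xenograft line."""
    if tumour_type not in DEFAULT_REGIONS:
        raise ValueError("tumour_type must be '22Rv1' or 'DU145'")
    return PhantomSpec(regions=DEFAULT_REGIONS[tumour_type],
                       grid_shape=grid_shape, seed=seed,
                       b0_amplitude_ppm=b0_amplitude_ppm)
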