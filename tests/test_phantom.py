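"""Digital phantom geometry, ground truth, and forward simulation."""

import numpy as np
import pytest

from qmtcest.phantom import (CESTPool, PhantomSpec, Protocol, REGION_LABELS,
                             RegionSpec, build_acquisition,
                             default_phantom_spec, make_phantom,
                             necrotic_core_ellipse,
                             simulate_study)
from qmtcest.relaxometry import eq1_signal, ir_signal
from tests.conftest import flat_regions


class TestSpecValidation:
    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(regions=flat_regions(), grid_shape=(8, 8))

    def test_duplicate_labels_rejected(self):
        regions = flat_regions() + (flat_regions()[0],)
        with pytest.raises(ValueError):
            PhantomSpec(regions=regions)

    def test_region_invariants(self):
        with pytest.raises(ValueError):
            RegionSpec(label="tumour", t1_obs_ms=(1000, 0),
                       t2_obs_ms=(1500, 0), t2_f_ms=(40, 0),
                       mt_effect_hz=(1.0, 0), t2_mt_us=(8, 0))
        with pytest.raises(ValueError):
            CESTPool(3.5, -0.1, 1.0)

    def test_protocol_reference_must_be_remote(self):
        with pytest.raises(ValueError):
            Protocol(reference_offset_ppm=10.0)


class TestGeometry:
    def test_zero_variance_regions_carry_exact_means(self, flat_spec):
        geom = make_phantom(flat_spec)
        tum = geom.label_image == REGION_LABELS["tumour"]
        assert np.allclose(geom.truth_maps["t1_obs_ms"][tum], 2200.0)
        assert np.allclose(geom.truth_maps["mt_effect_hz"][tum], 1.8)
        nec = geom.label_image == REGION_LABELS["necrosis"]
        assert np.allclose(geom.truth_maps["t2_mt_us"][nec], 7.4)

    def test_seeded_phantoms_identical(self):
        a = make_phantom(default_phantom_spec("22Rv1", seed=9))
        b = make_phantom(default_phantom_spec("22Rv1", seed=9))
        assert np.array_equal(a.label_image, b.label_image)
        for key in a.truth_maps:
            assert np.array_equal(a.truth_maps[key], b.truth_maps[key],
                                  equal_nan=True)

    def test_labels_partition_grid(self):
        geom = make_phantom(default_phantom_spec("DU145", seed=4))
        assert set(np.unique(geom.label_image)) <= set(REGION_LABELS.values())

    def test_necrotic_core_matches_rasterized_ellipse(self):
        spec = default_phantom_spec("22Rv1", seed=0)
        spec = PhantomSpec(regions=spec.regions, grid_shape=spec.grid_shape,
                           n_blood_specks=0, seed=0)
        geom = make_phantom(spec)
        count = int((geom.label_image == REGION_LABELS["necrosis"]).sum())
        cy, cx, ay, ax = necrotic_core_ellipse(spec.grid_shape)
        # brute-force rasterization oracle
        oracle = 0
        for i in range(spec.grid_shape[0]):
            for j in range(spec.grid_shape[1]):
                if ((i - cy) / ay) ** 2 + ((j - cx) / ax) ** 2 <= 1.0:
                    oracle += 1
        perimeter_ring = 2 * np.pi * max(ay, ax) + 8
        assert abs(count - oracle) <= perimeter_ring


class TestAcquisitionOrder:
    def test_references_interleaved_every_five(self):
        offs, is_ref = build_acquisition(np.arange(12.0), 667.0, every=5)
        assert is_ref.sum() == 4                    # lead-in, 2 interleaved, tail
        assert is_ref[0] and is_ref[-1]
        assert np.all(offs[is_ref] == 667.0)
        assert np.array_equal(offs[~is_ref], np.arange(12.0))


class TestSimulation:
    def test_low_b1_reduces_to_direct_saturation(self):
        """No MT pool, no CEST pools, no noise: the 0.5 µT spectrum equals the
        single-pool steady state with the free-pool T2."""
        regions = tuple(
            RegionSpec(label=r.label, t1_obs_ms=r.t1_obs_ms,
                       t2_obs_ms=r.t2_obs_ms, t2_f_ms=r.t2_obs_ms,
                       mt_effect_hz=(0.0, 0.0), t2_mt_us=r.t2_mt_us)
            for r in flat_regions(with_pools=False))
        spec = PhantomSpec(regions=regions, grid_shape=(24, 24),
                           b0_amplitude_ppm=0.0, n_blood_specks=0, seed=2)
        study = simulate_study(make_phantom(spec),
                               Protocol(noise_sd=0.0, drift_slope=0.0), seed=2)
        stack = study.zspec[0.5]
        i, j = 12, 12
        t1 = study.truth_maps["t1_obs_ms"][i, j]
        t2 = study.truth_maps["t2_obs_ms"][i, j]
        meas = ~stack.is_reference
        expected = eq1_signal(stack.offsets_ppm[meas], 0.5, t1, t2)
        assert np.allclose(stack.frames[meas, i, j], expected, atol=1e-12)

    def test_ir_series_matches_signal_model(self, study_noiseless):
        i, j = 16, 16
        t1 = study_noiseless.truth_maps["t1_obs_ms"][i, j]
        expected = ir_signal(t1, 1.0, np.array(study_noiseless.protocol.tis_ms),
                             study_noiseless.protocol.tr_ms)
        assert np.allclose(study_noiseless.ir_frames[:, i, j], expected)

    def test_z_bounded_and_pools_only_deepen(self, flat_spec,
                                             noiseless_protocol):
        study = simulate_study(make_phantom(flat_spec), noiseless_protocol,
                               seed=1)
        regions_np = tuple(
            RegionSpec(label=r.label, t1_obs_ms=r.t1_obs_ms,
                       t2_obs_ms=r.t2_obs_ms, t2_f_ms=r.t2_f_ms,
                       mt_effect_hz=r.mt_effect_hz, t2_mt_us=r.t2_mt_us)
            for r in flat_regions(with_pools=False))
        spec_np = PhantomSpec(regions=regions_np, grid_shape=(32, 32),
                              b0_amplitude_ppm=0.0, n_blood_specks=0, seed=1)
        study_np = simulate_study(make_phantom(spec_np), noiseless_protocol,
                                  seed=1)
        fg = study.geometry.mask
        for b1, stack in study.zspec.items():
            vals = stack.frames[:, fg]
            assert np.all((vals > 0) & (vals <= 1.0 + 1e-12))
            assert np.all(vals <= study_np.zspec[b1].frames[:, fg] + 1e-12)

    def test_reference_noise_matches_protocol_sd(self, flat_spec):
        """Sample SD of the noise at the 667-ppm references ≈ noise_sd·S0."""
        protocol = Protocol(noise_sd=0.01, drift_slope=0.0)
        study = simulate_study(make_phantom(flat_spec), protocol, seed=8)
        stack = study.zspec[6.0]
        fg = study.geometry.mask
        refs = stack.frames[stack.is_reference][:, fg]   # (n_ref, n_vox)
        resid = refs - refs.mean(axis=0)
        pooled_sd = np.sqrt((resid ** 2).sum()
                            / (refs.size - refs.shape[1]))
        assert pooled_sd == pytest.approx(0.01, rel=0.05)

    def test_seeded_simulation_bit_reproducible(self, flat_spec,
                                                noiseless_protocol):
        p = Protocol(noise_sd=0.005, drift_slope=1e-4)
        a = simulate_study(make_phantom(flat_spec), p, seed=5)
        b = simulate_study(make_phantom(flat_spec), p, seed=5)
        for b1 in a.zspec:
            assert np.array_equal(a.zspec[b1].frames, b.zspec[b1].frames)
        assert np.array_equal(a.ir_frames, b.ir_frames)
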