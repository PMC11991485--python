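"""Phantom generator: calibrated dielectrics, simulated acquisitions, scenes."""

from dataclasses import replace

import numpy as np
import pytest

import thzbean as tb
from thzbean.containers import DegeneratePhantomError
from thzbean.dielectric import LorentzDielectric, refractive_index
from thzbean.phantom import (
    AcquisitionConfig,
    BeanMap2D,
    make_bean_map,
    make_bean_phantom,
    quaker_transmission_excess,
    reference_pulse_waveform,
    simulate_bed_pattern,
    simulate_measurement,
    simulate_raster,
    simulate_reference_pulse,
    stray_waveform,
)


class TestAcquisitionConfig:
    def test_defaults_valid(self):
        cfg = AcquisitionConfig()
        assert cfg.n_samples == 3000
        f = cfg.frequency_axis()
        assert f[1] <= 0.03 and f[-1] >= 3.0

    @pytest.mark.parametrize("kwargs", [
        {"dt": 0.0},
        {"time_window": 10.0},  # < 30 x pulse_width
        {"relative_amplitude_noise": -1e-3},
        {"dt": 0.2},  # Nyquist below 3 THz
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AcquisitionConfig(**kwargs)


class TestBeanPhantoms:
    def test_green_slab_geometry(self):
        ph = make_bean_phantom("green_slab")
        assert len(ph.layers) == 1
        assert ph.layers[0][1] == 1500.0

    @pytest.mark.parametrize("variant,thickness", [
        ("roasted_slab", 1500.0), ("green_whole", 3500.0),
        ("roasted_whole", 3800.0), ("quaker_slab", 500.0),
        ("mature_slab_0p5", 500.0),
    ])
    def test_variant_thicknesses(self, variant, thickness):
        assert make_bean_phantom(variant).layers[0][1] == thickness

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            make_bean_phantom("espresso")

    def test_quaker_at_unit_density_equals_mature(self):
        q = make_bean_phantom("quaker_slab", density_factor=1.0)
        m = make_bean_phantom("mature_slab_0p5")
        assert q.layers[0][0] == m.layers[0][0]

    def test_green_penetration_anchor(self):
        # Im n(0.5 THz) = 0.3183 so that δ(0.5 THz) = 150 μm
        n = refractive_index(tb.GREEN_DIELECTRIC, np.array([0.5]))
        assert n.n[0].imag == pytest.approx(0.3183, abs=1e-3)

    def test_roast_ordering_im_n(self):
        f = np.linspace(0.1, 2.0, 500)
        k_green = refractive_index(tb.GREEN_DIELECTRIC, f).n.imag
        k_roast = refractive_index(tb.ROASTED_DIELECTRIC, f).n.imag
        assert np.all(k_green > k_roast)

    def test_two_layer_whole_bean_option(self):
        ph = make_bean_phantom("green_whole", two_layer=True)
        assert len(ph.layers) == 2
        assert ph.total_thickness_um == 3500.0

    def test_quaker_excess_calibration(self):
        _, excess, mask = quaker_transmission_excess()
        assert mask.any()
        assert 15.0 < excess[mask].max() <= 20.0


class TestReferencePulse:
    def test_noise_free_vapor_off_matches_closed_form(self):
        cfg = AcquisitionConfig(water_vapor=False, rng_seed=3).noise_free()
        trace = simulate_reference_pulse(cfg)
        expected = reference_pulse_waveform(cfg, cfg.time_axis())
        assert np.array_equal(trace.field, expected)

    def test_spectral_coverage(self):
        cfg = AcquisitionConfig(water_vapor=False).noise_free()
        trace = simulate_reference_pulse(cfg)
        spec = np.abs(np.fft.rfft(trace.field))
        f = cfg.frequency_axis()
        peak_f = f[np.argmax(spec)]
        assert 0.2 < peak_f < 0.45
        band = (f >= 0.1) & (f <= 3.0)
        assert np.all(spec[band] >= 1e-3 * spec.max())

    def test_vapor_produces_post_pulse_ringing(self):
        base = AcquisitionConfig(rng_seed=2).noise_free()
        on = simulate_reference_pulse(replace(base, water_vapor=True))
        off = simulate_reference_pulse(replace(base, water_vapor=False))
        t = base.time_axis()
        late = t > base.pulse_delay + 5.0 * base.pulse_width
        e_on = np.sum(on.field[late] ** 2)
        e_off = np.sum(off.field[late] ** 2)
        assert e_on > 10.0 * e_off

    def test_same_seed_identical(self):
        cfg = AcquisitionConfig(rng_seed=5)
        a = simulate_reference_pulse(cfg, realization=2)
        b = simulate_reference_pulse(cfg, realization=2)
        assert np.array_equal(a.field, b.field)

    def test_distinct_realizations_differ(self):
        cfg = AcquisitionConfig(rng_seed=5)
        a = simulate_reference_pulse(cfg, realization=0)
        b = simulate_reference_pulse(cfg, realization=1)
        assert not np.array_equal(a.field, b.field)


class TestSimulateMeasurement:
    def test_vacuum_phantom_identity(self):
        cfg = AcquisitionConfig(rng_seed=1, stray_fraction=0.0).noise_free()
        vacuum = tb.PhantomLayerStack(((LorentzDielectric(1.0), 1000.0),),
                                      label="vacuum")
        sample, reference, _ = simulate_measurement(vacuum, cfg)
        assert np.allclose(sample.field, reference.field, atol=1e-13)

    def test_zero_stray_fraction(self):
        cfg = replace(AcquisitionConfig(rng_seed=1).noise_free(),
                      stray_fraction=0.0)
        _, _, stray = simulate_measurement(make_bean_phantom("green_slab"),
                                           cfg)
        assert np.all(stray.field == 0)

    def test_main_transient_delay(self):
        # n = 2 slab, d = 1.5 mm: delay (n−1)d/c ≈ 5 ps
        cfg = AcquisitionConfig(rng_seed=1, water_vapor=False,
                                stray_fraction=0.0).noise_free()
        slab = tb.PhantomLayerStack(((LorentzDielectric(4.0), 1500.0),),
                                    label="n2")
        sample, reference, _ = simulate_measurement(slab, cfg)
        t_s = sample.time[np.argmax(np.abs(sample.field))]
        t_r = reference.time[np.argmax(np.abs(reference.field))]
        assert t_s - t_r == pytest.approx(5.0, abs=0.15)

    def test_stray_stable_across_calls_and_phantoms(self, default_cfg):
        _, _, s1 = simulate_measurement(make_bean_phantom("green_whole"),
                                        default_cfg)
        _, _, s2 = simulate_measurement(make_bean_phantom("roasted_slab"),
                                        default_cfg)
        assert np.array_equal(s1.field, s2.field)
        assert np.array_equal(s1.field, stray_waveform(default_cfg))

    def test_deterministic_given_seed(self, default_cfg):
        a = simulate_measurement(make_bean_phantom("green_slab"), default_cfg)
        b = simulate_measurement(make_bean_phantom("green_slab"), default_cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.field, y.field)

    def test_reflection_of_degenerate_phantom_rejected(self, default_cfg):
        vacuum = tb.PhantomLayerStack(((LorentzDielectric(1.0), 1000.0),),
                                      backing="air", label="vacuum")
        with pytest.raises(DegeneratePhantomError):
            simulate_measurement(vacuum, default_cfg, geometry="reflection")

    def test_reference_reproducibility_calibration(self):
        """Amplitude ratio of two independent references stays within ±0.2 %
        over 0.1–2 THz in at least 95 of 100 seeded repetitions."""
        ok = 0
        for seed in range(100):
            cfg = AcquisitionConfig(rng_seed=seed)
            r1 = tb.to_spectrum(simulate_reference_pulse(cfg, 0))
            r2 = tb.to_spectrum(simulate_reference_pulse(cfg, 1))
            _, band_max = tb.noise_level(r1, r2)
            ok += band_max <= 0.002
        assert ok >= 95


class TestBeanMap:
    def test_regions_partition_grid(self):
        m = make_bean_map("green")
        counts = {r: int(np.sum(m.region == r)) for r in BeanMap2D.REGIONS}
        assert sum(counts.values()) == 32 * 32
        assert all(counts[r] > 0 for r in BeanMap2D.REGIONS)

    def test_groove_is_contiguous_vertical_stripe(self):
        m = make_bean_map("roasted")
        ys, xs = np.where(m.region == "groove")
        assert set(xs) == {15, 16}  # a two-pixel-wide central stripe
        assert np.array_equal(np.unique(ys), np.arange(ys.min(), ys.max() + 1))

    def test_embryo_in_top_third_of_aperture(self):
        m = make_bean_map("roasted")
        ys, xs = np.where(m.region == "embryo")
        ay, _ = np.where(m.aperture)
        top_third = ay.min() + (ay.max() - ay.min()) / 3.0
        assert ys.mean() < top_third
        assert ys.size <= np.pi * 1.5**2 + 1  # small disc, <= 3 px diameter

    def test_multiplier_ordering(self):
        m = make_bean_map("roasted")
        assert np.all(m.extinction_mult[m.region == "lobe"] < 1.0)
        assert np.all(m.extinction_mult[m.region == "groove"] > 1.0)
        assert np.all(m.extinction_mult[m.region == "embryo"]
                      > m.extinction_mult[m.region == "groove"].max())


class TestSimulateRaster:
    def test_uniform_map_uniform_traces(self, noise_free_cfg):
        ones = np.ones((8, 8))
        m = BeanMap2D(ones.copy(), ones.copy(),
                      np.full((8, 8), "bulk"),
                      np.ones((8, 8), dtype=bool), pitch_mm=0.3)
        scan = simulate_raster(m, make_bean_phantom("green_slab"),
                               noise_free_cfg)
        first = scan.fields[0, 0]
        assert np.allclose(scan.fields, first[None, None, :], atol=1e-15)

    def test_outside_pixels_silent_when_noise_free(self, roasted_raster):
        bean_map, scan = roasted_raster
        outside = ~bean_map.aperture
        assert np.all(scan.fields[outside] == 0)

    def test_mean_pixel_matches_single_point_simulation(self, noise_free_cfg):
        ones = np.ones((4, 4))
        m = BeanMap2D(ones.copy(), ones.copy(),
                      np.full((4, 4), "bulk"),
                      np.ones((4, 4), dtype=bool), pitch_mm=0.3)
        phantom = make_bean_phantom("green_slab")
        scan = simulate_raster(m, phantom, noise_free_cfg)
        cfg0 = replace(noise_free_cfg, stray_fraction=0.0)
        sample, reference, _ = simulate_measurement(phantom, cfg0)
        f = noise_free_cfg.frequency_axis()
        i05 = np.argmin(np.abs(f - 0.5))
        ref_amp = np.abs(np.fft.rfft(reference.field))[i05]
        t_point = np.abs(np.fft.rfft(sample.field))[i05] / ref_amp
        pixel_amps = np.abs(np.fft.rfft(scan.fields, axis=-1))[:, :, i05]
        t_pixels = pixel_amps.mean() / ref_amp
        assert t_pixels == pytest.approx(t_point, rel=0.01)


class TestBedPattern:
    def test_all_empty_noise_free_is_silent(self):
        cfg = AcquisitionConfig(rng_seed=1).noise_free()
        layout = np.full((3, 3), "empty")
        scan = simulate_bed_pattern(layout, cfg)
        assert np.all(scan.fields == 0)

    def test_green_reflects_more_than_roasted(self, bed_scan):
        _, _, groups = bed_scan
        assert groups["green"].size >= 50 and groups["roasted"].size >= 50
        assert groups["green"].mean() > groups["roasted"].mean()

    def test_aligned_cells_match_front_surface_prediction(self):
        cfg = AcquisitionConfig(rng_seed=1).noise_free()
        layout = np.array([["green", "roasted"]], dtype=str)
        scan = simulate_bed_pattern(layout, cfg,
                                    orientation_factors=np.ones(2))
        f = cfg.frequency_axis()
        ref_spec = np.abs(np.fft.rfft(-scan.reference.field))
        band = (f >= 0.2) & (f <= 0.8)
        for i, diel in enumerate((tb.GREEN_DIELECTRIC, tb.ROASTED_DIELECTRIC)):
            n = refractive_index(diel, f).n
            R_pred = np.abs((1.0 - n) / (1.0 + n)) ** 2
            amp = np.abs(np.fft.rfft(scan.fields[0, i]))
            R_meas = (amp[band] / ref_spec[band]) ** 2
            assert np.allclose(R_meas, R_pred[band], rtol=0.01)

    def test_orientation_losses_exceed_order_of_magnitude(self, bed_scan):
        scan, img, groups = bed_scan
        orient = np.asarray(scan.meta["orientation_factors"])
        beans = np.isin(scan.labels, ("green", "roasted"))
        # mean intensity loss factor E[o²] is an order of magnitude or more
        assert np.mean(orient[beans] ** 2) < 0.15

    def test_unknown_cell_label_rejected(self, default_cfg):
        layout = np.array([["green", "banana"]], dtype=str)
        with pytest.raises(ValueError):
            simulate_bed_pattern(layout, default_cfg)
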