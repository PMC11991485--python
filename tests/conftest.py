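"""Shared fixtures: simulated datasets and fits reused across test modules."""

import numpy as np
import pytest

import thzbean as tb

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "suite", derandomize=True, deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def noise_free_cfg() -> tb.AcquisitionConfig:
    return tb.AcquisitionConfig(rng_seed=1).noise_free()


@pytest.fixture(scope="session")
def default_cfg() -> tb.AcquisitionConfig:
    return tb.AcquisitionConfig(rng_seed=1)


def simulate_tf(variant, cfg, window="tukey", pad_factor=4):
    """Simulate a phantom measurement and process it to a transfer function."""
    phantom = tb.make_bean_phantom(variant)
    sample, reference, stray = tb.simulate_measurement(phantom, cfg)
    corrected = tb.subtract_stray(sample, stray)
    return tb.transfer_function(
        tb.to_spectrum(corrected, window=window, pad_factor=pad_factor),
        tb.to_spectrum(reference, window=window, pad_factor=pad_factor),
    )


@pytest.fixture(scope="session")
def green_slab_tf(noise_free_cfg):
    """Noise-free green slab, default processing (Tukey window, pad 4)."""
    return simulate_tf("green_slab", noise_free_cfg)


@pytest.fixture(scope="session")
def green_fit(green_slab_tf):
    """Fit of the noise-free green slab dataset (the primary chain)."""
    return tb.fit_dielectric(green_slab_tf, 1500.0, tb.FitConfig(seed=1))


@pytest.fixture(scope="session")
def green_slab_tf_exact(noise_free_cfg):
    """Noise-free green slab with leakage-free processing (no window, pad 1)."""
    return simulate_tf("green_slab", noise_free_cfg, window="none",
                       pad_factor=1)


@pytest.fixture(scope="session")
def green_fit_exact(green_slab_tf_exact):
    return tb.fit_dielectric(green_slab_tf_exact, 1500.0, tb.FitConfig(seed=1))


@pytest.fixture(scope="session")
def roasted_fit_exact(noise_free_cfg):
    tf = simulate_tf("roasted_slab", noise_free_cfg, window="none",
                     pad_factor=1)
    return tb.fit_dielectric(tf, 1500.0, tb.FitConfig(seed=1))


@pytest.fixture(scope="session")
def green_whole_fit_exact(noise_free_cfg):
    tf = simulate_tf("green_whole", noise_free_cfg, window="none",
                     pad_factor=1)
    return tb.fit_dielectric(tf, 3500.0, tb.FitConfig(seed=1))


@pytest.fixture(scope="session")
def roasted_raster(noise_free_cfg):
    """Noise-free raster scan of the default roasted bean map."""
    bean_map = tb.make_bean_map("roasted")
    scan = tb.simulate_raster(bean_map, tb.make_bean_phantom("roasted_slab"),
                              noise_free_cfg)
    return bean_map, scan


@pytest.fixture(scope="session")
def bed_scan(default_cfg):
    layout = tb.default_bed_layout()
    scan = tb.simulate_bed_pattern(layout, default_cfg)
    img, groups = tb.integrated_reflect_map(scan)
    return scan, img, groups


@pytest.fixture(scope="session")
def fgrid():
    return np.linspace(0.05, 3.0, 600)
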