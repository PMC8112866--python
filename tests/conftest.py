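import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calibration():
    """Noise-free single-fluorophore calibration shared across tests.

    200 identical singles at 1000 ADU integrated intensity; the calibrated
    mean is within a fraction of a percent of 1000.
    """
    from microdomain.quant import calibrate_single_molecule
    from microdomain.simgen import FieldSimParams, simulate_dslb_field

    params = FieldSimParams(
        seed=101,
        field_size_px=(512, 512),
        n_singles=200,
        single_intensity_cv=0.0,
        noise_model="none",
    )
    image, _ = simulate_dslb_field(params)
    return calibrate_single_molecule(image, psf_sigma_px=params.psf_sigma_px)
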