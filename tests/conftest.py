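import pytest

from rctcnv import SimulationConfig, default_manifest


@pytest.fixture(scope="session")
def manifest():
    """The standard 35-probe screening panel."""
    return default_manifest()


@pytest.fixture(scope="session")
def manifest_mc():
    """Screening panel extended with the multicopy QC locus."""
    return default_manifest(include_multicopy=True)


@pytest.fixture
def noiseless_config():
    """All noise sources off: downstream ratios must equal copies/2 exactly."""
    return SimulationConfig(
        sigma_mlpa=0.0, sigma_count=0.0, amp_sd=0.0, probe_eff_sd=0.0,
        loss_freq=0.0, gain_freq=0.0, snp_artifact_freq=0.0,
        denat_fail_freq=0.0, expr_sd=0.0, seed=11,
    )


@pytest.fixture
def noisy_config():
    """Realistic assay noise, no CNV or failure modes unless spiked in."""
    return SimulationConfig(
        loss_freq=0.0, snp_artifact_freq=0.0, denat_fail_freq=0.0, seed=11,
    )
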