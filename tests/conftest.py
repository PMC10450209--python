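import pytest

from hrcentiles.config import BCCGAnchor, default_config


@pytest.fixture(scope="session")
def default_cohort():
    """One study-default synthetic cohort (n=801), shared across tests."""
    from hrcentiles.cohort import generate_cohort

    return generate_cohort(default_config(seed=20240301))


@pytest.fixture()
def anchored_config():
    """BCCG-anchored config with L, M, S interpolated between the endpoint medians."""
    anchors = {
        "mhr_bpm": (
            BCCGAnchor(age=11, L=1.0, M=208.64, S=0.03),
            BCCGAnchor(age=18, L=1.0, M=196.93, S=0.03),
        ),
        "rhr_bpm": (
            BCCGAnchor(age=11, L=1.0, M=73.86, S=0.08),
            BCCGAnchor(age=18, L=1.0, M=63.64, S=0.08),
        ),
    }
    return default_config(seed=11, bccg_anchors=anchors)
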