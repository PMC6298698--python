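import dataclasses

import pytest

from bkrect import synthetic_data as sd


@pytest.fixture(scope="session")
def catalog():
    return sd.make_preset_catalog()


@pytest.fixture(scope="session")
def wt_preset(catalog):
    return catalog["WT-beta2"]


def noise_free(preset):
    return dataclasses.replace(preset, noise_sd=0.0)


@pytest.fixture(scope="session")
def fast_tail_protocol():
    """Reduced tail family (±100 mV retained) for bulk tests."""
    return sd.tail_protocol(levels=(-150.0, -100.0, -50.0, 50.0, 100.0, 150.0))


@pytest.fixture(scope="session")
def fast_test_protocol():
    """Single +100 mV test pulse for bulk q fits."""
    return sd.test_pulse_protocol(levels=(100.0,))
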