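import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rodpath as rp

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def primate() -> rp.SpeciesParams:
    return rp.species_defaults("primate")


@pytest.fixture(scope="session")
def mouse() -> rp.SpeciesParams:
    return rp.species_defaults("mouse")


@pytest.fixture(scope="session")
def noiseless_rod_flash_store() -> rp.TraceStore:
    """Noiseless primate rod flash responses across backgrounds."""
    proto = {
        "master_seed": 0,
        "species": "primate",
        "cell_types": ["rod_current"],
        "backgrounds": [0.3, 1, 3, 10, 30, 100, 300],
        "noise_frac": 0.0,
        "cell_variability": False,
        "stimulus": {"kind": "flash", "contrast": 6.0, "duration_ms": 10,
                     "pre_ms": 200, "stim_ms": 600, "tail_ms": 0, "dt_ms": 2},
    }
    return rp.generate_dataset(proto)


@pytest.fixture(scope="session")
def sinusoid_store() -> rp.TraceStore:
    """Noiseless On parasol responses to 4 Hz sinusoids, several backgrounds."""
    proto = {
        "master_seed": 0,
        "species": "primate",
        "cell_types": ["On_parasol_exc"],
        "backgrounds": [0.2, 1, 5, 20, 100],
        "noise_frac": 0.0,
        "cell_variability": False,
        "stimulus": {"kind": "sinusoid", "contrast": 6.0, "frequency_hz": 4.0,
                     "pre_ms": 500, "stim_ms": 3000, "tail_ms": 0, "dt_ms": 1},
    }
    return rp.generate_dataset(proto)


def flash_trace(cell_type: str, bg: float, species="primate", condition="control",
                dt=1e-3, stim_s=1.5, **kw):
    stim = rp.StimulusSpec(kind="flash", background=bg, contrast=6.0,
                           duration_s=0.01, pre_s=0.2, stim_s=stim_s, tail_s=0.0,
                           dt_s=dt, **kw)
    return rp.simulate_cell(cell_type, stim, species, condition)


def response_amp(tr) -> float:
    return float(np.max(np.abs(tr.values - tr.baseline())))
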