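import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from fcglycoscope.glycans import default_library
from fcglycoscope.gpsm import SearchConfig, search
from fcglycoscope.synth import (
    PRESETS,
    SynthConfig,
    default_proteins,
    generate_glyco_run,
)

settings.register_profile(
    "fast",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def proteins():
    return default_proteins()


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def mrna_run_truth():
    """HCA_mRNA-preset glyco run at default noise, seed 7."""
    return generate_glyco_run(SynthConfig(preset=PRESETS["hca-mrna"], seed=7))


@pytest.fixture(scope="session")
def hca_n_run_truth():
    """HCA-N-preset glyco run at default noise, seed 7."""
    return generate_glyco_run(SynthConfig(preset=PRESETS["hca-n"], seed=7))


@pytest.fixture(scope="session")
def noiseless_run_truth():
    cfg = dataclasses.replace(
        SynthConfig(preset=PRESETS["hca-n"], seed=11),
        noise_peaks_ms1=0,
        noise_peaks_ms2=0,
        mz_jitter_ppm=0.0,
        intensity_cv=0.0,
        n_decoys=0,
    )
    return generate_glyco_run(cfg)


@pytest.fixture(scope="session")
def mrna_gpsms(mrna_run_truth, proteins, library):
    run, _truth = mrna_run_truth
    return search(run, proteins, library, SearchConfig())


@pytest.fixture(scope="session")
def hca_n_gpsms(hca_n_run_truth, proteins, library):
    run, _truth = hca_n_run_truth
    return search(run, proteins, library, SearchConfig())
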