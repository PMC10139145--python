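import numpy as np
import pytest

from tfdp import (
    ClassSpec,
    CohortConfig,
    TemperatureGrid,
    generate_cohort,
    mixture_preset,
    simulate_scan,
    single_species_mixture,
    six_curves,
)
from tfdp.features import detect_peaks

TM_BY_SPECIES = {"LYZ": 67.8, "LCN1": 69.4, "IGA": 72.9, "HSA": 75.1, "LTF": 67.4}


@pytest.fixture(scope="session")
def default_grid():
    return TemperatureGrid()


@pytest.fixture(scope="session")
def small_cohort():
    """15+15 subjects at the patient cluster means, default noise, fixed seed."""
    cfg = CohortConfig(
        control=ClassSpec(67.9, 77.7, n=15),
        poag=ClassSpec(64.6, 79.3, n=15),
        seed=42,
    )
    return generate_cohort(cfg)


def detected_tm(name: str, ligands=()) -> tuple:
    """Helper: noiseless single-protein scan -> (detected apex, PeakPair)."""
    run = simulate_scan(single_species_mixture(name, ligands=ligands), noise_sigma_rel=0.0)
    pk = detect_peaks(six_curves(run))
    return (pk.t1m if pk.t1m is not None else pk.t2m), pk


@pytest.fixture(scope="session")
def control_two_peak():
    run = simulate_scan(mixture_preset("CONTROL"), noise_sigma_rel=0.0)
    return detect_peaks(six_curves(run))
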