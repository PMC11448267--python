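import numpy as np
import pandas as pd
import pytest

from pdometab.seahorse import InjectionSchedule, PlateKineticSeries
from pdometab.synthetic import default_scenario


@pytest.fixture
def scenario():
    return default_scenario(seed=7)


@pytest.fixture
def quiet_scenario():
    """Noise-free scenario with fixed confluency for exact-recovery checks."""
    sc = default_scenario(seed=7)
    sc.seahorse["noise_sd"] = 0.0
    sc.seahorse["confluency_range"] = [1.0, 1.0]
    sc.tracing["noise_cv"] = 0.0
    return sc


def make_plate(assay_kind, phase_values, confluency=1.0, n_wells=1, cycles_per_phase=3):
    """Build a plate whose four phases hold the given constant values."""
    rates = np.repeat(np.asarray(phase_values, dtype=float), cycles_per_phase)
    rates = np.tile(rates, (n_wells, 1))
    wells = pd.DataFrame(
        {
            "well_id": [f"W{i}" for i in range(n_wells)],
            "group": ["g"] * n_wells,
            "treatment": ["DMSO"] * n_wells,
        }
    )
    return PlateKineticSeries(
        assay_kind=assay_kind,
        wells=wells,
        rates=rates,
        confluency=np.full(n_wells, confluency),
        schedule=InjectionSchedule.default(assay_kind, cycles_per_phase),
    )


@pytest.fixture
def plate_factory():
    return make_plate
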