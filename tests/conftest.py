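import numpy as np
import pytest

from respsens.types import WellReading


@pytest.fixture
def make_wells():
    """Factory building a three-compartment plate with prescribed viabilities.

    ``viabilities`` maps compartment -> list of % viability per dose; the
    fluorescence is placed between blank=100 and vehicle=1100 so Eq-1
    normalization recovers the prescribed values exactly.
    """

    def _make(doses, viabilities, blank=100.0, vehicle=1100.0, n_replicates=1):
        wells = []
        for comp, vs in viabilities.items():
            assert len(vs) == len(doses)
            for rep in range(1, n_replicates + 1):
                wells.append(WellReading(compartment=comp, role="blank",
                                         raw_fluorescence=blank, replicate_id=f"r{rep}"))
                wells.append(WellReading(compartment=comp, role="vehicle_control",
                                         raw_fluorescence=vehicle, replicate_id=f"r{rep}"))
            for dose, v in zip(doses, vs):
                for rep in range(1, n_replicates + 1):
                    wells.append(WellReading(
                        compartment=comp, role="sample",
                        raw_fluorescence=blank + (vehicle - blank) * v / 100.0,
                        dose=dose, replicate_id=f"r{rep}",
                    ))
        return wells

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
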