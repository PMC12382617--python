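import numpy as np
import pytest
from hypothesis import settings

import ebeamkin as ek

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    """Bundled fitted dose-response coefficients (7 antibiotics, 14 products)."""
    return ek.load_table3_registry()


@pytest.fixture(scope="session")
def tc_registry(registry):
    """Tetracycline and its hydroxylation marker product only."""
    tc = registry.antibiotics["tetracycline"]
    prod = registry.products["461.1549"]
    return ek.ModelRegistry(
        antibiotics={"tetracycline": tc},
        products={"461.1549": prod},
        parent_of={"461.1549": "tetracycline"},
        annotations={
            "tetracycline": registry.annotations.get("tetracycline", {}),
            "461.1549": registry.annotations.get("461.1549", {}),
        },
    )


@pytest.fixture(scope="session")
def experimental_doses():
    return (0.0, 0.1, 1.0, 3.0, 7.0)


@pytest.fixture()
def small_table():
    """One antibiotic, 5 doses x 3 replicates, exact exponential areas."""
    model = ek.AntibioticKinetics(c0=100.0, alpha=1.28)
    rows = []
    for dose in (0.0, 0.1, 1.0, 3.0, 7.0):
        for rep in (1, 2, 3):
            rows.append(
                ek.Observation(
                    dose_kGy=dose,
                    replicate=rep,
                    analyte="tetracycline",
                    mz=445.1592,
                    rt_min=6.68,
                    area=float(model.concentration(dose)),
                )
            )
    return ek.PeakTable(tuple(rows))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250924)
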