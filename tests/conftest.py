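import numpy as np
import pytest

from ntcpbench.cohort import Cohort, PatientRecord
from ntcpbench.dvh import DoseVolumeHistogram
from ntcpbench.synthetic_data import SimulationConfig, simulate_cohorts


def random_dvh(rng: np.random.Generator, max_bins: int = 50) -> DoseVolumeHistogram:
    """A random valid differential DVH (strictly increasing doses, unit volume)."""
    n_bins = int(rng.integers(1, max_bins + 1))
    doses = np.sort(rng.uniform(0.5, 80.0, size=n_bins))
    doses += np.arange(n_bins) * 1e-6  # enforce strict increase under duplicates
    volumes = rng.dirichlet(np.ones(n_bins))
    return DoseVolumeHistogram(doses=doses, volumes=volumes)


def uniform_dose_cohort(doses, labels) -> Cohort:
    """Cohort of single-bin (uniform-dose) patients — GMD independent of n."""
    records = [
        PatientRecord(
            patient_id=f"p{i}",
            dvh=DoseVolumeHistogram(doses=np.array([d]), volumes=np.array([1.0])),
            toxicity=int(y),
            batch="one",
        )
        for i, (d, y) in enumerate(zip(doses, labels))
    ]
    return Cohort(records)


@pytest.fixture(scope="session")
def small_cohorts():
    """A small simulated two-center pair for fast fitting tests."""
    config = SimulationConfig(n_train=150, n_test=75, seed=11)
    train, test, truth = simulate_cohorts(config)
    return train, test, truth


@pytest.fixture(scope="session")
def default_cohorts():
    """The default study conditions (194 train / 76 test)."""
    config = SimulationConfig(seed=5)
    train, test, truth = simulate_cohorts(config)
    return train, test, truth
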