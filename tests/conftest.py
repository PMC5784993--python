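import numpy as np
import pytest

from mtcsim import (LoadSpec, MuscleSpec, SimConfig, TendonSpec,
                    run_simulation)


@pytest.fixture(scope="session")
def muscle():
    return MuscleSpec()


@pytest.fixture(scope="session")
def load_20pct(muscle):
    """The default load: weight = 20% of maximal isometric force (~485 g)."""
    return LoadSpec(mass=0.20 * muscle.p0_force / 9.81)


@pytest.fixture(scope="session")
def tendon_compliant():
    return TendonSpec(youngs_modulus=0.0159e9)


@pytest.fixture(scope="session")
def tendon_rigid():
    return TendonSpec(youngs_modulus=5e9)


@pytest.fixture(scope="session")
def run_20pct_compliant(muscle, load_20pct, tendon_compliant):
    """One shared default-load run with the near-optimal compliant tendon."""
    return run_simulation(muscle, tendon_compliant, load_20pct,
                          SimConfig(max_time=2.0))


@pytest.fixture(scope="session")
def run_catch_pair(muscle):
    """The 100 ms catch, 100 g load contrast: compliant vs rigid tendon."""
    out = {}
    for label, e_gpa in [("compliant", 0.0159), ("rigid", 5.0)]:
        out[label] = run_simulation(
            MuscleSpec(), TendonSpec(youngs_modulus=e_gpa * 1e9),
            LoadSpec(mass=0.100, catch_delay=0.100), SimConfig(max_time=2.0))
    return out
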