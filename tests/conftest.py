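import numpy as np
import pytest

from fiberchrom import (
    BedGeometry,
    Component,
    FlowProgram,
    GroundTruth,
    SolverSettings,
    assemble_system,
    simulate,
)


@pytest.fixture(scope="session")
def bed():
    return BedGeometry()


@pytest.fixture(scope="session")
def truth_clean():
    """Ground truth with all noise switched off."""
    return GroundTruth(detector_sigma=0.0, batch_sigma=0.0, isec_sigma=0.0)


@pytest.fixture(scope="session")
def truth():
    return GroundTruth()


@pytest.fixture(scope="session")
def fast_settings():
    """Coarser grid for unit tests where 0.5% accuracy suffices."""
    return SolverSettings(n_cells=100, n_out=1200)


@pytest.fixture(scope="session")
def acetone_tracer_run(bed, fast_settings):
    """One shared non-binding acetone pulse simulation at 3 mL/min."""
    program = FlowProgram.tracer_pulse(species="acetone", F_ml_min=3.0)
    system = assemble_system(
        bed, [Component("acetone", 1.14e-9)], {}, program, settings=fast_settings
    )
    return system, simulate(system)


def inlet_moments(system, species):
    """Moments of the programmed (pre-column) inlet pulse of one species."""
    from fiberchrom.moments import peak_moments

    t = np.linspace(0.0, system._bounds[-1], 20001)
    c = system.inlet_raw(t)[:, system.species.index(species)]
    return peak_moments(t, c, threshold_frac=0.0)
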