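"""Shared fixtures: calibrated systems and sampled trajectories.

Expensive sampling runs are session-scoped and reused across test modules;
all randomness is seeded so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from evbkit.calibration import (CalibrationTargets, calibrate_evb,
                                quadrature_evaluator)
from evbkit.evb_core import EVBCoupling
from evbkit.sampler import SimulationConfig, run_fep_protocol
from evbkit.synthetic import (make_oracle_1d, make_toy_reaction,
                              toy_simulation_config)

REFERENCE_TARGETS = CalibrationTargets(dG_act_target=24.5, dG0_target=-12.8,
                                       tolerance=0.3, temperature=298.0)


@pytest.fixture(scope="session")
def calibrated_reference():
    """1D reference system with (delta_alpha, H12) fitted by quadrature."""
    system = make_oracle_1d("reference")
    result = calibrate_evb(
        quadrature_evaluator(system, REFERENCE_TARGETS.temperature),
        CalibrationTargets(24.5, -12.8, tolerance=1e-3, temperature=298.0))
    return system.with_coupling(result.coupling), result


@pytest.fixture(scope="session")
def reference_trajectories(calibrated_reference):
    """Ten fresh-seed replicates of the full 51-window protocol at 298 K."""
    system, _ = calibrated_reference
    cfg = SimulationConfig(seed=2024)
    return run_fep_protocol(system, 298.0, 51, 10, cfg)


@pytest.fixture(scope="session")
def toy_trajectories():
    """One replicate of the 3D toy reference protocol (short windows)."""
    system = make_toy_reaction("reference", seed=0)
    cfg = toy_simulation_config(seed=77, production=False)
    return run_fep_protocol(system, 298.0, 51, 1, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
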