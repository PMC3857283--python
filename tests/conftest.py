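"""Shared fixtures: tiny hand-built instances and the canonical simulation.

The expensive pieces (the canonical simulated survey and its reduced-scale
MCMC fit) are session-scoped so the recovery, adequacy and sensitivity
tests all share one sampler run.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import camsecr as cs
from camsecr.captures import CaptureArray, TrapStation

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_trap_instance():
    """One captured individual, two traps, four occasions, 12 mesh points."""
    stations = [
        TrapStation("T1", 0.0, 0.0, np.ones(4, np.int8)),
        TrapStation("T2", 1.0, 0.0, np.ones(4, np.int8)),
    ]
    ss = cs.build_statespace(stations, buffer_km=1.0, spacing_km=1.0)
    y = np.zeros((1, 2, 4), np.uint8)
    y[0, 0, 1] = 1
    y[0, 1, 3] = 1
    arr = CaptureArray(
        y, ["AF1"], ["T1", "T2"], 4,
        trap_xy=np.array([[0.0, 0.0], [1.0, 0.0]]),
        effort=np.ones((2, 4), np.int8),
    )
    return stations, ss, arr


@pytest.fixture(scope="session")
def canonical_sim():
    """Canonical design simulated at the study's fitted parameter values.

    13 stations, 63 occasions, 20 km buffer; 2 km mesh keeps the fit fast.
    """
    truth = cs.SimulationTruth(seed=1, spacing_km=2.0)
    stations = cs.make_trap_array(seed=1, n_occasions=truth.n_occasions)
    ss = cs.build_statespace(stations, truth.buffer_km, truth.spacing_km)
    rng = np.random.default_rng(1)
    centres, _ = cs.simulate_population(ss, truth, rng)
    arr, photos, _ = cs.simulate_capture_histories(centres, stations, truth, rng=rng)
    C = cs.prior_capture_indicator(arr)
    return {
        "truth": truth, "stations": stations, "ss": ss, "centres": centres,
        "arr": arr, "C": C, "photos": photos,
        "true_density": len(centres) / ss.suitable_area * 100.0,
    }


@pytest.fixture(scope="session")
def canonical_fit(canonical_sim):
    """Reduced-scale fit of the canonical simulation (25k draws, 5k burn-in)."""
    cfg = cs.McmcConfig(iterations=25_000, burn_in=5_000, seed=7)
    samples = cs.run_sampler(
        canonical_sim["arr"], canonical_sim["C"], canonical_sim["ss"], cfg
    )
    return samples
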