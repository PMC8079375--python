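import numpy as np
import pytest


def interior_transition_mask(bts, times, margin=6.0):
    """Samples whose governing binary transition lies at least ``margin``
    minutes after the trace start: edges detected inside the smoothing
    filters' end support are displaced by the shrinking windows and are
    excluded from exact round-trip claims."""
    ok = np.zeros((times.size, len(bts.transitions)), dtype=bool)
    for c, trs in enumerate(bts.transitions):
        tt = np.array([tr.time for tr in trs])
        if tt.size == 0:
            continue
        idx = np.searchsorted(tt, times, side="right") - 1
        has = idx >= 0
        ok[has, c] = tt[idx[has]] >= times[0] + margin
    return ok


@pytest.fixture(scope="session")
def transition_mask():
    return interior_transition_mask

from cyclesync import (InputSignal, ReporterConfig, cycling_params,
                       non_cycling_params, simulate, make_traces)


@pytest.fixture(scope="session")
def nc():
    return non_cycling_params()


@pytest.fixture(scope="session")
def cyc():
    return cycling_params()


@pytest.fixture(scope="session")
def cycling_mothers(cyc):
    """50 cycling mother cells, random initial phases, 600 min in +MET.

    Daughters are logged but not retained, so the traces are exactly the
    50 mothers.
    """
    return simulate(cyc, InputSignal.constant(0, 700), 600.0, dt=0.5,
                    N0=50, seed=11, initial_phases="random", capacity=50)


@pytest.fixture(scope="session")
def cdc10_noisy(cycling_mothers):
    """Two-level Cdc10 traces with noise sd = 10% of the level separation."""
    return make_traces(cycling_mothers,
                       ReporterConfig(kind="cdc10", noise_sd=0.4, seed=7))


@pytest.fixture(scope="session")
def cdc10_clean(cycling_mothers):
    return make_traces(cycling_mothers,
                       ReporterConfig(kind="cdc10", noise_sd=0.0))


@pytest.fixture(scope="session")
def nc_cycling_traj(nc):
    """Non-cycling founders driven continuously by -MET (all cycle at 75
    min); daughters not retained."""
    return simulate(nc, InputSignal.constant(1, 700), 600.0, dt=0.5,
                    N0=3, capacity=3)


@pytest.fixture(scope="session")
def cln2_clean(nc_cycling_traj):
    return make_traces(nc_cycling_traj,
                       ReporterConfig(kind="cln2", baseline=1.0,
                                      amplitude=10.0, noise_sd=0.0))
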