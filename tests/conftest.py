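import numpy as np
import pytest
from hypothesis import settings

import angiodyn as ad

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fig4_params():
    return ad.load_preset("fig4").params


@pytest.fixture(scope="session")
def fig5_params():
    return ad.load_preset("fig5").params


@pytest.fixture(scope="session")
def fig6a_spec():
    return ad.load_preset("fig6a")


def _wake_run(params, station_x=50.0):
    """Reduced-model invasion run on a scaled domain; returns the station
    time series used for wake-regularity classification."""
    grid = ad.Grid1D(L=1000.0, n=3000)
    initial = ad.default_initial(grid, params, p_seed=0.01, seed_width=1.0)
    t_out = np.arange(0.0, 1500.25, 0.5)
    states = ad.simulate(params, grid, initial, t_out, variant="reduced")
    node = int(round(station_x / grid.dx))
    t = np.array([st.t for st in states])
    series = np.array([st.p[node] for st in states])
    final = states[-1]
    return {"t": t, "station": series, "grid": grid, "final": final}


@pytest.fixture(scope="session")
def fig4_wake(fig4_params):
    return _wake_run(fig4_params)


@pytest.fixture(scope="session")
def fig5_wake(fig5_params):
    return _wake_run(fig5_params)


@pytest.fixture(scope="session")
def fig6a_run(fig6a_spec):
    """Full-model pre-therapy run at the caption grid (L=250, dx=25/900)."""
    spec = fig6a_spec
    grid = spec.grid
    initial = ad.default_initial(grid, spec.params, variant="full",
                                 **spec.initial)
    t_out = np.arange(0.0, 201.0, 10.0)
    states = ad.simulate(spec.params, grid, initial, t_out, variant="full")
    return {"states": states, "grid": grid, "params": spec.params}


@pytest.fixture(scope="session")
def chemo_outcomes():
    """Treatment experiments for all three occlusion scenarios, run at a
    reduced problem size (domain 120, therapy at t=100, horizon 160)."""
    base = ad.load_preset("fig7a").params
    grid = ad.Grid1D(L=120.0, n=1080)
    sched_s = ad.DoseSchedule(mode="single", c_init=1.0, k=0.9, t_start=100.0)
    sched_m = ad.DoseSchedule(mode="periodic", c_init=1.0, k=0.9,
                              T_per=10.0, n_boluses=4, t_start=100.0)
    outcomes = {}
    for name, delta in (("stable", 9.0), ("regular", 11.0),
                        ("irregular", 11.6)):
        outcomes[name] = ad.run_treatment_experiment(
            base.with_(delta=delta), grid, sched_s, sched_m,
            t_end=160.0, dt_out=0.5, scenario=name)
    return outcomes
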