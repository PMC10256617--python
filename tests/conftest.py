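import numpy as np
import pandas as pd
import pytest

from podcompare import simulate as sim


@pytest.fixture(scope="session")
def small_occupancy():
    return sim.OccupancyParams(
        base_encounter_rate=0.25, start_date="2021-04-01", end_date="2021-05-01"
    )


@pytest.fixture(scope="session")
def small_truth(small_occupancy):
    enc = sim.simulate_occupancy(small_occupancy, seed=1)
    return sim.simulate_click_trains(enc, sim.TrainParams(), seed=2, params_occ=small_occupancy)


@pytest.fixture(scope="session")
def pod_c(small_truth):
    return sim.apply_detector(small_truth, sim.profile_c_like(), seed=3)


@pytest.fixture(scope="session")
def pod_f(small_truth):
    return sim.apply_detector(small_truth, sim.profile_f_like(), seed=4)


@pytest.fixture(scope="session")
def effort(small_occupancy):
    return (small_occupancy.start, small_occupancy.end)


@pytest.fixture(scope="session")
def perfect_pod(small_truth):
    profile = sim.profile_f_like(
        pod_label="P", p_click=1.0, noise_slope=0.0, false_train_rate=0.0, min_clicks_train=2
    )
    return sim.apply_detector(small_truth, profile, seed=5)
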