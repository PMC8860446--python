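import numpy as np
import pytest

import sniffcode as sc


@pytest.fixture(scope="session")
def small_config():
    """Small but realistic session: 2 classes, 4 odors, 2 concentrations."""
    return sc.GeneratorConfig(
        classes={
            "fan": sc.ClassParams(n_units=20, latency_mean=0.072,
                                  latency_shift_per_doubling=0.0,
                                  rate_gain_per_doubling=0.2),
            "pyramidal": sc.ClassParams(n_units=20, latency_mean=0.078,
                                        latency_shift_per_doubling=-0.010,
                                        rate_gain_per_doubling=0.2),
        },
        n_odors=4, concentrations=(0.5, 1.0), trials_per_condition=10,
        response_prob=0.3,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return sc.simulate_session(small_config, seed=1234)


@pytest.fixture(scope="session")
def small_raster(small_session):
    trace, trials, spikes, gt = small_session
    onsets = sc.detect_inhalation_onsets(trace)
    aligned = sc.align_trials(trials, onsets)
    return sc.build_raster(spikes, aligned, window=(-0.10, 0.30))


def make_raster(spike_map, trials=None, window=(-0.10, 0.30)):
    """Hand-built aligned raster from {(unit, trial): [rel times]}."""
    import pandas as pd
    rows = [(u, t, rt) for (u, t), times in spike_map.items() for rt in times]
    spikes = pd.DataFrame(rows, columns=["unit_id", "trial_id", "rel_time_s"])
    if trials is None:
        tids = sorted({t for _, t in spike_map})
        trials = pd.DataFrame({
            "trial_id": tids,
            "odor_id": ["odor01"] * len(tids),
            "concentration": [1.0] * len(tids),
            "odor_on_s": np.zeros(len(tids)),
            "led": False,
            "t0_s": np.zeros(len(tids)),
            "valid": True,
        })
    units = np.array(sorted({u for u, _ in spike_map}))
    return sc.AlignedRaster(spikes=spikes, trials=trials, window=window,
                            units=units)
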