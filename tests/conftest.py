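import numpy as np
import pytest

from taucleave import (
    PeptideObservation,
    SimConfig,
    TimeSeriesDesign,
    make_tau_like_truth,
    simulate_digest,
    tau_2n4r,
)


@pytest.fixture(scope="session")
def tau():
    return tau_2n4r()


@pytest.fixture(scope="session")
def small_design():
    """Three time points, two replicates, two substrate-alone controls."""
    return TimeSeriesDesign.create([10.0, 60.0, 300.0], n_replicates=2, n_controls=2)


def make_observation(sequence, score, per_time, design, controls=None):
    """Build an observation from per-time replicate intensities.

    ``per_time`` maps time point -> list of replicate intensities (in
    replicate order); ``controls`` is a list over control samples.
    """
    intensities = {}
    for t, values in per_time.items():
        for sample, value in zip(design.experiment_samples(t), values):
            intensities[sample] = float(value)
    for sample, value in zip(design.control_samples(), controls or []):
        intensities[sample] = float(value)
    return PeptideObservation(sequence=sequence, score=score, intensities=intensities)


@pytest.fixture(scope="session")
def default_truth(tau):
    return make_tau_like_truth(tau)


@pytest.fixture(scope="session")
def default_sim(tau, default_truth):
    """One default-scenario simulated digest, shared across tests."""
    return simulate_digest(tau, default_truth, SimConfig(seed=11))
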