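"""Shared test fixtures.

The grid experiments are the expensive part of the suite, and several
tests (model-comparison orderings, parameter recovery, shared-seed
invariants) interrogate the same runs, so those runs are session-scoped
and computed once at reduced but statistically adequate sizes.
"""

from __future__ import annotations

import numpy as np
import pytest

from raceconf import make_fixture, run_noise_experiment, run_pe_ne_experiment
from raceconf.experiments import CrossoverConfig, SimConfig, run_crossover_experiment

# sizes chosen so each bundle builds in about a minute while keeping
# Monte-Carlo error small relative to the effects under test (the 0.1
# matched-d' discipline needs ~10k trials per condition)
EXP_CONFIG = SimConfig(n_per_stim=5000, n_calib=12_000)
ALPHA_GRID = np.round(np.arange(0.2, 0.95, 0.1), 3)
SIGMA_GRID = np.round(np.arange(0.11, 0.205, 0.01), 3)


@pytest.fixture(scope="session")
def pe_ne_bundle():
    """PE/NE fixture plus both readouts' grid runs against it."""
    fx = make_fixture("pe_ne", n_trials=8000, rng=7, keep_trials=False)
    targets = fx.experiment_targets()
    runs = {
        readout: run_pe_ne_experiment(
            readout, fx.truth["alpha_low"], ALPHA_GRID, targets, EXP_CONFIG, rng=3
        )
        for readout in ("c_x", "c_delta")
    }
    return {"fixture": fx, "targets": targets, "runs": runs}


@pytest.fixture(scope="session")
def noise_bundle():
    """Noise-design fixture plus both readouts' sigma-grid runs."""
    fx = make_fixture("noise", n_trials=8000, rng=17, keep_trials=False)
    targets = fx.experiment_targets()
    runs = {
        readout: run_noise_experiment(
            readout, fx.truth["sigma_low"], SIGMA_GRID, targets, EXP_CONFIG, rng=23
        )
        for readout in ("c_x", "c_delta")
    }
    return {"fixture": fx, "targets": targets, "runs": runs}


@pytest.fixture(scope="session")
def crossover_bundle():
    """Five-level design run for both readouts with shared seeds."""
    cfg = CrossoverConfig(n_per_stim=4000, n_calib=8000, d_mid=1.5, meta_d_mid=1.1)
    return {
        readout: run_crossover_experiment(readout, cfg, 42)
        for readout in ("c_x", "c_delta")
    }
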