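"""Unit and property tests for the two-stage race dynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from raceconf import (
    ModelParams,
    rate_confidence,
    simulate_block,
    simulate_trial,
    simulate_trials,
    step_accumulators,
    step_differencing,
)


class FixedNoise:
    """rng stub returning a predetermined noise vector every draw."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)

    def normal(self, loc, scale, size):
        return np.broadcast_to(self.values, size).copy()


# ---------------------------------------------------------------------------
# parameter validation


@pytest.mark.parametrize(
    "kwargs",
    [
        {"s_drives": (-0.1, 0.0)},
        {"sigma_acc": -1.0},
        {"threshold": 0.0},
        {"tau": -1},
        {"tau": 2.5},
        {"rating_thresholds": (1.0, 1.0, 2.0)},
        {"rating_thresholds": (1.0, 2.0)},  # wrong length for 4 ratings
        {"max_steps": 0},
        {"s_drives": (0.1, 0.1, 0.1)},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        ModelParams(**kwargs)


def test_mirrored_swaps_drives():
    p = ModelParams(s_drives=(0.02, 0.005))
    assert p.mirrored().s_drives == (0.005, 0.02)
    assert p.mirrored().mirrored() == p


# ---------------------------------------------------------------------------
# stage updates


def test_accumulator_step_noiseless_drift():
    p = ModelParams(s_drives=(0.25, 0.0), sigma_acc=0.0)
    out = step_accumulators(np.array([0.0, 0.0]), p, FixedNoise([0.0, 0.0]))
    assert np.allclose(out, [0.25, 0.0])


def test_accumulator_step_rectifies_at_zero():
    p = ModelParams(s_drives=(0.0, 0.0))
    out = step_accumulators(np.array([0.1, 0.1]), p, FixedNoise([-0.5, 0.2]))
    assert np.allclose(out, [0.0, 0.3])


def test_accumulator_dimension_mismatch():
    p = ModelParams(s_drives=(0.1, 0.0))
    with pytest.raises(ValueError):
        step_accumulators(np.zeros(3), p, 0)


def test_differencing_examples():
    p = ModelParams(sigma_diff=0.0)
    assert np.allclose(step_differencing(np.array([1.25, 0.0]), p, 0), [1.25, 0.0])
    assert np.allclose(step_differencing(np.array([0.4, 0.9]), p, 0), [0.0, 0.5])
    with pytest.raises(ValueError):
        step_differencing(np.zeros(3), p, 0)


def test_differencing_rectified_normal_mean():
    # with equal accumulators, E[delta] = E[max(N(0, sigma), 0)] = sigma/sqrt(2*pi)
    p = ModelParams(sigma_diff=0.1)
    rng = np.random.default_rng(3)
    x = np.tile([1.0, 1.0], (200_000, 1))
    d = step_differencing(x, p, rng)
    expected = 0.1 / np.sqrt(2 * np.pi)
    assert d.mean() == pytest.approx(expected, rel=0.02)


def test_accumulator_matches_scalar_walk_oracle():
    """100-step accumulator state matches an independently coded rectified
    scalar random walk (KS test at n = 10,000)."""
    n, steps, sigma = 10_000, 100, 0.1
    p = ModelParams(s_drives=(0.0, 0.0), sigma_acc=sigma)
    rng = np.random.default_rng(11)
    x = np.zeros((n, 2))
    for _ in range(steps):
        x = step_accumulators(x, p, rng)

    oracle_rng = np.random.default_rng(99)
    w = np.zeros(n)
    for _ in range(steps):
        w = np.maximum(w + oracle_rng.normal(0.0, sigma, n), 0.0)

    assert ks_2samp(x[:, 0], w).pvalue > 1e-3


# ---------------------------------------------------------------------------
# confidence rating


@pytest.mark.parametrize(
    "c, expected",
    [(0.5, 1), (2.5, 3), (2.0, 2), (3.5, 4), (1.0, 1)],
)
def test_rate_confidence_strict_threshold_count(c, expected):
    assert rate_confidence(c, (1.0, 2.0, 3.0)) == expected


def test_rate_confidence_rejects_unsorted():
    with pytest.raises(ValueError):
        rate_confidence(1.0, (2.0, 1.0, 3.0))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    c=st.floats(min_value=-5, max_value=20, allow_nan=False),
    gaps=st.lists(st.floats(min_value=1e-3, max_value=5), min_size=1, max_size=6),
)
def test_rate_confidence_matches_naive_count(c, gaps):
    thresholds = np.cumsum(gaps)
    naive = 1 + int(sum(c > u for u in thresholds))
    assert rate_confidence(c, thresholds) == naive


# ---------------------------------------------------------------------------
# full-trial simulation


def test_noiseless_closed_form_rt_and_confidence():
    """With zero noise and drives (s, 0) the winner crosses after
    ceil-like k = min{k : k*s > T} updates, i.e. at state index k+1, and
    c_x = (k + tau) * s."""
    p = ModelParams(s_drives=(0.25, 0.0), sigma_acc=0.0, sigma_diff=0.0, threshold=1.0)
    rec = simulate_trial(p, 0, 0)
    assert (rec.decision, rec.rt) == (0, 6)  # 5 updates of 0.25, resting state is t=1
    assert rec.c_x == pytest.approx(1.25)
    assert rec.c_delta == pytest.approx(1.25)

    rec4 = simulate_trial(p.replace(tau=4), 0, 0)
    assert rec4.c_x == pytest.approx(9 * 0.25)


def test_noiseless_closed_form_general():
    for s in (0.11, 0.3, 0.5):
        p = ModelParams(s_drives=(s, 0.0), sigma_acc=0.0, sigma_diff=0.0, threshold=1.0)
        rec = simulate_trial(p, 0, 0)
        k = int(np.floor(1.0 / s)) + 1  # first k with k*s > 1 (s*k never == 1 here)
        assert rec.rt == k + 1
        assert rec.c_x == pytest.approx(k * s)


def test_rectification_invariants_on_simulated_trials():
    p = ModelParams(s_drives=(0.01, 0.002), tau=20)
    df = simulate_trials(p, 0, 2000, 5)
    assert (df.c_x >= 0).all()
    assert (df.c_delta >= 0).all()
    assert (df.rt_steps >= 2).all()
    assert not df.censored.any()


def test_readout_ordering_without_differencing_noise():
    # delta_D = max(x_D - x_j, 0) <= x_D whenever xi is off
    p = ModelParams(s_drives=(0.012, 0.0), sigma_diff=0.0, tau=30)
    df = simulate_trials(p, 0, 4000, 8)
    assert (df.c_delta <= df.c_x + 1e-12).all()


def test_trial_record_rating_assigned_with_thresholds():
    p = ModelParams(
        s_drives=(0.25, 0.0), sigma_acc=0.0, sigma_diff=0.0, rating_thresholds=(0.5, 1.0, 2.0)
    )
    rec = simulate_trial(p, 0, 0)
    assert rec.rating == 3  # c_x = 1.25 surpasses 0.5 and 1.0 but not 2.0


def test_block_empty_design_and_zero_trials():
    p = ModelParams(s_drives=(0.01, 0.0))
    with pytest.raises(ValueError):
        simulate_block(p, [], 0)
    assert len(simulate_block(p, [(0, 0)], 0)) == 0


def test_block_symmetry_response_rate():
    p = ModelParams(s_drives=(0.02, 0.02))
    df = simulate_block(p, [(0, 5000), (1, 5000)], 1)
    rate = (df.response == 0).mean()
    se = 0.5 / np.sqrt(len(df))
    assert abs(rate - 0.5) < 3 * se


def test_block_deterministic_given_seed():
    p = ModelParams(s_drives=(0.01, 0.001), tau=10)
    a = simulate_block(p, [(0, 300), (1, 300)], 123)
    b = simulate_block(p, [(0, 300), (1, 300)], 123)
    pd.testing.assert_frame_equal(a, b)


def test_swap_symmetry_of_joint_distribution():
    """Swapping the alternatives' drives together with the stimulus label
    leaves accuracy, RT and confidence distributions invariant."""
    p = ModelParams(s_drives=(0.012, 0.003), tau=20)
    a = simulate_trials(p, 0, 10_000, 2)
    b = simulate_trials(p.mirrored(), 1, 10_000, 3)
    assert abs(a.correct.mean() - b.correct.mean()) < 0.02
    assert ks_2samp(a.rt_steps, b.rt_steps).pvalue > 1e-3
    assert ks_2samp(a.c_x, b.c_x).pvalue > 1e-3
    assert ks_2samp(a.c_delta, b.c_delta).pvalue > 1e-3


def test_rt_decreases_with_drive():
    medians = []
    for s in (0.005, 0.015, 0.03):
        p = ModelParams(s_drives=(s, 0.0))
        medians.append(simulate_trials(p, 0, 10_000, 7).rt_steps.median())
    assert medians[0] > medians[1] > medians[2]


def test_decisions_invariant_to_tau_under_shared_seed():
    """tau only affects the post-decision readout: with a shared seed the
    decision and RT streams are identical for any tau."""
    p = ModelParams(s_drives=(0.01, 0.0))
    a = simulate_trials(p, 0, 1500, 42)
    b = simulate_trials(p.replace(tau=50), 0, 1500, 42)
    assert (a.response == b.response).all()
    assert (a.rt_steps == b.rt_steps).all()
    assert not np.allclose(a.c_x, b.c_x)  # confidence does change


def test_censoring_flags_slow_trials():
    # zero drive, tiny noise: the bound is unreachable within the horizon
    p = ModelParams(s_drives=(0.0, 0.0), sigma_acc=0.001, max_steps=50)
    df = simulate_trials(p, 0, 200, 0)
    assert df.censored.all()
    assert (df.rt_steps == 50).all()
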