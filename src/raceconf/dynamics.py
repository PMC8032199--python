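"""Two-stage rectified race dynamics.

Stage 1: two independent accumulator units integrate momentary evidence,

    x_i(t) = max(x_i(t-1) + S_i + eps_i(t), 0),        eps ~ N(0, sigma_acc)

Stage 2: two differencing units compute the instantaneous rectified balance
of evidence (feed-forward excitation from the same-preference accumulator,
inhibition from the opposing one),

    delta_i(t) = max(x_i(t) - x_j(t) + xi_i(t), 0),    xi ~ N(0, sigma_diff)

A decision D is made the first time a differencing unit strictly exceeds
the bound T; that step is the reaction time.  Accumulation then continues
for ``tau`` further steps, after which two competing confidence readouts
are taken: ``c_x = x_D(rt + tau)`` (absolute decision-congruent evidence)
and ``c_delta = delta_D(rt + tau)`` (balance of evidence).  Raw confidence
is mapped to an ordinal rating by counting how many rating thresholds it
strictly exceeds.

Within a step the accumulators are advanced first and the differencing
units are then computed from the updated accumulators (the feed-forward
wiring implies this order).  The differencing units are memoryless: they
are recomputed from the current accumulator state each step.

Time convention: the time index t starts at 1 on the resting state
(x = 0), so the first accumulation update produces the state at t = 2 and
the reaction time reported for a trial is the state index at which the
winning differencing unit first exceeds the bound — one more than the
number of updates performed.  With zero noise and drives (s, 0) this gives
``rt = 1 + min{k : k*s > T}`` and ``c_x = (rt - 1 + tau) * s``.  This
indexing reproduces the model's published zero-drive reaction-time
statistics (average median RT ~80.6 steps, average minimum RT ~7.3 steps
at sigma = 0.1, T = 1 over 10 x 10,000 trials).

Two independent noise streams are used per simulation call: one for the
pre-decision race, one for the post-decision period.  Decisions and RTs are
therefore exactly invariant to ``tau`` under a shared seed, which the
experiment harnesses rely on when pairing simulations.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ModelParams, TrialRecord

__all__ = [
    "step_accumulators",
    "step_differencing",
    "rate_confidence",
    "simulate_trial",
    "simulate_trials",
    "simulate_block",
    "simulate_condition",
    "assign_ratings",
    "TRIAL_COLUMNS",
]

#: canonical column order for trial tables (CSV schema)
TRIAL_COLUMNS = [
    "condition",
    "stimulus",
    "response",
    "correct",
    "rt_steps",
    "c_x",
    "c_delta",
    "rating",
    "censored",
]


def _as_rng(rng) -> np.random.Generator:
    # anything exposing .normal works (allows deterministic stubs in tests)
    if hasattr(rng, "normal"):
        return rng
    return np.random.default_rng(rng)


def step_accumulators(x, params: ModelParams, rng) -> np.ndarray:
    """Advance the accumulator units one time step (rectified at zero)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(params.s_drives):
        raise ValueError(
            f"state has {x.shape[-1]} units but params define {len(params.s_drives)} drives"
        )
    eps = _as_rng(rng).normal(0.0, params.sigma_acc, size=x.shape)
    return np.maximum(x + np.asarray(params.s_drives) + eps, 0.0)


def step_differencing(x, params: ModelParams, rng) -> np.ndarray:
    """Compute both differencing units from the current accumulator state.

    ``delta_i = max(x_i - x_j + xi_i, 0)`` with independent noise per unit.
    Only the two-alternative case is supported.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != 2:
        raise ValueError("differencing units are defined for exactly two alternatives")
    xi = _as_rng(rng).normal(0.0, params.effective_sigma_diff, size=x.shape)
    return np.maximum(x - x[..., ::-1] + xi, 0.0)


def rate_confidence(c, thresholds) -> np.ndarray | int:
    """Ordinal rating: 1 + number of thresholds strictly exceeded by ``c``.

    ``thresholds`` must be strictly ascending; a confidence exactly equal
    to a threshold does not surpass it.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or np.any(np.diff(thr) <= 0):
        raise ValueError("rating thresholds must be a strictly ascending 1-D sequence")
    c_arr = np.asarray(c, dtype=float)
    # number of thresholds strictly below c == count of (c > U_r)
    rating = 1 + np.searchsorted(thr, c_arr, side="left")
    if np.ndim(c) == 0:
        return int(rating)
    return rating


def _pick_winner(delta: np.ndarray, crossed: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Winning unit among rows where at least one unit crossed the bound.

    The unit with the larger delta wins; an exact tie is broken uniformly
    at random.
    """
    win = np.where(delta[:, 0] >= delta[:, 1], 0, 1)
    ties = delta[:, 0] == delta[:, 1]
    if np.any(ties):
        win[ties] = rng.integers(0, 2, size=int(ties.sum()))
    # if only one unit crossed it necessarily has the larger delta when the
    # other is below T; guard anyway for the pathological case delta_j > T
    # with delta_i == delta_j handled by the tie above
    only = crossed[:, 0] != crossed[:, 1]
    win[only] = np.where(crossed[only, 0], 0, 1)
    return win


def simulate_trials(
    params: ModelParams,
    stimulus: int,
    n: int,
    rng,
    condition: str | None = None,
) -> pd.DataFrame:
    """Simulate ``n`` independent trials of one trial type, vectorized.

    ``params.s_drives`` are used as-is; ``stimulus`` only labels which
    alternative is the correct one (``correct = decision == stimulus``).

    Returns a DataFrame with columns ``stimulus, response, correct,
    rt_steps, c_x, c_delta, censored`` (plus ``condition`` if given).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if stimulus not in (0, 1):
        raise ValueError("stimulus must index one of the two alternatives (0 or 1)")
    rng = _as_rng(rng)
    rng_pre, rng_post = rng.spawn(2)

    drives = np.asarray(params.s_drives, dtype=float)
    sig_a = params.sigma_acc
    sig_d = params.effective_sigma_diff
    T = params.threshold

    # phase 1: race until each trial's differencing unit crosses the bound
    x = np.zeros((n, 2))
    ids = np.arange(n)
    decision = np.zeros(n, dtype=np.int64)
    rt = np.full(n, params.max_steps, dtype=np.int64)
    censored = np.zeros(n, dtype=bool)
    x_at_dec = np.zeros((n, 2))
    d_at_dec = np.zeros((n, 2))

    t = 1  # state index; t=1 is the resting state, updates produce t=2, 3, ...
    while ids.size and t < params.max_steps:
        t += 1
        x = np.maximum(x + drives + rng_pre.normal(0.0, sig_a, size=x.shape), 0.0)
        delta = np.maximum(
            x - x[:, ::-1] + rng_pre.normal(0.0, sig_d, size=x.shape), 0.0
        )
        crossed = delta > T
        hit = crossed.any(axis=1)
        if hit.any():
            done = ids[hit]
            decision[done] = _pick_winner(delta[hit], crossed[hit], rng_pre)
            rt[done] = t
            x_at_dec[done] = x[hit]
            d_at_dec[done] = delta[hit]
            keep = ~hit
            x = x[keep]
            ids = ids[keep]

    if ids.size:  # censored: decide by the larger delta at the horizon
        censored[ids] = True
        delta = np.maximum(
            x - x[:, ::-1] + rng_pre.normal(0.0, sig_d, size=x.shape), 0.0
        )
        decision[ids] = _pick_winner(delta, delta > -np.inf, rng_pre)
        x_at_dec[ids] = x
        d_at_dec[ids] = delta

    # phase 2: post-decision accumulation for tau steps (all trials at once;
    # the dynamics are time-homogeneous so alignment of absolute step
    # indices across trials is immaterial)
    if params.tau > 0:
        xs = x_at_dec.copy()
        for _ in range(params.tau):
            xs = np.maximum(xs + drives + rng_post.normal(0.0, sig_a, size=xs.shape), 0.0)
        d_final = np.maximum(
            xs - xs[:, ::-1] + rng_post.normal(0.0, sig_d, size=xs.shape), 0.0
        )
    else:
        xs = x_at_dec
        d_final = d_at_dec

    rows = np.arange(n)
    out = pd.DataFrame(
        {
            "stimulus": np.full(n, stimulus, dtype=np.int64),
            "response": decision,
            "correct": decision == stimulus,
            "rt_steps": rt,
            "c_x": xs[rows, decision],
            "c_delta": d_final[rows, decision],
            "censored": censored,
        }
    )
    if condition is not None:
        out.insert(0, "condition", condition)
    return out


def simulate_trial(params: ModelParams, stimulus: int, rng) -> TrialRecord:
    """Simulate a single trial and return its :class:`TrialRecord`."""
    df = simulate_trials(params, stimulus, 1, rng)
    row = df.iloc[0]
    rec = TrialRecord(
        stimulus=int(row.stimulus),
        decision=int(row.response),
        rt=int(row.rt_steps),
        c_x=float(row.c_x),
        c_delta=float(row.c_delta),
        correct=bool(row.correct),
        censored=bool(row.censored),
    )
    if params.rating_thresholds is not None:
        rec.rating = int(rate_confidence(rec.c_x, params.rating_thresholds))
    return rec


def simulate_block(
    params: ModelParams,
    design: Sequence[tuple[int, int]],
    rng,
    shuffle: bool = False,
    condition: str | None = None,
) -> pd.DataFrame:
    """Simulate a block given a design of ``(stimulus, n_trials)`` entries.

    For stimulus 0 the drives in ``params`` are used directly; for stimulus
    1 they are mirrored, so ``params`` describes the stimulus-0
    presentation of a symmetric design.  Trials are concatenated in design
    order unless ``shuffle`` is set.
    """
    if len(design) == 0:
        raise ValueError("design must be non-empty")
    rng = _as_rng(rng)
    parts = []
    for stim, n_trials in design:
        p = params if stim == 0 else params.mirrored()
        parts.append(simulate_trials(p, stim, n_trials, rng, condition=condition))
    out = pd.concat(parts, ignore_index=True)
    if shuffle:
        out = out.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    return out


def simulate_condition(
    params_by_stimulus: Mapping[int, ModelParams],
    n_per_stim: int,
    rng,
    condition: str | None = None,
) -> pd.DataFrame:
    """Simulate equal numbers of both stimulus classes of one condition.

    ``params_by_stimulus`` maps stimulus index (0, 1) to the trial-type
    parameters used when that stimulus is presented; this covers
    asymmetric designs where the two classes are not mirror images.
    """
    rng = _as_rng(rng)
    parts = [
        simulate_trials(params_by_stimulus[stim], stim, n_per_stim, rng, condition=condition)
        for stim in sorted(params_by_stimulus)
    ]
    return pd.concat(parts, ignore_index=True)


def assign_ratings(
    trials: pd.DataFrame, thresholds, readout: str = "c_x"
) -> pd.DataFrame:
    """Add a ``rating`` column derived from the chosen confidence readout."""
    if readout not in ("c_x", "c_delta"):
        raise ValueError("readout must be 'c_x' or 'c_delta'")
    out = trials.copy()
    out["rating"] = np.asarray(rate_confidence(out[readout].to_numpy(), thresholds))
    return out
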