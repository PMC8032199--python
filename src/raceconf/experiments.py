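"""Experiment harnesses for the three study designs that dissociate
confidence from accuracy, run for either confidence readout.

All three harnesses follow the same fitting discipline: accumulation noise
sigma and decision bound T are fixed a priori; stimulus drive S is
calibrated by simulation so that d' matches its target in every condition;
the post-decision duration tau is calibrated once, to the meta-d' target of
a single representative condition, and then reused everywhere; and rating
thresholds are fitted by quantile matching on the confidence sample pooled
across all conditions of a run.  Everything downstream of those fits
(response-conditional meta-d', confidence differences, RT effects) is a
prediction, not a fitted quantity.

Designs
-------
crossover
    One stimulus class has fixed drive S_A, the other takes five levels
    S_B spanning below and above S_A (the middle level equal to S_A).
    The diagnostic is the pair of signs of the response-conditional
    meta-d' slopes against d'.
pe_ne
    Both stimulus alternatives receive drive on every trial: S_NE =
    alpha * S_PE with alpha larger in the High-PE condition.  A grid of
    alpha_high values is swept; at each point S_PE is recalibrated so d'
    is matched to the Low-PE mean, and performance-matched confidence,
    meta-d' and RT differences are read out.
noise
    Single-signal design in which the High-PE condition has a larger
    accumulation noise sigma, swept on a grid, with S recalibrated per
    sigma to match d'.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .calibration import (
    DEFAULT_S_GRID,
    DEFAULT_TAU_GRID,
    CalibrationError,
    GridSpec,
    calibrate_s_for_dprime,
    calibrate_tau_for_meta_d,
    fit_rating_thresholds,
)
from .dynamics import assign_ratings, simulate_condition
from .params import ModelParams
from .sdt import RatingCounts, dprime, fit_meta_d, fit_response_conditional_meta_d

__all__ = [
    "SimConfig",
    "CrossoverConfig",
    "ConditionSummary",
    "CrossoverResult",
    "PEGridResult",
    "summarize_condition",
    "eta_rt",
    "run_crossover_experiment",
    "run_pe_ne_experiment",
    "run_noise_experiment",
    "fitting_error_report",
    "MEASURES",
]

MEASURES = ("confidence_diff", "meta_d_diff", "eta_rt")


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation knobs for the experiment harnesses."""

    sigma: float = 0.1
    threshold: float = 1.0
    n_ratings: int = 4
    n_per_stim: int = 5_000
    n_calib: int = 10_000
    s_grid: GridSpec = DEFAULT_S_GRID
    tau_grid: GridSpec = DEFAULT_TAU_GRID
    max_steps: int = 10_000

    def base_params(self, sigma: float | None = None) -> ModelParams:
        return ModelParams(
            s_drives=(0.0, 0.0),
            sigma_acc=self.sigma if sigma is None else sigma,
            threshold=self.threshold,
            n_ratings=self.n_ratings,
            max_steps=self.max_steps,
        )


@dataclass(frozen=True)
class CrossoverConfig(SimConfig):
    """Design of the fixed-vs-varying stimulus-strength experiment."""

    d_mid: float = 1.5
    meta_d_mid: float = 1.0
    level_scales: tuple[float, ...] = (0.4, 0.7, 1.0, 1.3, 1.6)
    rating_dist: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)


@dataclass
class ConditionSummary:
    """Per-condition behavioral summary (the quantities the studies plot)."""

    label: str
    d_prime: float
    criterion: float
    meta_d_overall: float
    meta_d_by_response: tuple[float, float]  # ("S1" responses, "S2" responses)
    mean_confidence: float
    rating_dist: np.ndarray
    rt_median: float
    rt_mean: float
    rt_min: float
    n_trials: int
    low_reliability: tuple[bool, bool] = (False, False)

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "d_prime": self.d_prime,
            "criterion": self.criterion,
            "meta_d_overall": self.meta_d_overall,
            "meta_d_s1": self.meta_d_by_response[0],
            "meta_d_s2": self.meta_d_by_response[1],
            "mean_confidence": self.mean_confidence,
            "rt_median": self.rt_median,
            "rt_mean": self.rt_mean,
            "rt_min": self.rt_min,
            "n_trials": self.n_trials,
        }
        for k, p in enumerate(self.rating_dist):
            d[f"p_rating_{k + 1}"] = p
        return d


def summarize_condition(
    trials: pd.DataFrame,
    label: str = "",
    n_ratings: int = 4,
    response_conditional: bool = True,
) -> ConditionSummary:
    """Aggregate a rated trial table into a :class:`ConditionSummary`."""
    if "rating" not in trials:
        raise ValueError("trials must carry a rating column (assign_ratings first)")
    counts = RatingCounts.from_trials(trials, n_ratings)
    d, c = dprime(counts)
    overall = fit_meta_d(counts)
    if response_conditional:
        rc1 = fit_response_conditional_meta_d(counts, "S1")
        rc2 = fit_response_conditional_meta_d(counts, "S2")
        by_resp = (rc1.meta_d, rc2.meta_d)
        low_rel = (rc1.low_reliability, rc2.low_reliability)
    else:
        by_resp = (float("nan"), float("nan"))
        low_rel = (False, False)
    ratings = trials["rating"].to_numpy()
    dist = np.bincount(ratings, minlength=n_ratings + 1)[1:].astype(float)
    dist /= dist.sum()
    return ConditionSummary(
        label=label,
        d_prime=d,
        criterion=c,
        meta_d_overall=overall.meta_d,
        meta_d_by_response=by_resp,
        mean_confidence=float(ratings.mean()),
        rating_dist=dist,
        rt_median=float(trials["rt_steps"].median()),
        rt_mean=float(trials["rt_steps"].mean()),
        rt_min=float(trials["rt_steps"].min()),
        n_trials=len(trials),
        low_reliability=low_rel,
    )


def eta_rt(
    rt_high_med: float, rt_low_med: float, rt_low_easy: float, rt_low_difficult: float
) -> float:
    """Relative RT effect size.

    The change in RT due to the High-vs-Low PE manipulation at matched
    intermediate performance, scaled by the change in RT due to task
    difficulty within the Low-PE arm:

        (rt_high_med - rt_low_med) / (rt_low_easy - rt_low_difficult)

    The ratio is reported as computed, without re-signing (both numerator
    and denominator are typically negative, making the ratio positive when
    High PE speeds responses).
    """
    denom = rt_low_easy - rt_low_difficult
    if denom == 0:
        raise ZeroDivisionError("easy and difficult RTs are equal; eta_rt undefined")
    return (rt_high_med - rt_low_med) / denom


# ---------------------------------------------------------------------------
# seed plumbing: named, reusable substreams so the High and Low arms of a
# grid can be paired (identical seeds at every grid point)


def _seed_seq(rng) -> np.random.SeedSequence:
    if isinstance(rng, np.random.SeedSequence):
        return rng
    if isinstance(rng, np.random.Generator):
        return np.random.SeedSequence(int(rng.integers(2**31)))
    return np.random.SeedSequence(rng if rng is not None else 0)


# ---------------------------------------------------------------------------
# crossover harness


@dataclass
class CrossoverResult:
    readout: str
    s_a: float
    tau: int
    thresholds: np.ndarray
    summaries: list[ConditionSummary]
    slope_s1: float
    slope_s2: float

    @property
    def crossover_signs(self) -> tuple[str, str]:
        """Signs of the response-conditional meta-d' trends vs d'."""
        return (
            "-" if self.slope_s1 < 0 else "+",
            "-" if self.slope_s2 < 0 else "+",
        )

    @property
    def has_crossover(self) -> bool:
        """X-shaped dissociation: S1-response meta-d' falls while
        S2-response meta-d' rises as d' increases."""
        return self.crossover_signs == ("-", "+")


def run_crossover_experiment(
    readout: str, config: CrossoverConfig, rng
) -> CrossoverResult:
    """Five-level varying-strength design with response-conditional meta-d'.

    Stimulus "A" trials always have drives ``(S_A, 0)``; stimulus "B"
    trials have ``(0, S_B_i)`` with ``S_B_i = scale_i * S_A`` over the five
    level scales (middle scale 1, i.e. S_B = S_A).  tau is calibrated to
    the overall meta-d' target at the middle level for the requested
    readout; thresholds are quantile-fitted on the confidence pooled over
    all five levels.
    """
    ss = _seed_seq(rng)
    ss_cal_s, ss_cal_tau, ss_sim = ss.spawn(3)
    base = config.base_params()

    s_a, _ = calibrate_s_for_dprime(
        config.d_mid,
        base,
        np.random.default_rng(ss_cal_s),
        grid_spec=config.s_grid,
        n_trials_per_point=config.n_calib,
        drive_ratio=0.0,
    )
    mid = base.replace(s_drives=(s_a, 0.0))
    tau, _ = calibrate_tau_for_meta_d(
        config.meta_d_mid,
        mid,
        np.random.default_rng(ss_cal_tau),
        readout=readout,
        rating_dist=config.rating_dist,
        grid_spec=config.tau_grid,
        n_trials_per_point=config.n_calib,
    )

    level_seeds = ss_sim.spawn(len(config.level_scales))
    sims = []
    for scale, child in zip(config.level_scales, level_seeds):
        s_b = scale * s_a
        params = {
            0: base.replace(s_drives=(s_a, 0.0), tau=tau),
            1: base.replace(s_drives=(0.0, s_b), tau=tau),
        }
        sims.append(
            simulate_condition(
                params, config.n_per_stim, np.random.default_rng(child), condition=f"SB{scale:g}"
            )
        )

    pooled_c = np.concatenate([df[readout].to_numpy() for df in sims])
    thresholds = fit_rating_thresholds(pooled_c, config.rating_dist)
    summaries = [
        summarize_condition(
            assign_ratings(df, thresholds, readout),
            label=str(df["condition"].iloc[0]),
            n_ratings=config.n_ratings,
        )
        for df in sims
    ]

    d_vals = [s.d_prime for s in summaries]
    slope_s1 = spearmanr(d_vals, [s.meta_d_by_response[0] for s in summaries]).statistic
    slope_s2 = spearmanr(d_vals, [s.meta_d_by_response[1] for s in summaries]).statistic
    return CrossoverResult(
        readout=readout,
        s_a=s_a,
        tau=tau,
        thresholds=thresholds,
        summaries=summaries,
        slope_s1=float(slope_s1),
        slope_s2=float(slope_s2),
    )


# ---------------------------------------------------------------------------
# grid harnesses (PE/NE balance and noise designs)


@dataclass
class PEGridResult:
    """Sweep of the High-PE arm's control parameter at matched performance.

    At every grid point the High arm's drive is recalibrated so its d'
    matches the Low-PE mean d'; ``confidence_diff``, ``meta_d_diff`` and
    ``eta_rt`` are then the performance-matched High-minus-Low readouts.
    """

    readout: str
    control_name: str  # "alpha_high" or "sigma_high"
    control_low: float
    grid: np.ndarray
    confidence_diff: np.ndarray
    meta_d_diff: np.ndarray
    eta_rt: np.ndarray
    d_high: np.ndarray
    meta_d_high: np.ndarray
    d_low_med: float
    meta_d_low_med: float
    tau: int
    best_index: int
    at_boundary: bool
    low_summaries: dict[str, ConditionSummary]
    high_summaries: list[ConditionSummary]
    targets: dict[str, float]

    @property
    def best_control(self) -> float:
        return float(self.grid[self.best_index])

    def at_best(self) -> dict[str, float]:
        i = self.best_index
        return {
            "confidence_diff": float(self.confidence_diff[i]),
            "meta_d_diff": float(self.meta_d_diff[i]),
            "eta_rt": float(self.eta_rt[i]),
        }

    def matched_dprime_gap(self) -> float:
        """Largest |d'_high - d'_low,med| across the grid (matching check)."""
        return float(np.max(np.abs(self.d_high - self.d_low_med)))


def _run_grid_experiment(
    readout: str,
    control_name: str,
    control_low: float,
    control_grid: Sequence[float],
    targets: Mapping[str, float],
    config: SimConfig,
    rng,
    *,
    is_noise: bool,
) -> PEGridResult:
    if readout not in ("c_x", "c_delta"):
        raise ValueError("readout must be 'c_x' or 'c_delta'")
    control_grid = np.asarray(control_grid, dtype=float)
    if is_noise:
        if np.any(control_grid <= control_low):
            raise ValueError("sigma_high grid must exceed sigma_low")
    else:
        if np.any(control_grid <= control_low) or np.any(control_grid >= 1):
            raise ValueError("alpha_high grid must lie in (alpha_low, 1)")

    d_easy = float(targets["d_easy"])
    d_difficult = float(targets["d_difficult"])
    d_med = 0.5 * (d_easy + d_difficult)
    meta_d_target = float(targets["meta_d"])
    rating_dist = np.asarray(
        targets.get("rating_dist", np.full(config.n_ratings, 1.0 / config.n_ratings)),
        dtype=float,
    )
    conf_target = targets.get("confidence_diff")

    ss = _seed_seq(rng)
    ss_cal_s, ss_cal_tau, ss_low, ss_high, ss_cal_high = ss.spawn(5)
    low_seeds = ss_low.spawn(3)
    base_low = config.base_params()
    ratio_low = 0.0 if is_noise else control_low

    # Low-PE arm: calibrate S for easy / difficult / med d' targets
    s_low = {}
    for (name, target), child in zip(
        (("easy", d_easy), ("difficult", d_difficult), ("med", d_med)),
        ss_cal_s.spawn(3),
    ):
        s_low[name], _ = calibrate_s_for_dprime(
            target,
            base_low,
            np.random.default_rng(child),
            grid_spec=config.s_grid,
            n_trials_per_point=config.n_calib,
            drive_ratio=ratio_low,
        )

    # tau: calibrated once at the Low-PE mean-d' point, then reused
    med_params = base_low.replace(s_drives=(s_low["med"], ratio_low * s_low["med"]))
    tau, _ = calibrate_tau_for_meta_d(
        meta_d_target,
        med_params,
        np.random.default_rng(ss_cal_tau),
        readout=readout,
        rating_dist=rating_dist,
        grid_spec=config.tau_grid,
        n_trials_per_point=config.n_calib,
    )

    def low_condition(name: str, child) -> pd.DataFrame:
        s = s_low[name]
        p0 = base_low.replace(s_drives=(s, ratio_low * s), tau=tau)
        return simulate_condition(
            {0: p0, 1: p0.mirrored()},
            config.n_per_stim,
            np.random.default_rng(child),
            condition=f"low_{name}",
        )

    low_sims = {
        name: low_condition(name, child)
        for name, child in zip(("easy", "difficult", "med"), low_seeds)
    }

    # High-PE arm: one simulation per grid point, re-calibrated for matched
    # d', sharing one seed across grid points (paired with the Low arm)
    n_grid = len(control_grid)
    conf_diff = np.empty(n_grid)
    meta_diff = np.empty(n_grid)
    etas = np.empty(n_grid)
    d_high_arr = np.empty(n_grid)
    meta_high_arr = np.empty(n_grid)
    low_summ_per_point: list[dict[str, ConditionSummary]] = []
    high_summaries: list[ConditionSummary] = []

    low_c = {name: df[readout].to_numpy() for name, df in low_sims.items()}
    meta_low_med_vals = np.empty(n_grid)

    for k, ctrl in enumerate(control_grid):
        if is_noise:
            # the sigma manipulation models stimulus (sensory-evidence)
            # variability, so it applies to the accumulation noise only;
            # internal differencing noise stays at its baseline value
            base_high = config.base_params(sigma=float(ctrl)).replace(sigma_diff=config.sigma)
            ratio_high = 0.0
        else:
            base_high = base_low
            ratio_high = float(ctrl)
        s_high, _ = calibrate_s_for_dprime(
            d_med,
            base_high,
            np.random.default_rng(ss_cal_high),
            grid_spec=config.s_grid,
            n_trials_per_point=config.n_calib,
            drive_ratio=ratio_high,
        )
        p_high = base_high.replace(s_drives=(s_high, ratio_high * s_high), tau=tau)
        high_df = simulate_condition(
            {0: p_high, 1: p_high.mirrored()},
            config.n_per_stim,
            np.random.default_rng(ss_high),
            condition=f"high_{control_name}={ctrl:g}",
        )

        # rating thresholds pooled across all conditions of this grid point
        pooled = np.concatenate(list(low_c.values()) + [high_df[readout].to_numpy()])
        thresholds = fit_rating_thresholds(pooled, rating_dist)
        low_summ = {
            name: summarize_condition(
                assign_ratings(df, thresholds, readout),
                label=f"low_{name}",
                n_ratings=config.n_ratings,
                response_conditional=False,
            )
            for name, df in low_sims.items()
        }
        high_summ = summarize_condition(
            assign_ratings(high_df, thresholds, readout),
            label=str(high_df["condition"].iloc[0]),
            n_ratings=config.n_ratings,
            response_conditional=False,
        )

        conf_diff[k] = high_summ.mean_confidence - low_summ["med"].mean_confidence
        meta_diff[k] = high_summ.meta_d_overall - low_summ["med"].meta_d_overall
        etas[k] = eta_rt(
            high_summ.rt_mean,
            low_summ["med"].rt_mean,
            low_summ["easy"].rt_mean,
            low_summ["difficult"].rt_mean,
        )
        d_high_arr[k] = high_summ.d_prime
        meta_high_arr[k] = high_summ.meta_d_overall
        meta_low_med_vals[k] = low_summ["med"].meta_d_overall
        low_summ_per_point.append(low_summ)
        high_summaries.append(high_summ)

    if conf_target is not None:
        best = int(np.argmin(np.abs(conf_diff - float(conf_target))))
        # the target confidence effect may simply not be attainable on the
        # grid (the boundary outcome the balance-of-evidence readout shows)
        at_boundary = bool(np.max(conf_diff) < float(conf_target))
    else:
        best = int(np.argmax(conf_diff))
        at_boundary = True

    return PEGridResult(
        readout=readout,
        control_name=control_name,
        control_low=control_low,
        grid=control_grid,
        confidence_diff=conf_diff,
        meta_d_diff=meta_diff,
        eta_rt=etas,
        d_high=d_high_arr,
        meta_d_high=meta_high_arr,
        d_low_med=low_summ_per_point[0]["med"].d_prime,
        meta_d_low_med=float(np.mean(meta_low_med_vals)),
        tau=tau,
        best_index=best,
        at_boundary=at_boundary,
        low_summaries=low_summ_per_point[best],
        high_summaries=high_summaries,
        targets={k: float(v) for k, v in targets.items() if np.isscalar(v)},
    )


def run_pe_ne_experiment(
    readout: str,
    alpha_low: float,
    alpha_high_grid: Sequence[float],
    targets: Mapping[str, float],
    config: SimConfig | None = None,
    rng=0,
) -> PEGridResult:
    """Superimposed positive/negative evidence design (alpha sweep).

    ``targets`` must provide ``d_easy``, ``d_difficult`` and ``meta_d``
    (the Low-PE calibration targets) and may provide ``confidence_diff``
    (the empirical performance-matched confidence effect used to pick the
    best-fitting ``alpha_high``), ``rating_dist``, ``meta_d_diff`` and
    ``eta_rt``.
    """
    if not 0 <= alpha_low < 1:
        raise ValueError("alpha_low must lie in [0, 1)")
    return _run_grid_experiment(
        readout,
        "alpha_high",
        float(alpha_low),
        alpha_high_grid,
        targets,
        config or SimConfig(),
        rng,
        is_noise=False,
    )


def run_noise_experiment(
    readout: str,
    sigma_low: float,
    sigma_high_grid: Sequence[float],
    targets: Mapping[str, float],
    config: SimConfig | None = None,
    rng=0,
) -> PEGridResult:
    """Signal-plus-noise design (sigma sweep), S recalibrated per sigma."""
    config = config or SimConfig()
    if sigma_low != config.sigma:
        config = replace(config, sigma=float(sigma_low))
    return _run_grid_experiment(
        readout,
        "sigma_high",
        float(sigma_low),
        sigma_high_grid,
        targets,
        config,
        rng,
        is_noise=True,
    )


def fitting_error_report(
    grid_results: PEGridResult | Mapping[str, PEGridResult],
    empirical_targets: Mapping[str, float],
) -> pd.DataFrame:
    """Signed prediction errors at each model's best-fitting grid point.

    ``error = predicted - target`` per measure (confidence_diff,
    meta_d_diff, eta_rt).  Measures with no supplied target are reported
    with a NaN error and ``target_missing=True``, never as zero error.
    Pass a mapping ``{model_name: PEGridResult}`` for a side-by-side
    multi-model table.
    """
    if isinstance(grid_results, PEGridResult):
        grid_results = {grid_results.readout: grid_results}
    rows = []
    for model, result in grid_results.items():
        predicted = result.at_best()
        for measure in MEASURES:
            target = empirical_targets.get(measure)
            rows.append(
                {
                    "model": model,
                    "measure": measure,
                    "predicted": predicted[measure],
                    "target": float(target) if target is not None else float("nan"),
                    "error": predicted[measure] - float(target)
                    if target is not None
                    else float("nan"),
                    "target_missing": target is None,
                    "best_" + result.control_name: result.best_control,
                    "at_boundary": result.at_boundary,
                }
            )
    return pd.DataFrame(rows)
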