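"""Synthetic "empirical" target datasets for the fitting pipeline.

Real studies supply condition-level summaries (d', meta-d', mean
confidence, rating distributions, RT) that the experiment harnesses fit
to.  This module generates stand-in datasets with the same statistical
structure by simulating the race model itself with known ground-truth
parameters, so the whole pipeline — calibration, threshold fitting, grid
sweeps, model comparison — can be exercised and parameter recovery can be
checked without any external download.

Fixtures are generated from the absolute-evidence (``c_x``) readout by
default, since that readout is the one found to describe empirical data; a
``c_delta``-generated mode exists for specificity testing (the model
comparison should then prefer the balance-of-evidence readout).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import (
    DEFAULT_S_GRID,
    GridSpec,
    calibrate_s_for_dprime,
    fit_rating_thresholds,
)
from .dynamics import assign_ratings, simulate_condition
from .experiments import ConditionSummary, eta_rt, summarize_condition
from .params import ModelParams

__all__ = ["StudyFixture", "make_fixture", "perturb_fixture", "DEFAULT_TRUTH"]

DESIGNS = ("crossover", "pe_ne", "noise")

#: default ground-truth parameters per design (the study conditions the
#: fixtures emulate: Low-PE mean d' of ~1.71 for the PE/NE design and
#: ~0.99 for the noise design, 4-point rating scales, and tau = 60
#: post-decision steps, which puts metacognitive efficiency meta-d'/d'
#: in the ~0.7-0.8 range typical of empirical datasets)
DEFAULT_TRUTH: dict[str, dict] = {
    "crossover": {
        "d_mid": 1.5,
        "level_scales": (0.4, 0.7, 1.0, 1.3, 1.6),
        "tau": 60,
        "sigma": 0.1,
        "rating_dist": (0.2, 0.3, 0.3, 0.2),
    },
    "pe_ne": {
        "alpha_low": 0.1,
        "alpha_high": 0.3,
        "d_easy": 2.21,
        "d_difficult": 1.21,
        "tau": 60,
        "sigma": 0.1,
        "rating_dist": (0.2, 0.3, 0.3, 0.2),
    },
    "noise": {
        "sigma_low": 0.1,
        "sigma_high": 0.13,
        "d_easy": 1.32,
        "d_difficult": 0.66,
        "tau": 60,
        "rating_dist": (0.2, 0.3, 0.3, 0.2),
    },
}


@dataclass
class StudyFixture:
    """A synthetic study dataset with known generating parameters.

    ``targets`` holds one row per condition (the summaries an experiment
    harness fits to); ``derived`` holds the cross-condition effect sizes
    (performance-matched confidence / meta-d' differences, relative RT
    effect); ``truth`` records the generating parameters for recovery
    tests; ``trials`` is the trial-level table the targets were computed
    from.
    """

    design_name: str
    targets: pd.DataFrame
    derived: dict[str, float]
    truth: dict
    seed: int
    trials: pd.DataFrame | None = None

    def experiment_targets(self) -> dict:
        """Target mapping consumed by the grid experiment harnesses."""
        t = self.targets.set_index("label")
        out = dict(self.derived)
        if self.design_name in ("pe_ne", "noise"):
            out["d_easy"] = float(t.loc["low_easy", "d_prime"])
            out["d_difficult"] = float(t.loc["low_difficult", "d_prime"])
            out["meta_d"] = 0.5 * float(
                t.loc["low_easy", "meta_d_overall"] + t.loc["low_difficult", "meta_d_overall"]
            )
        out["rating_dist"] = tuple(self.truth["rating_dist"])
        return out

    def save(self, directory) -> None:
        """Serialize as targets.csv + trials.csv + truth.json."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.targets.to_csv(directory / "targets.csv", index=False)
        if self.trials is not None:
            self.trials.to_csv(directory / "trials.csv", index=False)
        payload = {
            "design_name": self.design_name,
            "seed": self.seed,
            "truth": _jsonable(self.truth),
            "derived": self.derived,
        }
        (directory / "truth.json").write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, directory) -> "StudyFixture":
        directory = Path(directory)
        payload = json.loads((directory / "truth.json").read_text())
        trials_path = directory / "trials.csv"
        return cls(
            design_name=payload["design_name"],
            targets=pd.read_csv(directory / "targets.csv"),
            derived=payload["derived"],
            truth=payload["truth"],
            seed=payload["seed"],
            trials=pd.read_csv(trials_path) if trials_path.exists() else None,
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _summary_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


def make_fixture(
    design_name: str,
    ground_truth_params: Mapping | None = None,
    n_trials: int = 10_000,
    rng=0,
    readout: str = "c_x",
    keep_trials: bool = True,
    n_calib: int | None = None,
    s_grid: GridSpec = DEFAULT_S_GRID,
) -> StudyFixture:
    """Generate a synthetic study dataset from known model parameters.

    ``n_trials`` is the per-condition trial count (split evenly between
    the two stimulus classes).  ``ground_truth_params`` overrides entries
    of :data:`DEFAULT_TRUTH` for the named design.  Stimulus drives are
    calibrated by simulation so the generated conditions hit the
    ground-truth d' targets; everything else (meta-d', confidence, RT) is
    emergent and recorded as a target.
    """
    if design_name not in DESIGNS:
        raise ValueError(f"design_name must be one of {DESIGNS}")
    if n_trials <= 0:
        raise ValueError("n_trials must be positive (empty fixtures are refused)")
    truth = dict(DEFAULT_TRUTH[design_name])
    if ground_truth_params:
        unknown = set(ground_truth_params) - set(truth)
        if unknown:
            raise ValueError(f"unknown ground-truth parameters for {design_name}: {unknown}")
        truth.update(ground_truth_params)
    if readout not in ("c_x", "c_delta"):
        raise ValueError("readout must be 'c_x' or 'c_delta'")

    seed = int(np.random.SeedSequence(rng).entropy) if not isinstance(rng, int) else rng
    ss = np.random.SeedSequence(seed)
    ss_cal, ss_sim = ss.spawn(2)
    n_per_stim = max(n_trials // 2, 1)
    n_calib = n_calib or n_trials
    tau = int(truth["tau"])
    rating_dist = np.asarray(truth["rating_dist"], dtype=float)

    if design_name == "crossover":
        base = ModelParams(sigma_acc=truth["sigma"])
        s_a, _ = calibrate_s_for_dprime(
            truth["d_mid"],
            base,
            np.random.default_rng(ss_cal),
            grid_spec=s_grid,
            n_trials_per_point=n_calib,
            drive_ratio=0.0,
        )
        truth["s_a"] = s_a
        sims = []
        for scale, child in zip(truth["level_scales"], ss_sim.spawn(len(truth["level_scales"]))):
            params = {
                0: base.replace(s_drives=(s_a, 0.0), tau=tau),
                1: base.replace(s_drives=(0.0, scale * s_a), tau=tau),
            }
            sims.append(
                simulate_condition(
                    params, n_per_stim, np.random.default_rng(child), condition=f"SB{scale:g}"
                )
            )
        response_conditional = True
        derived_fn = None

    else:
        if design_name == "pe_ne":
            sigma_low = truth["sigma"]
            arms = {
                "low_easy": (truth["d_easy"], truth["alpha_low"], sigma_low),
                "low_difficult": (truth["d_difficult"], truth["alpha_low"], sigma_low),
                "low_med": (
                    0.5 * (truth["d_easy"] + truth["d_difficult"]),
                    truth["alpha_low"],
                    sigma_low,
                ),
                "high_med": (
                    0.5 * (truth["d_easy"] + truth["d_difficult"]),
                    truth["alpha_high"],
                    sigma_low,
                ),
            }
        else:  # noise design: sigma manipulation hits sensory noise only,
            # differencing noise stays at the Low-PE baseline in both arms
            arms = {
                "low_easy": (truth["d_easy"], 0.0, truth["sigma_low"]),
                "low_difficult": (truth["d_difficult"], 0.0, truth["sigma_low"]),
                "low_med": (
                    0.5 * (truth["d_easy"] + truth["d_difficult"]),
                    0.0,
                    truth["sigma_low"],
                ),
                "high_med": (
                    0.5 * (truth["d_easy"] + truth["d_difficult"]),
                    0.0,
                    truth["sigma_high"],
                ),
            }
        sims = []
        fitted_s = {}
        sigma_base = truth.get("sigma", truth.get("sigma_low"))
        for (label, (d_target, ratio, sigma)), cal_child, sim_child in zip(
            arms.items(), ss_cal.spawn(len(arms)), ss_sim.spawn(len(arms))
        ):
            base = ModelParams(sigma_acc=sigma, sigma_diff=float(sigma_base))
            s_fit, _ = calibrate_s_for_dprime(
                d_target,
                base,
                np.random.default_rng(cal_child),
                grid_spec=s_grid,
                n_trials_per_point=n_calib,
                drive_ratio=ratio,
            )
            fitted_s[label] = s_fit
            p0 = base.replace(s_drives=(s_fit, ratio * s_fit), tau=tau)
            sims.append(
                simulate_condition(
                    {0: p0, 1: p0.mirrored()},
                    n_per_stim,
                    np.random.default_rng(sim_child),
                    condition=label,
                )
            )
        truth["fitted_s"] = fitted_s
        response_conditional = False

    pooled_c = np.concatenate([df[readout].to_numpy() for df in sims])
    thresholds = fit_rating_thresholds(pooled_c, rating_dist)
    truth["readout"] = readout
    truth["rating_thresholds"] = thresholds.tolist()

    rated = [assign_ratings(df, thresholds, readout) for df in sims]
    summaries = [
        summarize_condition(
            df,
            label=str(df["condition"].iloc[0]),
            response_conditional=response_conditional,
        )
        for df in rated
    ]
    targets = _summary_frame(summaries)

    derived: dict[str, float] = {}
    if design_name in ("pe_ne", "noise"):
        by = {s.label: s for s in summaries}
        derived["confidence_diff"] = (
            by["high_med"].mean_confidence - by["low_med"].mean_confidence
        )
        derived["meta_d_diff"] = by["high_med"].meta_d_overall - by["low_med"].meta_d_overall
        derived["eta_rt"] = eta_rt(
            by["high_med"].rt_mean,
            by["low_med"].rt_mean,
            by["low_easy"].rt_mean,
            by["low_difficult"].rt_mean,
        )

    trials = pd.concat(rated, ignore_index=True) if keep_trials else None
    return StudyFixture(
        design_name=design_name,
        targets=targets,
        derived=derived,
        truth=truth,
        seed=seed,
        trials=trials,
    )


def perturb_fixture(
    fixture: StudyFixture, noise_spec: Mapping[str, float], rng=0
) -> StudyFixture:
    """Jitter fixture targets to emulate finite-sample empirical data.

    ``noise_spec`` maps target column names (e.g. ``d_prime``,
    ``meta_d_overall``, ``mean_confidence``, ``rt_mean``) or derived keys
    (``confidence_diff``, ``meta_d_diff``, ``eta_rt``) to the SD of
    additive Gaussian jitter.  Rating-distribution columns jittered via
    the special key ``rating_dist`` are renormalized to sum to 1.  Zero
    noise returns an identical fixture.  The trial table is dropped from
    the perturbed fixture since it no longer matches the targets.
    """
    if any(v < 0 for v in noise_spec.values()):
        raise ValueError("noise magnitudes must be non-negative")
    gen = np.random.default_rng(rng)
    targets = fixture.targets.copy()
    derived = dict(fixture.derived)
    rating_cols = [c for c in targets.columns if c.startswith("p_rating_")]
    for key, sd in noise_spec.items():
        if sd == 0:
            continue
        if key == "rating_dist":
            vals = targets[rating_cols].to_numpy(float)
            vals = np.clip(vals + gen.normal(0.0, sd, size=vals.shape), 1e-9, None)
            targets[rating_cols] = vals / vals.sum(axis=1, keepdims=True)
        elif key in targets.columns:
            targets[key] = targets[key] + gen.normal(0.0, sd, size=len(targets))
        elif key in derived:
            derived[key] = float(derived[key] + gen.normal(0.0, sd))
        else:
            raise KeyError(f"noise_spec key {key!r} matches no target")
    return StudyFixture(
        design_name=fixture.design_name,
        targets=targets,
        derived=derived,
        truth=dict(fixture.truth),
        seed=fixture.seed,
        trials=None if noise_spec and any(v > 0 for v in noise_spec.values()) else fixture.trials,
    )
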