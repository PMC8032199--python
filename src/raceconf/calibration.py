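"""Simulation-based calibration of the race model.

Closed forms for d' and meta-d' of the dynamic model are not available, so
control parameters are set by simulation: simulate the outcome (d' or
meta-d') at 10 evenly spaced values of the control parameter (stimulus
drive S, or post-decision duration tau), fit a least-squares quadratic to
the outcome-vs-control curve, and solve the quadratic for the control value
that yields the target outcome.  Confidence-rating thresholds are set by
quantile matching: threshold U_r is the empirical quantile of the pooled
raw-confidence sample at the cumulative probability of the target rating
distribution, so that the realized rating distribution reproduces the
target by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .dynamics import simulate_condition
from .params import ModelParams
from .sdt import RatingCounts, dprime, fit_meta_d

__all__ = [
    "CalibrationError",
    "CalibrationCurve",
    "GridSpec",
    "calibrate_s_for_dprime",
    "calibrate_tau_for_meta_d",
    "fit_rating_thresholds",
]


class CalibrationError(RuntimeError):
    """Raised when a calibration target cannot be reached on the grid."""


@dataclass(frozen=True)
class GridSpec:
    """An evenly spaced sweep of a scalar control parameter."""

    lo: float
    hi: float
    n_points: int = 10

    def values(self) -> np.ndarray:
        if self.hi <= self.lo:
            raise ValueError("grid upper bound must exceed lower bound")
        if self.n_points < 3:
            raise ValueError("grid needs at least 3 points for a quadratic fit")
        return np.linspace(self.lo, self.hi, self.n_points)


#: default stimulus-drive sweep: spans d' of roughly 0-3.5 at sigma=0.1, T=1
DEFAULT_S_GRID = GridSpec(0.0, 0.03, 10)
#: default post-decision-duration sweep (integer steps)
DEFAULT_TAU_GRID = GridSpec(0, 90, 10)


@dataclass
class CalibrationCurve:
    """A simulated outcome-vs-control curve with its quadratic fit."""

    control_name: str
    grid: np.ndarray
    outcomes: np.ndarray
    poly_coeffs: np.ndarray  # highest degree first, as np.polyfit
    n_trials_per_point: int
    fitted_control: float | None = None
    target: float | None = None

    @property
    def residual_rms(self) -> float:
        pred = np.polyval(self.poly_coeffs, self.grid)
        return float(np.sqrt(np.mean((self.outcomes - pred) ** 2)))

    @property
    def r_squared(self) -> float:
        pred = np.polyval(self.poly_coeffs, self.grid)
        ss_res = float(np.sum((self.outcomes - pred) ** 2))
        ss_tot = float(np.sum((self.outcomes - np.mean(self.outcomes)) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    def predict(self, control) -> np.ndarray:
        return np.polyval(self.poly_coeffs, control)

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("grid", "outcomes", "poly_coeffs"):
            d[k] = np.asarray(d[k]).tolist()
        d["residual_rms"] = self.residual_rms
        d["r_squared"] = self.r_squared
        return json.dumps(d, indent=2)


def _invert_quadratic(
    coeffs: np.ndarray, target: float, lo: float, hi: float, margin: float = 0.0
) -> float:
    """Solve poly(x) = target for the root inside [lo, hi].

    Roots within ``margin`` (half a grid step) outside the span are
    accepted and clipped to the span — fit noise can push the root for a
    boundary target slightly past the grid edge.  If both roots fall
    inside the span, the one on the increasing branch of the parabola is
    taken (the outcome curves are monotone nondecreasing in the control
    parameter).
    """
    a, b, c = coeffs
    roots = np.roots([a, b, c - target])
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots >= lo - margin) & (roots <= hi + margin)]
    if inside.size == 0:
        raise CalibrationError(
            f"target {target} has no quadratic root inside the grid [{lo}, {hi}]"
        )
    if inside.size > 1:
        slopes = 2 * a * inside + b
        increasing = inside[slopes > 0]
        inside = increasing if increasing.size else inside
    return float(np.clip(inside[0], lo, hi))


def _check_target_range(target: float, outcomes: np.ndarray, what: str) -> None:
    margin = 0.05 * (outcomes.max() - outcomes.min())
    if not (outcomes.min() - margin <= target <= outcomes.max() + margin):
        raise CalibrationError(
            f"target {what}={target:.4g} outside the simulated range "
            f"[{outcomes.min():.4g}, {outcomes.max():.4g}]"
        )


def calibrate_s_for_dprime(
    target_dprime: float,
    params_template: ModelParams,
    rng,
    grid_spec: GridSpec = DEFAULT_S_GRID,
    n_trials_per_point: int = 10_000,
    drive_ratio: float | None = None,
    auto_scale: bool = True,
) -> tuple[float, CalibrationCurve]:
    """Find the stimulus drive S that yields the target d'.

    ``params_template`` fixes everything except the drives.  The drive
    vector at control value S is ``(S, ratio * S)`` for stimulus 0 and its
    mirror for stimulus 1, where ``ratio`` is ``drive_ratio`` if given,
    otherwise the ratio ``s_drives[1] / s_drives[0]`` of the template
    (0 if the template's first drive is 0).  This covers both the
    single-signal design (ratio 0) and the superimposed positive/negative
    evidence design (ratio alpha).

    With ``auto_scale`` (default) the grid bounds are interpreted at the
    reference condition (sigma = 0.1, ratio 0) and rescaled by
    ``sigma / (0.1 * (1 - ratio))`` so the sweep spans a comparable d'
    range in every condition.

    Returns the fitted S and the :class:`CalibrationCurve`.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if drive_ratio is None:
        s0, s1 = params_template.s_drives
        drive_ratio = (s1 / s0) if s0 > 0 else 0.0
    if not 0 <= drive_ratio < 1:
        raise ValueError("drive ratio must lie in [0, 1)")

    grid = grid_spec.values()
    if auto_scale:
        # the grid bounds are stated for the reference condition (sigma = 0.1,
        # no opposing drive); sensitivity scales roughly with the effective
        # drive difference (1 - ratio) * S / sigma, so rescale the sweep to
        # keep the spanned d' range comparable across conditions
        grid = grid * (params_template.sigma_acc / 0.1) / (1.0 - drive_ratio)
    outcomes = np.empty_like(grid)
    n_per_stim = max(n_trials_per_point // 2, 1)
    for k, s in enumerate(grid):
        p0 = params_template.replace(s_drives=(s, drive_ratio * s))
        trials = simulate_condition({0: p0, 1: p0.mirrored()}, n_per_stim, rng)
        counts = _response_counts(trials, params_template.n_ratings)
        outcomes[k], _ = dprime(counts)

    coeffs = np.polyfit(grid, outcomes, 2)
    curve = CalibrationCurve("S", grid, outcomes, coeffs, n_trials_per_point, target=target_dprime)
    _check_target_range(target_dprime, outcomes, "d'")
    fitted = _invert_quadratic(
        coeffs, target_dprime, grid[0], grid[-1], margin=0.5 * (grid[1] - grid[0])
    )
    curve.fitted_control = fitted
    return fitted, curve


def calibrate_tau_for_meta_d(
    target_meta_d: float,
    params_template: ModelParams,
    rng,
    readout: str = "c_x",
    rating_dist: Sequence[float] | None = None,
    grid_spec: GridSpec = DEFAULT_TAU_GRID,
    n_trials_per_point: int = 10_000,
) -> tuple[int, CalibrationCurve]:
    """Find the post-decision duration tau that yields the target meta-d'.

    At each integer tau on the grid, a condition is simulated from
    ``params_template`` (drives as given, mirrored for stimulus 1), rating
    thresholds are fitted by the quantile procedure to ``rating_dist``
    (uniform by default) on that simulation's own pooled confidence
    sample, and overall meta-d' is computed from the resulting rating
    table.  A quadratic fit to meta-d' vs tau is then inverted and the
    solution rounded to the nearest integer step.
    """
    from .dynamics import assign_ratings  # local import to avoid cycle at module load

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if readout not in ("c_x", "c_delta"):
        raise ValueError("readout must be 'c_x' or 'c_delta'")
    n_r = params_template.n_ratings
    if rating_dist is None:
        rating_dist = np.full(n_r, 1.0 / n_r)

    grid = np.round(grid_spec.values()).astype(int)
    outcomes = np.empty(len(grid))
    n_per_stim = max(n_trials_per_point // 2, 1)
    for k, tau in enumerate(grid):
        p0 = params_template.replace(tau=int(tau))
        trials = simulate_condition({0: p0, 1: p0.mirrored()}, n_per_stim, rng)
        thresholds = fit_rating_thresholds(trials[readout].to_numpy(), rating_dist)
        rated = assign_ratings(trials, thresholds, readout)
        outcomes[k] = fit_meta_d(RatingCounts.from_trials(rated, n_r)).meta_d

    coeffs = np.polyfit(grid.astype(float), outcomes, 2)
    curve = CalibrationCurve(
        "tau", grid.astype(float), outcomes, coeffs, n_trials_per_point, target=target_meta_d
    )
    _check_target_range(target_meta_d, outcomes, "meta-d'")
    fitted = _invert_quadratic(
        coeffs, target_meta_d, grid[0], grid[-1], margin=0.5 * (grid[1] - grid[0])
    )
    fitted_tau = int(round(fitted))
    curve.fitted_control = float(fitted_tau)
    return fitted_tau, curve


def fit_rating_thresholds(
    raw_confidences: np.ndarray, target_dist: Sequence[float]
) -> np.ndarray:
    """Quantile-matched confidence thresholds.

    ``U_r`` is the type-7 (linear interpolation) empirical quantile of the
    pooled raw-confidence sample at cumulative probability
    ``sum(target_dist[:r])``, so thresholding the same sample reproduces
    the target rating distribution up to 1/n per category.  Degenerate
    samples that would produce non-ascending thresholds are deduplicated
    with an infinitesimal jitter (with a warning).
    """
    c = np.asarray(raw_confidences, dtype=float)
    if c.size == 0:
        raise ValueError("confidence sample is empty")
    p = np.asarray(target_dist, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("target_dist must be a probability vector summing to 1")
    cum = np.cumsum(p)[:-1]
    thresholds = np.quantile(c, cum)  # numpy default = linear = type 7
    if np.any(np.diff(thresholds) <= 0):
        warnings.warn(
            "degenerate confidence mass: rating thresholds deduplicated with jitter",
            RuntimeWarning,
            stacklevel=2,
        )
        scale = max(abs(thresholds[-1]), 1.0)
        for i in range(1, len(thresholds)):
            if thresholds[i] <= thresholds[i - 1]:
                thresholds[i] = thresholds[i - 1] + 1e-12 * scale
    return thresholds


def _response_counts(trials, n_ratings: int) -> RatingCounts:
    """RatingCounts with all mass on rating 1 (d'-only tables)."""
    arr = np.zeros((2, 2, n_ratings))
    grouped = trials.groupby(["stimulus", "response"]).size()
    for (s, r), n in grouped.items():
        arr[int(s), int(r), 0] = n
    return RatingCounts(arr, n_ratings)
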