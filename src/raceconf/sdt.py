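"""Type-1 and type-2 signal detection metrics: d', meta-d', and
response-conditional meta-d'.

All metrics operate on a 2 (stimulus) x 2 (response) x N_r (rating)
contingency table of trial counts.  d' is the standard equal-variance
sensitivity ``z(HR) - z(FAR)``.  meta-d' is the sensitivity that an ideal
equal-variance SDT observer would need in order to produce the observed
confidence-rating data, fitted by maximum likelihood over the
response-conditional rating distributions with the type-1 criterion fixed
at the observed relative criterion c' = c/d' (the standard identifiability
constraint).  Response-conditional meta-d' applies the same machinery to
the rating counts of a single response side.

A log-linear correction (0.5 added to every cell) is applied uniformly
before both the d' and meta-d' computations, for continuity at saturated
cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "RatingCounts",
    "MetaDFit",
    "dprime",
    "fit_meta_d",
    "fit_response_conditional_meta_d",
    "sdt_rating_probs",
]

_PAD = 0.5  # log-linear cell correction


@dataclass(frozen=True)
class RatingCounts:
    """Stimulus x response x rating trial counts.

    ``counts[s, r, k]`` is the number of trials with stimulus ``s`` (0 or
    1), response ``r`` (0 or 1) and confidence rating ``k + 1`` (ratings
    run 1..n_ratings).
    """

    counts: np.ndarray
    n_ratings: int = 4

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.shape != (2, 2, self.n_ratings):
            raise ValueError(
                f"counts must have shape (2, 2, {self.n_ratings}), got {arr.shape}"
            )
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if arr.sum() <= 0:
            raise ValueError("counts table is empty")
        object.__setattr__(self, "counts", arr)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, n_ratings: int = 4) -> "RatingCounts":
        """Aggregate a trial table (stimulus, response, rating columns)."""
        arr = np.zeros((2, 2, n_ratings))
        for (s, r, k), n in trials.groupby(["stimulus", "response", "rating"]).size().items():
            arr[int(s), int(r), int(k) - 1] = n
        return cls(arr, n_ratings)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame) -> "RatingCounts":
        """Read a count table with rows stimulus x response, columns ratings.

        Expects columns ``stimulus, response, r1..rN``.
        """
        rating_cols = [c for c in table.columns if c.startswith("r") and c[1:].isdigit()]
        n_ratings = len(rating_cols)
        arr = np.zeros((2, 2, n_ratings))
        for _, row in table.iterrows():
            arr[int(row["stimulus"]), int(row["response"])] = row[rating_cols].to_numpy(float)
        return cls(arr, n_ratings)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in (0, 1):
            for r in (0, 1):
                rows.append(
                    {"stimulus": s, "response": r}
                    | {f"r{k + 1}": self.counts[s, r, k] for k in range(self.n_ratings)}
                )
        return pd.DataFrame(rows)

    @property
    def padded(self) -> np.ndarray:
        return self.counts + _PAD

    def response_totals(self) -> np.ndarray:
        """(stimulus, response) totals, unpadded."""
        return self.counts.sum(axis=2)


def dprime(counts: RatingCounts) -> tuple[float, float]:
    """Equal-variance type-1 sensitivity and criterion.

    Returns ``(d_prime, criterion)`` with ``d' = z(HR) - z(FAR)`` and
    ``c = -(z(HR) + z(FAR)) / 2``, where HR and FAR are the padded
    response-1 rates given stimulus 1 and stimulus 0.
    """
    totals = counts.response_totals()
    if np.any(totals.sum(axis=1) <= 0):
        raise ValueError("each stimulus row needs at least one trial")
    # pad each response cell by 0.5 (adds 1 per stimulus row of 2 cells)
    padded = totals + _PAD
    rates = padded[:, 1] / padded.sum(axis=1)
    far, hr = rates[0], rates[1]
    d = norm.ppf(hr) - norm.ppf(far)
    c = -0.5 * (norm.ppf(hr) + norm.ppf(far))
    return float(d), float(c)


@dataclass
class MetaDFit:
    """Result of a maximum-likelihood (response-conditional) meta-d' fit.

    ``type2_criteria`` maps response side ("S1" / "S2") to the fitted
    type-2 criteria in z units: descending below the type-1 criterion on
    the "S1" side, ascending above it on the "S2" side.
    """

    meta_d: float
    type1_criterion: float
    type2_criteria: dict[str, np.ndarray]
    loglik: float
    converged: bool
    low_reliability: bool = False


def sdt_rating_probs(
    d: float, meta_c: float, t2c_s1: np.ndarray, t2c_s2: np.ndarray
) -> np.ndarray:
    """Joint (stimulus, response, rating) probabilities of an equal-variance
    SDT observer with sensitivity ``d``, type-1 criterion ``meta_c`` and
    the given type-2 criteria.

    ``t2c_s1`` are the criteria below ``meta_c`` in descending order;
    ``t2c_s2`` above it in ascending order.  Used both to build the fit
    likelihood and, in tests, to generate data from the exact model being
    fitted.
    """
    t2c_s1 = np.asarray(t2c_s1, dtype=float)
    t2c_s2 = np.asarray(t2c_s2, dtype=float)
    n_r = len(t2c_s2) + 1
    mus = (-d / 2.0, d / 2.0)
    probs = np.zeros((2, 2, n_r))
    # response "S2": regions between ascending edges meta_c < c1 < ... < inf
    edges_s2 = np.concatenate(([meta_c], t2c_s2, [np.inf]))
    # response "S1": regions between descending edges meta_c > a1 > ... > -inf
    edges_s1 = np.concatenate(([meta_c], t2c_s1, [-np.inf]))
    for s, mu in enumerate(mus):
        cdf_s2 = norm.cdf(edges_s2 - mu)
        probs[s, 1, :] = np.diff(cdf_s2)
        cdf_s1 = norm.cdf(edges_s1 - mu)
        probs[s, 0, :] = -np.diff(cdf_s1)
    return probs


def _type2_loglik(
    meta_d: float,
    c_prime: float,
    gaps_s1: np.ndarray,
    gaps_s2: np.ndarray,
    padded: np.ndarray,
    sides: tuple[int, ...],
) -> float:
    """Multinomial log-likelihood of the response-conditional rating counts."""
    meta_c = c_prime * meta_d
    t2c_s1 = meta_c - np.cumsum(np.exp(gaps_s1))
    t2c_s2 = meta_c + np.cumsum(np.exp(gaps_s2))
    probs = sdt_rating_probs(meta_d, meta_c, t2c_s1, t2c_s2)
    ll = 0.0
    for r in sides:
        p_resp = probs[:, r, :].sum(axis=1)  # P(response r | stimulus)
        cond = probs[:, r, :] / np.maximum(p_resp[:, None], 1e-300)
        ll += float(np.sum(padded[:, r, :] * np.log(np.maximum(cond, 1e-300))))
    return ll


def _init_gaps(padded: np.ndarray, r: int, meta_c: float, n_r: int) -> np.ndarray:
    """Initialize type-2 criterion gaps from the pooled rating ECDF of one
    response side, mapped through the standard normal quantile function."""
    pooled = padded[:, r, :].sum(axis=0)
    cum = np.cumsum(pooled) / pooled.sum()
    cum = np.clip(cum[:-1], 1e-4, 1 - 1e-4)
    base = norm.cdf(meta_c) if r == 1 else norm.cdf(-meta_c)
    # criteria move outward from meta_c through the remaining mass
    mass = (1.0 - base) * cum + base
    crit = norm.ppf(np.clip(mass, 1e-6, 1 - 1e-6))
    crit = np.abs(crit - meta_c) if r == 1 else np.abs(meta_c - crit)
    gaps = np.diff(np.concatenate(([0.0], np.maximum.accumulate(crit))))
    return np.log(np.maximum(gaps, 1e-3))


def _fit_type2(counts: RatingCounts, sides: tuple[int, ...]) -> MetaDFit:
    d, c = dprime(counts)
    c_prime = c / d if abs(d) > 1e-3 else 0.0
    padded = counts.padded
    n_r = counts.n_ratings
    n_gap = n_r - 1

    used = np.flatnonzero(counts.counts.sum(axis=(0, 1)) > 0)
    if used.size < 2:
        return MetaDFit(
            meta_d=float("nan"),
            type1_criterion=c,
            type2_criteria={},
            loglik=float("nan"),
            converged=False,
        )

    def objective(theta: np.ndarray) -> float:
        return -_type2_loglik(
            theta[0], c_prime, theta[1 : 1 + n_gap], theta[1 + n_gap :], padded, sides
        )

    best = None
    for m0 in (d, 0.5 * d if abs(d) > 0.2 else 0.25, 2.0):
        g1 = _init_gaps(padded, 0, c_prime * m0, n_r)
        g2 = _init_gaps(padded, 1, c_prime * m0, n_r)
        theta0 = np.concatenate(([m0], g1, g2))
        res = minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=[(-10.0, 10.0)] + [(-15.0, 5.0)] * (2 * n_gap),
            options={"ftol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    meta_d = float(best.x[0])
    meta_c = c_prime * meta_d
    t2c_s1 = meta_c - np.cumsum(np.exp(best.x[1 : 1 + n_gap]))
    t2c_s2 = meta_c + np.cumsum(np.exp(best.x[1 + n_gap :]))
    crit = {}
    if 0 in sides:
        crit["S1"] = t2c_s1
    if 1 in sides:
        crit["S2"] = t2c_s2
    # a side with (almost) no error trials makes the fit poorly constrained
    errors = counts.counts[1, 0, :].sum() if sides == (0,) else counts.counts[0, 1, :].sum()
    low_rel = len(sides) == 1 and errors < 5
    return MetaDFit(
        meta_d=meta_d,
        type1_criterion=c,
        type2_criteria=crit,
        loglik=-float(best.fun),
        converged=bool(best.success),
        low_reliability=bool(low_rel),
    )


def fit_meta_d(counts: RatingCounts) -> MetaDFit:
    """Overall meta-d': ML fit to the rating counts of both response sides.

    The type-1 criterion of the meta-observer is fixed at the observed
    relative criterion (meta-c = c' * meta-d' with c' = c/d'); meta-d' and
    the type-2 criteria of both response sides maximize the multinomial
    likelihood of the response-conditional rating counts.
    """
    return _fit_type2(counts, sides=(0, 1))


def fit_response_conditional_meta_d(counts: RatingCounts, response_side: str) -> MetaDFit:
    """meta-d' fitted from the rating counts of one response side.

    ``response_side`` is "S1" (response 0) or "S2" (response 1).  Requires
    at least one trial of each stimulus class on the selected side.
    """
    side = {"S1": 0, "S2": 1}.get(response_side)
    if side is None:
        raise ValueError("response_side must be 'S1' or 'S2'")
    side_totals = counts.response_totals()[:, side]
    if np.any(side_totals <= 0):
        raise ValueError(
            f"response side {response_side!r} needs at least one trial per stimulus"
        )
    return _fit_type2(counts, sides=(side,))
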