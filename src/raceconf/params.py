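"""Parameter and trial-record containers for the tuned-inhibition race model.

The model simulates a two-alternative perceptual decision as a race between
two rectified evidence accumulators ``x_i`` feeding rectified differencing
units ``delta_i``.  A single :class:`ModelParams` instance describes one
trial type: the per-alternative mean evidence increments (stimulus drives),
the accumulation and differencing noise, the decision bound, the number of
post-decision accumulation steps after which confidence is read out, and the
ordinal confidence-rating thresholds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = ["ModelParams", "TrialRecord"]


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of one simulated trial type.

    Parameters
    ----------
    s_drives
        Mean evidence increment per time step for each of the two
        accumulator units (arbitrary evidence units, all >= 0).  By
        convention the drives are stated for a presentation of stimulus
        alternative 0; :meth:`mirrored` gives the swapped-drive parameters
        used for the other alternative in symmetric designs.
    sigma_acc
        SD of the zero-mean Gaussian noise added to each accumulator on
        each step.
    sigma_diff
        SD of the noise added inside each differencing unit.  ``None``
        (default) means "same as ``sigma_acc``", reflecting the assumption
        that noise at both processing levels comes from one distribution;
        it is a separate field so it can be zeroed in tests.
    threshold
        Decision bound T on the differencing units (strict ``delta > T``).
    tau
        Number of post-decision accumulation steps before confidence is
        read out (integer >= 0).  Larger tau yields higher metacognitive
        sensitivity.
    rating_thresholds
        Strictly ascending confidence thresholds ``U_1..U_{n_ratings-1}``
        mapping raw confidence to an ordinal rating; may be ``None`` until
        fitted.
    n_ratings
        Size of the ordinal confidence scale (default 4).
    max_steps
        Censoring horizon: trials that have not crossed the bound by this
        step are flagged censored.
    """

    s_drives: tuple[float, float] = (0.0, 0.0)
    sigma_acc: float = 0.1
    sigma_diff: float | None = None
    threshold: float = 1.0
    tau: int = 0
    rating_thresholds: tuple[float, ...] | None = None
    n_ratings: int = 4
    max_steps: int = 10_000

    def __post_init__(self) -> None:
        drives = tuple(float(s) for s in self.s_drives)
        object.__setattr__(self, "s_drives", drives)
        if len(drives) != 2:
            raise ValueError("exactly two stimulus alternatives are supported")
        if any(s < 0 for s in drives):
            raise ValueError("stimulus drives must be non-negative")
        if self.sigma_acc < 0:
            raise ValueError("sigma_acc must be non-negative")
        if self.sigma_diff is not None and self.sigma_diff < 0:
            raise ValueError("sigma_diff must be non-negative")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if int(self.tau) != self.tau or self.tau < 0:
            raise ValueError("tau must be a non-negative integer")
        object.__setattr__(self, "tau", int(self.tau))
        if self.n_ratings < 2:
            raise ValueError("n_ratings must be at least 2")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")
        if self.rating_thresholds is not None:
            thr = tuple(float(u) for u in self.rating_thresholds)
            object.__setattr__(self, "rating_thresholds", thr)
            if len(thr) != self.n_ratings - 1:
                raise ValueError(
                    f"rating_thresholds must have length n_ratings-1={self.n_ratings - 1}"
                )
            if np.any(np.diff(thr) <= 0):
                raise ValueError("rating_thresholds must be strictly increasing")

    @property
    def effective_sigma_diff(self) -> float:
        """Differencing-noise SD actually used (defaults to ``sigma_acc``)."""
        return self.sigma_acc if self.sigma_diff is None else self.sigma_diff

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def mirrored(self) -> "ModelParams":
        """Parameters with the two alternatives' drives swapped."""
        return self.replace(s_drives=(self.s_drives[1], self.s_drives[0]))


@dataclass
class TrialRecord:
    """Outcome of one simulated trial.

    ``c_x`` is the raw confidence read from the winning accumulator unit
    (absolute decision-congruent evidence) at ``rt + tau``; ``c_delta`` is
    the raw confidence read from the winning differencing unit (balance of
    evidence) at the same instant.  ``rating`` is assigned later, once
    rating thresholds have been fitted.
    """

    stimulus: int
    decision: int
    rt: int
    c_x: float
    c_delta: float
    correct: bool
    censored: bool = False
    rating: int | None = None
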