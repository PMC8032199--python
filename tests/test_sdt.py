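"""Tests for d', meta-d' and response-conditional meta-d'.

The meta-d' fitter is checked two ways: parameter recovery on tables
generated from the exact equal-variance SDT observer being fitted, and an
independent re-implementation of the type-2 likelihood (written here, not
imported) used to verify that the fitted parameters are at the likelihood
optimum.
"""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import norm

from raceconf import RatingCounts, dprime, fit_meta_d, fit_response_conditional_meta_d
from raceconf.sdt import sdt_rating_probs


def sdt_table(d, meta_c, t2c_s1, t2c_s2, n=100_000, rng=None):
    """Counts from the exact SDT observer (expected counts if rng is None,
    multinomial sample otherwise)."""
    probs = sdt_rating_probs(d, meta_c, t2c_s1, t2c_s2)
    if rng is None:
        return RatingCounts(probs * n)
    counts = np.stack(
        [rng.multinomial(n, probs[s].ravel()).reshape(2, -1) for s in (0, 1)]
    )
    return RatingCounts(counts.astype(float))


# ---------------------------------------------------------------------------
# type-1 sensitivity


def test_dprime_textbook_rates():
    # HR = 841/1000, FAR = 159/1000: z(0.841) = -z(0.159) ~ 0.9985
    counts = np.zeros((2, 2, 4))
    counts[1, 1, 0], counts[1, 0, 0] = 841, 159
    counts[0, 1, 0], counts[0, 0, 0] = 159, 841
    d, c = dprime(RatingCounts(counts))
    assert d == pytest.approx(1.997, abs=0.01)
    assert c == pytest.approx(0.0, abs=1e-9)


def test_dprime_chance():
    counts = np.zeros((2, 2, 4))
    counts[:, :, 0] = 500
    d, _ = dprime(RatingCounts(counts))
    assert d == pytest.approx(0.0, abs=1e-12)


def test_dprime_padding_keeps_saturated_cells_finite_and_monotone():
    """As the hit cell approaches saturation d' grows continuously instead
    of diverging: the log-linear correction caps z(HR) at a finite value."""
    ds = []
    for hits in (990, 995, 999, 1000):
        counts = np.zeros((2, 2, 4))
        counts[1, 1, 0], counts[1, 0, 0] = hits, 1000 - hits
        counts[0, 1, 0], counts[0, 0, 0] = 200, 800
        d, _ = dprime(RatingCounts(counts))
        ds.append(d)
    assert np.all(np.isfinite(ds))
    assert np.all(np.diff(ds) > 0)


def test_dprime_requires_trials_per_stimulus():
    counts = np.zeros((2, 2, 4))
    counts[1, 1, 0] = 100
    with pytest.raises(ValueError):
        dprime(RatingCounts(counts))


# ---------------------------------------------------------------------------
# meta-d' parameter recovery (self-consistency oracles)


def test_meta_d_recovers_generating_sensitivity():
    t2c_s1 = np.array([-0.5, -1.0, -1.5])
    t2c_s2 = np.array([0.5, 1.0, 1.5])
    fit = fit_meta_d(sdt_table(1.5, 0.0, t2c_s1, t2c_s2))
    assert fit.converged
    assert fit.meta_d == pytest.approx(1.5, abs=0.03)


def test_meta_d_recovery_multinomial_sample():
    rng = np.random.default_rng(4)
    t2c_s1 = np.array([-0.4, -0.9, -1.6])
    t2c_s2 = np.array([0.3, 0.8, 1.4])
    fit = fit_meta_d(sdt_table(1.5, 0.1, t2c_s1, t2c_s2, n=100_000, rng=rng))
    assert fit.meta_d == pytest.approx(1.5, abs=0.05)


def test_response_conditional_recovery_symmetric_observer():
    t2c_s1 = np.array([-0.6, -1.2, -1.8])
    t2c_s2 = np.array([0.6, 1.2, 1.8])
    counts = sdt_table(2.0, 0.0, t2c_s1, t2c_s2)
    overall = fit_meta_d(counts).meta_d
    m1 = fit_response_conditional_meta_d(counts, "S1").meta_d
    m2 = fit_response_conditional_meta_d(counts, "S2").meta_d
    assert m1 == pytest.approx(2.0, abs=0.05)
    assert m2 == pytest.approx(2.0, abs=0.05)
    assert overall == pytest.approx(2.0, abs=0.05)


def test_ratings_independent_of_accuracy_give_zero_meta_d():
    """If each response side's rating distribution is identical for both
    stimulus classes, confidence carries no type-2 information."""
    counts = np.zeros((2, 2, 4))
    dist = np.array([0.4, 0.3, 0.2, 0.1])
    # response rates differ by stimulus (d' > 0) but ratings don't
    counts[0, 0] = 800 * dist
    counts[0, 1] = 200 * dist
    counts[1, 0] = 300 * dist
    counts[1, 1] = 700 * dist
    fit = fit_meta_d(RatingCounts(counts))
    assert abs(fit.meta_d) < 0.05


def test_one_sided_type2_information():
    """Constructed table where only "S2"-response ratings track accuracy:
    response-conditional meta-d' separates the two sides."""
    counts = np.zeros((2, 2, 4))
    flat = np.array([0.25, 0.25, 0.25, 0.25])
    low = np.array([0.4, 0.3, 0.2, 0.1])
    high = np.array([0.1, 0.2, 0.3, 0.4])
    counts[0, 0] = 700 * flat  # S1 correct: flat ratings
    counts[1, 0] = 300 * flat  # S1 error: identical -> no info
    counts[1, 1] = 700 * high  # S2 correct: high ratings
    counts[0, 1] = 300 * low  # S2 error: low ratings
    rc = RatingCounts(counts)
    m1 = fit_response_conditional_meta_d(rc, "S1").meta_d
    m2 = fit_response_conditional_meta_d(rc, "S2").meta_d
    assert abs(m1) < 0.1
    assert m2 > 0.5


def test_permuting_ratings_within_response_kills_meta_d():
    rng = np.random.default_rng(12)
    counts = sdt_table(1.8, 0.0, [-0.5, -1.0, -1.5], [0.5, 1.0, 1.5], n=50_000, rng=rng)
    base = fit_meta_d(counts).meta_d
    # permutation: make ratings independent of stimulus within response by
    # giving both stimulus rows the pooled per-response rating distribution
    shuffled = counts.counts.copy()
    for r in (0, 1):
        pooled = counts.counts[:, r, :].sum(axis=0)
        pooled = pooled / pooled.sum()
        for s in (0, 1):
            shuffled[s, r, :] = counts.counts[s, r, :].sum() * pooled
    permuted = fit_meta_d(RatingCounts(shuffled)).meta_d
    assert base > 1.5
    assert abs(permuted) < 0.1


def test_merging_rating_levels_loses_type2_information():
    counts = sdt_table(2.0, 0.0, [-0.5, -1.0, -1.5], [0.5, 1.0, 1.5])
    merged = np.zeros((2, 2, 2))
    merged[:, :, 0] = counts.counts[:, :, :2].sum(axis=2)
    merged[:, :, 1] = counts.counts[:, :, 2:].sum(axis=2)
    m_full = fit_meta_d(counts).meta_d
    m_merged = fit_meta_d(RatingCounts(merged, n_ratings=2)).meta_d
    assert m_merged <= m_full + 0.05


def test_type2_criteria_ordering_invariant():
    rng = np.random.default_rng(8)
    for d in (0.8, 1.5, 2.5):
        counts = sdt_table(d, 0.2, [-0.3, -0.8, -1.4], [0.4, 0.9, 1.5], n=50_000, rng=rng)
        fit = fit_meta_d(counts)
        assert fit.converged
        meta_c = fit.type1_criterion / d * fit.meta_d if d else 0.0
        s1 = fit.type2_criteria["S1"]
        s2 = fit.type2_criteria["S2"]
        assert np.all(np.diff(s1) < 0) and np.all(s1 < meta_c + 1e-9)
        assert np.all(np.diff(s2) > 0) and np.all(s2 > meta_c - 1e-9)


def test_degenerate_single_rating_table_flagged():
    counts = np.zeros((2, 2, 4))
    counts[:, :, 0] = [[700, 300], [300, 700]]
    fit = fit_meta_d(RatingCounts(counts))
    assert not fit.converged
    assert np.isnan(fit.meta_d)


def test_empty_response_side_rejected():
    counts = np.zeros((2, 2, 4))
    counts[:, 1, :] = 100
    with pytest.raises(ValueError):
        fit_response_conditional_meta_d(RatingCounts(counts), "S1")


# ---------------------------------------------------------------------------
# independent likelihood oracle


def _oracle_negloglik(meta_d, c_prime, counts, side):
    """Type-2 negative log-likelihood, written independently of the
    package: profile the (ordered) type-2 criteria of one response side by
    direct optimization of the conditional multinomial likelihood."""
    padded = counts.counts + 0.5
    meta_c = c_prime * meta_d
    n_crit = counts.n_ratings - 1
    sign = 1.0 if side == 1 else -1.0

    def nll(log_gaps):
        crit = meta_c + sign * np.cumsum(np.exp(log_gaps))
        edges = np.concatenate(([meta_c], crit, [sign * np.inf]))
        total = 0.0
        for s, mu in enumerate((-meta_d / 2, meta_d / 2)):
            cell = sign * np.diff(norm.cdf(sign * (edges - mu)))
            denom = norm.sf(meta_c - mu) if side == 1 else norm.cdf(meta_c - mu)
            total -= padded[s, side] @ np.log(np.maximum(np.abs(cell) / denom, 1e-300))
        return total

    best = np.inf
    for g0 in (-1.0, 0.0):
        res = minimize(nll, np.full(n_crit, g0), method="Nelder-Mead")
        best = min(best, res.fun)
    return best


def test_fit_sits_at_oracle_likelihood_optimum():
    """The fitted meta-d' beats (or matches) every value on a coarse grid
    when the oracle profiles out the criteria independently."""
    rng = np.random.default_rng(21)
    counts = sdt_table(1.3, 0.1, [-0.4, -0.9, -1.5], [0.5, 1.0, 1.6], n=20_000, rng=rng)
    d, c = dprime(counts)
    c_prime = c / d
    fit = fit_meta_d(counts)

    def total_nll(m):
        return _oracle_negloglik(m, c_prime, counts, 0) + _oracle_negloglik(
            m, c_prime, counts, 1
        )

    fit_nll = total_nll(fit.meta_d)
    for m in np.arange(0.6, 2.01, 0.2):
        assert fit_nll <= total_nll(m) + 0.5  # within numerical slack
    # and the oracle's own grid optimum is close to the fitted value
    grid = np.arange(0.8, 1.9, 0.05)
    grid_best = grid[int(np.argmin([total_nll(m) for m in grid]))]
    assert abs(grid_best - fit.meta_d) < 0.1
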