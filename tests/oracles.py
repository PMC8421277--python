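"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the Bloch simulator
sums explicitly dephased isochromats instead of tracking configuration
states, the regression oracle evaluates the closed-form OLS expressions,
and the Friedman oracle enumerates / resamples within-block rank
permutations.
"""

from __future__ import annotations

import itertools

import numpy as np


def isochromat_fingerprint(
    t1_ms: float,
    t2_ms: float,
    schedule,
    n_spins: int = 2000,
) -> np.ndarray:
    """Brute-force Bloch simulation of the spoiled SSFP fingerprint.

    ``n_spins`` isochromats are dephased uniformly across one crusher cycle
    per TR (the crusher is applied instantaneously at the end of each TR,
    after the readout).  RF pulses rotate about the y axis, matching the
    phase convention of the EPG simulator under test.  Returns the real
    part of the mean transverse magnetization at each TE.
    """
    n_t = schedule.n_timepoints
    psi = 2.0 * np.pi * np.arange(n_spins) / n_spins
    cpsi, spsi = np.cos(psi), np.sin(psi)
    mx = np.zeros(n_spins)
    my = np.zeros(n_spins)
    mz = np.full(
        n_spins,
        -schedule.inversion_efficiency if schedule.inversion else 1.0,
    )
    out = np.empty(n_t)
    for t in range(n_t):
        a = np.deg2rad(schedule.flip_angles_deg[t])
        ca, sa = np.cos(a), np.sin(a)
        mx, mz = ca * mx + sa * mz, -sa * mx + ca * mz
        te, tr = schedule.te_ms[t], schedule.tr_ms[t]
        e2te = np.exp(-te / t2_ms)
        out[t] = np.mean(mx) * e2te
        e2tr = np.exp(-tr / t2_ms)
        e1tr = np.exp(-tr / t1_ms)
        mx *= e2tr
        my *= e2tr
        mz = 1.0 - (1.0 - mz) * e1tr
        mx, my = mx * cpsi - my * spsi, mx * spsi + my * cpsi
    return out


def ols_closed_form(x: np.ndarray, y: np.ndarray):
    """Textbook OLS of y on x: slope, intercept, r squared."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    syy = np.sum((y - ybar) ** 2)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    r2 = sxy**2 / (sxx * syy)
    return slope, intercept, r2


def friedman_statistic_plain(blocks: np.ndarray) -> float:
    """Friedman Q from scratch (mid-ranks, tie-corrected), row loop."""
    blocks = np.asarray(blocks, float)
    n, k = blocks.shape
    ranks = np.empty_like(blocks)
    tie_term = 0.0
    for i in range(n):
        order = blocks[i].argsort(kind="mergesort")
        r = np.empty(k)
        r[order] = np.arange(1, k + 1, dtype=float)
        # mid-ranks for ties
        vals, counts = np.unique(blocks[i], return_counts=True)
        for v, c in zip(vals, counts):
            if c > 1:
                sel = blocks[i] == v
                r[sel] = r[sel].mean()
                tie_term += c**3 - c
        ranks[i] = r
    rj = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    corr = 1.0 - tie_term / (n * k * (k**2 - 1))
    if corr <= 0:
        return 0.0
    return q / corr


def friedman_exact_permutation_p(blocks: np.ndarray) -> float:
    """Exact permutation p-value: enumerate all within-block orderings.

    Feasible only for small n and k (k!^n arrangements); p is the fraction
    of arrangements whose Friedman statistic >= the observed one.
    """
    blocks = np.asarray(blocks, float)
    n, k = blocks.shape
    q_obs = friedman_statistic_plain(blocks)
    perms = list(itertools.permutations(range(k)))
    count = 0
    total = 0
    for combo in itertools.product(perms, repeat=n):
        permuted = np.stack([blocks[i, list(p)] for i, p in enumerate(combo)])
        total += 1
        if friedman_statistic_plain(permuted) >= q_obs - 1e-12:
            count += 1
    return count / total


def friedman_montecarlo_p_vectorized(
    blocks: np.ndarray, n_resamples: int, seed: int
) -> float:
    """Monte-Carlo permutation p for tie-free blocks, computed in bulk.

    Within-block values are permuted independently per resample; the
    statistic is evaluated directly from the rank-sum formula (valid here
    because continuous draws are tie-free).
    """
    from scipy.stats import rankdata

    blocks = np.asarray(blocks, float)
    n, k = blocks.shape
    q_obs = friedman_statistic_plain(blocks)
    rng = np.random.default_rng(seed)
    # permuting values within a block == permuting its ranks
    base_ranks = rankdata(blocks, axis=1)
    perms = rng.permuted(
        np.broadcast_to(base_ranks, (n_resamples, n, k)).copy(), axis=2
    )
    rj = perms.sum(axis=1)  # (n_resamples, k)
    q = 12.0 / (n * k * (k + 1)) * np.sum(rj**2, axis=1) - 3.0 * n * (k + 1)
    count = int(np.sum(q >= q_obs - 1e-12))
    return (count + 1) / (n_resamples + 1)


def friedman_montecarlo_p(blocks: np.ndarray, n_resamples: int, seed: int) -> float:
    """Monte-Carlo permutation p-value for the Friedman statistic."""
    blocks = np.asarray(blocks, float)
    rng = np.random.default_rng(seed)
    q_obs = friedman_statistic_plain(blocks)
    count = 0
    for _ in range(n_resamples):
        permuted = np.stack([rng.permutation(row) for row in blocks])
        if friedman_statistic_plain(permuted) >= q_obs - 1e-12:
            count += 1
    return (count + 1) / (n_resamples + 1)
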