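"""Monte-Carlo rank tests, power estimation, and minimal-sample-size search.

For potentials other than the step, no closed-form null distribution of the
strength estimator exists.  Tests are instead built on the sufficient
statistic T = -sum_i f((d_i - t)/sigma): its null distribution is
approximated by K i.i.d. samples of N distances drawn from q, and the
observed T is ranked among the null values.  H0 ("no interaction") is
rejected at level alpha when the observed value ranks strictly higher than
the ceil((1 - alpha) K)-th null order statistic; the matching exact MC
p-value is (1 + #{T_k >= T_obs}) / (K + 1), with ties counted against
rejection.

A shape-free variant bins the distances into L equal-width bins spanning
q's non-zero range and uses the Mahalanobis statistic
U = (T - E0)' Cov0^- (T - E0), with the null moments estimated from a first,
independent MC sample.

Power is estimated by simulation: sample data under a known true potential,
run the test, and report the rejection fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import DistanceSample
from .gibbs import model_density, sample_distances, sufficient_statistic
from .potentials import shape
from .state_density import StateDensity

__all__ = [
    "TestResult",
    "MCPowerResult",
    "MinNResult",
    "mc_rank_test",
    "nonparametric_test",
    "estimate_power",
    "min_n_for_power",
]


@dataclass
class TestResult:
    statistic_name: str
    observed: float
    K: int
    rank: int
    p_value: float
    alpha: float
    reject: bool
    seed: object = None

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "statistic": self.statistic_name,
                "observed": self.observed,
                "K": self.K,
                "rank": self.rank,
                "p_value": self.p_value,
                "alpha": self.alpha,
                "reject": self.reject,
                "seed": repr(self.seed),
            }
        )


@dataclass
class MCPowerResult:
    alpha: float
    N: int
    effect_size: float
    power: float
    stderr: float
    reps: int
    K: int


@dataclass
class MinNResult:
    N: int | None
    bracket: tuple[int, int]
    target: float
    status: str = "ok"  # or "not_attainable_at_cap"


def _rank_decision(observed: float, null_values: np.ndarray, alpha: float):
    """Rank rule shared by all MC tests.

    Returns (rank, p, reject): rank counts null values strictly below the
    observation (1 = smallest); rejection requires ranking strictly above
    the ceil((1-alpha)K)-th null order statistic.
    """
    K = len(null_values)
    null_sorted = np.sort(null_values)
    n_ge = int(np.count_nonzero(null_values >= observed))
    p = (1.0 + n_ge) / (K + 1.0)
    rank = K - n_ge + 1
    thresh_idx = math.ceil((1.0 - alpha) * K)  # 1-based order statistic
    reject = bool(observed > null_sorted[thresh_idx - 1])
    return rank, p, reject


def mc_rank_test(
    D: DistanceSample,
    q: StateDensity,
    family: str,
    sigma: float = 1.0,
    t: float = 0.0,
    K: int = 999,
    alpha: float = 0.05,
    seed=None,
) -> TestResult:
    """One-sided MC rank test for attraction using a parametric statistic.

    K samples of N = |D| distances are drawn from the null q; the observed
    sufficient statistic is ranked among the null statistics.
    """
    if K < 19:
        raise ValueError("K must be at least 19 for a meaningful rank test")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs = sufficient_statistic(D, family, sigma, t)
    # vectorized null draws: K x N inverse-CDF samples from q
    u = rng.random((K, D.N))
    d_null = np.interp(u, q.cdf_grid(), q.grid)
    t_null = -np.sum(shape(family, (d_null - t) / sigma), axis=1)
    rank, p, reject = _rank_decision(t_obs, t_null, alpha)
    return TestResult(f"T_{family}", t_obs, K, rank, p, alpha, reject, seed)


def _bin_edges(q: StateDensity, L: int) -> np.ndarray:
    """L + 1 strictly increasing thresholds spanning q's non-zero range."""
    nz = np.nonzero(q.density > 0)[0]
    lo, hi = q.grid[nz[0]], q.grid[nz[-1]]
    return np.linspace(lo, hi, L + 1)


def nonparametric_test(
    D: DistanceSample,
    q: StateDensity,
    L: int = 20,
    K: int = 999,
    alpha: float = 0.05,
    seed=None,
) -> TestResult:
    """Shape-free MC test on binned distance counts.

    Counts T over L equal-width bins spanning q's non-zero range are reduced
    to U = (T - E0)' Cov0^- (T - E0).  The null moments (E0, Cov0) come from
    a first MC sample; the observed U is then ranked among null U values
    from a second, independent MC sample (separate RNG streams — reusing the
    moment sample for ranking would bias the test).  Cov0 is inverted by
    Moore-Penrose pseudo-inverse, so empty bins cannot crash the test.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if K < 19:
        raise ValueError("K must be at least 19")
    if isinstance(seed, np.random.Generator):
        rng_mom, rng_rank = seed.spawn(2)
    else:
        ss = np.random.SeedSequence(seed)
        rng_mom, rng_rank = [np.random.default_rng(s) for s in ss.spawn(2)]
    edges = _bin_edges(q, L)
    cdf, grid = q.cdf_grid(), q.grid

    def counts(d_matrix):
        # row-wise histogram over fixed edges; clip into the span so the
        # extreme bins also collect out-of-range nulls
        idx = np.clip(np.searchsorted(edges, d_matrix, side="right") - 1, 0, L - 1)
        out = np.zeros((d_matrix.shape[0], L))
        for l in range(L):
            out[:, l] = np.count_nonzero(idx == l, axis=1)
        return out

    d_mom = np.interp(rng_mom.random((K, D.N)), cdf, grid)
    T_mom = counts(d_mom)
    E0 = T_mom.mean(axis=0)
    Cov0 = np.cov(T_mom, rowvar=False)
    Cinv = np.linalg.pinv(Cov0, rcond=1e-10)

    def U_of(T):
        r = T - E0
        return np.einsum("...i,ij,...j->...", r, Cinv, r)

    T_obs = counts(D.d[None, :])[0]
    u_obs = float(U_of(T_obs))

    d_rank = np.interp(rng_rank.random((K, D.N)), cdf, grid)
    u_null = U_of(counts(d_rank))
    rank, p, reject = _rank_decision(u_obs, u_null, alpha)
    return TestResult("U", u_obs, K, rank, p, alpha, reject, seed)


def estimate_power(
    q: StateDensity,
    true_potential,
    statistic: tuple[str, float, float],
    N: int,
    alpha: float = 0.05,
    K: int = 199,
    reps: int = 200,
    seed=None,
) -> MCPowerResult:
    """MC power of the rank test: rejection fraction over simulated datasets.

    ``statistic`` is (family, sigma, t) of the test statistic, which need
    not match the true potential — mismatch costs power.
    """
    if reps < 50:
        raise ValueError("reps must be >= 50 for a usable power estimate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    family, sigma, t = statistic
    md = model_density(q, true_potential) if true_potential is not None else None
    rejections = 0
    for _ in range(reps):
        if md is None:
            d = np.interp(rng.random(N), q.cdf_grid(), q.grid)
        else:
            d = np.interp(rng.random(N), md.cdf_grid(), md.grid)
        res = mc_rank_test(DistanceSample(d), q, family, sigma, t, K=K, alpha=alpha, seed=rng)
        rejections += res.reject
    p_hat = rejections / reps
    se = math.sqrt(max(p_hat * (1 - p_hat), 1.0 / reps) / reps)
    eff = getattr(true_potential, "epsilon", 0.0) if true_potential is not None else 0.0
    return MCPowerResult(alpha=alpha, N=N, effect_size=eff, power=p_hat,
                         stderr=se, reps=reps, K=K)


def min_n_for_power(
    q: StateDensity,
    true_potential,
    statistic: tuple[str, float, float],
    alpha: float = 0.05,
    target: float = 0.8,
    K: int = 199,
    reps: int = 200,
    n_start: int = 4,
    n_cap: int = 4096,
    seed=None,
) -> MinNResult:
    """Smallest N reaching the target power, by doubling then bisection.

    N is doubled from ``n_start`` until the estimated power reaches the
    target (or the cap), then the bracketing interval is bisected.  The MC
    noise of the power estimates carries over to the reported N.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target power must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def power_at(n):
        return estimate_power(q, true_potential, statistic, n, alpha, K, reps, seed=rng).power

    lo, hi = 0, n_start
    while True:
        if power_at(hi) >= target:
            break
        lo = hi
        if hi >= n_cap:
            return MinNResult(None, (lo, hi), target, status="not_attainable_at_cap")
        hi = min(2 * hi, n_cap)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target:
            hi = mid
        else:
            lo = mid
    return MinNResult(hi, (lo, hi), target)
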