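"""Classical object-based co-localization, recast as step-potential inference.

The threshold co-localization measure C^t (fraction of query objects within
distance t of a reference) implicitly assumes a step interaction potential.
Correcting C^t for the context baseline C0^t (its expectation under the
null q) yields a closed-form strength estimator

    eps_hat = ln[ C (1 - C0) / (C0 (1 - C)) ],

the log odds ratio of observed versus baseline co-localization.  Under the
null, N * C^t is Binomial(N, C0), which gives exact critical values and an
exact power analysis for the step statistic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import binom

from .geometry import DistanceSample
from .state_density import StateDensity, baseline_coloc

__all__ = [
    "EpsilonHat",
    "ColocResult",
    "CriticalValue",
    "PowerResult",
    "coloc_measure",
    "epsilon_hat_step",
    "analyze_coloc",
    "critical_coloc",
    "step_power",
]


@dataclass(frozen=True)
class EpsilonHat:
    """A strength estimate with an explicit degeneracy status.

    ``status`` is "ok" for a finite estimate; "plus_infinity" /
    "minus_infinity" when C saturates at 1 / 0; "undefined" when the
    baseline itself is degenerate (C0 in {0, 1}).  ``value`` is NaN whenever
    the status is not "ok" so that serialized output never carries raw
    floating infinities.
    """

    value: float
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class ColocResult:
    t: float
    C: float
    C0: float
    epsilon_hat: EpsilonHat
    N: int
    cell_id: str = "cell0"

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d)


@dataclass
class CriticalValue:
    """Smallest co-localization count that rejects the no-interaction null."""

    k: int | None
    critical_C: float | None
    critical_epsilon: EpsilonHat | None
    alpha: float
    N: int
    C0: float
    status: str = "ok"  # or "not_rejectable": no count up to N has tail prob <= alpha


@dataclass
class PowerResult:
    alpha: float
    N: int
    effect_size: float
    power: float
    critical_value: CriticalValue

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "N": self.N,
                "effect_size": self.effect_size,
                "power": self.power,
                "critical_count": self.critical_value.k,
                "status": self.critical_value.status,
            }
        )


def coloc_measure(D: DistanceSample, t: float) -> float:
    """C^t = #{d_i < t} / N (strict inequality: ties at t do not co-localize)."""
    return float(np.count_nonzero(D.d < t)) / D.N


def epsilon_hat_step(C: float, C0: float) -> EpsilonHat:
    """Closed-form step-potential strength: the log odds ratio of C vs C0."""
    if not (0.0 < C0 < 1.0):
        return EpsilonHat(float("nan"), "undefined")
    if C <= 0.0:
        return EpsilonHat(float("nan"), "minus_infinity")
    if C >= 1.0:
        return EpsilonHat(float("nan"), "plus_infinity")
    return EpsilonHat(math.log(C * (1.0 - C0) / (C0 * (1.0 - C))), "ok")


def analyze_coloc(D: DistanceSample, q: StateDensity, t: float = 0.0) -> ColocResult:
    """Observed C^t, baseline C0^t from q, and the corrected strength estimate."""
    C = coloc_measure(D, t)
    C0 = baseline_coloc(q, t)
    return ColocResult(t=t, C=C, C0=C0, epsilon_hat=epsilon_hat_step(C, C0), N=D.N,
                       cell_id=D.cell_id)


def critical_coloc(C0: float, N: int, alpha: float = 0.05) -> CriticalValue:
    """Smallest k with P(Binomial(N, C0) >= k) <= alpha, and the induced C, eps.

    When even k = N exceeds the level (large C0 with small N), no finite
    critical value exists and the result carries status "not_rejectable".
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0.0 < C0 < 1.0):
        raise ValueError("C0 must lie strictly between 0 and 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie strictly between 0 and 1")
    k_arr = np.arange(N + 1)
    tail = binom.sf(k_arr - 1, N, C0)  # P(X >= k)
    ok = np.nonzero(tail <= alpha)[0]
    if ok.size == 0:
        return CriticalValue(None, None, None, alpha, N, C0, status="not_rejectable")
    k = int(k_arr[ok[0]])
    crit_C = k / N
    return CriticalValue(k, crit_C, epsilon_hat_step(crit_C, C0), alpha, N, C0)


def step_power(C0: float, N: int, alpha: float, a: float) -> PowerResult:
    """Exact power of the binomial co-localization test at true step strength a.

    Under the alternative the success probability becomes
    p1 = C0 e^a / (C0 e^a + 1 - C0), the step-model co-localization
    probability; power is the upper tail of Binomial(N, p1) at the critical
    count.  A "not_rejectable" critical value yields zero power.
    """
    if not np.isfinite(a):
        raise ValueError("effect size a must be finite")
    cv = critical_coloc(C0, N, alpha)
    if cv.status != "ok":
        return PowerResult(alpha=alpha, N=N, effect_size=a, power=0.0, critical_value=cv)
    ea = math.exp(a)
    p1 = C0 * ea / (C0 * ea + 1.0 - C0)
    power = float(binom.sf(cv.k - 1, N, p1))
    return PowerResult(alpha=alpha, N=N, effect_size=a, power=power, critical_value=cv)
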