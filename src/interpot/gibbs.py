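"""The Gibbs distance model p(d | q, phi) and its inference primitives.

With the cellular context summarized by the state density q(d) and a
pairwise interaction potential phi(d), the NN distance of a query object is
distributed as

    p(d) = q(d) exp(-phi(d)) / Z,   Z = integral q(d) exp(-phi(d)) dd.

Z is the partition function.  Observed distances are i.i.d. under the
factorized model, so the log-likelihood of potential parameters given a
distance sample D = {d_i} is

    l = sum_i [log q(d_i) - phi(d_i)] - N log Z.

Because the model is an exponential family in the strength eps, the scalar

    T = -sum_i f((d_i - t) / sigma)

is a sufficient statistic for eps; larger T means stronger evidence of
attraction.  For the step shape, T is exactly the co-localization count.

All integrals are trapezoid quadrature on q's grid, so p, Z and l are
mutually consistent on one discretization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DistanceSample
from .potentials import shape
from .state_density import StateDensity

__all__ = [
    "ModelDensity",
    "partition_function",
    "model_density",
    "log_likelihood",
    "sample_distances",
    "sufficient_statistic",
]

#: floor applied to interpolated q inside the support, guarding log underflow
_Q_FLOOR = 1e-300


@dataclass
class ModelDensity:
    """p(d) on the state-density grid, with its partition function Z."""

    grid: np.ndarray
    density: np.ndarray
    Z: float

    def __call__(self, d) -> np.ndarray:
        return np.interp(np.asarray(d, dtype=float), self.grid, self.density, left=0.0, right=0.0)

    def cdf_grid(self) -> np.ndarray:
        dx = np.diff(self.grid)
        c = np.concatenate([[0.0], np.cumsum(dx * (self.density[1:] + self.density[:-1]) / 2.0)])
        return c / c[-1]


def _phi_on_grid(q: StateDensity, phi) -> np.ndarray:
    vals = np.asarray(phi(q.grid), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("potential is non-finite on the support of q")
    return vals


def _step_partition(q: StateDensity, phi) -> float | None:
    """Exact Z for a step potential: C0 e^eps + (1 - C0).

    The step shape is discontinuous at d = t, where trapezoid quadrature of
    q exp(-phi) would smear the jump over one grid cell; splitting the
    integral at t via the trapezoid CDF keeps Z consistent with the
    co-localization baseline to machine precision.
    """
    from .potentials import Potential  # local import to avoid cycle at module load

    if isinstance(phi, Potential) and phi.family == "step":
        from .state_density import baseline_coloc

        c0 = baseline_coloc(q, phi.t)
        return c0 * np.exp(phi.epsilon) + (1.0 - c0)
    return None


def partition_function(q: StateDensity, phi) -> float:
    """Z = integral of q(d) exp(-phi(d)) over q's support."""
    z = _step_partition(q, phi)
    if z is None:
        vals = _phi_on_grid(q, phi)
        z = float(np.trapezoid(q.density * np.exp(-vals), q.grid))
    if not (z > 0 and np.isfinite(z)):
        raise ValueError("partition function is not positive and finite")
    return z


def model_density(q: StateDensity, phi) -> ModelDensity:
    """The interacting distance distribution p(d) = q(d) exp(-phi(d)) / Z."""
    vals = _phi_on_grid(q, phi)
    weight = q.density * np.exp(-vals)
    z = partition_function(q, phi)
    return ModelDensity(grid=q.grid, density=weight / z, Z=z)


def log_likelihood(D: DistanceSample, q: StateDensity, phi) -> float:
    """l = sum_i [log q(d_i) - phi(d_i)] - N log Z.

    Distances outside q's support have zero model density; they are
    reported as an error rather than silently clamped.
    """
    lo, hi = q.support
    d = D.d
    bad = (d < lo) | (d > hi)
    if bad.any():
        raise ValueError(
            f"{bad.sum()} distance(s) outside the support [{lo:.4g}, {hi:.4g}] of q: "
            f"{np.sort(d[bad])[:10]}"
        )
    qv = np.maximum(q(d), _Q_FLOOR)
    z = partition_function(q, phi)
    return float(np.sum(np.log(qv) - np.asarray(phi(d), dtype=float)) - D.N * np.log(z))


def sample_distances(
    q: StateDensity, phi, N: int, seed=None, cell_id: str = "cell0"
) -> DistanceSample:
    """Draw N i.i.d. distances from p(d | q, phi) by inverse-CDF sampling.

    ``phi=None`` samples from the null q itself.  Accepts an integer seed or
    a numpy Generator; the draw is reproducible given the seed.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from .potentials import Potential

    if isinstance(phi, Potential) and phi.family == "step" and phi.epsilon != 0.0:
        # the step density is q rescaled piecewise around the jump at t; sample
        # the side exactly, then invert q's own CDF within the side -- this
        # avoids smearing the discontinuity over one grid cell
        from .state_density import baseline_coloc

        c0 = baseline_coloc(q, phi.t)
        z = c0 * np.exp(phi.epsilon) + (1.0 - c0)
        p_below = c0 * np.exp(phi.epsilon) / z
        below = rng.random(N) < p_below
        u = np.where(below, c0 * rng.random(N), c0 + (1.0 - c0) * rng.random(N))
    else:
        u = rng.random(N)
    if phi is None or (isinstance(phi, Potential) and phi.family == "step"):
        md_grid, md_cdf = q.grid, q.cdf_grid()
    else:
        md = model_density(q, phi)
        md_grid, md_cdf = md.grid, md.cdf_grid()
    # invert the piecewise-linear CDF; np.interp handles flat (zero-density)
    # stretches by mapping to their left edge
    d = np.interp(u, md_cdf, md_grid)
    return DistanceSample(d, cell_id=cell_id)


def sufficient_statistic(D: DistanceSample, family: str, sigma: float = 1.0, t: float = 0.0) -> float:
    """T = -sum_i f((d_i - t) / sigma); the exponential-family statistic for eps.

    Larger T indicates stronger attraction.  For ``family="step"`` and
    threshold t this is the integer count of distances below t, i.e. N * C^t.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (D.d - t) / sigma
    return float(-np.sum(shape(family, z)))
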