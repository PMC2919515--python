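"""Maximum-likelihood estimation of interaction potentials.

Three estimation problems are covered, in increasing generality:

* per-cell strength at fixed scale (1-D MLE of eps);
* per-cell (eps, sigma) by simplex search over (eps, log sigma);
* a batch of cells sharing one scale sigma* with cell-specific strengths
  eps_k, solved by a nested scheme: an outer 1-D optimization over
  log sigma* of the pooled log-likelihood, where each inner evaluation
  maximizes over every eps_k independently.

A penalized non-parametric potential (piece-wise linear hat-kernel
expansion with a Gaussian smoothness prior on successive weight
differences) is fitted jointly to all cells; its penalized log-likelihood
is strictly concave in the weights, so the quasi-Newton fit with the
analytic gradient attains the global optimum.

A Nadaraya-Watson kernel smoother for per-cell estimates against a
covariate (e.g. strength versus time post infection) rounds out the
module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .geometry import DistanceSample
from .gibbs import log_likelihood, partition_function
from .potentials import NonparametricPotential, Potential
from .state_density import StateDensity

__all__ = [
    "CellData",
    "StrengthFit",
    "CellFit",
    "PooledFit",
    "fit_strength",
    "fit_cell",
    "fit_pooled",
    "fit_nonparametric",
    "kernel_smooth",
]

#: relative objective tolerance for all optimizers
_OBJ_TOL = 1e-6
#: parameter tolerance
_PAR_TOL = 1e-4
_MAX_OUTER_ITER = 500


@dataclass
class CellData:
    """One cell's distance sample, its state density, and optional covariates."""

    cell_id: str
    D: DistanceSample
    q: StateDensity
    covariates: dict = field(default_factory=dict)


@dataclass
class StrengthFit:
    epsilon: float
    loglik: float
    stderr: float
    status: str = "converged"


@dataclass
class CellFit:
    epsilon: float
    sigma: float
    loglik: float
    stderr_epsilon: float
    stderr_sigma: float
    status: str = "converged"


@dataclass
class PooledFit:
    family: str
    sigma_star: float
    epsilons: dict
    loglik_per_cell: dict
    pooled_loglik: float
    n_params: int
    aic: float
    bic: float
    convergence: str
    iterations: int
    failed_cells: list = field(default_factory=list)


def _loglik_eps(D, q, family, sigma, t, eps):
    return log_likelihood(D, q, Potential(family, eps, sigma, t))


def fit_strength(
    D: DistanceSample, q: StateDensity, family: str, sigma: float, t: float = 0.0
) -> StrengthFit:
    """1-D MLE of the strength eps at fixed scale and shift.

    The standard error comes from the numerical observed information
    (negative second derivative of the log-likelihood at the optimum).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    def neg(eps):
        return -_loglik_eps(D, q, family, sigma, t, eps)

    # the log-likelihood is concave in eps (exponential family), so a
    # bounded Brent search over a wide interval cannot miss the optimum
    res = optimize.minimize_scalar(neg, bounds=(-50.0, 50.0), method="bounded",
                                   options={"xatol": 1e-9, "maxiter": 500})
    status = "converged" if res.success else "not_converged"
    eps = float(res.x)
    ll = -float(res.fun)
    h = 1e-4 * max(1.0, abs(eps))
    info = -(-neg(eps + h) - 2.0 * ll + -neg(eps - h)) / (h * h)
    stderr = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    return StrengthFit(eps, ll, stderr, status)


def fit_cell(
    D: DistanceSample, q: StateDensity, family: str, t: float = 0.0,
    sigma_starts=(0.5, 2.0, 8.0),
) -> CellFit:
    """Joint 2-D MLE of (eps, sigma) for one cell.

    Optimizes over (eps, log sigma) with a Nelder-Mead simplex, multi-started
    from several scales: the likelihood develops a ridge when eps is near 0
    (any sigma then fits equally well), which multi-start and an explicit
    "weakly_identified" status guard against.
    """
    if D.N < 10:
        warnings.warn(f"cell {D.cell_id!r}: only N={D.N} distances; the joint "
                      "(eps, sigma) fit may be unstable", stacklevel=2)

    def neg(theta):
        eps, logsig = theta
        if abs(eps) > 50 or abs(logsig) > 12:
            return 1e12
        return -_loglik_eps(D, q, family, math.exp(logsig), t, eps)

    best = None
    for s0 in sigma_starts:
        st = fit_strength(D, q, family, s0, t)
        res = optimize.minimize(neg, x0=[st.epsilon, math.log(s0)], method="Nelder-Mead",
                                options={"xatol": _PAR_TOL, "fatol": _OBJ_TOL,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    eps, logsig = best.x
    ll = -float(best.fun)
    # observed information from a finite-difference Hessian in (eps, log sigma)
    h = np.array([1e-4 * max(1.0, abs(eps)), 1e-4])
    H = np.zeros((2, 2))
    f0 = best.fun
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            fpp = neg(best.x + ei + ej)
            fpm = neg(best.x + ei - ej)
            fmp = neg(best.x - ei + ej)
            fmm = neg(best.x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    status = "converged" if best.success else "not_converged"
    try:
        cov = np.linalg.inv(H)
        se_eps = math.sqrt(cov[0, 0]) if cov[0, 0] > 0 else float("inf")
        se_logsig = math.sqrt(cov[1, 1]) if cov[1, 1] > 0 else float("inf")
    except np.linalg.LinAlgError:
        se_eps = se_logsig = float("inf")
        status = "weakly_identified"
    sigma = math.exp(logsig)
    if not np.isfinite(se_logsig) or se_logsig > 5.0:
        status = "weakly_identified"
    return CellFit(float(eps), sigma, ll, se_eps, se_logsig * sigma, status)


def fit_pooled(cells: list[CellData], family: str, t: float = 0.0,
               sigma_bounds=(0.05, 100.0)) -> PooledFit:
    """Common scale sigma*, per-cell strengths eps_k, by nested maximization.

    The outer problem is 1-D in log sigma*; each evaluation solves the inner
    per-cell strength MLEs at that scale (warm-started implicitly by the
    bracketing search).  The fit proceeds if at least 80% of the inner fits
    succeed; failed cells are reported and excluded from the pooled
    likelihood.
    """
    if not cells:
        raise ValueError("need at least one cell")
    n_eval = 0

    def pooled_at(logsig):
        nonlocal n_eval
        n_eval += 1
        sigma = math.exp(logsig)
        total, fails, fits = 0.0, [], {}
        for c in cells:
            st = fit_strength(c.D, c.q, family, sigma, t)
            fits[c.cell_id] = st
            if st.status != "converged":
                fails.append(c.cell_id)
            else:
                total += st.loglik
        return total, fails, fits

    def neg(logsig):
        return -pooled_at(logsig)[0]

    res = optimize.minimize_scalar(
        neg, bounds=(math.log(sigma_bounds[0]), math.log(sigma_bounds[1])),
        method="bounded", options={"xatol": _PAR_TOL, "maxiter": _MAX_OUTER_ITER})
    sigma_star = math.exp(float(res.x))
    total, fails, fits = pooled_at(float(res.x))
    if len(fails) > 0.2 * len(cells):
        raise RuntimeError(f"pooled fit failed: inner MLE did not converge for cells {fails}")
    ok = {cid: f for cid, f in fits.items() if f.status == "converged"}
    pooled_ll = sum(f.loglik for f in ok.values())
    n_params = len(ok) + 1
    n_obs = sum(c.D.N for c in cells if c.cell_id in ok)
    aic = 2 * n_params - 2 * pooled_ll
    bic = n_params * math.log(n_obs) - 2 * pooled_ll
    return PooledFit(
        family=family,
        sigma_star=sigma_star,
        epsilons={cid: f.epsilon for cid, f in ok.items()},
        loglik_per_cell={cid: f.loglik for cid, f in ok.items()},
        pooled_loglik=pooled_ll,
        n_params=n_params,
        aic=aic,
        bic=bic,
        convergence="converged" if res.success else "not_converged",
        iterations=n_eval,
        failed_cells=fails,
    )


def _hat_design(d: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Hat-kernel design matrix K[i, p] = kappa((d_i - d_p) / h), with the
    below-support clamp assigning full weight to the first support point."""
    h = support[1] - support[0]
    K = np.maximum(0.0, 1.0 - np.abs(d[:, None] - support[None, :]) / h)
    below = d < support[0]
    if below.any():
        K[below] = 0.0
        K[below, 0] = 1.0
    return K


def fit_nonparametric(
    cells: list[CellData],
    P: int = 21,
    d1: float = -5.0,
    spacing: float = 5.0,
    s: float = 2.0,
) -> NonparametricPotential:
    """Penalized joint MLE of the piece-wise linear potential.

    Maximizes  sum_k l(w | D_k) - sum_{p<P} (w_p - w_{p+1})^2 / (2 s^2)
    over (w_1 .. w_{P-1}) with w_P = 0.  The penalty is a Gaussian prior
    with standard deviation s on successive weight differences; it shrinks
    the potential toward a constant (and, through the w_P = 0 anchor,
    toward zero) where the data carry no signal.
    """
    if not cells:
        raise ValueError("need at least one cell")
    support = d1 + spacing * np.arange(P)
    # per-cell fixed quantities
    per_cell = []
    for c in cells:
        Kd = _hat_design(c.D.d, support)  # (N, P)
        Kg = _hat_design(c.q.grid, support)  # (G, P)
        per_cell.append((c, Kd.sum(axis=0), Kg))

    dmat = np.zeros((P - 1, P))  # difference operator on the free + pinned weights
    for p in range(P - 1):
        dmat[p, p], dmat[p, p + 1] = 1.0, -1.0

    def neg_and_grad(w_free):
        w = np.concatenate([w_free, [0.0]])
        total = 0.0
        grad = np.zeros(P)
        for c, kd_sum, Kg in per_cell:
            phi_grid = Kg @ w
            weight = c.q.density * np.exp(-phi_grid)
            Z = np.trapezoid(weight, c.q.grid)
            # E_p[kappa_p] under the model, by the same trapezoid rule
            tw = np.empty_like(weight)
            dx = np.diff(c.q.grid)
            tw[0] = dx[0] / 2
            tw[-1] = dx[-1] / 2
            tw[1:-1] = (dx[:-1] + dx[1:]) / 2
            Ek = (tw * weight) @ Kg / Z
            total += -(w @ kd_sum) - c.D.N * math.log(Z)
            grad += -kd_sum + c.D.N * Ek
        diffs = dmat @ w
        total -= float(diffs @ diffs) / (2.0 * s * s)
        grad -= (dmat.T @ diffs) / (s * s)
        return -total, -grad[: P - 1]

    res = optimize.minimize(neg_and_grad, x0=np.zeros(P - 1), jac=True, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8})
    w = np.concatenate([res.x, [0.0]])
    pot = NonparametricPotential(support, w, smoothness=s)
    pot.converged = bool(res.success)
    pot.penalized_loglik = -float(res.fun) + sum(
        float(np.sum(np.log(np.maximum(c.q(c.D.d), 1e-300)))) for c, _, _ in per_cell
    )
    return pot


def nonparametric_objective(cells: list[CellData], pot: NonparametricPotential,
                            s: float | None = None) -> float:
    """Penalized joint log-likelihood of a non-parametric potential.

    The likelihood term uses the full log-likelihood (including the fixed
    sum of log q terms), so values are directly comparable across weight
    vectors but not across datasets.
    """
    s = pot.smoothness if s is None else s
    ll = sum(log_likelihood(c.D, c.q, pot) for c in cells)
    diffs = np.diff(pot.weights)
    return ll - float(diffs @ diffs) / (2.0 * s * s)


def kernel_smooth(x, y, bandwidth: float, x_query=None, n_query: int = 200):
    """Nadaraya-Watson Gaussian-kernel regression with a local-sd band.

    Returns (x_query, mean, sd): the kernel-weighted local mean of y and the
    same-weights local standard deviation.  Query points whose total kernel
    weight underflows are omitted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points to smooth")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if x_query is None:
        x_query = np.linspace(x.min(), x.max(), n_query)
    x_query = np.asarray(x_query, dtype=float)
    w = np.exp(-0.5 * ((x_query[:, None] - x[None, :]) / bandwidth) ** 2)
    tot = w.sum(axis=1)
    keep = tot >= 1e-12
    w, tot, xq = w[keep], tot[keep], x_query[keep]
    mean = (w @ y) / tot
    dev = y[None, :] - mean[:, None]
    var = np.sum(w * dev * dev, axis=1) / tot
    sd = np.sqrt(np.maximum(var, 0.0))
    return xq, mean, sd
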