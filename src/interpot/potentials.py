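"""Interaction potential families phi(d) = eps * f((d - t) / sigma).

The strength eps, shape f, length scale sigma and shift t represent the
three aspects of a pairwise interaction independently.  All shapes follow
the attractive convention: f <= 0 near the origin with depth -1 and
f -> 0 as z -> +inf, so a positive strength eps means attraction toward the
reference objects and the potential is anchored at phi(+inf) = 0 (the
model density is invariant to an additive constant, so this anchoring is a
pure gauge choice).

Families
--------
step      : f(z) = -1 for z < 0, else 0.  The implicit model behind the
            classical threshold co-localization measure.
plummer   : f(z) = -1 for z <= 0, -1 / sqrt(1 + z^2) above.  Finite value
            and slope everywhere (C1 at 0), plateau -1 below the origin,
            ~1/z tail: a smooth generalization of the step.
hermquist : f(z) = -1/(1 + z) for z >= 0, C1-continued linearly below 0.
            Slow 1/z decay; the long-range shape.
linear1   : f(z) = min(z - 1, 0).  Linear rise, no plateau.
linear2   : f(z) = -1 for z <= 0, z - 1 on (0, 1), 0 for z >= 1.  A step
            potential with a linear ramp and a plateau below d = 0.

A piece-wise linear non-parametric potential is also provided: a weighted
sum of triangular (hat) kernels on equally spaced support points, i.e. the
linear interpolant through (d_p, w_p), clamped to w_1 below the first
support point and pinned to 0 at and beyond the last (w_P = 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["FAMILIES", "shape", "Potential", "NonparametricPotential"]


def _f_step(z):
    return np.where(z < 0, -1.0, 0.0)


def _f_plummer(z):
    # plateau at -1 below the origin, 1/z tail above; C1 at z = 0 since the
    # Plummer branch -1/sqrt(1+z^2) has zero slope there
    zp = np.maximum(z, 0.0)
    return np.where(z < 0, -1.0, -1.0 / np.sqrt(1.0 + zp * zp))


def _f_hermquist(z):
    return np.where(z >= 0, -1.0 / (1.0 + np.maximum(z, 0.0)), -1.0 + z)


def _f_linear1(z):
    return np.minimum(z - 1.0, 0.0)


def _f_linear2(z):
    return np.clip(z - 1.0, -1.0, 0.0)


FAMILIES = {
    "step": _f_step,
    "plummer": _f_plummer,
    "hermquist": _f_hermquist,
    "linear1": _f_linear1,
    "linear2": _f_linear2,
}


def shape(family: str, z) -> np.ndarray:
    """Evaluate the dimensionless shape function f of a named family."""
    try:
        f = FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown potential family {family!r}; known: {sorted(FAMILIES)}") from None
    return f(np.asarray(z, dtype=float))


@dataclass(frozen=True)
class Potential:
    """Parametric potential phi(d) = epsilon * f((d - t) / sigma)."""

    family: str
    epsilon: float = 0.0
    sigma: float = 1.0
    t: float = 0.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown potential family {self.family!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def __call__(self, d) -> np.ndarray:
        z = (np.asarray(d, dtype=float) - self.t) / self.sigma
        return self.epsilon * shape(self.family, z)

    def to_json(self) -> str:
        return json.dumps(
            {"family": self.family, "epsilon": self.epsilon, "sigma": self.sigma, "t": self.t}
        )

    @classmethod
    def from_json(cls, s: str) -> "Potential":
        return cls(**json.loads(s))


def evaluate(pot, d):
    """Evaluate a potential (parametric, non-parametric, or plain callable)."""
    return pot(d)


class NonparametricPotential:
    """Piece-wise linear potential: hat-kernel expansion on support points.

    phi(d) = sum_p w_p * max(0, 1 - |d - d_p| / h) with equally spaced
    support points d_p; the last weight is pinned to zero so phi vanishes
    at and beyond d_P.
    """

    def __init__(self, support_points, weights, smoothness: float = 2.0):
        sp = np.asarray(support_points, dtype=float)
        w = np.asarray(weights, dtype=float)
        if sp.ndim != 1 or sp.size < 2:
            raise ValueError("need at least two support points")
        steps = np.diff(sp)
        if not np.all(steps > 0):
            raise ValueError("support points must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise ValueError("support points must be equally spaced")
        if w.shape != sp.shape:
            raise ValueError("weights and support points must have the same length")
        if abs(w[-1]) > 1e-12:
            raise ValueError("the last weight w_P must be 0 (anchors phi at 0)")
        self.support_points = sp
        self.weights = w
        self.kernel_spacing = float(steps[0])
        self.smoothness = float(smoothness)

    @classmethod
    def default_grid(cls, weights=None, P: int = 21, d1: float = -5.0, spacing: float = 5.0,
                     smoothness: float = 2.0) -> "NonparametricPotential":
        """The default support layout: P = 21 points from -5 to 95, h = 5 px."""
        sp = d1 + spacing * np.arange(P)
        if weights is None:
            weights = np.zeros(P)
        return cls(sp, weights, smoothness)

    def __call__(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        # hat-kernel sum == linear interpolation through (d_p, w_p);
        # constant w_1 below d_1, exactly 0 at and beyond d_P since w_P = 0
        return np.interp(d, self.support_points, self.weights,
                         left=self.weights[0], right=0.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "support_points": self.support_points.tolist(),
                "weights": self.weights.tolist(),
                "h": self.kernel_spacing,
                "s": self.smoothness,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "NonparametricPotential":
        obj = json.loads(s)
        return cls(obj["support_points"], obj["weights"], obj.get("s", 2.0))
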