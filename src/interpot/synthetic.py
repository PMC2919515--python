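"""Synthetic cellular contexts and object sets with known ground truth.

The canonical benchmark context is M = 100 circular reference objects of
radius R = 3.57 placed uniformly at random in a 200 x 200 square domain,
giving a nominal circle-covered area fraction M pi R^2 / area = 0.1.
Regular (perturbed lattice) and clustered (Thomas parent/offspring)
placements probe how the context shapes the state density.

Query points are placed by exact rejection sampling from the factorized
interaction model: a uniform proposal in Omega is accepted with probability
exp(-(phi(d) - phi_min)), so the accepted positions follow a density
proportional to exp(-phi(d(x, Y))) and the resulting NN distances follow
p(d) = q(d) exp(-phi(d)) / Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import CellData
from .geometry import Domain, DistanceSample, ObjectSet, PolygonRef, signed_nn_distances
from .state_density import StateDensity, estimate_state_density

__all__ = ["ScenarioSpec", "generate_circles", "place_points", "generate_scenario",
            "circle_polygon", "nominal_covered_fraction"]

#: vertices used to render a circle as a polygon
CIRCLE_VERTICES = 64


@dataclass
class ScenarioSpec:
    """Declarative description of a synthetic scenario."""

    domain_size: tuple[float, float] = (200.0, 200.0)
    M: int = 100
    R: float = 3.57
    arrangement: str = "random"  # random | regular | clustered
    N: int = 100
    true_potential: object = None
    seed: int | None = None
    # clustered-mode knobs
    n_parents: int = 10
    offspring_sd: float = 10.0
    # regular-mode jitter as a fraction of the lattice spacing
    jitter_frac: float = 0.05

    def __post_init__(self):
        w, h = self.domain_size
        if self.M < 1 or self.R <= 0:
            raise ValueError("need M >= 1 circles of positive radius")
        if self.M * np.pi * self.R**2 >= w * h:
            raise ValueError("circles cannot nominally exceed the domain area")
        if self.N < 1:
            raise ValueError("need at least one query point (N >= 1)")
        if self.arrangement not in ("random", "regular", "clustered"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")


def nominal_covered_fraction(spec: ScenarioSpec) -> float:
    """M pi R^2 / |Omega|: the nominal (overlap-ignoring) covered area fraction."""
    w, h = spec.domain_size
    return spec.M * np.pi * spec.R**2 / (w * h)


def circle_polygon(center, radius: float, vertices: int = CIRCLE_VERTICES) -> PolygonRef:
    """A circle rendered as a regular polygon (max radial error R(1 - cos(pi/V)))."""
    ang = 2 * np.pi * np.arange(vertices) / vertices
    cx, cy = center
    return PolygonRef(np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)]))


def _centers(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    w, h = spec.domain_size
    if spec.arrangement == "random":
        return rng.uniform([0, 0], [w, h], size=(spec.M, 2))
    if spec.arrangement == "regular":
        side = int(np.ceil(np.sqrt(spec.M)))
        sx, sy = w / side, h / side
        if min(sx, sy) < 2 * spec.R:
            raise ValueError("regular arrangement infeasible: lattice spacing < circle diameter")
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        pts = np.column_stack([(gx.ravel() + 0.5) * sx, (gy.ravel() + 0.5) * sy])[: spec.M]
        jitter = rng.normal(0.0, spec.jitter_frac * min(sx, sy), size=pts.shape)
        return np.clip(pts + jitter, [spec.R, spec.R], [w - spec.R, h - spec.R])
    # clustered: Thomas-style parent/offspring placement
    parents = rng.uniform([0, 0], [w, h], size=(spec.n_parents, 2))
    assign = rng.integers(0, spec.n_parents, size=spec.M)
    pts = parents[assign] + rng.normal(0.0, spec.offspring_sd, size=(spec.M, 2))
    return np.mod(pts, [w, h])  # wrap to keep all M circles in the domain


def generate_circles(spec: ScenarioSpec, rng: np.random.Generator | None = None):
    """Place the reference circles; returns (list of PolygonRef, Domain)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    centers = _centers(spec, rng)
    Y = [circle_polygon(c, spec.R) for c in centers]
    w, h = spec.domain_size
    return Y, Domain.rectangle(w, h)


def place_points(
    domain: Domain,
    Y,
    phi,
    N: int,
    rng: np.random.Generator | int | None = None,
    batch: int = 4096,
    min_acceptance: float = 1e-4,
) -> np.ndarray:
    """Rejection-sample N query points from the factorized interaction model.

    ``phi=None`` places points uniformly in Omega.  Raises when the
    acceptance rate collapses below ``min_acceptance`` (potential too deep
    or badly scaled for rejection sampling).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    w, h = domain.bounding_box
    if phi is not None:
        # conservative lower bound of phi over achievable distances: signed
        # distances cannot drop below -(largest polygon circumradius)
        d_lo = 0.0
        for ref in Y:
            if isinstance(ref, PolygonRef):
                v = ref.vertices
                d_lo = min(d_lo, -float(np.max(np.linalg.norm(v - v.mean(axis=0), axis=1))))
        dgrid = np.linspace(d_lo, np.hypot(w, h), 4097)
        phi_min = float(np.min(phi(dgrid)))
        if not np.isfinite(phi_min):
            raise ValueError("potential unbounded below; rejection sampling impossible")
    out = []
    proposed = accepted = 0
    while sum(len(o) for o in out) < N:
        pts = rng.uniform([0, 0], [w, h], size=(batch, 2))
        pts = pts[domain.contains(pts)]
        if len(pts) == 0:
            proposed += batch
            continue
        if phi is None:
            keep = pts
        else:
            d = signed_nn_distances(pts, Y)
            p_acc = np.exp(-(np.asarray(phi(d), dtype=float) - phi_min))
            keep = pts[rng.random(len(pts)) < p_acc]
        proposed += batch
        accepted += len(keep)
        out.append(keep)
        if proposed > 50 * batch and accepted / proposed < min_acceptance:
            raise RuntimeError(
                f"rejection sampling acceptance rate {accepted / proposed:.2e} < "
                f"{min_acceptance}; reduce the potential depth or use a tighter bound")
    return np.concatenate(out)[:N]


def generate_scenario(spec: ScenarioSpec, grid_spacing: float = 0.25,
                      q: StateDensity | None = None) -> CellData:
    """Compose a full synthetic cell: context, q, points, distances, truth.

    Returns a CellData whose covariates carry the ground truth
    (``true_potential``) and the generated objects (``objects``, ``domain``).
    A precomputed ``q`` for the same context may be supplied to skip the
    grid sampling.
    """
    rng = np.random.default_rng(spec.seed)
    Y, domain = generate_circles(spec, rng)
    if q is None:
        q = estimate_state_density(domain, Y, grid_spacing=grid_spacing)
    X = place_points(domain, Y, spec.true_potential, spec.N, rng)
    objs = ObjectSet(X, Y, cell_id=f"synthetic-{spec.seed}")
    D = DistanceSample(signed_nn_distances(X, Y), cell_id=objs.cell_id)
    return CellData(
        cell_id=objs.cell_id,
        D=D,
        q=q,
        covariates={"true_potential": spec.true_potential, "objects": objs,
                    "domain": domain, "spec": spec},
    )
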