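"""Normalized quadrature measures on closed intervals.

A :class:`Measure` is a probability measure represented by quadrature
nodes and non-negative weights summing to one.  Averaging operators such
as ``A_x f = ∫ f(x, .) dμ(x)`` are evaluated by contracting function
values at the nodes against the weights, so a Lebesgue measure is simply
a normalized Gauss–Legendre rule and an empirical measure puts equal
mass on the observed sample points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Measure", "make_measure"]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class Measure:
    """Probability measure on an interval, given as a quadrature rule.

    Attributes
    ----------
    kind : {"lebesgue", "empirical", "custom"}
    nodes : ndarray
        Quadrature abscissae, all inside ``domain``.
    weights : ndarray
        Non-negative weights summing to 1 (to 1e-12).
    domain : (float, float)
        Closed interval carrying the measure.
    """

    kind: str
    nodes: np.ndarray
    weights: np.ndarray
    domain: tuple[float, float] = field(default=(0.0, 1.0))

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.shape != weights.shape:
            raise ValueError("nodes and weights must be 1-d arrays of equal length")
        if np.any(weights < -_WEIGHT_TOL):
            raise ValueError("measure weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"measure weights sum to {weights.sum():.12g}, expected 1 "
                "(probability measure)"
            )
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"degenerate domain [{lo}, {hi}]")
        eps = 1e-12 * max(1.0, abs(lo), abs(hi))
        if nodes.min() < lo - eps or nodes.max() > hi + eps:
            raise ValueError("measure nodes fall outside the stated domain")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @property
    def mean(self) -> float:
        """First moment ∫ x dμ(x)."""
        return float(self.weights @ self.nodes)

    def integrate(self, f) -> float:
        """∫ f dμ by the stored rule; `f` is vectorized over nodes."""
        vals = np.asarray(f(self.nodes), dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = self.nodes[~np.isfinite(vals)][0]
            raise ValueError(f"non-finite integrand value at node {bad!r}")
        return float(self.weights @ vals)


def make_measure(
    kind: str,
    domain: tuple[float, float] = (0.0, 1.0),
    order: int = 32,
    sample: np.ndarray | None = None,
) -> Measure:
    """Build a normalized measure on ``domain``.

    ``lebesgue`` uses a Gauss–Legendre rule of the given order, rescaled
    to the interval and normalized to total mass 1 (uniform probability
    measure); ``empirical`` puts weight 1/n on each sample point.
    """
    lo, hi = float(domain[0]), float(domain[1])
    if not lo < hi:
        raise ValueError(f"degenerate domain [{lo}, {hi}]")
    if kind == "lebesgue":
        if order < 2:
            raise ValueError("quadrature order must be >= 2")
        x, w = np.polynomial.legendre.leggauss(int(order))
        nodes = 0.5 * (hi - lo) * (x + 1.0) + lo
        weights = w / w.sum()
        return Measure("lebesgue", nodes, weights, (lo, hi))
    if kind == "empirical":
        if sample is None or len(sample) == 0:
            raise ValueError("empirical measure requires a non-empty sample")
        nodes = np.asarray(sample, dtype=float)
        if nodes.min() < lo or nodes.max() > hi:
            raise ValueError("sample points outside domain")
        weights = np.full(nodes.shape, 1.0 / nodes.size)
        return Measure("empirical", nodes, weights, (lo, hi))
    raise ValueError(f"unknown measure kind {kind!r}")
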