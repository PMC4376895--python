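"""Averaging operators applied to functions and to reproducing kernels.

The ANOVA projectors are built from the two averaging operators

    A_y f(x) = ∫ f(x, y) dμ_y(y)      A_x f(y) = ∫ f(x, y) dμ_x(x)

evaluated by the quadrature rule stored in each :class:`Measure`.  The
six operator combinations used by the decomposition are named

    "Ax", "Ay", "AxAy", "Ay(1-Ax)", "Ax(1-Ay)", "(1-Ax)(1-Ay)"

Applied to a reproducing kernel section R(., .; x_i, y_i) they yield the
averaged kernels whose weighted sums give the intercept, main-effect and
interaction components of a fitted spline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .kernels import Kernel
from .measures import Measure, make_measure

__all__ = ["average_function", "average_kernel", "AveragedKernel", "WHICH"]

WHICH = ("Ax", "Ay", "AxAy", "Ay(1-Ax)", "Ax(1-Ay)", "(1-Ax)(1-Ay)")


def _check_finite(vals: np.ndarray, pts) -> None:
    vals = np.asarray(vals)
    if not np.all(np.isfinite(vals)):
        nodes = np.broadcast_to(np.asarray(pts), vals.shape)
        bad = nodes[~np.isfinite(vals)].ravel()
        raise ValueError(
            f"non-finite function value at quadrature node {bad[0]!r}"
        )


def average_function(
    f: Callable, which: str, measures: Sequence[Measure]
) -> Callable:
    """Apply an averaging-operator combination to a bivariate function.

    Returns a vectorized function of the remaining variable(s); for
    "AxAy" the result is a constant function (of anything).
    """
    mx, my = measures
    wx, xq = mx.weights, mx.nodes
    wy, yq = my.weights, my.nodes

    def Ay(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        vals = np.asarray(f(x[:, None], yq[None, :]), dtype=float)
        _check_finite(vals, np.broadcast_to(yq, vals.shape))
        return vals @ wy

    def Ax(y):
        y = np.atleast_1d(np.asarray(y, dtype=float))
        vals = np.asarray(f(xq[None, :], y[:, None]), dtype=float)
        _check_finite(vals, np.broadcast_to(xq, vals.shape))
        return vals @ wx

    def AxAy():
        vals = np.asarray(f(xq[:, None], yq[None, :]), dtype=float)
        _check_finite(vals, vals)
        return float(wx @ vals @ wy)

    if which == "Ay":
        return lambda x: Ay(x)
    if which == "Ax":
        return lambda y: Ax(y)
    if which == "AxAy":
        c = AxAy()
        return lambda *args: np.full(np.shape(args[0]) if args else (), c)
    if which == "Ay(1-Ax)":
        c = AxAy()
        return lambda x: Ay(x) - c
    if which == "Ax(1-Ay)":
        c = AxAy()
        return lambda y: Ax(y) - c
    if which == "(1-Ax)(1-Ay)":
        c = AxAy()
        return lambda x, y: (
            np.asarray(f(x, y), dtype=float)
            - Ay(np.asarray(x, dtype=float).ravel()).reshape(np.shape(x))
            - Ax(np.asarray(y, dtype=float).ravel()).reshape(np.shape(y))
            + c
        )
    raise ValueError(f"unknown operator combination {which!r}; expected one of {WHICH}")


@dataclass
class AveragedKernel:
    """An averaging-operator combination applied to a bivariate kernel.

    ``sections(points, sources)`` evaluates the averaged kernel as a
    function of the non-integrated argument(s) at ``points`` with the
    source (second kernel argument) fixed at each row of ``sources``;
    shape (n_points, n_sources).  For "AxAy" pass ``points=None`` to get
    one scalar per source.
    """

    base: Kernel
    which: str
    measures: tuple[Measure, Measure]

    def sections(self, points, sources) -> np.ndarray:
        sources = np.atleast_2d(np.asarray(sources, dtype=float))
        k, (mx, my) = self.base, self.measures
        which = self.which

        def full(P):
            return k.gram(P, sources)

        def Ay_rows(xs):
            xs = np.atleast_1d(np.asarray(xs, dtype=float))
            P = np.column_stack(
                [np.repeat(xs, my.nodes.size), np.tile(my.nodes, xs.size)]
            )
            G = k.gram(P, sources).reshape(xs.size, my.nodes.size, -1)
            return np.tensordot(my.weights, G, axes=(0, 1))

        def Ax_rows(ys):
            ys = np.atleast_1d(np.asarray(ys, dtype=float))
            P = np.column_stack(
                [np.tile(mx.nodes, ys.size), np.repeat(ys, mx.nodes.size)]
            )
            G = k.gram(P, sources).reshape(ys.size, mx.nodes.size, -1)
            return np.tensordot(mx.weights, G, axes=(0, 1))

        def AxAy_row():
            P = np.column_stack(
                [np.repeat(mx.nodes, my.nodes.size), np.tile(my.nodes, mx.nodes.size)]
            )
            G = k.gram(P, sources).reshape(mx.nodes.size, my.nodes.size, -1)
            return np.einsum("i,j,ijk->k", mx.weights, my.weights, G)

        if which == "Ay":
            return Ay_rows(points)
        if which == "Ax":
            return Ax_rows(points)
        if which == "AxAy":
            return AxAy_row()[None, :]
        if which == "Ay(1-Ax)":
            return Ay_rows(points) - AxAy_row()[None, :]
        if which == "Ax(1-Ay)":
            return Ax_rows(points) - AxAy_row()[None, :]
        if which == "(1-Ax)(1-Ay)":
            P = np.atleast_2d(np.asarray(points, dtype=float))
            return (
                full(P)
                - Ay_rows(P[:, 0])
                - Ax_rows(P[:, 1])
                + AxAy_row()[None, :]
            )
        raise ValueError(f"unknown operator combination {which!r}")


def _refined(measure: Measure, factor: int) -> Measure:
    if measure.kind != "lebesgue":
        return measure
    return make_measure(
        "lebesgue", measure.domain, order=measure.nodes.size * factor
    )


def average_kernel(
    kernel: Kernel,
    which: str,
    measures: Sequence[Measure],
    check: bool = False,
    check_tol: float = 1e-6,
) -> AveragedKernel:
    """Averaged kernel under the given measures.

    With ``check=True`` the quadrature is verified by doubling the
    Gauss–Legendre order on a probe set of source points; on
    disagreement beyond ``check_tol`` the rule is refined once (warning)
    and an error is raised if the refined rule still disagrees.
    """
    if kernel.dim != 2:
        raise ValueError("average_kernel expects a bivariate kernel")
    if which not in WHICH:
        raise ValueError(f"unknown operator combination {which!r}")
    mx, my = measures
    ak = AveragedKernel(kernel, which, (mx, my))
    if not check:
        return ak
    rng = np.random.default_rng(0)
    lo = np.array([d[0] for d in kernel.domain])
    hi = np.array([d[1] for d in kernel.domain])
    probe = lo + (hi - lo) * rng.random((5, 2))
    pts = None if which == "AxAy" else probe[:, 0]
    if which in ("Ax", "Ax(1-Ay)"):
        pts = probe[:, 1]
    elif which == "(1-Ax)(1-Ay)":
        pts = probe
    for attempt in range(2):
        fine = AveragedKernel(kernel, which, (_refined(mx, 2), _refined(my, 2)))
        delta = np.max(np.abs(ak.sections(pts, probe) - fine.sections(pts, probe)))
        if delta <= check_tol:
            return ak
        if attempt == 0:
            warnings.warn(
                f"quadrature disagreement {delta:.2e} for {which}; refining once",
                stacklevel=2,
            )
            mx, my = _refined(mx, 2), _refined(my, 2)
            ak = AveragedKernel(kernel, which, (mx, my))
    raise RuntimeError(
        f"averaged kernel quadrature failed to converge for {which} "
        f"(residual {delta:.2e} > {check_tol:.1e})"
    )
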