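"""Functional ANOVA decomposition of fitted bivariate splines.

Two routes to the same decomposition
``f(x,y) = c + f_x(x) + f_y(y) + f_xy(x,y)``:

* :func:`posthoc_decompose` applies the averaging operators to *any*
  fitted bivariate spline (for instance a thin-plate spline) by
  integrating the reproducing-kernel sections and the null-space basis
  functions numerically.  Each component is a weighted sum of averaged
  kernels, linear in the fitted coefficients, so its pointwise posterior
  variance follows from the joint coefficient covariance by
  ``var = M Sigma M'`` (for the intercept this is the
  ``R0 Sigma_alpha R0'`` formula with ``R0_ij = A_x A_y R(.,.;x_i,y_i)``).
* :func:`classic_ssanova` fits the tensor-product block model in which
  the four subspaces are separate kernel blocks, and reads the
  components directly off the blocks.

When the fitted kernel *is* a tensor product (and the same measures are
used), the two routes agree identically — the post-hoc operators project
exactly onto the blocks.

Component conventions: main effects have zero mean under the
decomposition measures and the interaction has zero marginals; the
components sum to the fitted surface by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fitting import FittedSpline, Observations, PenalizedSystem, select_lambda
from .kernels import (
    MarginalCubicKernel,
    TensorProductKernel,
    center_marginal,
    make_marginal_kernel,
)
from .measures import Measure, make_measure

__all__ = [
    "Component",
    "Decomposition",
    "posthoc_decompose",
    "component_variance",
    "classic_ssanova",
    "significance_mask",
    "LABELS",
]

LABELS = ("intercept", "main_x", "main_y", "interaction")


@dataclass
class Component:
    """One ANOVA component of a fitted spline.

    The component is the linear functional ``rows(points) @ coef`` of
    the fitted coefficients; the same row matrix propagates the joint
    coefficient covariance into pointwise posterior variances.  Row
    matrices are cached per evaluation grid, so re-evaluating on the
    same grid is bit-identical.
    """

    label: str
    rows_fn: Callable[[np.ndarray | None], np.ndarray]
    coef: np.ndarray
    cov: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False)

    def row_matrix(self, points=None) -> np.ndarray:
        key = (
            None
            if points is None
            else np.ascontiguousarray(np.asarray(points, dtype=float)).tobytes()
        )
        if key not in self._cache:
            self._cache[key] = self.rows_fn(points)
        return self._cache[key]

    def evaluate(self, points=None) -> np.ndarray:
        return self.row_matrix(points) @ self.coef

    def variance(self, points=None) -> np.ndarray:
        M = self.row_matrix(points)
        return np.maximum(np.einsum("ij,jk,ik->i", M, self.cov, M), 0.0)

    def sd(self, points=None) -> np.ndarray:
        return np.sqrt(self.variance(points))


@dataclass
class Decomposition:
    """The four ANOVA components of one fitted bivariate spline."""

    components: dict[str, Component]
    fit: FittedSpline
    measures: tuple[Measure, Measure]

    def __getitem__(self, label: str) -> Component:
        if label not in self.components:
            raise KeyError(f"unknown component {label!r}; have {LABELS}")
        return self.components[label]

    def evaluate_sum(self, points: np.ndarray) -> np.ndarray:
        """c + f_x + f_y + f_xy at 2-d points (reconstructs the fit)."""
        P = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(P.shape[0], float(self["intercept"].evaluate()[0]))
        out += self["main_x"].evaluate(P[:, 0])
        out += self["main_y"].evaluate(P[:, 1])
        out += self["interaction"].evaluate(P)
        return out


def _averaged_row_builders(fit: FittedSpline, measures):
    """Row-matrix builders for the averaged design of a bivariate fit."""
    mx, my = measures

    def full_rows(P):
        return fit.design_rows(P)

    def Ay_rows(xs):
        xs = np.atleast_1d(np.asarray(xs, dtype=float)).ravel()
        P = np.column_stack(
            [np.repeat(xs, my.nodes.size), np.tile(my.nodes, xs.size)]
        )
        M = fit.design_rows(P).reshape(xs.size, my.nodes.size, -1)
        return np.tensordot(my.weights, M, axes=(0, 1))

    def Ax_rows(ys):
        ys = np.atleast_1d(np.asarray(ys, dtype=float)).ravel()
        P = np.column_stack(
            [np.tile(mx.nodes, ys.size), np.repeat(ys, mx.nodes.size)]
        )
        M = fit.design_rows(P).reshape(ys.size, mx.nodes.size, -1)
        return np.tensordot(mx.weights, M, axes=(0, 1))

    def AxAy_row():
        P = np.column_stack(
            [
                np.repeat(mx.nodes, my.nodes.size),
                np.tile(my.nodes, mx.nodes.size),
            ]
        )
        M = fit.design_rows(P).reshape(mx.nodes.size, my.nodes.size, -1)
        return np.einsum("i,j,ijk->k", mx.weights, my.weights, M)

    return full_rows, Ay_rows, Ax_rows, AxAy_row


def posthoc_decompose(
    fit: FittedSpline, measures: Sequence[Measure] | None = None
) -> Decomposition:
    """SS-ANOVA decomposition of an arbitrary fitted bivariate spline.

    The averaging operators act on the whole fitted function — kernel
    part and null-space part alike — so e.g. the unpenalized plane of a
    thin-plate fit contributes its measure-mean to the intercept and its
    centered linear parts to the main effects.
    """
    if fit.kernel.dim != 2:
        raise NotImplementedError(
            "post-hoc decomposition is implemented for bivariate fits; "
            "for a bivariate term inside a larger additive model use "
            "amm.decompose_pair"
        )
    if measures is None:
        measures = tuple(
            make_measure("lebesgue", dom, order=32) for dom in fit.kernel.domain
        )
    mx, my = measures
    full_rows, Ay_rows, Ax_rows, AxAy_row = _averaged_row_builders(fit, measures)
    r0 = AxAy_row()

    def intercept_rows(points=None):
        return r0[None, :]

    def main_x_rows(xs):
        return Ay_rows(xs) - r0[None, :]

    def main_y_rows(ys):
        return Ax_rows(ys) - r0[None, :]

    def interaction_rows(P):
        P = np.atleast_2d(np.asarray(P, dtype=float))
        return full_rows(P) - Ay_rows(P[:, 0]) - Ax_rows(P[:, 1]) + r0[None, :]

    coef, cov = fit.coef, fit.cov
    comps = {
        "intercept": Component("intercept", intercept_rows, coef, cov),
        "main_x": Component("main_x", main_x_rows, coef, cov),
        "main_y": Component("main_y", main_y_rows, coef, cov),
        "interaction": Component("interaction", interaction_rows, coef, cov),
    }
    return Decomposition(comps, fit, (mx, my))


def component_variance(
    fit: FittedSpline,
    component_label: str,
    points,
    measures: Sequence[Measure] | None = None,
) -> np.ndarray:
    """Pointwise posterior variance of one ANOVA component."""
    decomp = posthoc_decompose(fit, measures)
    return decomp[component_label].variance(points)


def significance_mask(component: Component, points, k: float = 2.0) -> np.ndarray:
    """Pointwise significance: True where |mean| >= k * sd (inclusive)."""
    mean = component.evaluate(points)
    sd = component.sd(points)
    return np.abs(mean) >= k * sd


def _tensor_block_decomposition(
    fit: FittedSpline, measures: tuple[Measure, Measure]
) -> Decomposition:
    """Read components directly off the blocks of a tensor-product fit."""
    kern: TensorProductKernel = fit.kernel  # type: ignore[assignment]
    reps = fit.representers
    p = fit.beta.size
    m = fit.alpha.size
    _, tx, ty, txy = kern.theta

    def pad(K):
        return np.hstack([K, np.zeros((K.shape[0], p))])

    def intercept_rows(points=None):
        row = np.zeros((1, m + p))
        if p:
            row[0, m] = 1.0  # unpenalized constant
        return row

    def main_x_rows(xs):
        xs = np.atleast_1d(np.asarray(xs, dtype=float)).ravel()
        return pad(tx * kern.kx.gram(xs, reps[:, 0]))

    def main_y_rows(ys):
        ys = np.atleast_1d(np.asarray(ys, dtype=float)).ravel()
        return pad(ty * kern.ky.gram(ys, reps[:, 1]))

    def interaction_rows(P):
        P = np.atleast_2d(np.asarray(P, dtype=float))
        Gx = kern.kx.gram(P[:, 0], reps[:, 0])
        Gy = kern.ky.gram(P[:, 1], reps[:, 1])
        return pad(txy * Gx * Gy)

    coef, cov = fit.coef, fit.cov
    comps = {
        "intercept": Component("intercept", intercept_rows, coef, cov),
        "main_x": Component("main_x", main_x_rows, coef, cov),
        "main_y": Component("main_y", main_y_rows, coef, cov),
        "interaction": Component("interaction", interaction_rows, coef, cov),
    }
    return Decomposition(comps, fit, measures)


DEFAULT_THETA_GRID = 10.0 ** np.arange(-2.0, 3.5, 1.0)


def marginal_knots(values: np.ndarray, k: int) -> np.ndarray:
    """k quantile-spread knots over the observed values of one covariate."""
    return np.unique(np.quantile(values, np.linspace(0.0, 1.0, k)))


def classic_ssanova(
    obs: Observations,
    kernels: Sequence[MarginalCubicKernel] | None = None,
    measures: Sequence[Measure] | None = None,
    criterion: str = "gcv",
    theta_grid: np.ndarray | None = None,
    refine: bool = True,
    knots_per_axis: int = 10,
):
    """Tensor-product SS-ANOVA fit with per-block penalty weights.

    The representer basis is the cross product of ``knots_per_axis``
    quantile knots per marginal (the usual low-rank cubic regression
    basis).  The intercept block is unpenalized (theta_0 = inf); the
    remaining block weights are selected on a log grid jointly with the
    overall smoothing parameter, which is profiled out by the selection
    criterion at each grid point (theta_x is fixed at 1 — the overall
    scale is redundant with lambda).  Returns the fitted tensor spline
    and its block-wise decomposition.
    """
    if obs.d != 2:
        raise ValueError("classic_ssanova expects bivariate observations")
    if kernels is None:
        doms = [
            (float(obs.x[:, j].min()), float(obs.x[:, j].max())) for j in range(2)
        ]
        kernels = [make_marginal_kernel(doms[0]), make_marginal_kernel(doms[1])]
    if measures is None:
        measures = tuple(
            make_measure("lebesgue", k.domain[0], order=32) for k in kernels
        )
    mx, my = measures
    bx = center_marginal(kernels[0], mx)
    by = center_marginal(kernels[1], my)
    if theta_grid is None:
        theta_grid = DEFAULT_THETA_GRID
    theta_grid = np.asarray(theta_grid, dtype=float)

    x = obs.x
    n = obs.n
    kx_knots = marginal_knots(x[:, 0], knots_per_axis)
    ky_knots = marginal_knots(x[:, 1], knots_per_axis)
    KX, KY = np.meshgrid(kx_knots, ky_knots, indexing="ij")
    reps = np.column_stack([KX.ravel(), KY.ravel()])
    Gx = bx.gram(x[:, 0], reps[:, 0])
    Gy = by.gram(x[:, 1], reps[:, 1])
    Gxy = Gx * Gy
    Px = bx.gram(reps[:, 0], reps[:, 0])
    Py = by.gram(reps[:, 1], reps[:, 1])
    Pxy = Px * Py
    T = np.ones((n, 1))
    T_rep = np.ones((reps.shape[0], 1))

    from .fitting import Design  # local import to avoid cycle at module load

    def try_theta(ty_, txy_):
        K = Gx + ty_ * Gy + txy_ * Gxy
        P = Px + ty_ * Py + txy_ * Pxy
        P = 0.5 * (P + P.T)
        design = Design(
            J=K, T=T, P=P, T_rep=T_rep, representers=reps, constrain=False
        )
        system = PenalizedSystem(design, obs.z, obs.weights)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam = select_lambda(system, criterion)
        return system.criterion(lam, criterion), lam, system

    best = None
    for ty_ in theta_grid:
        for txy_ in theta_grid:
            score, lam, system = try_theta(ty_, txy_)
            if best is None or score < best[0]:
                best = (score, lam, system, ty_, txy_)
    if refine:
        step = 10.0 ** 0.5
        ty0, txy0 = best[3], best[4]
        for ty_ in (ty0 / step, ty0, ty0 * step):
            for txy_ in (txy0 / step, txy0, txy0 * step):
                if ty_ == ty0 and txy_ == txy0:
                    continue
                score, lam, system = try_theta(ty_, txy_)
                if score < best[0]:
                    best = (score, lam, system, ty_, txy_)
    score, lam, system, ty_best, txy_best = best

    alpha, beta = system.coefficients(lam)
    edf = system.edf(lam)
    rss = system.rss(lam)
    sigma2 = rss / max(n - edf, np.finfo(float).eps)
    cov = system.covariance(lam, sigma2)
    kern = TensorProductKernel(bx, by, (np.inf, 1.0, ty_best, txy_best))
    fit = FittedSpline(
        kernel=kern,
        representers=reps,
        alpha=alpha,
        beta=beta,
        lam=float(lam),
        sigma2=float(sigma2),
        cov=cov,
        edf=float(edf),
        criterion=criterion,
        crit_value=float(score),
        obs=obs,
        theta=kern.theta,
    )
    decomp = _tensor_block_decomposition(fit, (mx, my))
    return fit, decomp
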