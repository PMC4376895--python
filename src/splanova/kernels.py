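"""Reproducing kernels and their penalty structure.

Three concrete kernels are provided:

* :class:`ThinPlateKernel` — the bivariate thin-plate spline kernel
  ``eta(r) = r^2 log(r) / (8 pi)`` whose penalty is the rotation-invariant
  (isotropic) integrated squared second derivative
  ``J(f) = ∬ f_xx^2 + 2 f_xy^2 + f_yy^2``.  Its null space (unpenalized
  functions) is the affine plane ``{1, x, y}``.
* :class:`MarginalCubicKernel` — the cubic-smoothing-spline kernel on an
  interval, written with scaled Bernoulli polynomials so that both the
  penalized part and the centered linear part have exact zero mean under
  the uniform measure.
* :class:`TensorProductKernel` — the block kernel of the classic
  smoothing-spline ANOVA: one reproducing-kernel block per ANOVA
  subspace (intercept, x main effect, y main effect, interaction), each
  carrying its own penalty weight ``theta``.

Conventions: ``gram(A, B)`` evaluates the *penalized* part of the kernel
pairwise; the unpenalized part is exposed as ``nullspace_basis``, a list
of plain functions.  Covariates are affinely mapped to the unit interval
per axis internally, so kernel values and penalties always live on the
rescaled domain; the scale factor is absorbed by the smoothing parameter.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

from .measures import Measure, make_measure

__all__ = [
    "Kernel",
    "ThinPlateKernel",
    "MarginalCubicKernel",
    "CenteredMarginalKernel",
    "TensorProductKernel",
    "make_tps_kernel",
    "make_marginal_kernel",
    "center_marginal",
    "make_tensor_kernel",
    "kernel_to_config",
    "kernel_from_config",
]

Interval = tuple[float, float]


def _check_interval(iv: Interval) -> Interval:
    lo, hi = float(iv[0]), float(iv[1])
    if not lo < hi:
        raise ValueError(f"degenerate interval [{lo}, {hi}]")
    return lo, hi


class Kernel:
    """Base class: penalized-part reproducing kernel + null-space basis."""

    dim: int
    domain: tuple[Interval, ...]

    def gram(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Pairwise penalized-kernel matrix, shape (len(A), len(B))."""
        raise NotImplementedError

    def evaluate(self, p, q) -> float:
        """Kernel value at a single pair of points."""
        A = np.atleast_2d(np.asarray(p, dtype=float))
        B = np.atleast_2d(np.asarray(q, dtype=float))
        return float(self.gram(A, B)[0, 0])

    @property
    def nullspace_basis(self) -> list[Callable[[np.ndarray], np.ndarray]]:
        return []

    def nullspace_matrix(self, P: np.ndarray) -> np.ndarray:
        """Evaluate the null-space basis at points P → (n, p) matrix."""
        P = np.atleast_2d(np.asarray(P, dtype=float))
        funcs = self.nullspace_basis
        if not funcs:
            return np.zeros((P.shape[0], 0))
        return np.column_stack([f(P) for f in funcs])

    def _rescale(self, P: np.ndarray) -> np.ndarray:
        """Affine map of each coordinate to [0, 1]."""
        P = np.atleast_2d(np.asarray(P, dtype=float))
        if P.shape[1] != self.dim:
            raise ValueError(f"expected {self.dim}-d points, got shape {P.shape}")
        out = np.empty_like(P)
        for j, (lo, hi) in enumerate(self.domain):
            out[:, j] = (P[:, j] - lo) / (hi - lo)
        return out


class ThinPlateKernel(Kernel):
    """Thin-plate spline kernel on a rectangle, radial profile r^2 log r.

    The kernel is conditionally positive definite: Gram matrices are PSD
    only on the subspace orthogonal to the null space {1, x, y}, which is
    why fits carry the side condition T' alpha = 0.
    """

    dim = 2
    conditionally_pd = True  # Gram PSD only subject to T' alpha = 0

    def __init__(self, domain: Sequence[Interval] = ((0.0, 1.0), (0.0, 1.0))):
        self.domain = (_check_interval(domain[0]), _check_interval(domain[1]))

    def gram(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        Au = self._rescale(A)
        Bu = self._rescale(B)
        d2 = (
            (Au[:, :1] - Bu[:, 0][None, :]) ** 2
            + (Au[:, 1:2] - Bu[:, 1][None, :]) ** 2
        )
        out = np.zeros_like(d2)
        pos = d2 > 0
        # r^2 log r = d2 * log(d2) / 2;  limit 0 at r = 0
        out[pos] = d2[pos] * np.log(d2[pos]) / 2.0
        return out / (8.0 * math.pi)

    @property
    def nullspace_basis(self):
        def const(P):
            return np.ones(np.atleast_2d(P).shape[0])

        def lin_x(P):
            return self._rescale(P)[:, 0]

        def lin_y(P):
            return self._rescale(P)[:, 1]

        return [const, lin_x, lin_y]


def _k1(t: np.ndarray) -> np.ndarray:
    return t - 0.5


def _k2(t: np.ndarray) -> np.ndarray:
    u = t - 0.5
    return (u * u - 1.0 / 12.0) / 2.0


def _k4(t: np.ndarray) -> np.ndarray:
    u = t - 0.5
    u2 = u * u
    return (u2 * u2 - u2 / 2.0 + 7.0 / 240.0) / 24.0


class MarginalCubicKernel(Kernel):
    """Cubic smoothing-spline kernel on an interval (Bernoulli form).

    On the rescaled coordinate ``t in [0,1]`` the full marginal
    reproducing kernel is

        R(s, t) = 1 + k1(s) k1(t) + [k2(s) k2(t) - k4(|s - t|)]

    with ``k_r = B_r(.)/r!`` the scaled Bernoulli polynomials.  The
    three blocks reproduce the constant, centered-linear, and smooth
    (penalized, curvature-carrying) subspaces; the last two have exact
    zero mean under the uniform measure.  ``gram`` returns the penalized
    block only; the null space is {1, t - 1/2}.
    """

    dim = 1

    def __init__(self, domain: Interval = (0.0, 1.0)):
        self.domain = (_check_interval(domain),)

    def _t(self, A) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        if A.ndim == 1:
            A = A[:, None]
        return self._rescale(A)[:, 0]

    def gram(self, A, B) -> np.ndarray:
        s = self._t(A)
        t = self._t(B)
        return self.block_gram("smooth", s, t, rescaled=True)

    def full_gram(self, A, B) -> np.ndarray:
        """Reproducing kernel of the whole marginal space (all blocks)."""
        s = self._t(A)
        t = self._t(B)
        out = np.ones((s.size, t.size))
        out += _k1(s)[:, None] * _k1(t)[None, :]
        out += self.block_gram("smooth", s, t, rescaled=True)
        return out

    def block_gram(self, block: str, A, B, rescaled: bool = False) -> np.ndarray:
        s = np.asarray(A, dtype=float) if rescaled else self._t(A)
        t = np.asarray(B, dtype=float) if rescaled else self._t(B)
        if block == "const":
            return np.ones((s.size, t.size))
        if block == "linear":
            return _k1(s)[:, None] * _k1(t)[None, :]
        if block == "smooth":
            return _k2(s)[:, None] * _k2(t)[None, :] - _k4(
                np.abs(s[:, None] - t[None, :])
            )
        raise ValueError(f"unknown block {block!r}")

    @property
    def nullspace_basis(self):
        def const(P):
            return np.ones(self._t(P).size)

        def lin(P):
            return _k1(self._t(P))

        return [const, lin]


class CenteredMarginalKernel(Kernel):
    """A univariate kernel double-centered under a probability measure.

    Sections of the centered kernel integrate to zero:
    ``∫ R_c(u, t) dμ(u) = 0`` for every t, which makes it the
    reproducing kernel of the zero-mean subspace ``(1 - A) V`` of the
    base marginal space.  Centering uses the measure's own quadrature
    rule, so the zero-mean property holds exactly under that rule.
    """

    dim = 1

    def __init__(self, base: Kernel, measure: Measure):
        if base.dim != 1:
            raise ValueError("centering requires a univariate kernel")
        self.base = base
        self.measure = measure
        self.domain = base.domain
        # full marginal RK if the kernel distinguishes it, else its gram
        self._base_gram = getattr(base, "full_gram", base.gram)
        w = measure.weights
        G_nodes = self._base_gram(measure.nodes, measure.nodes)
        self._abar = float(w @ G_nodes @ w)

    def _avg_at(self, B) -> np.ndarray:
        """a(t) = ∫ R(u, t) dμ(u) for arbitrary t."""
        return self.measure.weights @ self._base_gram(
            self.measure.nodes, np.asarray(B, dtype=float)
        )

    def gram(self, A, B) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        B = np.asarray(B, dtype=float)
        G = self._base_gram(A, B)
        aA = self._avg_at(A)
        aB = self._avg_at(B)
        return G - aA[:, None] - aB[None, :] + self._abar

    @property
    def nullspace_basis(self):
        return []


class TensorProductKernel(Kernel):
    """Block kernel of the classic SS-ANOVA tensor-product construction.

    The product of the two decomposed marginal spaces splits into four
    subspaces — intercept (1⊗1), x main effect (V_x⊗1), y main effect
    (1⊗V_y) and interaction (V_x⊗V_y) — with reproducing kernels
    1, R_x, R_y and R_x·R_y.  Each block enters the joint penalty with
    weight ``1/theta_b``; equivalently the combined penalized kernel is
    ``sum_b theta_b R_b``.  ``theta_0 = inf`` removes the intercept from
    the penalty (moves it into the null space), which is the default.
    """

    dim = 2
    LABELS = ("intercept", "main_x", "main_y", "interaction")

    def __init__(
        self,
        kx: Kernel,
        ky: Kernel,
        theta: Sequence[float] = (math.inf, 1.0, 1.0, 1.0),
    ):
        if kx.dim != 1 or ky.dim != 1:
            raise ValueError("marginal kernels must be univariate")
        theta = tuple(float(t) for t in theta)
        if len(theta) != 4:
            raise ValueError("theta must have 4 entries (one per block)")
        for t in theta:
            if not (t > 0):
                raise ValueError(f"theta weights must be positive, got {t}")
        if any(math.isinf(t) for t in theta[1:]):
            raise ValueError("only the intercept block may be unpenalized")
        self.kx = kx
        self.ky = ky
        self.theta = theta
        self.domain = (kx.domain[0], ky.domain[0])

    def _marginal_grams(self, A, B):
        A = np.atleast_2d(np.asarray(A, dtype=float))
        B = np.atleast_2d(np.asarray(B, dtype=float))
        Gx = self.kx.gram(A[:, 0], B[:, 0])
        Gy = self.ky.gram(A[:, 1], B[:, 1])
        return Gx, Gy

    def block_gram(self, label: str, A, B) -> np.ndarray:
        Gx, Gy = self._marginal_grams(A, B)
        if label == "intercept":
            return np.ones(Gx.shape)
        if label == "main_x":
            return Gx
        if label == "main_y":
            return Gy
        if label == "interaction":
            return Gx * Gy
        raise ValueError(f"unknown block {label!r}")

    def gram(self, A, B) -> np.ndarray:
        Gx, Gy = self._marginal_grams(A, B)
        t0, tx, ty, txy = self.theta
        out = tx * Gx + ty * Gy + txy * Gx * Gy
        if not math.isinf(t0):
            out = out + t0
        return out

    @property
    def nullspace_basis(self):
        if math.isinf(self.theta[0]):
            def const(P):
                return np.ones(np.atleast_2d(P).shape[0])

            return [const]
        return []


def make_tps_kernel(domain: Sequence[Interval] = ((0, 1), (0, 1))) -> ThinPlateKernel:
    """Thin-plate kernel on the given rectangle (isotropic penalty)."""
    return ThinPlateKernel(domain)


def make_marginal_kernel(
    domain: Interval = (0.0, 1.0), measure: Measure | None = None
) -> MarginalCubicKernel:
    """Univariate cubic-smoothing-spline kernel on ``domain``.

    ``measure``, if given, must be a valid probability measure on the
    domain; it is only validated here (the kernel itself is
    measure-free — centering is a separate step).
    """
    kern = MarginalCubicKernel(domain)
    if measure is not None:
        if abs(measure.weights.sum() - 1.0) > 1e-9:
            raise ValueError("measure must be normalized to total mass 1")
    return kern


def center_marginal(kernel: Kernel, measure: Measure) -> CenteredMarginalKernel:
    """Center a univariate kernel so every section has measure-mean zero.

    Idempotent: centering an already-centered kernel changes nothing
    (the averaging operator 1 - A is a projector).
    """
    if kernel.dim != 1:
        raise ValueError("center_marginal requires a univariate kernel")
    return CenteredMarginalKernel(kernel, measure)


def make_tensor_kernel(
    kx: MarginalCubicKernel,
    ky: MarginalCubicKernel,
    measures: Sequence[Measure] | None = None,
    theta: Sequence[float] = (math.inf, 1.0, 1.0, 1.0),
) -> TensorProductKernel:
    """Assemble the four-block tensor-product SS-ANOVA kernel.

    With ``measures`` given, the marginal kernels are centered under
    them, so the main-effect blocks reproduce zero-mean functions and
    the interaction block zero-marginal functions.  Without measures,
    the raw marginal blocks (constant block removed) are used, in which
    case setting every theta to 1 reassembles the plain product kernel.
    """
    if measures is not None:
        mx, my = measures
        bx: Kernel = center_marginal(kx, mx)
        by: Kernel = center_marginal(ky, my)
    else:
        class _Raw(Kernel):
            dim = 1

            def __init__(self, base):
                self.base = base
                self.domain = base.domain

            def gram(self, A, B):
                return self.base.full_gram(A, B) - 1.0

        bx = _Raw(kx)
        by = _Raw(ky)
    return TensorProductKernel(bx, by, theta)


def kernel_to_config(kernel: Kernel) -> dict:
    """Serializable description of a kernel (YAML-friendly)."""
    if isinstance(kernel, ThinPlateKernel):
        return {"kind": "tps", "domain": [list(iv) for iv in kernel.domain]}
    if isinstance(kernel, MarginalCubicKernel):
        return {"kind": "cubic", "domain": [list(kernel.domain[0])]}
    if isinstance(kernel, TensorProductKernel):
        return {
            "kind": "tensor",
            "domain": [list(iv) for iv in kernel.domain],
            "theta": [None if math.isinf(t) else t for t in kernel.theta],
        }
    raise ValueError(f"cannot serialize kernel of type {type(kernel).__name__}")


def kernel_from_config(cfg: dict, order: int = 32) -> Kernel:
    """Rebuild a kernel from its config block (inverse of to_config)."""
    kind = cfg["kind"]
    dom = cfg.get("domain")
    if kind == "tps":
        dom = dom or [[0, 1], [0, 1]]
        return make_tps_kernel([tuple(d) for d in dom])
    if kind == "cubic":
        dom = dom or [[0, 1]]
        return make_marginal_kernel(tuple(dom[0]))
    if kind == "tensor":
        dom = dom or [[0, 1], [0, 1]]
        theta = cfg.get("theta") or [None, 1.0, 1.0, 1.0]
        theta = [math.inf if t is None else float(t) for t in theta]
        kx = MarginalCubicKernel(tuple(dom[0]))
        ky = MarginalCubicKernel(tuple(dom[1]))
        measures = [
            make_measure("lebesgue", tuple(dom[0]), order=order),
            make_measure("lebesgue", tuple(dom[1]), order=order),
        ]
        return make_tensor_kernel(kx, ky, measures, theta)
    raise ValueError(f"unknown kernel kind {kind!r}")
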