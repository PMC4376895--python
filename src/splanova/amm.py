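"""Additive mixed models with smooth terms and crossed random intercepts.

The model is a sum of centered smooth terms (univariate cubic, bivariate
thin-plate, or bivariate tensor-interaction), a global intercept, and
Gaussian random intercepts for one or more grouping factors:

    z = c0 + sum_t f_t(x_t) + sum_g r_g[group] + eps .

Random intercepts enter as ridge-penalized dummy-coded blocks; the ridge
weight of factor g is ``lambda_g = sigma^2 / sigma_g^2``, the classical
spline/mixed-model equivalence, so a single penalized least-squares
solver fits everything jointly.  Per-block smoothing parameters are
selected by coordinate-wise optimization of REML (default) or GCV.

Each smooth block is pre-whitened: its penalty Gram is factored and the
coefficients rescaled so the block penalty is ``lambda_b ||u_b||^2``,
which keeps the joint normal equations well conditioned.

A synthetic fixation-duration generator emulates the structure of eye-
movement corpora (log durations, incoming saccade amplitude, word
lengths and frequencies of the previous/current/next word, crossed
reader and word random effects) so the reading analyses can be
exercised without a real corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh, qr

from .decompose import Decomposition, posthoc_decompose
from .fitting import FittedSpline, IllPosedFitError
from .kernels import (
    Kernel,
    MarginalCubicKernel,
    ThinPlateKernel,
    center_marginal,
)
from .measures import Measure, make_measure

__all__ = [
    "AMMSpec",
    "AMMFit",
    "fit_amm",
    "decompose_pair",
    "term_effect",
    "synth_reading_data",
    "subset_study",
    "SubsetStudyResult",
]


@dataclass
class AMMSpec:
    """Model structure: smooth terms, random factors, response column.

    ``terms`` is a list of (covariates, kind): a single column name with
    kind "cubic", or a pair of names with kind "tps" (isotropic thin
    plate) or "tensor" (interaction-only tensor-product block; pair it
    with explicit cubic main effects for the classic SS-ANOVA layout).
    """

    terms: Sequence[tuple]
    random_factors: Sequence[str] = ()
    response: str = "z"

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("need at least one smooth term")
        norm = []
        for cols, kind in self.terms:
            if isinstance(cols, str):
                cols = (cols,)
            cols = tuple(cols)
            if kind == "cubic" and len(cols) != 1:
                raise ValueError("cubic terms take exactly one covariate")
            if kind in ("tps", "tensor") and len(cols) != 2:
                raise ValueError(f"{kind} terms take exactly two covariates")
            if kind not in ("cubic", "tps", "tensor"):
                raise ValueError(f"unknown term kind {kind!r}")
            norm.append((cols, kind))
        self.terms = norm


class _SmoothBlock:
    """One whitened smooth term: columns, unpenalized parts, evaluators."""

    def __init__(self, cols, kind, data: pd.DataFrame, n_knots_1d=20, n_knots_2d=7):
        self.cols = cols
        self.kind = kind
        x = data[list(cols)].to_numpy(dtype=float)
        self.domains = tuple(
            (float(x[:, j].min()), float(x[:, j].max())) for j in range(len(cols))
        )
        self.measures = tuple(
            make_measure("lebesgue", dom, order=24) for dom in self.domains
        )
        if kind == "cubic":
            dom = self.domains[0]
            kern = center_marginal(MarginalCubicKernel(dom), self.measures[0])
            knots = np.unique(
                np.quantile(x[:, 0], np.linspace(0, 1, n_knots_1d))
            )[:, None]
            self.kernel: Kernel = kern
            self.knots = knots
            self.Zc = None
            P = kern.gram(knots[:, 0], knots[:, 0])
        elif kind == "tps":
            kern = ThinPlateKernel(self.domains)
            kx = np.quantile(x[:, 0], np.linspace(0, 1, n_knots_2d))
            ky = np.quantile(x[:, 1], np.linspace(0, 1, n_knots_2d))
            KX, KY = np.meshgrid(np.unique(kx), np.unique(ky), indexing="ij")
            knots = np.column_stack([KX.ravel(), KY.ravel()])
            self.kernel = kern
            self.knots = knots
            T_rep = kern.nullspace_matrix(knots)
            Q, _ = qr(T_rep, mode="full")
            self.Zc = Q[:, T_rep.shape[1]:]
            P = self.Zc.T @ kern.gram(knots, knots) @ self.Zc
        else:  # tensor interaction block
            bx = center_marginal(MarginalCubicKernel(self.domains[0]), self.measures[0])
            by = center_marginal(MarginalCubicKernel(self.domains[1]), self.measures[1])
            self.marginals = (bx, by)
            kx = np.unique(np.quantile(x[:, 0], np.linspace(0, 1, n_knots_2d)))
            ky = np.unique(np.quantile(x[:, 1], np.linspace(0, 1, n_knots_2d)))
            KX, KY = np.meshgrid(kx, ky, indexing="ij")
            knots = np.column_stack([KX.ravel(), KY.ravel()])
            self.kernel = None
            self.knots = knots
            P = bx.gram(knots[:, 0], knots[:, 0]) * by.gram(knots[:, 1], knots[:, 1])
            self.Zc = None
        P = 0.5 * (P + P.T)
        e, V = eigh(P)
        keep = e > e.max() * 1e-12
        self.W = (V[:, keep] / np.sqrt(e[keep]))  # whitening: alpha-ish = W u
        self.rank = int(keep.sum())
        self.X = self._raw_columns(x) @ self.W
        self.fixed = self._fixed_columns(x)

    # raw penalized columns before whitening (centered sections)
    def _raw_columns(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "cubic":
            return self.kernel.gram(x[:, 0], self.knots[:, 0])
        if self.kind == "tps":
            G = self.kernel.gram(x, self.knots) @ self.Zc
            self._col_means = self._tps_col_means()
            return G - self._col_means[None, :]
        bx, by = self.marginals
        return bx.gram(x[:, 0], self.knots[:, 0]) * by.gram(x[:, 1], self.knots[:, 1])

    def _tps_col_means(self) -> np.ndarray:
        mx, my = self.measures
        P = np.column_stack(
            [
                np.repeat(mx.nodes, my.nodes.size),
                np.tile(my.nodes, mx.nodes.size),
            ]
        )
        G = (self.kernel.gram(P, self.knots) @ self.Zc).reshape(
            mx.nodes.size, my.nodes.size, -1
        )
        return np.einsum("i,j,ijk->k", mx.weights, my.weights, G)

    def _fixed_columns(self, x: np.ndarray) -> np.ndarray:
        """Unpenalized, measure-centered columns (tps plane only)."""
        if self.kind != "tps":
            return np.zeros((x.shape[0], 0))
        out = np.column_stack(
            [x[:, j] - self.measures[j].mean for j in range(2)]
        )
        return out

    def evaluate_columns(self, pts: np.ndarray):
        """(whitened penalized cols, fixed cols) at new points."""
        pts = np.asarray(pts, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        if self.kind == "cubic":
            pen = self.kernel.gram(pts[:, 0], self.knots[:, 0]) @ self.W
        elif self.kind == "tps":
            pen = (
                self.kernel.gram(pts, self.knots) @ self.Zc
                - self._col_means[None, :]
            ) @ self.W
        else:
            bx, by = self.marginals
            pen = (
                bx.gram(pts[:, 0], self.knots[:, 0])
                * by.gram(pts[:, 1], self.knots[:, 1])
            ) @ self.W
        fixed = self._fixed_columns(pts)
        return pen, fixed


@dataclass
class AMMFit:
    """Joint penalized fit of an additive mixed model."""

    spec: AMMSpec
    blocks: list
    factor_levels: dict
    coef: np.ndarray
    cov: np.ndarray
    sigma2: float
    edf: float
    lambdas: dict
    slices: dict
    criterion: str
    crit_value: float

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    def variance_components(self) -> dict:
        """Estimated random-intercept standard deviations per factor."""
        return {
            g: float(np.sqrt(self.sigma2 / self.lambdas[("factor", g)]))
            for g in self.spec.random_factors
        }

    def blups(self, factor: str) -> pd.Series:
        sl = self.slices[("factor", factor)]
        return pd.Series(self.coef[sl], index=self.factor_levels[factor])

    def fitted(self, data: pd.DataFrame) -> np.ndarray:
        out = np.full(len(data), self.intercept)
        for i, blk in enumerate(self.blocks):
            mean, _ = term_effect(self, i, data[list(blk.cols)].to_numpy(float))
            out += mean
        for g in self.spec.random_factors:
            blup = self.blups(g)
            out += blup.reindex(data[g]).fillna(0.0).to_numpy()
        return out


def _term_design(blocks, n):
    """Stack intercept + fixed parts + whitened penalized blocks."""
    fixed_cols = [np.ones((n, 1))]
    fixed_index = {}
    pos = 1
    for i, blk in enumerate(blocks):
        if blk.fixed.shape[1]:
            fixed_index[i] = slice(pos, pos + blk.fixed.shape[1])
            fixed_cols.append(blk.fixed)
            pos += blk.fixed.shape[1]
    return np.hstack(fixed_cols), fixed_index


def fit_amm(
    data: pd.DataFrame,
    spec: AMMSpec,
    criterion: str = "reml",
    max_sweeps: int = 4,
    tol: float = 1e-3,
) -> AMMFit:
    """Fit the additive mixed model by penalized least squares.

    Smoothing parameters (one per smooth term, one per random factor)
    are selected by coordinate-wise golden-section optimization of the
    chosen criterion; REML is the default, matching mixed-model
    practice for variance components.
    """
    if criterion not in ("reml", "gcv"):
        raise ValueError(f"unknown criterion {criterion!r}")
    z = data[spec.response].to_numpy(dtype=float)
    n = z.size
    blocks = [_SmoothBlock(cols, kind, data) for cols, kind in spec.terms]
    Xfixed, fixed_index = _term_design(blocks, n)
    p0 = Xfixed.shape[1]
    # fixed part must be full rank, else terms are aliased
    svals = np.linalg.svd(Xfixed, compute_uv=False)
    if svals.min() < 1e-8 * svals.max():
        aliased = [
            f"{blocks[i].cols}" for i in fixed_index
        ]
        raise IllPosedFitError(
            "rank-deficient fixed part; aliased unpenalized parts among "
            f"terms {aliased} (shared covariates between thin-plate terms?)"
        )
    pieces = [Xfixed]
    slices: dict = {"fixed": slice(0, p0)}
    pos = p0
    pen_groups = []  # (key, slice, rank)
    for i, blk in enumerate(blocks):
        sl = slice(pos, pos + blk.rank)
        slices[("term", i)] = sl
        pen_groups.append((("term", i), sl, blk.rank))
        pieces.append(blk.X)
        pos += blk.rank
    factor_levels = {}
    for g in spec.random_factors:
        codes, levels = pd.factorize(data[g], sort=True)
        if len(levels) < 2:
            raise ValueError(f"random factor {g!r} needs >= 2 levels")
        D = np.zeros((n, len(levels)))
        D[np.arange(n), codes] = 1.0
        sl = slice(pos, pos + len(levels))
        slices[("factor", g)] = sl
        pen_groups.append((("factor", g), sl, len(levels)))
        pieces.append(D)
        pos += len(levels)
        factor_levels[g] = levels
    X = np.hstack(pieces)
    q = X.shape[1]
    XtX = X.T @ X
    Xtz = X.T @ z
    z2 = float(z @ z)

    def make_M(lam: dict) -> np.ndarray:
        M = XtX.copy()
        for key, sl, _r in pen_groups:
            idx = np.arange(sl.start, sl.stop)
            M[idx, idx] += lam[key]
        return M

    def crit_and_state(lam: dict):
        M = make_M(lam)
        try:
            Mc = cho_factor(M)
        except np.linalg.LinAlgError:
            return np.inf, None
        b = cho_solve(Mc, Xtz)
        rss = max(z2 - 2 * float(b @ Xtz) + float(b @ (XtX @ b)), 1e-300)
        edf = float(np.trace(cho_solve(Mc, XtX)))
        if criterion == "gcv":
            denom = n - edf
            score = np.inf if denom <= 0 else n * rss / denom**2
        else:
            pen = sum(
                lam[key] * float(b[sl] @ b[sl]) for key, sl, _ in pen_groups
            )
            prss = rss + pen
            nr = n - p0
            sig2 = prss / nr
            logdetM = 2.0 * float(np.sum(np.log(np.diag(Mc[0]))))
            logdetP = sum(r * np.log(lam[key]) for key, _sl, r in pen_groups)
            score = nr * np.log(sig2) + logdetM - logdetP
        return score, (b, rss, edf, Mc)

    # scale-aware initial lambdas
    lam = {}
    for key, sl, r in pen_groups:
        lam[key] = max(np.trace(XtX[sl, sl]) / max(r, 1), 1e-8)
    score, state = crit_and_state(lam)
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    for _sweep in range(max_sweeps):
        moved = 0.0
        for key, _sl, _r in pen_groups:
            base = np.log(lam[key])
            a, bnd = base - 8.0, base + 8.0
            c1 = bnd - gr * (bnd - a)
            c2 = a + gr * (bnd - a)

            def f(logl):
                trial = dict(lam)
                trial[key] = np.exp(logl)
                s, _ = crit_and_state(trial)
                return s

            f1, f2 = f(c1), f(c2)
            for _ in range(25):
                if bnd - a < 0.05:
                    break
                if f1 <= f2:
                    bnd, c2, f2 = c2, c1, f1
                    c1 = bnd - gr * (bnd - a)
                    f1 = f(c1)
                else:
                    a, c1, f1 = c1, c2, f2
                    c2 = a + gr * (bnd - a)
                    f2 = f(c2)
            new = float(np.exp(0.5 * (a + bnd)))
            moved = max(moved, abs(np.log(new) - base))
            lam[key] = new
        score, state = crit_and_state(lam)
        if moved < tol:
            break
    if state is None:
        raise IllPosedFitError("AMM normal equations are singular")
    b, rss, edf, Mc = state
    sigma2 = rss / max(n - edf, 1.0)
    cov = sigma2 * cho_solve(Mc, np.eye(q))
    cov = 0.5 * (cov + cov.T)
    fit = AMMFit(
        spec=spec,
        blocks=blocks,
        factor_levels=factor_levels,
        coef=b,
        cov=cov,
        sigma2=float(sigma2),
        edf=float(edf),
        lambdas=lam,
        slices=slices,
        criterion=criterion,
        crit_value=float(score),
    )
    fit._fixed_index = fixed_index  # term -> slice into fixed columns
    return fit


def _term_row_matrix(fit: AMMFit, term: int, pts: np.ndarray):
    """Rows mapping the full coefficient vector to term values at pts."""
    blk = fit.blocks[term]
    pen, fixed = blk.evaluate_columns(pts)
    q = fit.coef.size
    M = np.zeros((pen.shape[0], q))
    M[:, fit.slices[("term", term)]] = pen
    fi = getattr(fit, "_fixed_index", {})
    if term in fi:
        M[:, fi[term]] = fixed
    return M


def term_effect(fit: AMMFit, term: int, pts: np.ndarray):
    """Posterior mean and pointwise variance of one smooth term."""
    M = _term_row_matrix(fit, term, pts)
    mean = M @ fit.coef
    var = np.maximum(np.einsum("ij,jk,ik->i", M, fit.cov, M), 0.0)
    return mean, var


def decompose_pair(
    fit: AMMFit, term: int, measures: Sequence[Measure] | None = None
) -> Decomposition:
    """Post-hoc SS-ANOVA decomposition of one bivariate thin-plate term.

    The term's coefficient block (with its covariance submatrix) is
    repackaged as a stand-alone fitted bivariate spline and passed to
    the averaging-operator decomposition; the resulting main effects are
    *partial* effects, holding the model's other terms fixed.
    """
    blk = fit.blocks[term]
    if blk.kind != "tps":
        raise ValueError(
            f"decompose_pair needs a bivariate tps term; term {term} is "
            f"{blk.kind!r} on {blk.cols}"
        )
    if measures is None:
        measures = blk.measures
    # term function: f(u) = R(u, knots) Zc W u_b - const + fixed plane
    # repackaged as alpha = Zc W u_b over the knots plus beta on {1,x,y}
    u_sl = fit.slices[("term", term)]
    fi = getattr(fit, "_fixed_index", {})
    f_sl = fi.get(term)
    A = blk.Zc @ blk.W  # (m, r)
    u = fit.coef[u_sl]
    alpha = A @ u
    lin = fit.coef[f_sl] if f_sl is not None else np.zeros(2)
    # beta in the kernel's rescaled null-space coordinates {1, xs, ys}:
    # fixed columns are (x - mean); x = lo + (hi-lo)*xs
    scales = np.array([hi - lo for lo, hi in blk.domains])
    los = np.array([lo for lo, _hi in blk.domains])
    beta_lin = lin * scales
    const = -float((blk._col_means @ blk.W) @ u)
    const += float(lin @ (los - np.array([m.mean for m in blk.measures])))
    beta = np.concatenate([[const], beta_lin])
    # covariance of (alpha, beta) from the joint coefficient covariance
    q = fit.coef.size
    B = np.zeros((alpha.size + 3, q))
    B[: alpha.size, u_sl] = A
    B[alpha.size, u_sl] = -(blk._col_means @ blk.W)
    if f_sl is not None:
        B[alpha.size, f_sl] = los - np.array([m.mean for m in blk.measures])
        B[alpha.size + 1, f_sl] = np.array([scales[0], 0.0])
        B[alpha.size + 2, f_sl] = np.array([0.0, scales[1]])
    cov = B @ fit.cov @ B.T
    pseudo = FittedSpline(
        kernel=blk.kernel,
        representers=blk.knots,
        alpha=alpha,
        beta=beta,
        lam=fit.lambdas[("term", term)],
        sigma2=fit.sigma2,
        cov=cov,
        edf=float("nan"),
        criterion=fit.criterion,
    )
    return posthoc_decompose(pseudo, measures)


# ----------------------------------------------------------------------
# synthetic reading data


def _default_effects() -> dict:
    """Smooth effect shapes qualitatively matching reading corpora:
    monotone for the previous word's frequency, clearly non-monotone for
    the fixated word, weak for the upcoming word; magnitudes ~0.1 on the
    log-duration scale."""
    return {
        "amp": lambda a: 0.08 * np.log1p(a) - 0.12,
        "len_prev": lambda l: 0.02 * (l - 1.5),
        "len_cur": lambda l: 0.05 * (l - 1.5),
        "len_next": lambda l: -0.02 * (l - 1.5),
        "freq_prev": lambda v: -0.06 * (v - 1.5),
        "freq_cur": lambda v: 0.12 * np.exp(-((v - 1.5) ** 2) / 0.5) - 0.05,
        "freq_next": lambda v: 0.03 * np.exp(-((v - 1.0) ** 2) / 0.4) - 0.01,
    }


def synth_reading_data(
    n_readers: int = 50,
    n_words: int = 60,
    n_obs: int = 3000,
    effects: dict | None = None,
    pair_effects: dict | None = None,
    sigma_id: float = 0.2,
    sigma_w: float = 0.1,
    sigma_eps: float = 0.3,
    c0: float = 5.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate synthetic single-fixation reading data.

    Columns: log duration ``dur_log``, incoming saccade amplitude
    ``amp`` (letters), log word lengths ``len_prev/cur/next`` and log
    frequencies ``freq_prev/cur/next`` on [0, 3], plus ``reader`` and
    ``word`` ids.  The response is ``c0 + sum of effects + r_reader +
    r_word + eps`` with independent Gaussian random intercepts, so the
    ground truth of every component is known.  ``pair_effects`` maps a
    pair of covariate names to a bivariate interaction function (default
    none: purely additive truth).
    """
    if min(sigma_id, sigma_w, sigma_eps) <= 0:
        raise ValueError("standard deviations must be positive")
    rng = np.random.default_rng(seed)
    eff = dict(_default_effects())
    if effects:
        eff.update(effects)
    word_len = rng.uniform(0.0, 3.0, n_words)
    word_freq = rng.uniform(0.0, 3.0, n_words)
    r_id = rng.normal(0.0, sigma_id, n_readers)
    r_w = rng.normal(0.0, sigma_w, n_words)
    reader = rng.integers(0, n_readers, n_obs)
    word = rng.integers(0, n_words, n_obs)
    df = pd.DataFrame(
        {
            "reader": reader,
            "word": word,
            "amp": rng.uniform(1.0, 12.0, n_obs),
            "len_prev": rng.uniform(0.0, 3.0, n_obs),
            "len_cur": word_len[word],
            "len_next": rng.uniform(0.0, 3.0, n_obs),
            "freq_prev": rng.uniform(0.0, 3.0, n_obs),
            "freq_cur": word_freq[word],
            "freq_next": rng.uniform(0.0, 3.0, n_obs),
        }
    )
    tau = np.full(n_obs, float(c0))
    for col, f in eff.items():
        tau += f(df[col].to_numpy())
    if pair_effects:
        for (ca, cb), f in pair_effects.items():
            tau += f(df[ca].to_numpy(), df[cb].to_numpy())
    tau += r_id[reader] + r_w[word] + rng.normal(0.0, sigma_eps, n_obs)
    df["dur_log"] = tau
    return df


@dataclass
class SubsetStudyResult:
    """Across-subset component evaluations for the frequency pair."""

    pair: tuple[str, str]
    methods: tuple[str, ...]
    xs: np.ndarray
    ys: np.ndarray
    xy: np.ndarray
    values: dict = field(default_factory=dict)  # (method, comp) -> (reps, pts)
    skipped: list = field(default_factory=list)

    def mean(self, method, comp):
        return self.values[(method, comp)].mean(axis=0)

    def sd(self, method, comp):
        return self.values[(method, comp)].std(axis=0, ddof=1)

    def trace_variability(self, method, comp) -> float:
        v = self.values[(method, comp)]
        return float(np.sum(np.var(v, axis=0, ddof=1)))


def subset_study(
    data: pd.DataFrame,
    subset_size: int,
    reps: int,
    seed: int,
    methods=("tensor", "posthoc"),
    pair: tuple[str, str] = ("freq_prev", "freq_cur"),
    extra_terms: Sequence[tuple] = (("amp", "cubic"),),
    random_factors: Sequence[str] = ("reader",),
    response: str = "dur_log",
    grid: int = 21,
    criterion: str = "gcv",
) -> SubsetStudyResult:
    """Repeat fit + decomposition on random subsets of the data.

    Emulates dividing a large corpus into small subsets and comparing
    the across-subset variability of the frequency main and interaction
    effects between the tensor-product and thin-plate post-hoc routes.
    Subsets are drawn without replacement within each replicate.
    """
    if subset_size > len(data):
        raise ValueError("subset_size exceeds the dataset")
    rng = np.random.default_rng(seed)
    lo_a, hi_a = data[pair[0]].min(), data[pair[0]].max()
    lo_b, hi_b = data[pair[1]].min(), data[pair[1]].max()
    xs = np.linspace(lo_a, hi_a, grid)
    ys = np.linspace(lo_b, hi_b, grid)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    xy = np.column_stack([XX.ravel(), YY.ravel()])
    comps = ("main_x", "main_y", "interaction")
    rows = {(m, c): [] for m in methods for c in comps}
    skipped = []
    for rep in range(reps):
        idx = rng.choice(len(data), size=subset_size, replace=False)
        sub = data.iloc[idx].reset_index(drop=True)
        try:
            rep_vals = {}
            for method in methods:
                if method == "posthoc":
                    spec = AMMSpec(
                        terms=list(extra_terms) + [(pair, "tps")],
                        random_factors=random_factors,
                        response=response,
                    )
                    fit = fit_amm(sub, spec, criterion=criterion)
                    dec = decompose_pair(fit, len(list(extra_terms)))
                    rep_vals[method] = {
                        "main_x": dec["main_x"].evaluate(xs),
                        "main_y": dec["main_y"].evaluate(ys),
                        "interaction": dec["interaction"].evaluate(xy),
                    }
                elif method == "tensor":
                    spec = AMMSpec(
                        terms=list(extra_terms)
                        + [(pair[0], "cubic"), (pair[1], "cubic"), (pair, "tensor")],
                        random_factors=random_factors,
                        response=response,
                    )
                    fit = fit_amm(sub, spec, criterion=criterion)
                    k0 = len(list(extra_terms))
                    mean_a, _ = term_effect(fit, k0, xs[:, None])
                    mean_b, _ = term_effect(fit, k0 + 1, ys[:, None])
                    mean_ab, _ = term_effect(fit, k0 + 2, xy)
                    rep_vals[method] = {
                        "main_x": mean_a,
                        "main_y": mean_b,
                        "interaction": mean_ab,
                    }
                else:
                    raise ValueError(f"unknown method {method!r}")
        except Exception as exc:  # noqa: BLE001
            skipped.append((rep, repr(exc)))
            continue
        for m in methods:
            for c in comps:
                rows[(m, c)].append(rep_vals[m][c])
    return SubsetStudyResult(
        pair=pair,
        methods=tuple(methods),
        xs=xs,
        ys=ys,
        xy=xy,
        values={k: np.asarray(v) for k, v in rows.items()},
        skipped=skipped,
    )
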