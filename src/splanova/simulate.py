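"""Replicated simulation studies comparing the two decomposition routes.

Two closed-form test surfaces on the unit square:

* ``example1``: ``2(x - 1/2) + sin(2 pi y) + sin(2 pi x) cos(2 pi y)`` —
  nearly, but not exactly, isotropic smoothness; its ANOVA components
  under Lebesgue measures are available in closed form because all
  full-period sine/cosine means vanish.
* ``example2``: ``2(x - 1/2) + 2(1/2 - y) + exp(-((x-1/2)^2 + (y-1/2)^2)/0.08)``
  — isotropic by construction (radial Gaussian bump); its components
  are obtained by high-order quadrature.

A study draws ``reps`` independent datasets (uniform covariates,
Gaussian noise), runs the tensor-product SS-ANOVA and/or the thin-plate
post-hoc decomposition on each, and evaluates every component on fixed
grids.  Two summary metrics compare the methods: the trace of the
across-replicate covariance of grid values (variability) and the
grid-averaged squared bias against the true component (MSB).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decompose import classic_ssanova, posthoc_decompose
from .fitting import Observations, fit_spline
from .kernels import make_tps_kernel
from .measures import make_measure

__all__ = [
    "SimulationSpec",
    "StudyResult",
    "true_function",
    "true_decomposition",
    "sample_dataset",
    "run_study",
    "trace_variability",
    "mean_squared_bias",
    "metrics_table",
]

FUNCTION_IDS = ("example1", "example2")
COMPONENTS = ("main_x", "main_y", "interaction")


def true_function(function_id: str, x, y):
    """Evaluate one of the two test surfaces."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if function_id == "example1":
        return (
            2.0 * (x - 0.5)
            + np.sin(2 * np.pi * y)
            + np.sin(2 * np.pi * x) * np.cos(2 * np.pi * y)
        )
    if function_id == "example2":
        return (
            2.0 * (x - 0.5)
            + 2.0 * (0.5 - y)
            + np.exp(-((x - 0.5) ** 2 + (y - 0.5) ** 2) / 0.08)
        )
    raise ValueError(f"unknown function id {function_id!r}")


def true_decomposition(function_id: str, order: int = 128) -> dict:
    """True ANOVA components under Lebesgue measures on [0,1]^2.

    ``example1`` has closed-form components (the periodic terms have
    zero mean over a full period); ``example2`` components come from
    applying the averaging operators with Gauss–Legendre quadrature of
    the given order.
    """
    if function_id == "example1":
        return {
            "intercept": 0.0,
            "main_x": lambda x: 2.0 * (np.asarray(x, float) - 0.5),
            "main_y": lambda y: np.sin(2 * np.pi * np.asarray(y, float)),
            "interaction": lambda x, y: np.sin(2 * np.pi * np.asarray(x, float))
            * np.cos(2 * np.pi * np.asarray(y, float)),
        }
    if function_id == "example2":
        from .averaging import average_function

        measures = (
            make_measure("lebesgue", (0.0, 1.0), order=order),
            make_measure("lebesgue", (0.0, 1.0), order=order),
        )

        def f(x, y):
            return true_function("example2", x, y)

        c = float(average_function(f, "AxAy", measures)())
        fx = average_function(f, "Ay(1-Ax)", measures)
        fy = average_function(f, "Ax(1-Ay)", measures)
        fxy = average_function(f, "(1-Ax)(1-Ay)", measures)
        return {"intercept": c, "main_x": fx, "main_y": fy, "interaction": fxy}
    raise ValueError(f"unknown function id {function_id!r}")


@dataclass
class SimulationSpec:
    """Design of one replicated study (one function, one sample size)."""

    function_id: str = "example1"
    n: int = 30
    noise_var: float = 0.25
    reps: int = 100
    seed: int = 0
    grid_1d: int = 101
    grid_2d: int = 21

    def __post_init__(self) -> None:
        if self.function_id not in FUNCTION_IDS:
            raise ValueError(f"unknown function id {self.function_id!r}")
        if self.n < 10:
            raise ValueError("need n >= 10")
        if self.noise_var <= 0:
            raise ValueError("noise variance must be positive")


def sample_dataset(spec: SimulationSpec, rep_index: int) -> Observations:
    """Draw one replicate: uniform covariates, Gaussian noise.

    The stream is seeded by (seed, rep_index), so replicates are
    mutually independent and each is individually reproducible.
    """
    rng = np.random.default_rng([int(spec.seed), int(rep_index)])
    x = rng.random((spec.n, 2))
    z = true_function(spec.function_id, x[:, 0], x[:, 1])
    z = z + rng.normal(0.0, np.sqrt(spec.noise_var), size=spec.n)
    return Observations(x=x, z=z)


@dataclass
class StudyResult:
    """Per-replicate component evaluations on fixed grids."""

    spec: SimulationSpec
    methods: tuple[str, ...]
    xs: np.ndarray
    ys: np.ndarray
    xy: np.ndarray          # (G2*G2, 2) flattened 2-d grid
    values: dict = field(default_factory=dict)  # (method, comp) -> (reps, pts)
    intercepts: dict = field(default_factory=dict)  # (method,) -> (reps,)
    failures: list = field(default_factory=list)

    @property
    def n_reps(self) -> int:
        for v in self.values.values():
            return v.shape[0]
        return 0


def _evaluate_components(decomp, xs, ys, xy):
    return {
        "main_x": decomp["main_x"].evaluate(xs),
        "main_y": decomp["main_y"].evaluate(ys),
        "interaction": decomp["interaction"].evaluate(xy),
        "intercept": float(decomp["intercept"].evaluate()[0]),
    }


def run_study(
    spec: SimulationSpec, methods=("tensor", "posthoc"), criterion: str = "gcv"
) -> StudyResult:
    """Run all replicates of a study for the requested methods.

    ``tensor`` fits the block tensor-product SS-ANOVA; ``posthoc`` fits
    a single thin-plate spline and decomposes it with the averaging
    operators.  Replicates whose fit fails are recorded and excluded;
    more than 5% failures aborts the study.
    """
    methods = tuple(methods)
    if not methods:
        raise ValueError("need at least one method")
    for method in methods:
        if method not in ("tensor", "posthoc"):
            raise ValueError(f"unknown method {method!r}")
    xs = np.linspace(0.0, 1.0, spec.grid_1d)
    ys = np.linspace(0.0, 1.0, spec.grid_1d)
    g2 = np.linspace(0.0, 1.0, spec.grid_2d)
    XX, YY = np.meshgrid(g2, g2, indexing="ij")
    xy = np.column_stack([XX.ravel(), YY.ravel()])
    measures = (
        make_measure("lebesgue", (0.0, 1.0), order=32),
        make_measure("lebesgue", (0.0, 1.0), order=32),
    )
    tps = make_tps_kernel(((0.0, 1.0), (0.0, 1.0)))

    rows: dict = {(m, c): [] for m in methods for c in COMPONENTS}
    icpt: dict = {m: [] for m in methods}
    failures = []
    for rep in range(spec.reps):
        obs = sample_dataset(spec, rep)
        try:
            rep_evals = {}
            for method in methods:
                if method == "tensor":
                    _, decomp = classic_ssanova(
                        obs, measures=measures, criterion=criterion
                    )
                else:
                    fit = fit_spline(tps, obs, criterion=criterion)
                    decomp = posthoc_decompose(fit, measures)
                rep_evals[method] = _evaluate_components(decomp, xs, ys, xy)
        except Exception as exc:  # noqa: BLE001 - record & skip bad replicate
            failures.append((rep, repr(exc)))
            continue
        for method in methods:
            for c in COMPONENTS:
                rows[(method, c)].append(rep_evals[method][c])
            icpt[method].append(rep_evals[method]["intercept"])
    if len(failures) > 0.05 * spec.reps:
        raise RuntimeError(
            f"study failed: {len(failures)}/{spec.reps} replicates errored; "
            f"first: {failures[0]}"
        )
    values = {k: np.asarray(v) for k, v in rows.items()}
    intercepts = {m: np.asarray(v) for m, v in icpt.items()}
    return StudyResult(
        spec=spec,
        methods=methods,
        xs=xs,
        ys=ys,
        xy=xy,
        values=values,
        intercepts=intercepts,
        failures=failures,
    )


def trace_variability(
    result: StudyResult, component: str, method: str, per_point: bool = False
) -> float:
    """Trace of the across-replicate covariance of grid values.

    Equals the sum over grid points of the across-replicate variance
    (sample variance, ddof=1).  ``per_point=True`` divides by the number
    of grid points, decoupling the summary from grid resolution.
    """
    vals = result.values[(method, component)]
    if vals.shape[0] < 2:
        raise ValueError("trace variability needs at least 2 replicates")
    tr = float(np.sum(np.var(vals, axis=0, ddof=1)))
    return tr / vals.shape[1] if per_point else tr


def mean_squared_bias(
    result: StudyResult, component: str, method: str, truth=None
) -> float:
    """Grid average of (across-replicate mean - true component)^2."""
    vals = result.values[(method, component)]
    mean = vals.mean(axis=0)
    if truth is None:
        truth = true_decomposition(result.spec.function_id)[component]
    if callable(truth):
        if component == "main_x":
            tvals = np.asarray(truth(result.xs), dtype=float)
        elif component == "main_y":
            tvals = np.asarray(truth(result.ys), dtype=float)
        else:
            tvals = np.asarray(truth(result.xy[:, 0], result.xy[:, 1]), dtype=float)
    else:
        tvals = np.asarray(truth, dtype=float)
    if tvals.shape != mean.shape:
        raise ValueError("truth grid does not match the metric grid")
    return float(np.mean((mean - tvals) ** 2))


def metrics_table(results) -> pd.DataFrame:
    """Assemble variability and MSB metrics for one or more studies.

    Rows: tr and MSB for f_x, f_y, f_xy; columns: (method, n) pairs.
    """
    if isinstance(results, StudyResult):
        results = [results]
    cols = {}
    for res in results:
        truths = true_decomposition(res.spec.function_id)
        for method in res.methods:
            col = {}
            for comp, short in zip(COMPONENTS, ("fx", "fy", "fxy")):
                col[f"tr_{short}"] = trace_variability(res, comp, method)
                col[f"msb_{short}"] = mean_squared_bias(
                    res, comp, method, truths[comp]
                )
            cols[(method, res.spec.n)] = col
    order = ["tr_fx", "tr_fy", "tr_fxy", "msb_fx", "msb_fy", "msb_fxy"]
    df = pd.DataFrame(cols).reindex(order)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["method", "n"])
    return df
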