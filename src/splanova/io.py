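"""Tabular input and component output for the command-line tools."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import Decomposition, significance_mask

log = logging.getLogger("splanova")

__all__ = ["read_table", "write_components", "read_components"]


def read_table(path, columns: dict[str, str]) -> pd.DataFrame:
    """Read a CSV/TSV and return the mapped columns, renamed to roles.

    ``columns`` maps role -> column name (e.g. {"x": "freq_prev",
    "z": "dur_log"}).  Rows with missing values in any mapped column are
    dropped with a logged count; a missing column or a non-numeric
    covariate raises with a message naming the offender.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    out = {}
    for role, col in columns.items():
        if col not in df.columns:
            raise ValueError(f"column '{col}' not found in {path.name}")
        out[role] = df[col]
    table = pd.DataFrame(out)
    numeric_roles = [r for r in table.columns if not r.startswith("factor")]
    for role in numeric_roles:
        coerced = pd.to_numeric(table[role], errors="coerce")
        bad = coerced.isna() & table[role].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column '{columns[role]}' at row "
                f"{int(np.flatnonzero(bad)[0])}"
            )
        table[role] = coerced
    n0 = len(table)
    table = table.dropna().reset_index(drop=True)
    if len(table) < n0:
        log.warning("dropped %d row(s) with missing mapped values", n0 - len(table))
    return table


def write_components(
    decomp: Decomposition,
    grid: int,
    out_dir,
    k_sd: float = 2.0,
    metadata: dict | None = None,
) -> Path:
    """Write a decomposition to ``out_dir`` in long format.

    ``components.csv`` columns: component, x, y, mean, sd, significant
    (|mean| >= k_sd * sd); intercept rows leave x and y empty.  A
    ``metadata.json`` records the kernel, smoothing parameters, measures
    and anything passed in ``metadata`` — enough to re-run the command.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (lox, hix), (loy, hiy) = decomp.fit.kernel.domain
    xs = np.linspace(lox, hix, grid)
    ys = np.linspace(loy, hiy, grid)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    P = np.column_stack([XX.ravel(), YY.ravel()])
    rows = []

    def add(label, xvals, yvals, pts):
        comp = decomp[label]
        mean = comp.evaluate(pts)
        sd = comp.sd(pts)
        sig = significance_mask(comp, pts, k=k_sd)
        for i in range(mean.size):
            rows.append(
                {
                    "component": label,
                    "x": "" if xvals is None else xvals[i],
                    "y": "" if yvals is None else yvals[i],
                    "mean": mean[i],
                    "sd": sd[i],
                    "significant": bool(sig[i]),
                }
            )

    add("intercept", None, None, None)
    add("main_x", xs, None, xs)
    add("main_y", None, ys, ys)
    add("interaction", P[:, 0], P[:, 1], P)
    table = pd.DataFrame(rows)
    csv_path = out_dir / "components.csv"
    table.to_csv(csv_path, index=False)

    meta = {
        "lambda": decomp.fit.lam,
        "edf": decomp.fit.edf,
        "sigma2": decomp.fit.sigma2,
        "criterion": decomp.fit.criterion,
        "theta": list(decomp.fit.theta) if decomp.fit.theta else None,
        "kernel": type(decomp.fit.kernel).__name__,
        "measures": [
            {"kind": m.kind, "order": int(m.nodes.size), "domain": list(m.domain)}
            for m in decomp.measures
        ],
        "grid": grid,
        "sd_multiplier": k_sd,
    }
    if metadata:
        meta.update(metadata)
    from . import __version__

    meta["package_version"] = __version__
    with open(out_dir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return csv_path


def read_components(path) -> pd.DataFrame:
    """Round-trip reader for a components.csv file."""
    return pd.read_csv(path)
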