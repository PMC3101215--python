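"""Tabular input/output for the command-line interface."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .timecourse import FitResult, Mode, TimeCourse, from_long_format

__all__ = ["read_table", "round_to_granularity", "write_results"]


def round_to_granularity(values: np.ndarray, granularity: float) -> np.ndarray:
    """Round each value to the nearest multiple of ``granularity``,
    half-up on ties (102.5 at granularity 5 -> 105)."""
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    return np.floor(np.asarray(values, dtype=float) / granularity + 0.5) * granularity


def read_table(
    path,
    time_col: str = "time",
    response_col: str = "response",
    mode: Mode | str = Mode.CONTINUOUS,
    rounding: float | None = None,
    sep: str | None = None,
) -> TimeCourse:
    """Parse a long-format CSV/TSV (one row per observation) into a
    TimeCourse, optionally rounding the time variable before grouping.

    Errors carry 1-based data-row numbers (header excluded).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in (time_col, response_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    t = pd.to_numeric(df[time_col], errors="coerce")
    y = pd.to_numeric(df[response_col], errors="coerce")
    for name, col in ((time_col, t), (response_col, y)):
        bad = col.index[col.isna()]
        if len(bad):
            raise ValueError(f"{path}: unparseable {name!r} value at row {bad[0] + 1}")
    t = t.to_numpy(dtype=float)
    y = y.to_numpy(dtype=float)
    mode = Mode(mode)
    if mode is Mode.BINARY:
        bad = np.nonzero(~((y == 0.0) | (y == 1.0)))[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"{path}: non-binary response {y[i]!r} at row {i + 1} in binary mode"
            )
    if rounding is not None:
        t = round_to_granularity(t, rounding)
    return from_long_format(zip(t, y), mode)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_results(
    fit: FitResult,
    tc: TimeCourse,
    outdir,
    prefix: str = "result",
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
    extra: dict | None = None,
) -> dict[str, Path]:
    """Write the block table, the pointwise table and a JSON summary.

    Returns the paths written. Numbers are serialised at full (repr)
    precision, so identical fits give byte-identical JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "blocks": outdir / f"{prefix}_blocks.tsv",
        "pointwise": outdir / f"{prefix}_pointwise.tsv",
        "summary": outdir / f"{prefix}_summary.json",
    }

    blocks = fit.partition.blocks
    block_rows = []
    for k, b in enumerate(blocks):
        block_rows.append(
            {
                "block": k + 1,
                "start_time": tc.times[b.start - 1],
                "end_time": tc.times[b.end - 1],
                "n_obs": int(tc.m[b.start - 1 : b.end].sum()),
                "estimate": fit.block_estimates[k],
                "p_vs_next": fit.junction_pvalues[k] if k < len(blocks) - 1 else np.nan,
            }
        )
    pd.DataFrame(block_rows).to_csv(paths["blocks"], sep="\t", index=False)

    pw = pd.DataFrame({"time": tc.times, "estimate": fit.pointwise_estimates})
    if lower is not None:
        pw["lower"] = lower
    if upper is not None:
        pw["upper"] = upper
    pw.to_csv(paths["pointwise"], sep="\t", index=False)

    from . import __version__

    summary = {
        "version": __version__,
        "method": fit.method,
        "mode": tc.mode.value,
        "alpha": fit.alpha,
        "n_time_points": tc.n,
        "n_observations": tc.N,
        "n_blocks": fit.n_blocks,
        "change_points": list(fit.change_points),
        "objective": fit.objective,
        "sigma2_hat": fit.sigma2_hat,
        "feasible": fit.feasible,
        "junction_pvalues": fit.junction_pvalues.tolist(),
    }
    if extra:
        summary.update(extra)
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return paths
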