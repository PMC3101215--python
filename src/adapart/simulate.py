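"""Synthetic scenarios and the evaluation metrics used to compare methods.

Four default mean profiles (single step, flat null, three-level multi-step,
small-amplitude U shape) with i.i.d. Gaussian noise (or Bernoulli draws in
binary mode) at each of n equally spaced time points, m replicates each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import fit_recursive_combination, fit_recursive_partition
from .dp import fit_dp
from .model_selection import DEFAULT_ALPHA_GRID, FITTERS
from .timecourse import FitResult, Mode, TimeCourse
from .twosample import TestSpec

__all__ = [
    "ScenarioSpec",
    "ComparisonReport",
    "make_profile",
    "default_scenarios",
    "simulate_scenario",
    "overall_mse",
    "pointwise_stats",
    "run_comparison",
]


def make_profile(
    shape: str,
    n: int,
    levels: Sequence[float] | None = None,
    breaks: Sequence[int] | None = None,
) -> np.ndarray:
    """Piecewise-constant mean profile of length n.

    shape: 'flat' (one level), 'step' (two levels, break at n//2),
    'multistep' / 'ushape' (arbitrary levels over equal thirds by default).
    ``breaks`` are 1-based indices of the last time point of each segment
    but the final one.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    defaults = {
        "flat": ([0.0], []),
        "step": ([0.0, 1.0], [n // 2]),
        "multistep": ([0.0, 1.0, 0.3], [n // 3, 2 * n // 3]),
        "ushape": ([0.5, 0.0, 0.5], [n // 3, 2 * n // 3]),
    }
    if shape not in defaults:
        raise ValueError(f"unknown profile shape {shape!r}")
    lv, br = defaults[shape]
    if levels is not None:
        lv = list(levels)
    if breaks is not None:
        br = list(breaks)
    if len(br) != len(lv) - 1:
        raise ValueError("need one break fewer than levels")
    if any(not (0 < b < n) for b in br) or list(br) != sorted(set(br)):
        raise ValueError("breaks must be strictly increasing inside 1..n-1")
    mu = np.empty(n)
    bounds = [0] + list(br) + [n]
    for level, a, b in zip(lv, bounds, bounds[1:]):
        mu[a:b] = level
    return mu


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one synthetic time course."""

    name: str
    mu: np.ndarray = field(repr=False)
    sigma: float = 1.0
    m: int = 10
    mode: Mode = Mode.CONTINUOUS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "mode", Mode(self.mode))
        if self.mu.size < 2:
            raise ValueError("need at least two time points")
        if self.mode is Mode.CONTINUOUS and self.sigma <= 0:
            raise ValueError("sigma must be positive in continuous mode")
        if self.mode is Mode.BINARY and not np.all((self.mu >= 0) & (self.mu <= 1)):
            raise ValueError("binary-mode means must lie in [0, 1]")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def n(self) -> int:
        return int(self.mu.size)


def default_scenarios(
    m: int = 10, sigma: float = 1.0, mode: Mode | str = Mode.CONTINUOUS, seed: int = 0
) -> list[ScenarioSpec]:
    """The four default scenarios: step, flat, multi-step, U shape."""
    mode = Mode(mode)
    shapes = [("step", 20), ("flat", 20), ("multistep", 30), ("ushape", 30)]
    out = []
    for shape, n in shapes:
        mu = make_profile(shape, n)
        if mode is Mode.BINARY:
            # keep probabilities away from {0, 1}
            mu = 0.2 + 0.6 * (mu - mu.min()) / max(mu.ptp(), 1.0)
        out.append(ScenarioSpec(shape, mu, sigma=sigma, m=m, mode=mode, seed=seed))
    return out


def simulate_scenario(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> tuple[TimeCourse, np.ndarray]:
    """Draw one dataset: y_ij = mu_i + sigma*eps (continuous) or
    Bernoulli(mu_i) (binary). Returns the TimeCourse and the true means."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    times = np.arange(1, spec.n + 1, dtype=float)
    if spec.mode is Mode.CONTINUOUS:
        obs = [spec.mu[i] + spec.sigma * rng.standard_normal(spec.m) for i in range(spec.n)]
    else:
        obs = [rng.binomial(1, spec.mu[i], size=spec.m).astype(float) for i in range(spec.n)]
    return TimeCourse(times, obs, spec.mode), spec.mu.copy()


def overall_mse(fit: FitResult, truth: np.ndarray, tc: TimeCourse) -> float:
    """Observation-weighted error of the fitted means:
    sum_i m_i (muhat_i - mu_i)^2 / N."""
    truth = np.asarray(truth, dtype=float)
    if truth.size != tc.n:
        raise ValueError("truth length must match the number of time points")
    d = fit.pointwise_estimates - truth
    return float(np.sum(tc.m * d * d) / tc.N)


def pointwise_stats(
    estimates: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-time-point (mse, bias, variance) over an R x n table of
    estimates. The variance denominator is R (not R-1) so that
    mse = bias^2 + variance holds exactly."""
    est = np.asarray(estimates, dtype=float)
    if est.ndim != 2:
        raise ValueError("estimates must be an R x n table")
    truth = np.asarray(truth, dtype=float)
    dev = est - truth[None, :]
    mse = np.mean(dev * dev, axis=0)
    bias = np.mean(dev, axis=0)
    centred = est - est.mean(axis=0, keepdims=True)
    var = np.mean(centred * centred, axis=0)
    return mse, bias, var


@dataclass(frozen=True)
class ComparisonReport:
    """Tidy per-(scenario, method, replicate) records of the best overall
    MSE over the alpha grid and the alpha attaining it."""

    records: pd.DataFrame

    def ratios(self) -> pd.DataFrame:
        """Per-replicate best-MSE and selected-alpha ratios of each
        baseline against dp."""
        wide_mse = self.records.pivot_table(
            index=["scenario", "m", "replicate"], columns="method", values="best_mse"
        )
        wide_a = self.records.pivot_table(
            index=["scenario", "m", "replicate"], columns="method", values="best_alpha"
        )
        out = pd.DataFrame(index=wide_mse.index)
        for meth in wide_mse.columns:
            if meth == "dp":
                continue
            out[f"mse_ratio_{meth}_dp"] = wide_mse[meth] / wide_mse["dp"]
            out[f"alpha_ratio_{meth}_dp"] = wide_a[meth] / wide_a["dp"]
        return out.reset_index()

    def summary(self) -> pd.DataFrame:
        return (
            self.records.groupby(["scenario", "m", "method"])[["best_mse", "best_alpha"]]
            .median()
            .reset_index()
        )

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def run_comparison(
    scenarios: Sequence[ScenarioSpec],
    methods: Sequence[str] = ("dp", "rc", "rp"),
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    R: int = 100,
    seed: int = 0,
) -> ComparisonReport:
    """Replicate the simulation comparison: per replicate and method, fit at
    every alpha in the grid and record the minimum overall MSE together
    with the alpha attaining it (ties -> smallest alpha)."""
    if R < 1:
        raise ValueError("R must be >= 1")
    for meth in methods:
        if meth not in FITTERS:
            raise ValueError(f"unknown method {meth!r}")
    grid = sorted(float(a) for a in alpha_grid)
    rows: list[dict] = []
    for si, sc in enumerate(scenarios):
        spec = TestSpec.for_mode(sc.mode)
        for rep in range(R):
            rng = np.random.default_rng(np.random.SeedSequence([seed, si, rep]))
            tc, truth = simulate_scenario(sc, rng=rng)
            for meth in methods:
                fitter = FITTERS[meth]
                best_mse = None
                best_alpha = None
                for a in grid:  # ascending, strict < keeps the smallest alpha on ties
                    fit = fitter(tc, a, spec)
                    mse = overall_mse(fit, truth, tc)
                    if best_mse is None or mse < best_mse:
                        best_mse, best_alpha = mse, a
                rows.append(
                    {
                        "scenario": sc.name,
                        "m": sc.m,
                        "method": meth,
                        "replicate": rep,
                        "best_mse": best_mse,
                        "best_alpha": best_alpha,
                    }
                )
    return ComparisonReport(records=pd.DataFrame(rows))
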