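"""Cross-validated choice of the significance level alpha.

Alpha acts as a smoothing parameter: a smaller value yields fewer blocks.
Folds split *observations* (not time points); a held-out observation whose
time point vanished from the training data is predicted by linear
interpolation between the nearest fitted time points, with constant
extrapolation outside the training range. Ties in CV error go to the
smallest alpha, which gives the most significant junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .baselines import fit_recursive_combination, fit_recursive_partition
from .dp import fit_dp
from .timecourse import FitResult, Mode, TimeCourse, group_records
from .twosample import TestSpec

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "CVSpec",
    "AlphaSelection",
    "predict_heldout",
    "cv_error",
    "cv_errors",
    "select_alpha",
    "FITTERS",
]

# 12-value default grid spanning the levels reported in applications
DEFAULT_ALPHA_GRID: tuple[float, ...] = (
    1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5,
)

FITTERS: dict[str, Callable[..., FitResult]] = {
    "dp": fit_dp,
    "rc": fit_recursive_combination,
    "rp": fit_recursive_partition,
}


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation layout: leave-one-out or seeded k-fold over
    observations, squared-error loss (log-loss optional in binary mode)."""

    scheme: str = "loo"
    k: int = 10
    seed: int = 0
    loss: str = "squared"

    def __post_init__(self) -> None:
        if self.scheme not in ("loo", "kfold"):
            raise ValueError("scheme must be 'loo' or 'kfold'")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2 for kfold")
        if self.loss not in ("squared", "log"):
            raise ValueError("loss must be 'squared' or 'log'")


@dataclass(frozen=True)
class AlphaSelection:
    grid: tuple[float, ...]
    cv_errors: np.ndarray = field(repr=False)
    chosen: float = 0.0


def predict_heldout(fit: FitResult, train_tc: TimeCourse, time: float) -> float:
    """Fitted value at ``time``: the block estimate if the time point was in
    training, linear interpolation between the two nearest training points
    otherwise, constant extrapolation beyond the range."""
    if train_tc.n == 0:  # pragma: no cover - unreachable by construction
        raise ValueError("empty training set")
    return float(np.interp(float(time), train_tc.times, fit.pointwise_estimates))


def _fold_indices(N: int, cv: CVSpec) -> list[np.ndarray]:
    if cv.scheme == "loo":
        return [np.array([i]) for i in range(N)]
    rng = np.random.default_rng(cv.seed)
    perm = rng.permutation(N)
    return [f for f in np.array_split(perm, cv.k) if f.size]


def _loss(y: np.ndarray, pred: np.ndarray, loss: str) -> float:
    if loss == "squared":
        return float(np.sum((y - pred) ** 2))
    eps = 1e-12
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def cv_errors(
    tc: TimeCourse,
    grid: Sequence[float],
    spec: TestSpec | None = None,
    cv: CVSpec = CVSpec(),
    method: str = "dp",
) -> np.ndarray:
    """Total held-out prediction error per alpha in ``grid``.

    Shares the per-fold training course (and its junction p-value cache)
    across the whole grid, so a full grid costs little more than one alpha.
    """
    if method not in FITTERS:
        raise ValueError(f"unknown method {method!r}")
    if spec is None:
        spec = TestSpec.for_mode(tc.mode)
    fitter = FITTERS[method]
    zt = tc.expanded_times()
    zy = tc.pooled()
    N = tc.N
    errors = np.zeros(len(grid))
    for fold in _fold_indices(N, cv):
        mask = np.ones(N, dtype=bool)
        mask[fold] = False
        if not mask.any():
            raise ValueError("a training fold has zero observations")
        tc_train = group_records(zt[mask], zy[mask], tc.mode)
        for gi, a in enumerate(grid):
            fit = fitter(tc_train, a, spec)
            preds = np.interp(zt[fold], tc_train.times, fit.pointwise_estimates)
            errors[gi] += _loss(zy[fold], preds, cv.loss)
    return errors


def cv_error(
    tc: TimeCourse,
    alpha: float,
    spec: TestSpec | None = None,
    cv: CVSpec = CVSpec(),
    method: str = "dp",
) -> float:
    """Total CV prediction error at a single alpha."""
    return float(cv_errors(tc, [alpha], spec=spec, cv=cv, method=method)[0])


def select_alpha(
    tc: TimeCourse,
    grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    spec: TestSpec | None = None,
    cv: CVSpec = CVSpec(),
    method: str = "dp",
) -> AlphaSelection:
    """Pick the alpha from ``grid`` minimising CV error (ties -> smallest)."""
    if len(grid) == 0:
        raise ValueError("alpha grid must be non-empty")
    grid_sorted = tuple(sorted(float(a) for a in grid))
    errs = cv_errors(tc, grid_sorted, spec=spec, cv=cv, method=method)
    chosen = grid_sorted[int(np.argmin(errs))]  # argmin returns first minimum
    return AlphaSelection(grid=grid_sorted, cv_errors=errs, chosen=chosen)
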