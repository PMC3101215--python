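"""Data model for replicated time-course observations.

A :class:`TimeCourse` holds ``n`` strictly increasing distinct time values
with ``m_i >= 1`` replicate responses each (``N`` observations in total).
Prefix sums over the expanded observation vector give O(1) summaries
(count, sum, sum of squares) for any block of consecutive time points,
which is what makes the dynamic program cheap.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import xlogy

__all__ = [
    "Mode",
    "TimeCourse",
    "Block",
    "Partition",
    "FitResult",
    "from_long_format",
    "group_records",
    "block_stats",
    "block_negloglik",
    "partition_objective",
    "estimate_variance",
]


class Mode(str, enum.Enum):
    """Response type: Gaussian (SSE objective) or Bernoulli (NLL objective)."""

    CONTINUOUS = "continuous"
    BINARY = "binary"


class TimeCourse:
    """Ordered distinct time points with per-point replicate observations.

    Parameters
    ----------
    times
        Strictly increasing distinct time values.
    observations
        One non-empty sequence of responses per time point. In binary mode
        every response must be 0 or 1.
    mode
        ``Mode.CONTINUOUS`` or ``Mode.BINARY`` (or their string values).
    """

    __slots__ = (
        "times",
        "observations",
        "mode",
        "n",
        "m",
        "N",
        "_pc",
        "_ps",
        "_pss",
        "_pvalue_cache",
    )

    def __init__(
        self,
        times: Sequence[float],
        observations: Sequence[Sequence[float]],
        mode: Mode | str = Mode.CONTINUOUS,
    ) -> None:
        times_arr = np.asarray(times, dtype=float)
        if times_arr.ndim != 1 or times_arr.size == 0:
            raise ValueError("no observations")
        if times_arr.size > 1 and np.any(np.diff(times_arr) <= 0):
            raise ValueError("times must be strictly increasing with no duplicates")
        if len(observations) != times_arr.size:
            raise ValueError(
                f"got {times_arr.size} times but {len(observations)} observation groups"
            )
        obs = [np.asarray(o, dtype=float) for o in observations]
        for i, o in enumerate(obs):
            if o.ndim != 1 or o.size == 0:
                raise ValueError(f"time point {times_arr[i]} has no observations")
        mode = Mode(mode)
        if mode is Mode.BINARY:
            for i, o in enumerate(obs):
                if not np.all((o == 0.0) | (o == 1.0)):
                    raise ValueError(
                        f"non-binary response at time {times_arr[i]} in binary mode"
                    )

        self.times = times_arr
        self.observations = obs
        self.mode = mode
        self.n = int(times_arr.size)
        self.m = np.array([o.size for o in obs], dtype=np.int64)
        self.N = int(self.m.sum())
        # prefix stats; position 0 is the empty prefix
        self._pc = np.concatenate(([0], np.cumsum(self.m)))
        self._ps = np.concatenate(([0.0], np.cumsum([float(o.sum()) for o in obs])))
        self._pss = np.concatenate(
            ([0.0], np.cumsum([float(np.square(o).sum()) for o in obs]))
        )
        # junction p-values depend only on the data, never on alpha, so they
        # are memoised on the instance and shared across fits
        self._pvalue_cache: dict = {}

    # ------------------------------------------------------------------
    def pooled(self) -> np.ndarray:
        """All responses concatenated in time order."""
        return np.concatenate(self.observations)

    def expanded_times(self) -> np.ndarray:
        """Time value of each of the N observations (the expanded variable)."""
        return np.repeat(self.times, self.m)

    def with_flat_observations(self, values: np.ndarray) -> "TimeCourse":
        """Same time grid/replicate structure, responses replaced by ``values``."""
        values = np.asarray(values, dtype=float)
        if values.size != self.N:
            raise ValueError(f"expected {self.N} values, got {values.size}")
        splits = np.split(values, self._pc[1:-1])
        return TimeCourse(self.times, splits, self.mode)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TimeCourse(n={self.n}, N={self.N}, mode={self.mode.value!r}, "
            f"times=[{self.times[0]:g}..{self.times[-1]:g}])"
        )


def group_records(
    times: np.ndarray, values: np.ndarray, mode: Mode | str = Mode.CONTINUOUS
) -> TimeCourse:
    """Group parallel (time, response) arrays into a :class:`TimeCourse`.

    Sorting is stable, so input order is preserved within a time point.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise ValueError("no observations")
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    y_sorted = values[order]
    uniq, start_idx = np.unique(t_sorted, return_index=True)
    groups = np.split(y_sorted, start_idx[1:])
    return TimeCourse(uniq, groups, mode)


def from_long_format(
    records: Iterable[tuple[float, float]], mode: Mode | str = Mode.CONTINUOUS
) -> TimeCourse:
    """Build a :class:`TimeCourse` from an iterable of (time, response) pairs.

    Raises ``ValueError`` on empty input, and in binary mode names the
    offending record if a response is not 0/1.
    """
    recs = list(records)
    if not recs:
        raise ValueError("no observations")
    mode = Mode(mode)
    t = np.array([r[0] for r in recs], dtype=float)
    y = np.array([r[1] for r in recs], dtype=float)
    if mode is Mode.BINARY:
        bad = np.nonzero(~((y == 0.0) | (y == 1.0)))[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"non-binary response {y[i]!r} at record {i + 1} (time {t[i]!r})"
            )
    return group_records(t, y, mode)


@dataclass(frozen=True)
class Block:
    """A run of consecutive time points, 1-based inclusive indices."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid block [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Partition:
    """Consecutive non-overlapping blocks covering time points 1..n."""

    blocks: tuple[Block, ...]
    change_points: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("empty partition")
        if self.blocks[0].start != 1:
            raise ValueError("partition must start at time point 1")
        for left, right in zip(self.blocks, self.blocks[1:]):
            if right.start != left.end + 1:
                raise ValueError(
                    f"blocks [{left.start},{left.end}] and "
                    f"[{right.start},{right.end}] are not consecutive"
                )
        if self.change_points and len(self.change_points) != len(self.blocks) - 1:
            raise ValueError("change_points must have one entry per junction")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def boundaries(self) -> tuple[int, ...]:
        """End index of every block but the last (the junction positions)."""
        return tuple(b.end for b in self.blocks[:-1])


def make_partition(blocks: Sequence[Block], tc: TimeCourse) -> Partition:
    """Partition with change points reported as the time value of the last
    point of each left block (documented convention)."""
    cps = tuple(float(tc.times[b.end - 1]) for b in blocks[:-1])
    return Partition(tuple(blocks), cps)


@dataclass(frozen=True)
class FitResult:
    """A fitted significance-restricted partition.

    ``pointwise_estimates[i]`` equals the estimate of the block containing
    time point i+1; ``objective`` is the total SSE (continuous) or total
    negative log-likelihood (binary), additive over blocks.
    """

    partition: Partition
    block_estimates: np.ndarray
    pointwise_estimates: np.ndarray
    objective: float
    alpha: float
    method: str
    sigma2_hat: float | None = None
    junction_pvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    feasible: bool = True
    triplet_sets: list | None = field(default=None, repr=False, compare=False)

    @property
    def n_blocks(self) -> int:
        return self.partition.n_blocks

    @property
    def change_points(self) -> tuple[float, ...]:
        return self.partition.change_points


# ----------------------------------------------------------------------
# block-level summaries and objectives


def block_stats(tc: TimeCourse, b: Block) -> tuple[int, float, float]:
    """(count, mean, SSE) of the observations in block ``b``, in O(1).

    SSE is computed as sum-of-squares minus count*mean^2; tiny negative
    floating residue is clamped to zero.
    """
    if b.end > tc.n:
        raise ValueError(f"block [{b.start},{b.end}] exceeds n={tc.n}")
    c = int(tc._pc[b.end] - tc._pc[b.start - 1])
    s = float(tc._ps[b.end] - tc._ps[b.start - 1])
    q = float(tc._pss[b.end] - tc._pss[b.start - 1])
    mean = s / c
    sse = q - c * mean * mean
    if sse < 0.0:
        sse = 0.0
    return c, mean, sse


def block_negloglik(tc: TimeCourse, b: Block) -> float:
    """Bernoulli negative log-likelihood of block ``b`` at its MLE proportion.

    With k successes among c observations and p = k/c this is
    -[k ln p + (c-k) ln(1-p)], using the 0*ln(0) = 0 convention.
    """
    if tc.mode is not Mode.BINARY:
        raise ValueError("binary objective on continuous data")
    if b.end > tc.n:
        raise ValueError(f"block [{b.start},{b.end}] exceeds n={tc.n}")
    c = int(tc._pc[b.end] - tc._pc[b.start - 1])
    k = float(tc._ps[b.end] - tc._ps[b.start - 1])
    p = k / c
    nll = -(float(xlogy(k, p)) + float(xlogy(c - k, 1.0 - p)))
    return max(nll, 0.0)


def block_objective(tc: TimeCourse, b: Block) -> float:
    """Mode-appropriate block objective (SSE or negative log-likelihood)."""
    if tc.mode is Mode.BINARY:
        return block_negloglik(tc, b)
    return block_stats(tc, b)[2]


def partition_objective(tc: TimeCourse, p: Partition) -> float:
    """Total objective of a partition: the sum of its block objectives."""
    if p.blocks[-1].end != tc.n:
        raise ValueError(
            f"partition ends at {p.blocks[-1].end} but the course has n={tc.n}"
        )
    total = 0.0
    for b in p.blocks:  # left-to-right accumulation, matching the DP scores
        total += block_objective(tc, b)
    return total


def estimate_variance(tc: TimeCourse, sse: float) -> float:
    """MLE of the common variance: SSE / N (continuous mode only)."""
    if tc.mode is not Mode.CONTINUOUS:
        raise ValueError("variance estimate is defined for continuous mode only")
    if sse < 0:
        raise ValueError("sse must be non-negative")
    return sse / tc.N
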