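"""Modified dynamic program for significance-restricted segmentation.

The DP state at time point t is a *triplet set* S_t: records
``(link, index, score)`` where ``link`` is the time point right before the
last block of a candidate partition of 1..t, ``index`` locates the
predecessor record inside S_link, and ``score`` is the accumulated
objective (SSE or Bernoulli NLL). S_t holds at most one record per link
value — the lowest-scoring feasible one — and is kept sorted by score.

Feasibility screening: a predecessor record in S_s may be linked iff its
last block (link+1..s) differs significantly from the new block (s+1..t)
at level alpha. Because that test depends on the predecessor only through
(link, s), scanning S_s in score order and taking the first feasible
record yields the optimal feasible extension per link value, which is what
makes the restricted optimisation globally exact.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .timecourse import (
    Block,
    FitResult,
    Mode,
    TimeCourse,
    block_negloglik,
    block_stats,
    estimate_variance,
    make_partition,
)
from .twosample import TestSpec, junction_pvalue_fn

__all__ = ["Triplet", "fit_dp", "backtrack", "exhaustive_oracle", "assemble_fit"]


class Triplet(NamedTuple):
    """One DP record: predecessor time point, its index in S_link, and the
    accumulated objective of the partition ending here."""

    link: int
    index: int
    score: float


def _objective_fn(tc: TimeCourse):
    """O(1) objective of block (a..b), 1-based inclusive, from prefix stats."""
    pc, ps, pss = tc._pc, tc._ps, tc._pss
    if tc.mode is Mode.BINARY:
        def obj(a: int, b: int) -> float:
            return block_negloglik(tc, Block(a, b))
    else:
        def obj(a: int, b: int) -> float:
            c = pc[b] - pc[a - 1]
            mean = (ps[b] - ps[a - 1]) / c
            sse = (pss[b] - pss[a - 1]) - c * mean * mean
            return sse if sse > 0.0 else 0.0
    return obj


def fit_dp(
    tc: TimeCourse,
    alpha: float,
    spec: TestSpec | None = None,
    keep_triplets: bool = True,
) -> FitResult:
    """Globally optimal partition within the alpha-restricted space.

    Builds the triplet sets S_1..S_n with feasibility screening, then
    backtracks from the lowest-scoring record of S_n. The returned
    ``objective`` is exactly that record's score.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if spec is None:
        spec = TestSpec.for_mode(tc.mode)
    n = tc.n
    obj = _objective_fn(tc)
    pv = junction_pvalue_fn(tc, spec)

    S: list[list[Triplet] | None] = [None] * (n + 1)
    S[1] = [Triplet(0, 0, obj(1, 1))]
    for t in range(2, n + 1):
        # the single-block candidate is always present (and inserted first,
        # which fixes the tie-break order together with the stable sort)
        entries = [Triplet(0, 0, obj(1, t))]
        for s in range(1, t):
            for j, trip in enumerate(S[s]):
                if pv(trip.link + 1, s, t) <= alpha:
                    entries.append(Triplet(s, j, trip.score + obj(s + 1, t)))
                    break
        entries.sort(key=lambda e: e.score)  # stable: insertion order breaks ties
        S[t] = entries

    blocks = backtrack(S, n, 0)
    fit = assemble_fit(
        tc,
        blocks,
        alpha,
        spec,
        method="dp",
        objective=S[n][0].score,
        triplet_sets=S if keep_triplets else None,
    )
    return fit


def backtrack(triplet_sets: Sequence, t: int, position: int = 0) -> list[Block]:
    """Follow (link, index) pointers from ``triplet_sets[t][position]`` back
    to link 0, returning the blocks in left-to-right order."""
    try:
        trip = triplet_sets[t][position]
    except (IndexError, TypeError) as exc:  # pragma: no cover - defensive
        raise RuntimeError("broken triplet chain") from exc
    blocks: list[Block] = []
    cur = t
    while True:
        blocks.append(Block(trip.link + 1, cur))
        if trip.link == 0:
            break
        cur = trip.link
        try:
            trip = triplet_sets[cur][trip.index]
        except (IndexError, TypeError) as exc:
            raise RuntimeError("broken triplet chain") from exc
    blocks.reverse()
    if blocks[0].start != 1:
        raise RuntimeError("broken triplet chain: backtrack did not reach point 1")
    return blocks


def exhaustive_oracle(
    tc: TimeCourse, alpha: float, spec: TestSpec | None = None, max_n: int = 20
) -> FitResult:
    """Brute-force reference: enumerate all 2^(n-1) compositions of 1..n.

    A composition is feasible iff every adjacent junction has p <= alpha
    (the single-block composition is vacuously feasible). Returns the
    feasible composition with minimal objective; ties are broken by
    lexicographic order of the reversed block-start tuple, which coincides
    with the DP's insertion-order convention (smaller last-block start is
    preferred at every level).
    """
    if spec is None:
        spec = TestSpec.for_mode(tc.mode)
    n = tc.n
    if n > max_n:
        raise ValueError(f"exhaustive enumeration guarded at n <= {max_n}")
    obj = _objective_fn(tc)
    pv = junction_pvalue_fn(tc, spec)

    best_score: float | None = None
    best_key: tuple | None = None
    best_blocks: list[Block] | None = None
    for mask in range(1 << (n - 1)):
        starts = [1]
        for i in range(n - 1):
            if (mask >> i) & 1:
                starts.append(i + 2)
        ends = [s - 1 for s in starts[1:]] + [n]
        feasible = True
        for k in range(len(starts) - 1):
            if pv(starts[k], ends[k], ends[k + 1]) > alpha:
                feasible = False
                break
        if not feasible:
            continue
        score = 0.0
        for a, b in zip(starts, ends):  # left-to-right, matching the DP sums
            score += obj(a, b)
        key = tuple(reversed(starts))
        if best_score is None or (score, key) < (best_score, best_key):
            best_score, best_key = score, key
            best_blocks = [Block(a, b) for a, b in zip(starts, ends)]
    assert best_blocks is not None  # single block is always feasible
    return assemble_fit(tc, best_blocks, alpha, spec, method="oracle", objective=best_score)


def assemble_fit(
    tc: TimeCourse,
    blocks: Sequence[Block],
    alpha: float,
    spec: TestSpec,
    method: str,
    objective: float | None = None,
    triplet_sets: list | None = None,
) -> FitResult:
    """Package a block sequence into a :class:`FitResult` with estimates,
    junction p-values and the post-hoc feasibility flag."""
    partition = make_partition(list(blocks), tc)
    estimates = np.empty(len(blocks))
    pointwise = np.empty(tc.n)
    for k, b in enumerate(blocks):
        _, mean, _ = block_stats(tc, b)
        estimates[k] = mean
        pointwise[b.start - 1 : b.end] = mean
    if objective is None:
        obj = _objective_fn(tc)
        objective = 0.0
        for b in blocks:
            objective += obj(b.start, b.end)
    pv = junction_pvalue_fn(tc, spec)
    pvals = np.array(
        [
            pv(left.start, left.end, right.end)
            for left, right in zip(blocks, blocks[1:])
        ]
    )
    feasible = bool(np.all(pvals <= alpha)) if pvals.size else True
    sigma2 = estimate_variance(tc, objective) if tc.mode is Mode.CONTINUOUS else None
    return FitResult(
        partition=partition,
        block_estimates=estimates,
        pointwise_estimates=pointwise,
        objective=float(objective),
        alpha=float(alpha),
        method=method,
        sigma2_hat=sigma2,
        junction_pvalues=pvals,
        feasible=feasible,
        triplet_sets=triplet_sets,
    )
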