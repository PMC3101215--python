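"""Greedy approximations: recursive combination and recursive partition.

Recursive combination (RC) starts from all-singleton blocks and merges;
recursive partition (RP) starts from one block and splits. Both pick, per
loop, the single admissible move that maximises the overall likelihood
(equivalently, minimises the total objective). Neither guarantees the
restricted global optimum the DP delivers.
"""

from __future__ import annotations

from .dp import _objective_fn, assemble_fit
from .timecourse import Block, FitResult, TimeCourse
from .twosample import TestSpec, junction_pvalue_fn

__all__ = ["fit_recursive_combination", "fit_recursive_partition"]


def fit_recursive_combination(
    tc: TimeCourse, alpha: float, spec: TestSpec | None = None
) -> FitResult:
    """Bottom-up merging.

    A pair of adjacent blocks may merge while its junction p-value exceeds
    alpha (the complement of feasibility, so the stopping state is exactly
    the alpha-restricted space); among mergeable pairs the one giving the
    smallest total objective is merged. One merge per loop.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if spec is None:
        spec = TestSpec.for_mode(tc.mode)
    obj = _objective_fn(tc)
    pv = junction_pvalue_fn(tc, spec)

    blocks = [(i, i) for i in range(1, tc.n + 1)]
    objs = [obj(i, i) for i in range(1, tc.n + 1)]
    while len(blocks) > 1:
        best_delta = None
        best_k = None
        for k in range(len(blocks) - 1):
            a, b = blocks[k]
            _, c = blocks[k + 1]
            if pv(a, b, c) > alpha:
                delta = obj(a, c) - objs[k] - objs[k + 1]
                if best_delta is None or delta < best_delta:
                    best_delta = delta
                    best_k = k
        if best_k is None:
            break
        a, _ = blocks[best_k]
        _, c = blocks[best_k + 1]
        blocks[best_k : best_k + 2] = [(a, c)]
        objs[best_k : best_k + 2] = [obj(a, c)]
    return assemble_fit(tc, [Block(a, b) for a, b in blocks], alpha, spec, method="rc")


def fit_recursive_partition(
    tc: TimeCourse,
    alpha: float,
    spec: TestSpec | None = None,
    internal_only: bool = False,
) -> FitResult:
    """Top-down splitting.

    A split of a block is admissible iff every junction test it changes has
    p <= alpha: the new internal junction, plus the left-part-vs-left-
    neighbour and right-part-vs-right-neighbour tests where those
    neighbours exist (the "triplet" for middle blocks, "pair" at the
    boundaries, a single test for the first split). ``internal_only=True``
    switches to the alternative reading that checks only the new internal
    junction. Among admissible splits the one giving the smallest total
    objective is performed; one split per loop.

    RP may terminate in a configuration that is not alpha-feasible overall;
    the returned FitResult's ``feasible`` flag records this.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if spec is None:
        spec = TestSpec.for_mode(tc.mode)
    obj = _objective_fn(tc)
    pv = junction_pvalue_fn(tc, spec)

    blocks = [(1, tc.n)]
    objs = [obj(1, tc.n)]
    while True:
        best_delta = None
        best_move = None
        for k, (a, b) in enumerate(blocks):
            for s in range(a, b):
                if pv(a, s, b) > alpha:
                    continue
                if not internal_only:
                    if k > 0:
                        aL, bL = blocks[k - 1]
                        if pv(aL, bL, s) > alpha:
                            continue
                    if k < len(blocks) - 1:
                        _, bR = blocks[k + 1]
                        if pv(s + 1, b, bR) > alpha:
                            continue
                left, right = obj(a, s), obj(s + 1, b)
                delta = left + right - objs[k]
                if best_delta is None or delta < best_delta:
                    best_delta = delta
                    best_move = (k, s, left, right)
        if best_move is None:
            break
        k, s, left, right = best_move
        a, b = blocks[k]
        blocks[k : k + 1] = [(a, s), (s + 1, b)]
        objs[k : k + 1] = [left, right]
    return assemble_fit(tc, [Block(a, b) for a, b in blocks], alpha, spec, method="rp")
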