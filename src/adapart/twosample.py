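"""Two-sample comparisons that define "significantly different at level alpha".

Continuous responses use the pooled two-sample Student t-test; binary
responses use the two-sample proportion z-test, Fisher's exact test, or an
automatic rule that falls back to Fisher when any 2x2 cell is small.

A junction between two adjacent blocks is *feasible* at level alpha when
the configured test on the pooled block data gives p <= alpha. For
one-sided alternatives "greater"/"less" describe the right block relative
to the left block (monotone-increasing / monotone-decreasing fits).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional

from scipy.special import ndtr, stdtr
from scipy.stats import fisher_exact as _scipy_fisher

from .timecourse import Block, Mode, TimeCourse

__all__ = [
    "Family",
    "Alternative",
    "TestSpec",
    "TestResult",
    "pooled_t_test",
    "prop_z_test",
    "fisher_exact_test",
    "select_binary_test",
    "junction_pvalue",
    "junction_feasible",
    "junction_pvalue_fn",
]


class Family(str, enum.Enum):
    STUDENT_T = "student_t"
    PROPORTION_Z = "proportion_z"
    FISHER_EXACT = "fisher_exact"
    AUTO_BINARY = "auto_binary"


class Alternative(str, enum.Enum):
    TWO_SIDED = "two_sided"
    GREATER = "greater"
    LESS = "less"


@dataclass(frozen=True)
class TestSpec:
    """Which two-sample test to run at block junctions, and its sidedness."""

    __test__ = False  # keep pytest from collecting this as a test class

    family: Family = Family.STUDENT_T
    alternative: Alternative = Alternative.TWO_SIDED

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "alternative", Alternative(self.alternative))

    @classmethod
    def for_mode(cls, mode: Mode | str, alternative: Alternative | str = Alternative.TWO_SIDED) -> "TestSpec":
        mode = Mode(mode)
        family = Family.STUDENT_T if mode is Mode.CONTINUOUS else Family.AUTO_BINARY
        return cls(family, Alternative(alternative))


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample comparison.

    ``statistic`` is None for Fisher's exact test. ``degenerate`` flags the
    small-sample rule (any sample of size < 2 reports p = 1) or a pooled
    proportion of exactly 0 or 1.
    """

    __test__ = False

    statistic: Optional[float]
    pvalue: float
    family_used: Family
    degenerate: bool = False


def _t_pvalue(t: float, df: int, alternative: Alternative) -> float:
    if alternative is Alternative.TWO_SIDED:
        return min(1.0, 2.0 * float(stdtr(df, -abs(t))))
    if alternative is Alternative.GREATER:
        return float(stdtr(df, -t))
    return float(stdtr(df, t))


def _z_pvalue(z: float, alternative: Alternative) -> float:
    if alternative is Alternative.TWO_SIDED:
        return min(1.0, 2.0 * float(ndtr(-abs(z))))
    if alternative is Alternative.GREATER:
        return float(ndtr(-z))
    return float(ndtr(z))


def pooled_t_test(
    n1: int,
    mean1: float,
    ss1: float,
    n2: int,
    mean2: float,
    ss2: float,
    alternative: Alternative | str = Alternative.TWO_SIDED,
) -> TestResult:
    """Pooled-variance two-sample t-test from summary statistics.

    ``ss1``/``ss2`` are within-sample sums of squared deviations. If either
    sample has fewer than two observations the reported p-value is 1
    (degenerate). A zero pooled variance yields p = 1 when the means are
    equal and p = 0 otherwise, with direction respected for one-sided
    alternatives.
    """
    alternative = Alternative(alternative)
    if n1 < 2 or n2 < 2:
        return TestResult(None, 1.0, Family.STUDENT_T, degenerate=True)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    diff = mean1 - mean2
    if s2 <= 0.0:
        if diff == 0.0:
            return TestResult(0.0, 1.0, Family.STUDENT_T)
        stat = math.inf if diff > 0 else -math.inf
        if alternative is Alternative.TWO_SIDED:
            p = 0.0
        elif alternative is Alternative.GREATER:
            p = 0.0 if diff > 0 else 1.0
        else:
            p = 0.0 if diff < 0 else 1.0
        return TestResult(stat, p, Family.STUDENT_T)
    t = diff / math.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    return TestResult(t, _t_pvalue(t, df, alternative), Family.STUDENT_T)


def prop_z_test(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    alternative: Alternative | str = Alternative.TWO_SIDED,
) -> TestResult:
    """Two-sample z-test for proportions with a pooled standard error."""
    alternative = Alternative(alternative)
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if n1 < 2 or n2 < 2:
        return TestResult(None, 1.0, Family.PROPORTION_Z, degenerate=True)
    pbar = (k1 + k2) / (n1 + n2)
    if pbar == 0.0 or pbar == 1.0:
        # all failures or all successes: no evidence of a difference
        return TestResult(0.0, 1.0, Family.PROPORTION_Z, degenerate=True)
    z = (k1 / n1 - k2 / n2) / math.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2))
    return TestResult(z, _z_pvalue(z, alternative), Family.PROPORTION_Z)


_FISHER_ALT = {
    Alternative.TWO_SIDED: "two-sided",
    Alternative.GREATER: "greater",
    Alternative.LESS: "less",
}


@lru_cache(maxsize=1 << 18)
def _fisher_pvalue(k1: int, n1: int, k2: int, n2: int, alt: str) -> float:
    return float(_scipy_fisher([[k1, n1 - k1], [k2, n2 - k2]], alternative=alt).pvalue)


def fisher_exact_test(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    alternative: Alternative | str = Alternative.TWO_SIDED,
) -> TestResult:
    """Fisher's exact test on the 2x2 table [[k1, n1-k1], [k2, n2-k2]].

    Two-sided p-values use the probability-mass convention (sum of tables
    at most as probable as the observed one).
    """
    alternative = Alternative(alternative)
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p = _fisher_pvalue(int(k1), int(n1), int(k2), int(n2), _FISHER_ALT[alternative])
    return TestResult(None, min(p, 1.0), Family.FISHER_EXACT)


def select_binary_test(k1: int, n1: int, k2: int, n2: int) -> Family:
    """Fisher's exact test when any observed 2x2 cell is below six, else z."""
    if min(k1, n1 - k1, k2, n2 - k2) < 6:
        return Family.FISHER_EXACT
    return Family.PROPORTION_Z


# ----------------------------------------------------------------------
# block junctions


def _block_pvalue(tc: TimeCourse, lstart: int, mid: int, rend: int, spec: TestSpec) -> float:
    """p-value comparing block (lstart..mid) against block (mid+1..rend).

    Sample 1 is the right block, sample 2 the left block, so one-sided
    alternatives read right-vs-left.
    """
    pc, ps, pss = tc._pc, tc._ps, tc._pss
    cL = int(pc[mid] - pc[lstart - 1])
    sL = float(ps[mid] - ps[lstart - 1])
    cR = int(pc[rend] - pc[mid])
    sR = float(ps[rend] - ps[mid])
    if tc.mode is Mode.CONTINUOUS:
        if spec.family is not Family.STUDENT_T:
            raise ValueError("continuous mode permits only the Student t family")
        mL = sL / cL
        mR = sR / cR
        ssL = max(float(pss[mid] - pss[lstart - 1]) - cL * mL * mL, 0.0)
        ssR = max(float(pss[rend] - pss[mid]) - cR * mR * mR, 0.0)
        return pooled_t_test(cR, mR, ssR, cL, mL, ssL, spec.alternative).pvalue
    kL, kR = int(round(sL)), int(round(sR))
    family = spec.family
    if family is Family.AUTO_BINARY:
        family = select_binary_test(kR, cR, kL, cL)
    if family is Family.PROPORTION_Z:
        return prop_z_test(kR, cR, kL, cL, spec.alternative).pvalue
    if family is Family.FISHER_EXACT:
        return fisher_exact_test(kR, cR, kL, cL, spec.alternative).pvalue
    raise ValueError(f"family {family} is not valid in binary mode")


def junction_pvalue_fn(tc: TimeCourse, spec: TestSpec) -> Callable[[int, int, int], float]:
    """Memoised ``pv(lstart, mid, rend)`` closure over ``tc``'s cache.

    The cache lives on the TimeCourse, keyed by block indices and the test
    configuration; it is shared across fits at different alpha because
    junction p-values never depend on alpha.
    """
    cache = tc._pvalue_cache
    tag = (spec.family, spec.alternative)

    def pv(lstart: int, mid: int, rend: int) -> float:
        key = (lstart, mid, rend, tag)
        p = cache.get(key)
        if p is None:
            p = _block_pvalue(tc, lstart, mid, rend, spec)
            cache[key] = p
        return p

    return pv


def junction_pvalue(tc: TimeCourse, left: Block, right: Block, spec: TestSpec) -> float:
    """p-value of the two-sample test between two adjacent blocks."""
    if left.end + 1 != right.start:
        raise ValueError(
            f"blocks [{left.start},{left.end}] and [{right.start},{right.end}] "
            "are not adjacent"
        )
    return junction_pvalue_fn(tc, spec)(left.start, left.end, right.end)


def junction_feasible(
    tc: TimeCourse, left: Block, right: Block, alpha: float, spec: TestSpec
) -> tuple[bool, float]:
    """Whether two adjacent blocks differ significantly at level alpha.

    Feasibility uses p <= alpha (not strict), which reproduces both limit
    behaviours: alpha=0 forbids every junction with a positive p-value and
    alpha=1 admits all junctions including degenerate p=1 ones.
    """
    p = junction_pvalue(tc, left, right, spec)
    return p <= alpha, p
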